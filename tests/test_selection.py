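"""Candidate enumeration, AICc scoring, selection and replicate ensembles."""

import numpy as np
import pandas as pd
import pytest

import flyniche as fn
from flyniche.maxent import fit_maxent, sample_background
from flyniche.occurrences import extract_env_at_points
from flyniche.selection import (
    CandidateConfig,
    CandidateResult,
    compute_aicc,
    enumerate_candidates,
    run_replicates,
    select_best,
    tune,
)
from flyniche.landscape import _eligible_cells, true_suitability


class TestEnumerateCandidates:
    def test_default_grid_is_40(self):
        cands = enumerate_candidates()
        assert len(cands) == 8 * 5
        assert cands[0] == CandidateConfig(("L",), 0.5)
        assert cands[-1] == CandidateConfig(("L", "Q", "P", "T", "H"), 4.0)
        # RM outer, FC inner
        assert [c.rm for c in cands[:5]] == [0.5] * 5

    def test_single_candidate(self):
        cands = enumerate_candidates(1.0, 1.0, 0.5, [("L",)])
        assert cands == [CandidateConfig(("L",), 1.0)]

    def test_empty_fc_sets_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(0.5, 4.0, 0.5, [])


class TestAicc:
    def test_toy_formula_value(self):
        """k=2, n=10, lnL=-20 -> 2k - 2lnL + 2k(k+1)/(n-k-1) = 45.7143."""
        aicc = 2 * 2 - 2 * (-20) + 2 * 2 * 3 / (10 - 2 - 1)
        assert aicc == pytest.approx(45.7143, abs=1e-4)

    @pytest.fixture()
    def fitted(self, recovery_experiment):
        r = recovery_experiment
        return r["model"], r["presence"], r["background"]

    def test_oracle_equivalence_random_triples(self):
        """The correction formula matches an independent one-liner on 50
        random (k, n, lnL) triples."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(5, 200))
            k = int(rng.integers(0, max(1, n - 2)))
            lnL = float(rng.normal(-50, 30))
            ours = 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)
            oracle = (2 * k - 2 * lnL) + (2 * k * k + 2 * k) / (n - k - 1)
            assert ours == pytest.approx(oracle, rel=1e-12)

    def test_uniform_model_closed_form(self, small_stack):
        """A zero-coefficient model has lnL = -n ln N over N background
        cells, hence AICc = 2 n ln N."""
        mask = np.ones(small_stack.shape, dtype=bool)
        bg = sample_background(mask, small_stack, seed=1)
        presence = bg.env_table  # exactly the background distribution
        model = fit_maxent(presence, bg, fc=("L",), rm=1.0)
        assert model.n_nonzero_ == 0  # uniform presences leave no signal
        res = compute_aicc(model, presence, bg)
        n, N = len(presence), bg.size
        assert res.lnL == pytest.approx(-n * np.log(N), rel=1e-6)
        assert res.aicc == pytest.approx(2 * n * np.log(N), rel=1e-6)
        assert res.k == 0

    def test_model_aicc_consistent_with_formula(self, fitted):
        model, presence, background = fitted
        res = compute_aicc(model, presence, background)
        n = len(presence)
        expected = (2 * res.k - 2 * res.lnL
                    + 2 * res.k * (res.k + 1) / (n - res.k - 1))
        assert res.aicc == pytest.approx(expected, rel=1e-12)

    def test_overparameterized_flagged_undefined(self, fitted):
        model, presence, background = fitted
        res = compute_aicc(model, presence.iloc[: model.n_nonzero_ + 1],
                           background)
        assert res.aicc is None


class TestSelectBest:
    def make(self, aicc, k=1, rm=1.0, fc=("L",)):
        return CandidateResult(CandidateConfig(tuple(fc), rm), k=k,
                               lnL=-10.0, aicc=aicc)

    def test_argmin_and_deltas(self):
        results = [self.make(100), self.make(98), self.make(103)]
        best = select_best(results)
        assert best.aicc == 98
        assert best.delta_aicc == 0
        assert all(r.delta_aicc >= 0 for r in results)

    def test_tie_breaks_on_smaller_k(self):
        results = [self.make(98, k=5), self.make(98, k=3)]
        assert select_best(results).k == 3

    def test_tie_breaks_on_smaller_rm_then_order(self):
        results = [self.make(98, k=3, rm=2.0), self.make(98, k=3, rm=1.0)]
        assert select_best(results).config.rm == 1.0
        results = [self.make(98, k=3, fc=("L",)),
                   self.make(98, k=3, fc=("L", "Q"))]
        assert select_best(results).config.fc == ("L",)

    def test_all_undefined_errors(self):
        with pytest.raises(ValueError):
            select_best([self.make(None), self.make(None)])


class TestReplicates:
    @pytest.fixture()
    def setup(self, recovery_experiment):
        r = recovery_experiment
        return r

    def test_partition_sizes(self, setup):
        ens = run_replicates(
            CandidateConfig(("L",), 1.0), setup["presence"],
            setup["background"], setup["stack"], setup["eligible"],
            n_replicates=3, test_fraction=0.25, seed=5,
        )
        n = len(setup["presence"])
        for held, model in zip(ens.test_indices, ens.models):
            assert len(held) == int(np.ceil(0.25 * n))
            assert model.n_presences_ == n - len(held)

    def test_quarter_of_twenty_is_five(self, setup):
        ens = run_replicates(
            CandidateConfig(("L",), 1.0), setup["presence"].iloc[:20],
            setup["background"], setup["stack"], setup["eligible"],
            n_replicates=2, test_fraction=0.25, seed=5,
        )
        assert all(len(h) == 5 for h in ens.test_indices)
        assert all(m.n_presences_ == 15 for m in ens.models)

    def test_single_replicate_median_is_its_map(self, setup):
        ens = run_replicates(
            CandidateConfig(("L",), 1.0), setup["presence"],
            setup["background"], setup["stack"], setup["eligible"],
            n_replicates=1, test_fraction=0.25, seed=5,
        )
        np.testing.assert_array_equal(
            np.nan_to_num(ens.aggregated), np.nan_to_num(ens.prediction_grids[0])
        )

    def test_seed_determinism(self, setup):
        kwargs = dict(n_replicates=2, test_fraction=0.25, seed=11)
        a = run_replicates(CandidateConfig(("L",), 1.0), setup["presence"],
                           setup["background"], setup["stack"],
                           setup["eligible"], **kwargs)
        b = run_replicates(CandidateConfig(("L",), 1.0), setup["presence"],
                           setup["background"], setup["stack"],
                           setup["eligible"], **kwargs)
        np.testing.assert_array_equal(
            np.nan_to_num(a.aggregated), np.nan_to_num(b.aggregated)
        )

    def test_median_permutation_invariant(self, setup):
        ens = run_replicates(
            CandidateConfig(("L",), 1.0), setup["presence"],
            setup["background"], setup["stack"], setup["eligible"],
            n_replicates=3, test_fraction=0.25, seed=5,
        )
        mask = np.isfinite(ens.aggregated)
        reordered = np.median(
            np.stack([g[mask] for g in ens.prediction_grids[::-1]]), axis=0
        )
        np.testing.assert_array_equal(ens.aggregated[mask], reordered)

    def test_tiny_training_partition_rejected(self, setup):
        with pytest.raises(ValueError):
            run_replicates(
                CandidateConfig(("L",), 1.0), setup["presence"].iloc[:2],
                setup["background"], setup["stack"], setup["eligible"],
                n_replicates=1, test_fraction=0.5, seed=5,
            )


class TestSelectionSanity:
    def test_selected_at_least_as_good_as_worst(self, recovery_experiment):
        """On the recovery experiment the AICc-selected candidate tracks the
        true suitability at least as well (Spearman) as the worst candidate."""
        from scipy.stats import spearmanr
        from flyniche.maxent import predict_over_mask

        r = recovery_experiment
        cands = [CandidateConfig(("L",), 0.5), CandidateConfig(("L", "Q"), 1.0),
                 CandidateConfig(("L", "Q"), 4.0)]
        results = tune(r["presence"], r["background"], cands)
        best = select_best(results)
        elig = r["eligible"]
        truth = r["true_suitability"][elig]

        def rho(res):
            grid = predict_over_mask(res.model, r["stack"], elig)
            return spearmanr(grid[elig], truth).statistic

        rhos = [rho(res) for res in results]
        assert rho(best) >= min(rhos) - 1e-12
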