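"""Penalized maximum-entropy model: solver correctness and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import flyniche as fn
from flyniche.maxent import (
    MaxentDensity,
    _solve_penalized,
    fit_maxent,
    jackknife_importance,
    load_lambdas,
    permutation_importance,
    sample_background,
    save_lambdas,
)
from flyniche.occurrences import extract_env_at_points
from flyniche.landscape import _eligible_cells


@pytest.fixture(scope="module")
def informative_fit():
    """200 presences driven by env_1; env_3 replaced by pure iid noise."""
    stack = fn.generate_landscape(50, 50, 3, 6, None, 21)
    stack.env_layers["env_3"] = np.random.default_rng(77).uniform(
        size=stack.shape
    )
    truth = fn.SyntheticSpeciesTruth({"env_1": 4.0}, (0, 4000), seed=22)
    occ = fn.generate_species(stack, truth, 200)
    eligible = np.zeros(stack.shape, dtype=bool)
    eligible.ravel()[_eligible_cells(stack, truth)] = True
    background = sample_background(eligible, stack, seed=23)
    presence = extract_env_at_points(stack, occ, stack.layer_names)
    model = fit_maxent(presence, background, fc=("L", "Q"), rm=1.0)
    return stack, presence, background, model


class TestSampleBackground:
    def test_small_m_uses_all_cells_row_major(self, small_stack):
        mask = np.zeros(small_stack.shape, dtype=bool)
        mask[3:8, 2:12] = True
        bg = sample_background(mask, small_stack, cap=10_000, seed=0)
        assert bg.size == 50
        expected = np.flatnonzero(mask.ravel())
        np.testing.assert_array_equal(bg.cell_indices, expected)

    def test_large_m_capped_at_exact_count(self, stack64):
        mask = np.ones(stack64.shape, dtype=bool)  # 4096 cells
        bg = sample_background(mask, stack64, cap=1000, seed=5)
        assert bg.size == 1000
        assert len(np.unique(bg.cell_indices)) == 1000

    def test_seed_determinism(self, stack64):
        mask = np.ones(stack64.shape, dtype=bool)
        a = sample_background(mask, stack64, cap=500, seed=9)
        b = sample_background(mask, stack64, cap=500, seed=9)
        np.testing.assert_array_equal(a.cell_indices, b.cell_indices)

    def test_empty_m_errors(self, small_stack):
        with pytest.raises(ValueError, match="empty"):
            sample_background(np.zeros(small_stack.shape, bool), small_stack)


class TestSolverOracles:
    def test_two_cell_moment_equation(self):
        """Single binary feature, presence mean 0.75, no penalty:
        lambda solves E_model[f] = 0.75, i.e. lambda = ln 3."""
        F_bg = np.array([[0.0], [1.0]])
        F_pres = np.array([[1.0]] * 3 + [[0.0]])
        sol = _solve_penalized(F_pres, F_bg, np.array([0.0]), 5000, 1e-5)
        # independent oracle: solve e^l/(1+e^l) = 0.75 by bisection
        lo, hi = 0.0, 5.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if np.exp(mid) / (1 + np.exp(mid)) < 0.75:
                lo = mid
            else:
                hi = mid
        assert sol["lambdas"][0] == pytest.approx(lo, abs=1e-6)
        assert sol["lambdas"][0] == pytest.approx(np.log(3), abs=1e-6)
        raw = np.exp(F_bg @ sol["lambdas"] - sol["log_Z"])
        np.testing.assert_allclose(raw, [0.25, 0.75], atol=1e-7)

    def test_two_cell_kkt_boundary_with_penalty(self):
        """With beta = 0.1 the moment sits on the box edge: E_model[f]
        = 0.65 and lambda = ln(0.65/0.35)."""
        F_bg = np.array([[0.0], [1.0]])
        F_pres = np.array([[1.0]] * 3 + [[0.0]])
        sol = _solve_penalized(F_pres, F_bg, np.array([0.1]), 5000, 1e-5)
        assert sol["lambdas"][0] == pytest.approx(np.log(0.65 / 0.35), abs=1e-6)

    def test_uniform_presence_gives_null_model(self, small_stack):
        """Presences drawn exactly uniformly from the background leave no
        signal: all coefficients shrink to (near) zero."""
        mask = np.ones(small_stack.shape, dtype=bool)
        bg = sample_background(mask, small_stack, seed=1)
        presence = bg.env_table  # the exact background distribution
        model = fit_maxent(presence, bg, fc=("L",), rm=1.0)
        assert np.max(np.abs(model.lambdas_)) <= 1e-4
        raw = model.predict(bg.env_table)
        np.testing.assert_allclose(raw, 1 / bg.size, rtol=1e-3)

    def test_grid_search_oracle_equivalence(self):
        """On a 2-feature, 12-cell problem the solver's objective matches a
        dense grid search refined to 1e-4 steps within 1e-5."""
        rng = np.random.default_rng(8)
        F_bg = rng.uniform(size=(12, 2))
        F_pres = F_bg[rng.choice(12, size=6, p=np.linspace(1, 2, 12) / np.sum(np.linspace(1, 2, 12)))]
        betas = np.array([0.02, 0.02])
        sol = _solve_penalized(F_pres, F_bg, betas, 5000, 1e-7)

        pres_mean = F_pres.mean(axis=0)

        def objective(lams):  # independent re-statement of the objective
            s = F_bg @ lams.T
            lse = np.log(np.exp(s).sum(axis=0))
            return (-(lams @ pres_mean) + lse
                    + np.abs(lams) @ betas)

        center = np.zeros(2)
        width = 4.0
        for step in (0.1, 0.01, 1e-3, 1e-4):
            g = np.arange(-width, width + step / 2, step)
            l1, l2 = np.meshgrid(center[0] + g, center[1] + g)
            lams = np.column_stack([l1.ravel(), l2.ravel()])
            vals = objective(lams)
            center = lams[int(vals.argmin())]
            width = 2 * step
        best_grid = objective(center[None, :])[0]
        assert abs(sol["objective"] - best_grid) <= 1e-5

    def test_non_finite_features_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, np.nan, 0.5]})
        y = np.array([1, 0, 0, 0])
        with pytest.raises(ValueError):
            MaxentDensity(fc=("L",)).fit(X, y)


class TestFittedModelInvariants:
    def test_background_normalization(self, informative_fit):
        _, _, background, model = informative_fit
        raw = model.predict(background.env_table)
        assert abs(raw.sum() - 1.0) <= 1e-9

    def test_objective_monotone_nonincreasing(self, informative_fit):
        _, _, _, model = informative_fit
        diffs = np.diff(model.objective_path_)
        assert np.all(diffs <= 1e-10)

    def test_kkt_moment_condition_every_feature(self, informative_fit):
        _, presence, background, model = informative_fit
        F_pres = model.expansion_.transform(presence)
        F_bg = model.expansion_.transform(background.env_table)
        p = np.exp(F_bg @ model.lambdas_ - model.log_Z_)
        gap = np.abs(F_bg.T @ p - F_pres.mean(axis=0))
        assert model.converged_
        assert np.all(gap <= model.betas_ + 1e-6)

    def test_sparsity_monotone_in_rm(self, informative_fit):
        _, presence, background, _ = informative_fit
        m_lo = fit_maxent(presence, background, fc=("L", "Q", "P", "T", "H"),
                          rm=0.5, n_hinge_knots=10, n_threshold_knots=10)
        m_hi = fit_maxent(presence, background, fc=("L", "Q", "P", "T", "H"),
                          rm=4.0, n_hinge_knots=10, n_threshold_knots=10)
        assert m_hi.n_nonzero_ <= m_lo.n_nonzero_

    def test_sklearn_param_interface(self):
        m = MaxentDensity(fc=("L",), rm=2.0)
        assert m.get_params()["rm"] == 2.0
        m.set_params(rm=3.0)
        assert m.rm == 3.0


class TestImportance:
    def test_jackknife_noise_layer_changes_little(self, informative_fit):
        _, presence, background, _ = informative_fit
        jk = jackknife_importance(presence, background, fc=("L", "Q"), rm=1.0)
        full = jk["full_gain"].iloc[0]
        assert abs(jk.loc["env_3", "gain_without"] - full) <= 0.05
        assert abs(jk.loc["env_1", "gain_with_only"] - full) <= 0.05

    def test_jackknife_single_layer_rejected(self, informative_fit):
        _, presence, background, _ = informative_fit
        with pytest.raises(ValueError):
            jackknife_importance(presence[["env_1"]], background)

    def test_permutation_shares_sum_to_100(self, informative_fit):
        _, presence, background, model = informative_fit
        shares = permutation_importance(
            model, presence, background.env_table, n_permutations=3, seed=3
        )
        assert shares.sum() == pytest.approx(100.0)
        assert (shares >= 0).all()

    def test_permutation_noise_layer_small_share(self, informative_fit):
        _, presence, background, model = informative_fit
        shares = permutation_importance(
            model, presence, background.env_table, n_permutations=5, seed=3
        )
        assert shares["env_3"] <= 5.0
        assert shares["env_1"] == shares.max()

    def test_single_layer_share_is_100(self, informative_fit):
        _, presence, background, _ = informative_fit
        from flyniche.maxent import BackgroundSample

        bg1 = BackgroundSample(
            cell_indices=background.cell_indices,
            env_table=background.env_table[["env_1"]],
            size=background.size, seed=background.seed,
        )
        model = fit_maxent(presence[["env_1"]], bg1, fc=("L",), rm=1.0)
        shares = permutation_importance(
            model, presence[["env_1"]], bg1.env_table, n_permutations=2, seed=1
        )
        assert shares.iloc[0] == pytest.approx(100.0)


class TestSerialization:
    def test_lambdas_round_trip_exact(self, informative_fit, tmp_path):
        stack, presence, background, model = informative_fit
        p = tmp_path / "model.lambdas"
        save_lambdas(model, p)
        back = load_lambdas(p)
        np.testing.assert_array_equal(back.lambdas_, model.lambdas_)
        assert back.log_Z_ == model.log_Z_
        np.testing.assert_allclose(
            back.predict(presence), model.predict(presence)
        )
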