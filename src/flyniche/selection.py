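"""Candidate enumeration, AICc model selection, and replicate ensembles.

Tuning follows the regularization-multiplier x feature-class grid
convention: RM from 0.5 to 4.0 in 0.5 steps crossed with the five
feature-class sets L, LQ, LQP, LQPT, LQPTH (40 candidates by default).
Each candidate is fitted on the full presence set and scored by AICc
computed from the background-renormalized raw scores at the presence
cells with k = the number of nonzero coefficients (the Warren-Seifert
convention of the presence-only tuning literature); the candidate with
delta AICc = 0 wins, ties broken by (fewer coefficients, smaller RM,
feature-class order).  The selected configuration is then refitted in
replicates with a held-out test fraction and the per-cell median of the
replicate raw maps is the final suitability estimate.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .landscape import LandscapeStack
from .maxent import (
    BackgroundSample,
    MaxentDensity,
    fit_maxent,
    predict_over_mask,
)

__all__ = [
    "CandidateConfig",
    "CandidateResult",
    "ReplicateEnsemble",
    "DEFAULT_FC_SETS",
    "enumerate_candidates",
    "compute_aicc",
    "tune",
    "select_best",
    "run_replicates",
]

DEFAULT_FC_SETS: tuple[tuple[str, ...], ...] = (
    ("L",),
    ("L", "Q"),
    ("L", "Q", "P"),
    ("L", "Q", "P", "T"),
    ("L", "Q", "P", "T", "H"),
)
DEFAULT_RM_GRID = (0.5, 4.0, 0.5)
LAMBDA_ZERO_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class CandidateConfig:
    fc: tuple[str, ...]
    rm: float

    @property
    def fc_label(self) -> str:
        return "".join(self.fc)


@dataclasses.dataclass
class CandidateResult:
    config: CandidateConfig
    k: int
    lnL: float
    aicc: float | None  # None when k >= n - 1 (correction undefined)
    delta_aicc: float | None = None
    model: MaxentDensity | None = None


def enumerate_candidates(
    rm_min: float = DEFAULT_RM_GRID[0],
    rm_max: float = DEFAULT_RM_GRID[1],
    rm_step: float = DEFAULT_RM_GRID[2],
    fc_sets: Sequence[Sequence[str]] = DEFAULT_FC_SETS,
) -> list[CandidateConfig]:
    """Inclusive RM grid crossed with feature-class sets (RM outer, FC inner)."""
    if rm_step <= 0:
        raise ValueError("rm_step must be > 0")
    if rm_min > rm_max:
        raise ValueError("rm_min must be <= rm_max")
    if not fc_sets:
        raise ValueError("fc_sets must be nonempty")
    n_steps = int(round((rm_max - rm_min) / rm_step))
    rms = [rm_min + i * rm_step for i in range(n_steps + 1)]
    rms = [rm for rm in rms if rm <= rm_max + 1e-12]
    return [
        CandidateConfig(fc=tuple(fc), rm=round(rm, 10))
        for rm in rms
        for fc in fc_sets
    ]


def aicc_formula(k: int, n: int, lnL: float) -> float | None:
    """Small-sample-corrected AIC; None when the correction is undefined."""
    if k >= n - 1:
        return None
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)


def compute_aicc(
    model: MaxentDensity,
    presence_table: pd.DataFrame,
    background: BackgroundSample,
) -> CandidateResult:
    """AICc of a model fitted on the full presence set.

    Raw scores are standardized to sum to one over the background, the
    presence log-likelihood is evaluated under that density, k counts
    coefficients with |lambda| > 1e-8, and

        AICc = 2k - 2 lnL + 2k(k+1)/(n - k - 1),   n = #presences,

    undefined (None) when k >= n - 1.
    """
    raw_bg = model.predict(background.env_table)
    raw_pres = model.predict(presence_table)
    std_pres = raw_pres / raw_bg.sum()
    lnL = float(np.log(std_pres).sum())
    k = int(np.sum(np.abs(model.lambdas_) > LAMBDA_ZERO_TOL))
    n = len(presence_table)
    aicc = aicc_formula(k, n, lnL)
    return CandidateResult(
        config=CandidateConfig(fc=model.expansion_.fc, rm=model.rm),
        k=k, lnL=lnL, aicc=aicc, model=model,
    )


def tune(
    presence_table: pd.DataFrame,
    background: BackgroundSample,
    candidates: Sequence[CandidateConfig] | None = None,
    max_iterations: int = 5000,
    convergence_threshold: float = 1e-5,
    n_hinge_knots: int = 20,
    n_threshold_knots: int = 20,
) -> list[CandidateResult]:
    """Fit and AICc-score every candidate configuration."""
    if candidates is None:
        candidates = enumerate_candidates()
    results = []
    for cand in candidates:
        model = fit_maxent(
            presence_table, background, fc=cand.fc, rm=cand.rm,
            max_iterations=max_iterations,
            convergence_threshold=convergence_threshold,
            n_hinge_knots=n_hinge_knots,
            n_threshold_knots=n_threshold_knots,
        )
        results.append(compute_aicc(model, presence_table, background))
    return results


def select_best(results: Sequence[CandidateResult]) -> CandidateResult:
    """Minimum-AICc candidate; fills delta_aicc on every defined result.

    Ties at the minimum break by smaller k, then smaller RM, then the
    position of the candidate in the input order (feature-class order).
    """
    defined = [r for r in results if r.aicc is not None]
    if not defined:
        raise ValueError("AICc undefined for every candidate")
    best_aicc = min(r.aicc for r in defined)
    for r in defined:
        r.delta_aicc = r.aicc - best_aicc
    tied = [
        (r.k, r.config.rm, i, r)
        for i, r in enumerate(results)
        if r.aicc is not None and r.aicc == best_aicc
    ]
    tied.sort(key=lambda t: t[:3])
    return tied[0][3]


def results_table(results: Sequence[CandidateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fc": [r.config.fc_label for r in results],
            "rm": [r.config.rm for r in results],
            "k": [r.k for r in results],
            "lnL": [r.lnL for r in results],
            "aicc": [np.nan if r.aicc is None else r.aicc for r in results],
            "delta_aicc": [
                np.nan if r.delta_aicc is None else r.delta_aicc for r in results
            ],
        }
    )


@dataclasses.dataclass
class ReplicateEnsemble:
    """Replicate fits of the selected configuration and their median map."""

    n_replicates: int
    test_fraction: float
    models: list[MaxentDensity]
    test_indices: list[np.ndarray]  # held-out presence row indices per replicate
    prediction_grids: list[np.ndarray]
    aggregated: np.ndarray  # per-cell median over replicates (NaN outside M)


def run_replicates(
    best: CandidateConfig,
    presence_table: pd.DataFrame,
    background: BackgroundSample,
    stack: LandscapeStack,
    M_mask: np.ndarray,
    n_replicates: int = 10,
    test_fraction: float = 0.25,
    seed: int = 0,
    replicate_type: str = "subsample",
    max_iterations: int = 5000,
    convergence_threshold: float = 1e-5,
    n_hinge_knots: int = 20,
    n_threshold_knots: int = 20,
) -> ReplicateEnsemble:
    """Replicate fits with held-out test presences; median aggregation.

    Each replicate holds out ceil(test_fraction * n) presences drawn
    uniformly without replacement (independently per replicate under the
    seed) and fits on the rest.  ``replicate_type="bootstrap"`` instead
    resamples the training partition with replacement (Maxent's own
    bootstrap replicate flavour).  The aggregated map is the cellwise
    median of the replicate raw maps.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    if replicate_type not in ("subsample", "bootstrap"):
        raise ValueError(f"unknown replicate_type {replicate_type!r}")
    n = len(presence_table)
    n_test = int(np.ceil(test_fraction * n))
    if n - n_test < 2:
        raise ValueError("training partition smaller than 2 presences")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_replicates)
    models, test_idx, grids = [], [], []
    for child in child_seeds:
        rng = np.random.default_rng(child)
        held = np.sort(rng.choice(n, size=n_test, replace=False))
        train = np.setdiff1d(np.arange(n), held)
        if replicate_type == "bootstrap":
            train = train[rng.integers(0, len(train), size=len(train))]
        model = fit_maxent(
            presence_table.iloc[train], background, fc=best.fc, rm=best.rm,
            max_iterations=max_iterations,
            convergence_threshold=convergence_threshold,
            n_hinge_knots=n_hinge_knots,
            n_threshold_knots=n_threshold_knots,
        )
        models.append(model)
        test_idx.append(held)
        grids.append(predict_over_mask(model, stack, M_mask))
    aggregated = np.full(stack.shape, np.nan)
    aggregated[M_mask] = np.median(
        np.stack([g[M_mask] for g in grids]), axis=0
    )
    return ReplicateEnsemble(
        n_replicates=n_replicates,
        test_fraction=test_fraction,
        models=models,
        test_indices=test_idx,
        prediction_grids=grids,
        aggregated=aggregated,
    )
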