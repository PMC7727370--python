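"""Penalized maximum-entropy (Gibbs) suitability model.

The model places a density over the background cells of the calibration
region M:

    raw(x) = exp(lambda . f(x)) / Z,   Z = sum_b exp(lambda . f(b)),

where f are the scaled features of :mod:`flyniche.features`.  The
coefficients minimize the convex penalized objective

    -(1/n) sum_presences lambda.f(x)
        + log sum_background exp(lambda.f(b))
        + sum_j beta_j |lambda_j|,

whose stationarity condition is the soft moment-matching (KKT) box:
|E_model[f_j] - mean_presence[f_j]| <= beta_j for every feature.  The
L1 penalty is handled exactly by splitting lambda into nonnegative
positive/negative parts and running L-BFGS-B on the smooth bound-
constrained equivalent, which is monotone in the objective.

Raw output sums to one over the background sample; predictions are only
meaningful inside M (the model is never extrapolated or clamped).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .accessible_area import AccessibleArea
from .features import Feature, FeatureExpansion, build_features, default_betas
from .landscape import LandscapeStack

__all__ = [
    "BackgroundSample",
    "MaxentDensity",
    "sample_background",
    "fit_maxent",
    "predict_raw",
    "predict_over_mask",
    "training_gain",
    "jackknife_importance",
    "permutation_importance",
    "save_lambdas",
    "load_lambdas",
]

MAX_BACKGROUND = 10_000
KKT_TOL = 1e-6
PGTOL = 1e-9


@dataclasses.dataclass
class BackgroundSample:
    """Background cells of M with their env value table."""

    cell_indices: np.ndarray  # flat row-major indices into the stack
    env_table: pd.DataFrame
    size: int
    seed: int

    def __post_init__(self) -> None:
        if self.size > MAX_BACKGROUND:
            raise ValueError(f"background exceeds the {MAX_BACKGROUND}-cell cap")
        if len(np.unique(self.cell_indices)) != self.size:
            raise ValueError("duplicate background cells")


def sample_background(
    M: AccessibleArea | np.ndarray,
    stack: LandscapeStack,
    cap: int = MAX_BACKGROUND,
    seed: int = 0,
    layer_names: Sequence[str] | None = None,
) -> BackgroundSample:
    """Background cells from M: all of them, or `cap` drawn uniformly.

    If M has at most ``cap`` cells every cell is used in row-major order
    (no sampling); otherwise exactly ``cap`` distinct cells are drawn
    uniformly without replacement (reproducible under ``seed``) and
    returned in row-major order.
    """
    mask = M.mask if isinstance(M, AccessibleArea) else M
    if cap < 1:
        raise ValueError("cap must be >= 1")
    flat = np.flatnonzero(mask.ravel() & ~stack.nodata_mask.ravel())
    if flat.size == 0:
        raise ValueError("accessible area is empty")
    if flat.size > cap:
        rng = np.random.default_rng(seed)
        flat = np.sort(rng.choice(flat, size=cap, replace=False))
    names = list(layer_names) if layer_names is not None else stack.layer_names
    rows, cols = np.unravel_index(flat, stack.shape)
    table = pd.DataFrame(
        {n: stack.env_layers[n][rows, cols] for n in names}
    )
    return BackgroundSample(cell_indices=flat, env_table=table,
                            size=flat.size, seed=seed)


# -- solver ---------------------------------------------------------------


def _solve_penalized(F_pres, F_bg, betas, max_iterations, convergence_threshold):
    """Minimize the penalized objective; returns a result dict.

    L-BFGS-B on the positive/negative split of lambda.  The stop on
    relative objective improvement is tied to ``convergence_threshold``;
    projected-gradient stationarity at PGTOL certifies the KKT moment
    condition at KKT_TOL.
    """
    n_feat = F_bg.shape[1]
    pres_mean = F_pres.mean(axis=0)
    objective_path: list[float] = []

    def split(z):
        return z[:n_feat] - z[n_feat:]

    def fun(z):
        lam = split(z)
        s = F_bg @ lam
        lse = logsumexp(s)
        f = -pres_mean @ lam + lse + betas @ np.abs(lam)
        p = np.exp(s - lse)
        g = F_bg.T @ p - pres_mean
        grad = np.concatenate([g + betas, -g + betas])
        return f, grad

    def kkt_of(z):
        lam = split(z)
        s = F_bg @ lam
        p = np.exp(s - logsumexp(s))
        gap = F_bg.T @ p - pres_mean
        return float(np.max(np.maximum(0.0, np.abs(gap) - betas)))

    z0 = np.zeros(2 * n_feat)
    objective_path.append(fun(z0)[0])

    bounds = [(0, None)] * (2 * n_feat)
    cb = lambda z: objective_path.append(fun(z)[0])
    res = minimize(
        fun, z0, jac=True, method="L-BFGS-B", bounds=bounds, callback=cb,
        options={"maxiter": max_iterations,
                 "ftol": convergence_threshold * 1e-4,
                 "gtol": PGTOL, "maxls": 50},
    )
    total_it = int(res.nit)
    # the objective stop can fire marginally before the moment (KKT) box is
    # certified; polish to stationarity with the iteration budget that is left
    if kkt_of(res.x) > KKT_TOL and total_it < max_iterations:
        res2 = minimize(
            fun, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
            callback=cb,
            options={"maxiter": max_iterations - total_it,
                     "ftol": 1e-18, "gtol": PGTOL, "maxls": 100},
        )
        if res2.fun <= res.fun:
            res = res2
        total_it += int(res2.nit)
    lam = split(res.x)
    # the split is degenerate (both parts can be positive); collapse it
    lam[np.abs(lam) < 1e-12] = 0.0
    s = F_bg @ lam
    log_Z = float(logsumexp(s))
    p = np.exp(s - log_Z)
    moment_gap = F_bg.T @ p - pres_mean  # E_model[f] - mean_presence[f]
    kkt_violation = float(np.max(np.maximum(0.0, np.abs(moment_gap) - betas)))
    if len(objective_path) >= 2 and objective_path[1] > objective_path[0] + 1e-9:
        raise RuntimeError(
            "objective increased on the first iteration; feature scaling is broken"
        )
    return {
        "lambdas": lam,
        "log_Z": log_Z,
        "n_iterations": total_it,
        "converged": kkt_violation <= KKT_TOL,
        "kkt_violation": kkt_violation,
        "objective_path": np.array(objective_path),
        "objective": float(fun(res.x)[0]),
    }


class MaxentDensity(BaseEstimator):
    """Scikit-learn style penalized maximum-entropy density estimator.

    Parameters
    ----------
    fc : sequence of str
        Feature classes, subset of {"L","Q","P","T","H"} containing "L".
    rm : float
        Regularization multiplier scaling every per-feature L1 penalty.
    n_hinge_knots, n_threshold_knots : int
        Knots per layer (per direction for hinge).
    max_iterations : int
        Solver iteration cap.
    convergence_threshold : float
        Relative objective-improvement stopping tolerance.
    betas : array or None
        Explicit per-feature penalties overriding the defaults.

    The estimator is fitted on an environmental value table ``X`` (rows =
    presence and background cells) with binary labels ``y`` (1 =
    presence, 0 = background).  Fitted attributes carry a trailing
    underscore; ``predict`` returns the raw (background-normalized Gibbs)
    score of each row.
    """

    def __init__(
        self,
        fc: Sequence[str] = ("L", "Q"),
        rm: float = 1.0,
        n_hinge_knots: int = 20,
        n_threshold_knots: int = 20,
        max_iterations: int = 5000,
        convergence_threshold: float = 1e-5,
        betas: np.ndarray | None = None,
    ):
        self.fc = fc
        self.rm = rm
        self.n_hinge_knots = n_hinge_knots
        self.n_threshold_knots = n_threshold_knots
        self.max_iterations = max_iterations
        self.convergence_threshold = convergence_threshold
        self.betas = betas

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary: 1 = presence, 0 = background")
        pres = X[y == 1]
        bg = X[y == 0]
        if len(pres) < 1:
            raise ValueError("need at least one presence row")
        if len(bg) < 2:
            raise ValueError("need at least two background rows")
        if not np.all(np.isfinite(X.to_numpy(dtype=float))):
            raise ValueError("non-finite environmental values")
        self.expansion_ = build_features(
            bg, fc=self.fc,
            n_hinge_knots=self.n_hinge_knots,
            n_threshold_knots=self.n_threshold_knots,
        )
        F_bg = self.expansion_.transform(bg)
        F_pres = self.expansion_.transform(pres)
        if self.betas is not None:
            betas = np.asarray(self.betas, dtype=float)
            if betas.shape != (len(self.expansion_),):
                raise ValueError("betas length does not match the expansion")
        else:
            betas = default_betas(
                self.expansion_, len(pres), self.rm, background_features=F_bg
            )
        sol = _solve_penalized(
            F_pres, F_bg, betas,
            self.max_iterations, self.convergence_threshold,
        )
        self.betas_ = betas
        self.lambdas_ = sol["lambdas"]
        self.log_Z_ = sol["log_Z"]
        self.converged_ = sol["converged"]
        self.kkt_violation_ = sol["kkt_violation"]
        self.n_iterations_ = sol["n_iterations"]
        self.objective_path_ = sol["objective_path"]
        self.objective_ = sol["objective"]
        self.n_presences_ = len(pres)
        self.background_size_ = len(bg)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        """Raw score per row: exp(lambda.f(x) - log Z)."""
        check_is_fitted(self, "lambdas_")
        F = self.expansion_.transform(pd.DataFrame(X))
        return np.exp(F @ self.lambdas_ - self.log_Z_)

    def score(self, X, y=None) -> float:
        """Mean log raw score of presence rows (y == 1, or all rows)."""
        check_is_fitted(self, "lambdas_")
        X = pd.DataFrame(X)
        if y is not None:
            X = X[np.asarray(y) == 1]
        return float(np.log(self.predict(X)).mean())

    @property
    def n_nonzero_(self) -> int:
        check_is_fitted(self, "lambdas_")
        return int(np.sum(np.abs(self.lambdas_) > 1e-8))


# -- functional surface ---------------------------------------------------


def fit_maxent(
    presence_table: pd.DataFrame,
    background: BackgroundSample,
    fc: Sequence[str] = ("L", "Q"),
    rm: float = 1.0,
    max_iterations: int = 5000,
    convergence_threshold: float = 1e-5,
    n_hinge_knots: int = 20,
    n_threshold_knots: int = 20,
    betas: np.ndarray | None = None,
) -> MaxentDensity:
    """Fit a Maxent density from a presence env table and a background sample."""
    X = pd.concat([presence_table, background.env_table], ignore_index=True)
    y = np.concatenate(
        [np.ones(len(presence_table), dtype=int),
         np.zeros(background.size, dtype=int)]
    )
    return MaxentDensity(
        fc=fc, rm=rm,
        n_hinge_knots=n_hinge_knots, n_threshold_knots=n_threshold_knots,
        max_iterations=max_iterations,
        convergence_threshold=convergence_threshold,
        betas=betas,
    ).fit(X, y)


def predict_raw(model: MaxentDensity, env_table: pd.DataFrame) -> np.ndarray:
    """Raw Gibbs scores for an env value table (rows must lie inside M)."""
    return model.predict(env_table)


def predict_over_mask(
    model: MaxentDensity, stack: LandscapeStack, mask: np.ndarray
) -> np.ndarray:
    """Raw prediction grid over M; cells outside M are NaN."""
    flat = np.flatnonzero(mask.ravel())
    rows, cols = np.unravel_index(flat, stack.shape)
    table = pd.DataFrame(
        {n: stack.env_layers[n][rows, cols] for n in model.expansion_.layer_names}
    )
    out = np.full(stack.shape, np.nan)
    out[rows, cols] = model.predict(table)
    return out


def training_gain(
    model: MaxentDensity, presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
) -> float:
    """Regularized training gain: improvement in presence log-loss over the
    uniform (null) background model, minus the L1 penalty.

    gain = mean_pres[lambda.f] - (log sum_bg exp(lambda.f) - log N_bg)
           - sum_j beta_j |lambda_j|
    """
    F_pres = model.expansion_.transform(presence_table)
    F_bg = model.expansion_.transform(background_table)
    lam = model.lambdas_
    lse = logsumexp(F_bg @ lam)
    return float(
        F_pres.mean(axis=0) @ lam
        - (lse - np.log(len(F_bg)))
        - model.betas_ @ np.abs(lam)
    )


def jackknife_importance(
    presence_table: pd.DataFrame,
    background: BackgroundSample,
    fc: Sequence[str] = ("L", "Q"),
    rm: float = 1.0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Per-layer jackknife of regularized training gain.

    For each layer, refit the model without that layer's features
    (``gain_without``) and with only that layer (``gain_with_only``);
    ``full_gain`` is the gain of the all-layer model.  A layer whose
    removal barely lowers the gain contributes little beyond the others.
    """
    layers = list(presence_table.columns)
    if len(layers) < 2:
        raise ValueError("jackknife requires at least 2 layers")

    def gain_for(cols):
        sub_bg = BackgroundSample(
            cell_indices=background.cell_indices,
            env_table=background.env_table[cols],
            size=background.size,
            seed=background.seed,
        )
        m = fit_maxent(presence_table[cols], sub_bg, fc=fc, rm=rm, **fit_kwargs)
        return training_gain(m, presence_table[cols], sub_bg.env_table)

    full = gain_for(layers)
    rows = []
    for layer in layers:
        rest = [l for l in layers if l != layer]
        rows.append(
            {
                "layer": layer,
                "gain_without": gain_for(rest),
                "gain_with_only": gain_for([layer]),
                "full_gain": full,
            }
        )
    return pd.DataFrame(rows).set_index("layer")


def permutation_importance(
    model: MaxentDensity,
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Relative contribution (%) of each layer by permutation.

    Each layer's values are shuffled jointly across the presence and
    background rows; the drop in training gain under the fitted
    coefficients, averaged over permutations and floored at zero, is
    normalized to sum to 100.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    layers = model.expansion_.layer_names
    base = training_gain(model, presence_table, background_table)
    n_pres = len(presence_table)
    stacked = pd.concat(
        [presence_table[layers], background_table[layers]], ignore_index=True
    )
    drops = np.zeros(len(layers))
    for j, layer in enumerate(layers):
        for _ in range(n_permutations):
            perm = stacked.copy()
            perm[layer] = rng.permutation(perm[layer].to_numpy())
            g = training_gain(model, perm.iloc[:n_pres], perm.iloc[n_pres:])
            drops[j] += base - g
    drops = np.maximum(drops / n_permutations, 0.0)
    total = drops.sum()
    if total == 0:  # no layer matters; split evenly
        shares = np.full(len(layers), 100.0 / len(layers))
    else:
        shares = 100.0 * drops / total
    return pd.Series(shares, index=layers, name="contribution_pct")


# -- serialization --------------------------------------------------------


def save_lambdas(model: MaxentDensity, path: str | Path) -> None:
    """Flat text lambdas file; round-trips exactly (repr floats)."""
    lines = [
        f"# log_Z {model.log_Z_!r}",
        f"# rm {model.rm!r}",
        f"# fc {','.join(model.expansion_.fc)}",
        f"# layers {','.join(model.expansion_.layer_names)}",
        "name\tftype\tlayers\tknot\tscale_min\tscale_max\tlambda",
    ]
    for f, lam in zip(model.expansion_.features, model.lambdas_):
        knot = "" if f.knot is None else repr(float(f.knot))
        lines.append(
            f"{f.name}\t{f.ftype}\t{'|'.join(f.layers)}\t{knot}"
            f"\t{float(f.scale_min)!r}\t{float(f.scale_max)!r}\t{float(lam)!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_lambdas(path: str | Path) -> MaxentDensity:
    """Rebuild a fitted model (expansion + coefficients) from a lambdas file."""
    lines = Path(path).read_text().splitlines()
    meta = {}
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            _, key, val = ln.split(None, 2)
            meta[key] = val
        else:
            body_start = i
            break
    feats, lams = [], []
    for ln in lines[body_start + 1:]:
        name, ftype, lys, knot, smin, smax, lam = ln.split("\t")
        feats.append(
            Feature(
                name=name, ftype=ftype, layers=tuple(lys.split("|")),
                knot=None if knot == "" else float(knot),
                scale_min=float(smin), scale_max=float(smax),
            )
        )
        lams.append(float(lam))
    fc = tuple(meta["fc"].split(","))
    model = MaxentDensity(fc=fc, rm=float(meta["rm"]))
    model.expansion_ = FeatureExpansion(
        features=feats, layer_names=meta["layers"].split(","), fc=fc
    )
    model.lambdas_ = np.array(lams)
    model.log_Z_ = float(meta["log_Z"])
    model.converged_ = True
    return model
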