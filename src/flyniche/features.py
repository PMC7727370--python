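"""Maxent-style feature expansion of environmental variables.

The Gibbs density is log-linear in a basis of *features* derived from
the raw environmental layers.  Feature classes follow the Maxent
convention: linear (L), quadratic (Q), pairwise product (P), threshold
step (T) and hinge ramp (H).  Every feature is affinely scaled so that
it maps the background sample into [0, 1]; threshold and hinge knots are
placed at evenly spaced interior points of each layer's background range.

The per-feature L1 penalty ``beta_j`` is the regularization multiplier
times a per-class base value (interpolated on the number of presences)
times the feature's background standard deviation over sqrt(n presences).
The base table below is this package's documented default; it follows
the shape of the published Maxent defaults (tighter regularization for
threshold features, constant for hinge, relaxing as presences grow).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Feature", "FeatureExpansion", "build_features", "default_betas"]

FEATURE_CLASSES = ("L", "Q", "P", "T", "H")

#: Per-class base regularization, linearly interpolated on n_presences
#: and clamped at the table ends.
BETA_TABLE: dict[str, list[tuple[int, float]]] = {
    "linear": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "product": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "threshold": [(10, 2.0), (100, 1.0)],
    "hinge": [(10, 0.5), (100, 0.5)],
}

_TYPE_OF_CLASS = {"L": "linear", "Q": "quadratic", "P": "product",
                  "T": "threshold", "H": "hinge"}


@dataclasses.dataclass(frozen=True)
class Feature:
    """One basis function: type, source layer(s), optional knot, scale bounds."""

    name: str
    ftype: str  # linear | quadratic | product | threshold | hinge_fwd | hinge_rev
    layers: tuple[str, ...]
    knot: float | None
    scale_min: float
    scale_max: float

    def raw(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.layers[0]].to_numpy(dtype=float)
        if self.ftype == "linear":
            return x
        if self.ftype == "quadratic":
            return x * x
        if self.ftype == "product":
            return x * table[self.layers[1]].to_numpy(dtype=float)
        if self.ftype == "threshold":
            return (x > self.knot).astype(float)
        if self.ftype == "hinge_fwd":
            return np.maximum(0.0, x - self.knot)
        if self.ftype == "hinge_rev":
            return np.maximum(0.0, self.knot - x)
        raise ValueError(f"unknown feature type {self.ftype}")

    def value(self, table: pd.DataFrame) -> np.ndarray:
        lo, hi = self.scale_min, self.scale_max
        return (self.raw(table) - lo) / (hi - lo)


@dataclasses.dataclass
class FeatureExpansion:
    """An ordered feature basis fitted on a background sample."""

    features: list[Feature]
    layer_names: list[str]
    fc: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def transform(self, env_table: pd.DataFrame) -> np.ndarray:
        """Scaled feature matrix (rows x features) for an env value table."""
        missing = [n for n in self.layer_names if n not in env_table.columns]
        if missing:
            raise KeyError(f"env table lacks layers {missing}")
        out = np.column_stack([f.value(env_table) for f in self.features])
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite feature values")
        return out


def _knots(lo: float, hi: float, k: int) -> np.ndarray:
    """k knots strictly inside (lo, hi), evenly spaced."""
    return lo + (np.arange(1, k + 1) / (k + 1)) * (hi - lo)


def build_features(
    env_table: pd.DataFrame,
    fc: Sequence[str] = ("L",),
    n_hinge_knots: int = 20,
    n_threshold_knots: int = 20,
) -> FeatureExpansion:
    """Build a feature expansion on a background env table.

    ``fc`` is a subset of {L, Q, P, T, H} containing L.  Scaling bounds
    and knots are computed on ``env_table`` (the background sample).
    """
    fc = tuple(fc)
    if "L" not in fc:
        raise ValueError("feature classes must include L")
    unknown = set(fc) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}")
    if len(env_table) == 0:
        raise ValueError("empty background table")
    layers = list(env_table.columns)
    rng_of = {}
    for name in layers:
        v = env_table[name].to_numpy(dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            raise ValueError(f"layer {name!r} is constant on the background")
        rng_of[name] = (lo, hi)

    feats: list[Feature] = []

    def scaled(name, ftype, lys, knot, raw_vals):
        lo, hi = float(np.min(raw_vals)), float(np.max(raw_vals))
        if lo == hi:  # degenerate feature (e.g. knot at the very edge)
            hi = lo + 1.0
        feats.append(Feature(name, ftype, tuple(lys), knot, lo, hi))

    if "L" in fc:
        for name in layers:
            scaled(f"L({name})", "linear", [name], None, env_table[name])
    if "Q" in fc:
        for name in layers:
            scaled(f"Q({name})", "quadratic", [name], None,
                   env_table[name].to_numpy(dtype=float) ** 2)
    if "P" in fc:
        for i, a in enumerate(layers):
            for b in layers[i + 1:]:
                scaled(
                    f"P({a}*{b})", "product", [a, b], None,
                    env_table[a].to_numpy(dtype=float)
                    * env_table[b].to_numpy(dtype=float),
                )
    if "T" in fc:
        for name in layers:
            lo, hi = rng_of[name]
            for knot in _knots(lo, hi, n_threshold_knots):
                feats.append(
                    Feature(f"T({name}@{knot:.6g})", "threshold", (name,),
                            float(knot), 0.0, 1.0)
                )
    if "H" in fc:
        for name in layers:
            lo, hi = rng_of[name]
            for knot in _knots(lo, hi, n_hinge_knots):
                feats.append(
                    Feature(f"H+({name}@{knot:.6g})", "hinge_fwd", (name,),
                            float(knot), 0.0, hi - float(knot))
                )
            for knot in _knots(lo, hi, n_hinge_knots):
                feats.append(
                    Feature(f"H-({name}@{knot:.6g})", "hinge_rev", (name,),
                            float(knot), 0.0, float(knot) - lo)
                )
    return FeatureExpansion(features=feats, layer_names=layers, fc=fc)


def _base_beta(ftype: str, n_presences: int) -> float:
    key = {"hinge_fwd": "hinge", "hinge_rev": "hinge"}.get(ftype, ftype)
    table = BETA_TABLE[key]
    ns = np.array([t[0] for t in table], dtype=float)
    bs = np.array([t[1] for t in table], dtype=float)
    return float(np.interp(n_presences, ns, bs))


def default_betas(
    expansion: FeatureExpansion,
    n_presences: int,
    rm: float,
    background_features: np.ndarray | None = None,
    background_table: pd.DataFrame | None = None,
) -> np.ndarray:
    """Per-feature L1 penalties: rm * base(class, n) * s_j / sqrt(n).

    ``s_j`` is the feature's standard deviation over the background
    (population normalization); pass either the precomputed scaled
    feature matrix or the background env table.
    """
    if n_presences < 1:
        raise ValueError("n_presences must be >= 1")
    if rm < 0:
        raise ValueError("rm must be >= 0")
    if background_features is None:
        if background_table is None:
            raise ValueError("need background_features or background_table")
        background_features = expansion.transform(background_table)
    s = background_features.std(axis=0)
    base = np.array([_base_beta(f.ftype, n_presences) for f in expansion.features])
    return rm * base * s / np.sqrt(n_presences)
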