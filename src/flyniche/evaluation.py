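"""Partial-ROC evaluation and lower-training-presence binarization.

Presence-only predictions cannot be scored with an ordinary ROC because
true absences are unknown.  The partial-ROC procedure replaces the
false-positive rate with the *fractional predicted area* a(t) — the
proportion of the calibration region M predicted suitable at threshold t
— and restricts attention to the high-sensitivity region s(t) >= 1 - E,
where E is the allowable omission rate (default 5%).  The statistic is
the AUC ratio: the area under the sensitivity-vs-area curve on that
region divided by the area under the diagonal s = a (a random
classifier) on the same interval.  A ratio of 1.0 is random
performance; significance is assessed by bootstrap over the test points
(p = fraction of bootstrap ratios <= 1).

Binary suitable/unsuitable maps use the lower-training-presence
threshold (LTPT): sort the predicted values at the training presences,
drop the lowest floor(E * n), and threshold at the smallest remaining
value, so at most a fraction E of training presences is omitted.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .landscape import LandscapeStack
from .occurrences import OccurrenceSet

__all__ = [
    "EvaluationConfig",
    "PartialROCResult",
    "partial_roc",
    "ltpt_threshold",
    "binarize",
    "suitable_region_geojson",
]

MAX_THRESHOLD_CLASSES = 1000


@dataclasses.dataclass(frozen=True)
class EvaluationConfig:
    """Partial-ROC settings: omission E, bootstrap count and fraction, seed."""

    E: float = 0.05
    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.E < 1):
            raise ValueError("E must lie strictly between 0 and 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not (0 < self.bootstrap_fraction <= 1):
            raise ValueError("bootstrap_fraction must lie in (0, 1]")


@dataclasses.dataclass
class PartialROCResult:
    auc_ratios: np.ndarray
    mean_ratio: float
    p_value: float
    E: float
    degenerate: bool = False


def _auc_ratio(thresholds, area_frac, test_values, E):
    """AUC ratio for one set of test values over a fixed threshold sweep.

    ``thresholds`` descend; ``area_frac`` is the matching fractional
    predicted area (ascending).  Sensitivity at t is the proportion of
    test values >= t.  The curve is restricted to s >= 1 - E and
    integrated by trapezoid against the diagonal on the same a-interval.
    """
    s = (test_values[None, :] >= thresholds[:, None]).mean(axis=1)
    s_min = 1 - E
    keep = s >= s_min
    if keep.sum() == 0:
        return 1.0
    a = area_frac[keep]
    sv = s[keep]
    # enter the restricted region exactly at the s = 1 - E crossing:
    # without this interpolated boundary point the curve starts at a step
    # overshoot (s jumps past 1 - E in increments of 1/m), which biases
    # every ratio upward even for a random classifier
    first = int(np.argmax(keep))
    if first > 0 and s[first] > s_min:
        ds = s[first] - s[first - 1]
        frac = (s_min - s[first - 1]) / ds if ds > 0 else 1.0
        a_star = area_frac[first - 1] + frac * (area_frac[first] - area_frac[first - 1])
        a = np.concatenate([[a_star], a])
        sv = np.concatenate([[s_min], sv])
    if len(a) < 2:
        return 1.0
    model_area = np.trapezoid(sv, a)
    random_area = np.trapezoid(a, a)  # diagonal s = a on the same interval
    if random_area == 0:
        return 1.0
    return float(model_area / random_area)


def partial_roc(
    prediction: np.ndarray,
    test_points: OccurrenceSet,
    stack: LandscapeStack,
    config: EvaluationConfig = EvaluationConfig(),
) -> PartialROCResult:
    """Bootstrap partial-ROC AUC ratios of a prediction grid over M.

    ``prediction`` is a grid with finite values inside M and NaN outside.
    Test points are looked up in their containing cells.  Per bootstrap
    replicate, ceil(bootstrap_fraction * m) test points are resampled
    with replacement and the AUC ratio on the region s >= 1 - E is
    computed against the fixed area curve of the full prediction.
    A constant prediction is degenerate: every ratio is 1.0 (a constant
    map *is* a random classifier).
    """
    vals = prediction[np.isfinite(prediction)]
    if vals.size == 0:
        raise ValueError("prediction has no finite cells")
    test_values = []
    for rid, lon, lat in test_points.records:
        r, c = stack.cell_of(lon, lat)
        v = prediction[r, c]
        if not np.isfinite(v):
            raise ValueError(f"test record {rid!r} falls outside M")
        test_values.append(v)
    test_values = np.asarray(test_values)
    if test_values.size < 5:
        raise ValueError("need at least 5 test points inside M")

    if np.unique(vals).size < 2:
        ratios = np.ones(config.n_bootstrap)
        return PartialROCResult(
            auc_ratios=ratios, mean_ratio=1.0, p_value=1.0, E=config.E,
            degenerate=True,
        )

    thresholds = np.unique(vals)[::-1]  # descending
    if thresholds.size > MAX_THRESHOLD_CLASSES:
        idx = np.linspace(0, thresholds.size - 1, MAX_THRESHOLD_CLASSES)
        thresholds = thresholds[np.round(idx).astype(int)]
    area_frac = (vals[None, :] >= thresholds[:, None]).mean(axis=1)

    rng = np.random.default_rng(config.seed)
    m = test_values.size
    n_draw = int(np.ceil(config.bootstrap_fraction * m))
    ratios = np.empty(config.n_bootstrap)
    for b in range(config.n_bootstrap):
        sample = test_values[rng.integers(0, m, size=n_draw)]
        ratios[b] = _auc_ratio(thresholds, area_frac, sample, config.E)
    return PartialROCResult(
        auc_ratios=ratios,
        mean_ratio=float(ratios.mean()),
        p_value=float(np.mean(ratios <= 1.0)),
        E=config.E,
    )


def ltpt_threshold(
    prediction: np.ndarray,
    training_points: OccurrenceSet,
    stack: LandscapeStack,
    E: float = 0.05,
) -> float:
    """Lower-training-presence threshold at allowable omission E.

    Sort the predicted values at the training presences ascending, drop
    the lowest floor(E * n), and return the smallest remaining value.
    The fraction of training presences strictly below the returned
    threshold is therefore at most E.
    """
    if not (0 <= E < 1):
        raise ValueError("E must lie in [0, 1)")
    if len(training_points) == 0:
        raise ValueError("empty training set")
    v = []
    for rid, lon, lat in training_points.records:
        r, c = stack.cell_of(lon, lat)
        val = prediction[r, c]
        if not np.isfinite(val):
            raise ValueError(f"training record {rid!r} falls outside M")
        v.append(val)
    v = np.sort(np.asarray(v))
    drop = int(np.floor(E * len(v)))
    return float(v[drop])


def ltpt_threshold_values(values: np.ndarray, E: float = 0.05) -> float:
    """LTPT directly from predicted values at the training presences."""
    if not (0 <= E < 1):
        raise ValueError("E must lie in [0, 1)")
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty training set")
    return float(v[int(np.floor(E * v.size))])


def binarize(prediction: np.ndarray, threshold: float) -> np.ma.MaskedArray:
    """Suitable (>= threshold) / unsuitable map over M.

    Cells outside M (NaN in the prediction) are masked nodata, not
    "unsuitable".
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    outside = ~np.isfinite(prediction)
    suitable = np.zeros(prediction.shape, dtype=bool)
    inside = ~outside
    suitable[inside] = prediction[inside] >= threshold
    return np.ma.MaskedArray(suitable, mask=outside)


def suitable_region_geojson(
    binary: np.ma.MaskedArray, stack: LandscapeStack
) -> dict:
    """GeoJSON FeatureCollection of the suitable region (unioned cell boxes)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    cells = np.argwhere(np.asarray(binary.filled(False)))
    half = stack.cell_size / 2
    boxes = []
    for r, c in cells:
        lon, lat = stack.cell_center(int(r), int(c))
        boxes.append(box(lon - half, lat - half, lon + half, lat + half))
    geoms = [] if not boxes else [unary_union(boxes)]
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"class": "suitable"},
             "geometry": mapping(g)}
            for g in geoms
        ],
    }
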