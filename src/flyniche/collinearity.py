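"""Environmental collinearity reduction by pairwise Pearson correlation.

Strongly correlated bioclimatic layers carry redundant information and
destabilize coefficient-based importance measures, so pairs with
|r| above a threshold (default 0.8) are pruned before modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .landscape import LandscapeStack

__all__ = ["CollinearityFilter", "filter_collinear"]

DEFAULT_THRESHOLD = 0.8


class CollinearityFilter(TransformerMixin, BaseEstimator):
    """Drop one member of each over-correlated variable pair.

    Pairwise Pearson correlations (population normalization) are computed
    over the fitting rows.  Iteratively, while any pair exceeds the
    threshold in absolute value, the worst pair is located and the member
    with the larger mean absolute correlation against all remaining
    variables is dropped (ties broken by column order: the later column
    is dropped).  On return every retained pair satisfies |r| <= threshold.

    Attributes
    ----------
    retained_ : list of str
        Names of the retained columns, in input order.
    dropped_ : list of str
        Names of the dropped columns, in drop order.
    correlation_ : pandas.DataFrame
        The full correlation table computed on the fitting data.
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie strictly between 0 and 1")
        X = pd.DataFrame(X)
        names = [str(c) for c in X.columns]
        if len(names) < 2:
            raise ValueError("need at least 2 layers to filter collinearity")
        values = X.to_numpy(dtype=float)
        sd = values.std(axis=0)  # population normalization
        for name, s in zip(names, sd):
            if s == 0:
                raise ValueError(f"layer {name!r} is constant; correlation undefined")
        corr = np.corrcoef(values, rowvar=False)
        self.correlation_ = pd.DataFrame(corr, index=names, columns=names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)

        keep = list(range(len(names)))
        dropped: list[str] = []
        while True:
            sub = np.abs(corr[np.ix_(keep, keep)])
            np.fill_diagonal(sub, 0.0)
            worst = sub.max()
            if worst <= self.threshold:
                break
            i_loc, j_loc = np.unravel_index(int(sub.argmax()), sub.shape)
            # mean |r| of each pair member against all other remaining layers
            mean_i = sub[i_loc].sum() / (len(keep) - 1)
            mean_j = sub[j_loc].sum() / (len(keep) - 1)
            if mean_i > mean_j:
                drop_loc = i_loc
            elif mean_j > mean_i:
                drop_loc = j_loc
            else:  # tie: drop the later column
                drop_loc = max(i_loc, j_loc)
            dropped.append(names[keep[drop_loc]])
            keep.pop(drop_loc)
        self.retained_ = [names[i] for i in keep]
        self.dropped_ = dropped
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        return pd.DataFrame(X)[self.retained_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "retained_")
        return np.asarray(self.retained_, dtype=object)


def filter_collinear(
    stack: LandscapeStack,
    threshold: float = DEFAULT_THRESHOLD,
    region: np.ndarray | None = None,
):
    """Prune over-correlated environmental layers of a raster stack.

    Correlations are computed over non-nodata cells, restricted to the
    boolean ``region`` grid when given (e.g. the accessible area M).

    Returns ``(retained_names, dropped_names, correlation_table)``.
    """
    valid = ~stack.nodata_mask
    if region is not None:
        valid = valid & region
    table = pd.DataFrame(
        {name: grid[valid] for name, grid in stack.env_layers.items()}
    )
    f = CollinearityFilter(threshold=threshold).fit(table)
    return f.retained_, f.dropped_, f.correlation_
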