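"""Quantile-anchored monotone spline normalization (qspline).

Each early-batch column is mapped onto the pooled mean distribution of the
late-batch replicate measurements through a monotone cubic spline fitted to
paired quantile anchors.  Outside the fitted range the mapping continues
linearly with the boundary slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = ["QsplineModel", "mean_distribution", "fit_qspline"]

DEFAULT_LEVELS = np.linspace(0.01, 0.99, 99)


def mean_distribution(expr: pd.DataFrame) -> np.ndarray:
    """Pooled target distribution: the mean of the sorted columns."""
    return np.sort(expr.to_numpy(), axis=0).mean(axis=1)


@dataclass
class QsplineModel:
    """Per-column monotone quantile mappings onto a common target."""

    levels: np.ndarray
    source_quantiles: dict[str, np.ndarray]
    target_quantiles: dict[str, np.ndarray]
    _splines: dict[str, PchipInterpolator] = field(default_factory=dict, repr=False)

    def predict_column(self, column: str, x: np.ndarray) -> np.ndarray:
        spline = self._splines[column]
        x = np.asarray(x, dtype=float)
        lo, hi = spline.x[0], spline.x[-1]
        out = spline(np.clip(x, lo, hi))
        below, above = x < lo, x > hi
        if below.any() or above.any():
            logger.warning(
                "qspline: %d values outside the fitted range of column %s; "
                "extrapolating with the boundary slope",
                int(below.sum() + above.sum()), column)
            d_lo = float(spline.derivative()(lo))
            d_hi = float(spline.derivative()(hi))
            out[below] = spline(lo) + d_lo * (x[below] - lo)
            out[above] = spline(hi) + d_hi * (x[above] - hi)
        return out

    def apply(self, expr: pd.DataFrame) -> pd.DataFrame:
        out = expr.copy()
        for c in self._splines:
            if c in out.columns:
                out[c] = self.predict_column(c, expr[c].to_numpy())
        return out


def fit_qspline(source: pd.DataFrame, target_distribution: np.ndarray,
                levels: np.ndarray = DEFAULT_LEVELS) -> QsplineModel:
    """Fit one monotone quantile mapping per source column.

    Anchors are the ``levels`` quantiles of each source column paired with the
    same quantiles of the target; the target anchors are isotonically
    repaired before a monotone cubic (PCHIP) interpolant is fitted, so the
    mapping is monotone non-decreasing over the data range by construction.
    """
    levels = np.asarray(levels, float)
    if not np.all(np.diff(levels) > 0):
        raise ValueError("anchor quantile levels must be strictly increasing")
    target = np.asarray(target_distribution, float)
    tq_full = np.quantile(target, levels)
    model = QsplineModel(levels=levels, source_quantiles={}, target_quantiles={})
    for c in source.columns:
        sq = np.quantile(source[c].to_numpy(), levels)
        # merge anchors with tied source quantiles (flat stretches of data)
        uniq, inverse = np.unique(np.round(sq, 12), return_inverse=True)
        tq = np.array([tq_full[inverse == k].mean() for k in range(len(uniq))])
        if len(uniq) < 5:
            raise ValueError(
                f"column {c}: fewer than 5 distinct quantile anchors")
        tq = IsotonicRegression(increasing=True).fit_transform(uniq, tq)
        model.source_quantiles[c] = uniq
        model.target_quantiles[c] = tq
        model._splines[c] = PchipInterpolator(uniq, tq)
    return model
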