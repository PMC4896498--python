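"""Seven batch-effect correction methods behind one dispatcher.

The regression family (Deming, Passing-Bablok, linear mixed model, cubic
polynomial) learns a mapping from the early batch to the late batch on the
technical-replicate pairs and rescales the early batch.  ``qspline`` maps
each early-batch column onto the pooled late-batch replicate distribution.
``combat`` applies per-gene empirical-Bayes location-scale adjustment and
``ruv`` removes factor-analytic unwanted variation estimated from replicates
and negative controls.  Every method can optionally be preceded by per-batch
quantile normalization (``qn_first``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import BATCH, GROUP, IS_NEGATIVE_CONTROL, SUBJECT
from ..qc import quantile_normalize
from .combat import CombatModel, combat_correct
from .qspline import QsplineModel, fit_qspline, mean_distribution
from .rescale import (
    RescaleModel, apply_rescale, build_replicate_pairs, fit_deming,
    fit_lmm_rescale, fit_passing_bablok, fit_polynomial,
)
from .ruv import RUVModel, replicate_ruv_correct

__all__ = [
    "METHODS",
    "correct",
    "CombatModel", "combat_correct",
    "QsplineModel", "fit_qspline", "mean_distribution",
    "RescaleModel", "apply_rescale", "build_replicate_pairs",
    "fit_deming", "fit_lmm_rescale", "fit_passing_bablok", "fit_polynomial",
    "RUVModel", "replicate_ruv_correct",
]

METHODS = ("deming", "passing_bablok", "lmm", "polynomial",
           "qspline", "combat", "ruv")


def _replicate_group_map(meta: pd.DataFrame) -> pd.Series:
    """Replicate map for RUV: per subject, the BL-aliquot measurements.

    BL_rep and BLFU_rep columns of a subject are technical replicates of the
    same RNA; FU_rep and cohort samples are excluded so that no biological
    variation enters the factor estimate.
    """
    mask = meta[GROUP].isin(["BL_rep", "BLFU_rep"])
    labels = pd.Series(np.nan, index=meta.index, dtype=object)
    labels[mask] = meta.loc[mask, SUBJECT].astype(str)
    return labels


def correct(expr: pd.DataFrame, meta: pd.DataFrame, method: str,
            qn_first: bool = False, probes: pd.DataFrame | None = None,
            k: int | None = None, lam: float = 1.0):
    """Apply one of the seven correction methods; returns (matrix, model).

    ``probes`` (annotation with negative-control flags) is required for
    ``ruv``; ``k`` defaults to min(n_samples // 4, median replicates per
    sample); ``lam`` is the Deming error-variance ratio.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    meta = meta.loc[expr.columns]
    if qn_first:
        expr = quantile_normalize(expr, meta[BATCH])
    batches = meta[BATCH]

    if method in ("deming", "lmm", "polynomial"):
        x, y, subj = build_replicate_pairs(expr, meta)
        if method == "deming":
            model = fit_deming(x, y, lam=lam)
        elif method == "lmm":
            model = fit_lmm_rescale(x, y, subj)
        else:
            model = fit_polynomial(x, y, subj)
        return apply_rescale(model, expr, batches), model

    if method == "passing_bablok":
        bl = meta.index[meta[GROUP] == "BL_rep"]
        fu = meta.index[meta[GROUP] == "BLFU_rep"]
        if len(bl) == 0 or len(fu) == 0:
            raise ValueError("Passing-Bablok needs BL_rep and BLFU_rep samples")
        model = fit_passing_bablok(expr[bl].mean(axis=1).to_numpy(),
                                   expr[fu].mean(axis=1).to_numpy())
        return apply_rescale(model, expr, batches), model

    if method == "qspline":
        fu = meta.index[meta[GROUP] == "BLFU_rep"]
        if len(fu) == 0:
            raise ValueError("qspline needs BLFU_rep samples as the target")
        target = mean_distribution(expr[fu])
        source_cols = expr.columns[batches == "BL"]
        model = fit_qspline(expr[source_cols], target)
        return apply_rescale(model, expr, batches), model

    if method == "combat":
        return combat_correct(expr, batches)

    # ruv
    if probes is None:
        raise ValueError("ruv requires the probe annotation (negative controls)")
    controls = probes.index[probes[IS_NEGATIVE_CONTROL].astype(bool)]
    labels = _replicate_group_map(meta)
    if k is None:
        sizes = labels.dropna().value_counts()
        if len(sizes) == 0:
            raise ValueError("ruv needs replicate samples to pick a default k")
        k = int(min(len(expr.columns) // 4, sizes.median()))
    return replicate_ruv_correct(expr, labels, controls, k)
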