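"""Replicate-based removal of unwanted variation (RUV).

Technical replicates of the same RNA aliquot differ only by unwanted
(technical) variation, so the span of the within-replicate-group centered
measurements estimates the unwanted-factor directions.  The top-k right
singular vectors of that centered matrix give the factor loadings ``alpha``
(k x genes); per-sample scores ``W`` are then estimated by least-squares
projection of each sample's negative-control values onto ``alpha`` restricted
to the controls, and ``W @ alpha`` is subtracted from the whole matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RUVModel", "replicate_ruv_correct"]


@dataclass
class RUVModel:
    """Fitted unwanted-variation factors."""

    k: int
    alpha: np.ndarray          # k x genes loadings
    w: pd.DataFrame            # samples x k scores
    control_index: list[str]
    singular_values: np.ndarray


def replicate_ruv_correct(expr: pd.DataFrame, replicate_groups: pd.Series,
                          control_index, k: int,
                          ) -> tuple[pd.DataFrame, RUVModel]:
    """Estimate and remove k unwanted factors from replicate structure.

    ``replicate_groups`` maps sample IDs to replicate-group labels; samples
    with a missing (NaN) label contribute no rows to the factor estimation
    but are still corrected.  ``control_index`` lists the negative-control
    probes used to project every sample onto the factor loadings.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    controls = pd.Index(control_index)
    controls = controls[controls.isin(expr.index)]
    if k > 0 and len(controls) == 0:
        raise ValueError("no negative-control probes available")

    samples = expr.columns
    if k == 0:
        model = RUVModel(k=0, alpha=np.zeros((0, expr.shape[0])),
                         w=pd.DataFrame(index=samples, columns=[], dtype=float),
                         control_index=list(controls),
                         singular_values=np.zeros(0))
        return expr.copy(), model

    groups = replicate_groups.reindex(samples)
    rows = []
    n_groups = 0
    for _, members in groups.dropna().groupby(groups.dropna()).groups.items():
        if len(members) < 2:
            continue
        block = expr[list(members)].to_numpy().T  # replicates x genes
        rows.append(block - block.mean(axis=0, keepdims=True))
        n_groups += 1
    if n_groups == 0:
        raise ValueError("need at least one replicate group with >= 2 members")
    centered = np.vstack(rows)

    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    available = int((s > tol).sum())
    if k > available:
        raise ValueError(
            f"k={k} exceeds the rank of the centered replicate matrix "
            f"(maximum achievable k is {available})")
    alpha = vt[:k]  # k x genes

    ctrl_rows = expr.index.get_indexer(controls)
    alpha_c = alpha[:, ctrl_rows]               # k x controls
    y_c = expr.to_numpy()[ctrl_rows, :].T       # samples x controls
    w, *_ = np.linalg.lstsq(alpha_c.T, y_c.T, rcond=None)  # k x samples
    w = w.T                                     # samples x k
    corrected = expr.to_numpy() - (w @ alpha).T
    model = RUVModel(
        k=k, alpha=alpha,
        w=pd.DataFrame(w, index=samples,
                       columns=[f"W{i + 1}" for i in range(k)]),
        control_index=list(controls),
        singular_values=s[:k].copy(),
    )
    return pd.DataFrame(corrected, index=expr.index, columns=samples), model
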