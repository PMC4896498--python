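"""Parametric empirical-Bayes location-scale batch adjustment (ComBat).

Three steps, per gene ``g`` and batch ``i`` with an intercept-only design:

1. **Standardize**: ``Z = (Y - alpha_g) / sigma_g`` where ``alpha_g`` is the
   batch-size-weighted grand mean (so ``sum_i n_i * gamma_ig = 0``) and
   ``sigma_g^2`` the pooled residual variance after removing batch means.
2. **Empirical Bayes**: per-batch location estimates ``gamma_ig`` (batch means
   of Z) are shrunk toward a normal prior and scale estimates ``delta2_ig``
   (batch variances of Z, MLE denominator) toward an inverse-gamma prior,
   hyperparameters by method of moments across genes, posteriors by
   fixed-point iteration.
3. **Restore**: ``Y* = sigma_g / delta*_ig * (Z - gamma*_ig) + alpha_g``.

The MLE (1/n) denominator for ``delta2`` makes the adjustment an exact
identity when two batches are statistically identical copies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CombatModel", "combat_correct"]

_EPS = 1e-12


@dataclass
class CombatModel:
    """Fitted parameters of the empirical-Bayes adjustment."""

    batches: list[str]
    batch_sizes: dict[str, int]
    alpha: pd.Series            # per-gene grand mean
    sigma2: pd.Series           # per-gene pooled variance
    gamma_hat: pd.DataFrame     # batch x gene location estimates
    delta2_hat: pd.DataFrame    # batch x gene scale estimates
    gamma_star: pd.DataFrame    # EB posterior locations
    delta2_star: pd.DataFrame   # EB posterior scales
    hyperparameters: dict       # per batch: gamma_bar, tau2_bar, a_prior, b_prior
    n_iterations: dict
    skipped_genes: list[str]


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _eb_fit(z_batch: np.ndarray, gamma_hat: np.ndarray, delta2_hat: np.ndarray,
            conv: float = 1e-4, max_iter: int = 500,
            ) -> tuple[np.ndarray, np.ndarray, dict, int]:
    """Fixed-point EB posteriors for one batch (genes vectorized)."""
    n = z_batch.shape[1]
    gamma_bar = float(gamma_hat.mean())
    tau2_bar = float(gamma_hat.var(ddof=1)) if len(gamma_hat) > 1 else 0.0
    s2 = float(delta2_hat.var(ddof=1)) if len(delta2_hat) > 1 else 0.0

    if s2 <= _EPS:
        # degenerate scale prior: all genes share one delta2, nothing to shrink
        a = b = float("nan")
        delta2_star = delta2_hat.copy()
        if tau2_bar <= _EPS:
            gamma_star = np.full_like(gamma_hat, gamma_bar)
        else:
            gamma_star = (n * tau2_bar * gamma_hat + delta2_star * gamma_bar) \
                / (n * tau2_bar + delta2_star)
        hyper = {"gamma_bar": gamma_bar, "tau2_bar": tau2_bar,
                 "a_prior": a, "b_prior": b}
        return gamma_star, delta2_star, hyper, 0

    a = _aprior(delta2_hat)
    b = _bprior(delta2_hat)
    # sum of squares around gamma: SS(g) = n*delta2_hat + n*(gamma_hat - g)^2
    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * tau2_bar * gamma_hat + delta2_star * gamma_bar) \
            / (n * tau2_bar + delta2_star)
        ss = n * delta2_hat + n * (gamma_hat - g_new) ** 2
        d_new = (b + 0.5 * ss) / (n / 2.0 + a - 1.0)
        change = max(np.abs(g_new - gamma_star).max(),
                     np.abs(d_new - delta2_star).max())
        gamma_star, delta2_star = g_new, d_new
        if change < conv:
            break
    else:
        logger.warning("EB iteration did not converge in %d steps", max_iter)
        it = max_iter
    hyper = {"gamma_bar": gamma_bar, "tau2_bar": tau2_bar,
             "a_prior": a, "b_prior": b}
    return gamma_star, delta2_star, hyper, it


def combat_correct(expr: pd.DataFrame, batches: pd.Series,
                   conv: float = 1e-4, max_iter: int = 500,
                   ) -> tuple[pd.DataFrame, CombatModel]:
    """Remove per-gene batch location/scale differences by empirical Bayes.

    ``batches`` assigns every column of ``expr`` to a batch (>= 2 batches,
    each with >= 2 samples).  Genes with zero pooled variance are passed
    through uncorrected with a warning.
    """
    batches = batches.reindex(expr.columns)
    if batches.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = [str(b) for b in pd.unique(batches)]
    if len(levels) < 2:
        raise ValueError("need at least 2 batches")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    cols_by_batch = {b: expr.columns[(batches == b).to_numpy()] for b in levels}
    for b, cols in cols_by_batch.items():
        if len(cols) < 2:
            raise ValueError(f"batch {b} has fewer than 2 samples")

    Y = expr.to_numpy(dtype=float)
    n_total = Y.shape[1]
    sizes = {b: len(cols_by_batch[b]) for b in levels}
    batch_idx = {b: expr.columns.get_indexer(cols_by_batch[b]) for b in levels}

    batch_means = {b: Y[:, batch_idx[b]].mean(axis=1) for b in levels}
    alpha = sum(sizes[b] * batch_means[b] for b in levels) / n_total
    resid = Y.copy()
    for b in levels:
        resid[:, batch_idx[b]] -= batch_means[b][:, None]
    sigma2 = (resid ** 2).sum(axis=1) / n_total

    total_var = Y.var(axis=1)
    skip = total_var <= _EPS
    if skip.any():
        warnings.warn(f"{int(skip.sum())} zero-variance genes passed through "
                      "uncorrected")
    # genes constant within every batch but offset between batches: the
    # standardization is degenerate, so apply the location-only limit of the
    # adjustment (batch means mapped to the grand mean)
    location_only = (sigma2 <= _EPS) & ~skip
    sigma = np.sqrt(np.where(sigma2 <= _EPS, 1.0, sigma2))

    Z = (Y - alpha[:, None]) / sigma[:, None]
    gamma_hat = {b: Z[:, batch_idx[b]].mean(axis=1) for b in levels}
    delta2_hat = {b: Z[:, batch_idx[b]].var(axis=1, ddof=0) for b in levels}

    out = Y.copy()
    gamma_star, delta2_star, hyper, iters = {}, {}, {}, {}
    active = ~skip & ~location_only
    for b in levels:
        if location_only.any():
            cols = batch_idx[b]
            out[np.ix_(location_only, cols)] = (
                Y[np.ix_(location_only, cols)]
                - batch_means[b][location_only, None]
                + alpha[location_only, None])
    for b in levels:
        gs, ds, hp, it = _eb_fit(Z[active][:, batch_idx[b]],
                                 gamma_hat[b][active], delta2_hat[b][active],
                                 conv=conv, max_iter=max_iter)
        g_full = np.zeros(Y.shape[0])
        d_full = np.ones(Y.shape[0])
        g_full[active] = gs
        d_full[active] = ds
        gamma_star[b], delta2_star[b] = g_full, d_full
        hyper[b], iters[b] = hp, it
        adj = (sigma / np.sqrt(d_full))[:, None] \
            * (Z[:, batch_idx[b]] - g_full[:, None]) + alpha[:, None]
        cols = batch_idx[b]
        out[np.ix_(active, cols)] = adj[active]

    corrected = pd.DataFrame(out, index=expr.index, columns=expr.columns)
    model = CombatModel(
        batches=levels, batch_sizes=sizes,
        alpha=pd.Series(alpha, index=expr.index),
        sigma2=pd.Series(sigma2, index=expr.index),
        gamma_hat=pd.DataFrame(gamma_hat, index=expr.index).T,
        delta2_hat=pd.DataFrame(delta2_hat, index=expr.index).T,
        gamma_star=pd.DataFrame(gamma_star, index=expr.index).T,
        delta2_star=pd.DataFrame(delta2_star, index=expr.index).T,
        hyperparameters=hyper, n_iterations=iters,
        skipped_genes=expr.index[skip].tolist(),
    )
    return corrected, model
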