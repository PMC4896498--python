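"""Regression-based batch rescaling: Deming, Passing-Bablok, LMM, polynomial.

All four estimate a mapping from the early-batch (BL_rep) measurements to the
late-batch (BLFU_rep) measurements of the same RNA aliquots and then rescale
every value of the early batch through that mapping.  Deming and
Passing-Bablok are errors-in-variables estimators (both axes noisy); the
linear mixed model and the cubic polynomial absorb between-subject biology
with subject terms so that only the technical relation enters the mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from ..containers import BATCH, GROUP, SUBJECT

logger = logging.getLogger(__name__)

__all__ = [
    "RescaleModel",
    "build_replicate_pairs",
    "fit_deming",
    "fit_passing_bablok",
    "fit_lmm_rescale",
    "fit_polynomial",
    "apply_rescale",
]


@dataclass(frozen=True)
class RescaleModel:
    """Fitted coefficients of a batch-rescaling regression.

    ``coefficients`` is (intercept, slope) for the linear methods and
    (intercept, linear, quadratic, cubic) for the polynomial.
    """

    method: str
    coefficients: tuple[float, ...]
    error_variance_ratio: float | None = None  # Deming lambda

    def __post_init__(self) -> None:
        n = 4 if self.method == "polynomial" else 2
        if len(self.coefficients) != n:
            raise ValueError(f"{self.method} model needs {n} coefficients")
        if self.error_variance_ratio is not None and self.error_variance_ratio <= 0:
            raise ValueError("error variance ratio must be > 0")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c * x ** p for p, c in enumerate(self.coefficients))


def build_replicate_pairs(expr: pd.DataFrame, meta: pd.DataFrame,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x, y, subject) arrays from all within-subject BL_rep x BLFU_rep pairs.

    For each subject every BL_rep column is paired with every BLFU_rep column
    (the Cartesian product) and the pairing is pooled over all probes, so a
    subject with 2 x 3 replicates contributes 6 pairs per probe.
    """
    xs, ys, subj = [], [], []
    n_probes = expr.shape[0]
    for subject, rows in meta.groupby(SUBJECT):
        bl = rows.index[rows[GROUP] == "BL_rep"]
        fu = rows.index[rows[GROUP] == "BLFU_rep"]
        for a in bl:
            for b in fu:
                xs.append(expr[a].to_numpy())
                ys.append(expr[b].to_numpy())
                subj.append(np.full(n_probes, subject))
    if not xs:
        raise ValueError("no BL_rep / BLFU_rep pairs in the data")
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(subj))


def fit_deming(x: np.ndarray, y: np.ndarray, lam: float = 1.0) -> RescaleModel:
    """Closed-form Deming (errors-in-variables) regression.

    ``lam`` is the ratio of the error variances var(eps_y) / var(eps_x); the
    default 1 gives orthogonal regression.  Slope::

        b = [ (Syy - lam*Sxx) + sqrt((Syy - lam*Sxx)^2 + 4*lam*Sxy^2) ] / (2*Sxy)
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("Deming regression needs >= 3 paired points")
    if lam <= 0:
        raise ValueError("error variance ratio must be > 0")
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    if sxx == 0:
        raise ValueError("x has zero variance; Deming slope undefined")
    if sxy == 0:
        slope = float(np.sqrt(lam * syy / sxx)) if syy > 0 else 0.0
    else:
        disc = (syy - lam * sxx) ** 2 + 4.0 * lam * sxy ** 2
        slope = ((syy - lam * sxx) + np.sqrt(disc)) / (2.0 * sxy)
    return RescaleModel("deming", (float(ym - slope * xm), float(slope)),
                        error_variance_ratio=lam)


def fit_passing_bablok(x: np.ndarray, y: np.ndarray) -> RescaleModel:
    """Exact Passing-Bablok regression on probe-wise batch means.

    The slope is the shifted median of all pairwise slopes
    S_ij = (y_j - y_i)/(x_j - x_i), excluding undefined slopes (equal x) and
    slopes exactly -1, with the classical offset K = #{S_ij < -1}; the
    intercept is median(y - slope*x).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("Passing-Bablok needs >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all x identical; slope undefined")
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    valid = dx != 0
    slopes = dy[valid] / dx[valid]
    slopes = slopes[slopes != -1.0]
    if len(slopes) == 0:
        raise ValueError("no valid pairwise slopes")
    slopes.sort()
    n = len(slopes)
    k_off = int(np.sum(slopes < -1.0))
    if n // 2 + k_off >= n:
        # the classical shifted median assumes positively associated inputs
        raise ValueError("Passing-Bablok shifted median is out of range; "
                         "inputs are predominantly negatively associated")
    if n % 2:
        slope = slopes[(n - 1) // 2 + k_off]
    else:
        slope = 0.5 * (slopes[n // 2 - 1 + k_off] + slopes[n // 2 + k_off])
    intercept = float(np.median(y - slope * x))
    return RescaleModel("passing_bablok", (intercept, float(slope)))


def fit_lmm_rescale(x: np.ndarray, y: np.ndarray,
                    subjects: np.ndarray) -> RescaleModel:
    """Linear mixed model y ~ x with a random intercept per subject (REML).

    Only the fixed effects enter the rescaling; the subject intercepts soak
    up between-individual biology.  A singular or non-converging fit falls
    back to ordinary least squares with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(subjects)) < 2:
        raise ValueError("mixed model needs >= 2 subjects")
    if len(x) < 3:
        raise ValueError("mixed model needs >= 3 pairs")
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # bfgs: the default lbfgs can report convergence with corrupt
            # fixed effects when the subject variance hits the zero boundary
            fit = MixedLM(y, exog, groups=np.asarray(subjects)).fit(
                reml=True, method="bfgs")
        if not np.all(np.isfinite(fit.fe_params)):
            raise np.linalg.LinAlgError("non-finite fixed effects")
        b0, b1 = fit.fe_params[:2]
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"mixed model fit failed ({err}); falling back to OLS")
        b0, b1 = np.polynomial.polynomial.polyfit(x, y, 1)
    return RescaleModel("lmm", (float(b0), float(b1)))


def fit_polynomial(x: np.ndarray, y: np.ndarray,
                   subjects: np.ndarray | None = None) -> RescaleModel:
    """Third-order polynomial least squares with subject indicator covariates.

    Subject dummies (first level as reference) absorb individual offsets;
    only the four polynomial coefficients are returned.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 5:
        raise ValueError("polynomial regression needs >= 5 distinct x values")
    cols = [np.ones_like(x), x, x ** 2, x ** 3]
    if subjects is not None:
        levels = np.unique(subjects)
        for lev in levels[1:]:
            cols.append((np.asarray(subjects) == lev).astype(float))
    design = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient polynomial design")
    return RescaleModel("polynomial", tuple(float(c) for c in coef[:4]))


def apply_rescale(model, expr: pd.DataFrame, batches: pd.Series,
                  source_batch: str = "BL") -> pd.DataFrame:
    """Map every value of the source batch through the fitted model.

    ``model`` may be a :class:`RescaleModel` or any object with a
    ``predict(x)`` method (e.g. a qspline mapping); columns of the other
    batch are left untouched.
    """
    batches = batches.reindex(expr.columns)
    out = expr.copy()
    cols = expr.columns[batches == source_batch]
    per_column = hasattr(model, "predict_column")
    for c in cols:
        if per_column:
            out[c] = model.predict_column(c, expr[c].to_numpy())
        else:
            out[c] = model.predict(expr[c].to_numpy())
    return out
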