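"""Quality control for two-batch longitudinal expression matrices.

The cascade mirrors a standard BeadChip workflow: array-level signal-to-noise
filtering, a per-batch mean-level filter, restriction to probes shared between
chip versions, detection-above-background calling against negative controls,
an expressed-probe filter, sample mix-up detection from sex-specific and
polymorphism-in-probe signals, and per-batch quantile normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BATCH, IS_NEGATIVE_CONTROL, ON_V3, ON_V4, ROLE, SUBJECT, TIMEPOINT,
)

logger = logging.getLogger(__name__)

__all__ = [
    "snr",
    "filter_samples",
    "intersect_shared_probes",
    "detection_call",
    "low_detection_samples",
    "filter_expressed",
    "detect_mixups_sex",
    "detect_mixups_snp",
    "detect_mixups",
    "quantile_normalize",
    "QCReport",
    "run_qc",
]


def snr(intensities: np.ndarray) -> float:
    """Array signal-to-noise ratio: 95th / 5th percentile of raw intensities.

    Quantiles use linear interpolation between order statistics.  Input must
    be raw-scale (not log) intensities; the ratio is scale-dependent.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise ValueError("SNR needs at least 20 finite intensity values")
    if (x <= 0).any():
        raise ValueError("SNR is defined for positive intensities only")
    q5, q95 = np.quantile(x, [0.05, 0.95])
    if q5 <= 0:
        raise ValueError("5th percentile is non-positive; SNR undefined")
    return float(q95 / q5)


@dataclass
class QCReport:
    """Everything the QC cascade measured and decided."""

    snr: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    mean_log2: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    excluded_samples: list[dict] = field(default_factory=list)
    detection_fraction: pd.DataFrame | None = None  # probe x batch
    kept_probes: list[str] = field(default_factory=list)
    low_detection_samples: list[str] = field(default_factory=list)
    mixup_pairs: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "snr": self.snr.round(4).to_dict(),
            "mean_log2": self.mean_log2.round(4).to_dict(),
            "excluded_samples": self.excluded_samples,
            "n_kept_probes": len(self.kept_probes),
            "kept_probes": list(self.kept_probes),
            "low_detection_samples": list(self.low_detection_samples),
            "mixup_pairs": self.mixup_pairs,
        }


def filter_samples(expr: pd.DataFrame, meta: pd.DataFrame,
                   snr_min: float = 6.0, sd_limit: float = 3.0,
                   ) -> tuple[pd.DataFrame, QCReport]:
    """Drop low-SNR arrays, then per-batch mean-level outliers.

    SNR is computed on the raw intensity scale (2**log2).  A sample is dropped
    when SNR <= ``snr_min``, or when its mean log2 expression deviates from
    its batch's mean-of-means by more than ``sd_limit`` batch SDs.  Each
    excluded sample carries exactly one primary reason.
    """
    for batch, cols in meta.groupby(BATCH).groups.items():
        if len(cols) < 4:
            raise ValueError(f"batch {batch} has fewer than 4 samples")
    report = QCReport()
    raw = np.power(2.0, expr)
    report.snr = raw.apply(lambda col: snr(col.to_numpy()), axis=0)
    report.mean_log2 = expr.mean(axis=0)

    keep = report.snr > snr_min
    for s in report.snr.index[~keep]:
        report.excluded_samples.append(
            {"sample_id": s, "reason": "snr", "snr": float(report.snr[s])})

    # mean-level filter within each measurement batch, on SNR-passing samples
    for batch, samples in meta[keep.reindex(meta.index, fill_value=False)].groupby(BATCH).groups.items():
        means = report.mean_log2[list(samples)]
        center, sd = means.mean(), means.std(ddof=1)
        if sd == 0:
            continue
        for s in means.index[(means - center).abs() > sd_limit * sd]:
            keep[s] = False
            report.excluded_samples.append(
                {"sample_id": s, "reason": "mean-level",
                 "mean_log2": float(means[s]),
                 "batch_mean": float(center), "batch_sd": float(sd)})

    kept_cols = [c for c in expr.columns if keep[c]]
    kept_meta = meta.loc[kept_cols]
    for batch in meta[BATCH].unique():
        if (kept_meta[BATCH] == batch).sum() == 0:
            raise ValueError(f"batch {batch} is empty after sample filtering")
    return expr[kept_cols], report


def intersect_shared_probes(expr_bl: pd.DataFrame, expr_fu: pd.DataFrame,
                            probes: pd.DataFrame,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to probes present on both chip versions.

    Both outputs carry the shared probes in the annotation's row order.
    """
    for mat, name in ((expr_bl, "BL"), (expr_fu, "FU")):
        uncovered = mat.index.difference(probes.index)
        if len(uncovered):
            raise ValueError(
                f"{name} matrix has probes missing from the annotation: "
                f"{list(uncovered[:5])}")
    shared = probes.index[probes[ON_V3].astype(bool) & probes[ON_V4].astype(bool)]
    shared = shared[shared.isin(expr_bl.index) & shared.isin(expr_fu.index)]
    if len(shared) == 0:
        raise ValueError("no probes shared between chip versions")
    return expr_bl.loc[shared], expr_fu.loc[shared]


def detection_call(expr: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Detection-above-background p-values against negative controls.

    For every sample, each probe's p-value is the corrected empirical tail
    probability of its intensity under that sample's own negative-control
    distribution::

        p = (1 + #{controls >= intensity}) / (1 + #controls)

    so p lies in (0, 1] and decreases monotonically with intensity.  A probe
    is conventionally called detected when p < 0.05.
    """
    nc = probes.index[probes[IS_NEGATIVE_CONTROL].astype(bool)]
    nc = nc[nc.isin(expr.index)]
    if len(nc) == 0:
        raise ValueError("no negative-control probes in the matrix")
    if len(nc) < 20:
        raise ValueError("need at least 20 negative-control probes")
    values = expr.to_numpy()
    out = np.empty_like(values)
    nc_rows = expr.index.get_indexer(nc)
    n_ctrl = len(nc)
    for j in range(values.shape[1]):
        controls = np.sort(values[nc_rows, j])
        # controls >= v  <=>  n_ctrl - first index where control >= v
        ge = n_ctrl - np.searchsorted(controls, values[:, j], side="left")
        out[:, j] = (1.0 + ge) / (1.0 + n_ctrl)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def low_detection_samples(detections: pd.DataFrame, alpha: float = 0.05,
                          min_detected: int = 6000) -> list[str]:
    """Samples with fewer than ``min_detected`` probes at p < alpha."""
    counts = (detections < alpha).sum(axis=0)
    return counts.index[counts < min_detected].tolist()


def filter_expressed(detections: pd.DataFrame, meta: pd.DataFrame,
                     alpha: float = 0.05, fraction: float = 0.10) -> list[str]:
    """Probes detected in strictly more than ``fraction`` of each batch.

    A probe is kept when its detected fraction exceeds the threshold in the
    BL batch AND in the FU batch (strict inequality on both).
    """
    batches = meta.loc[detections.columns, BATCH]
    keep = pd.Series(True, index=detections.index)
    for batch in ("BL", "FU"):
        cols = batches.index[batches == batch]
        if len(cols) == 0:
            raise ValueError(f"batch {batch} has no samples")
        frac = (detections[cols] < alpha).mean(axis=1)
        keep &= frac > fraction
    return detections.index[keep].tolist()


def _mixup_flags(expr: pd.DataFrame, meta: pd.DataFrame, probe: str,
                 sd_limit: float) -> list[dict]:
    """Per-subject BL-FU difference of one probe, 3-SD outlier rule."""
    values = expr.loc[probe]
    d = {}
    for subject, rows in meta.groupby(SUBJECT):
        bl = rows.index[rows[TIMEPOINT] == "BL"]
        fu = rows.index[rows[TIMEPOINT] == "FU"]
        if len(bl) == 0 or len(fu) == 0:
            continue
        d[subject] = float(values[bl].mean() - values[fu].mean())
    d = pd.Series(d)
    if len(d) < 2:
        return []
    center, sd = d.mean(), d.std(ddof=1)
    if sd == 0:
        # degenerate spread: the 3-SD band is empty only by degeneracy
        return []
    flagged = d.index[(d - center).abs() > sd_limit * sd]
    return [{"subject_id": s, "difference": float(d[s]),
             "deviation_sd": float(abs(d[s] - center) / sd)} for s in flagged]


def detect_mixups_sex(expr: pd.DataFrame, meta: pd.DataFrame,
                      probes: pd.DataFrame, sd_limit: float = 3.0) -> list[dict]:
    """Flag subjects whose sex-probe BL-FU change is a >3-SD outlier.

    The female-specific and male-specific probes are screened independently
    and the union of flags returned, each labelled with the triggering probe.
    """
    out = []
    for role in ("sex_female", "sex_male"):
        hits = probes.index[probes[ROLE] == role]
        hits = hits[hits.isin(expr.index)]
        if len(hits) == 0:
            raise ValueError(f"no probe with role {role}")
        for rec in _mixup_flags(expr, meta, hits[0], sd_limit):
            rec["detector"] = "sex"
            rec["probe"] = hits[0]
            out.append(rec)
    return out


def detect_mixups_snp(expr: pd.DataFrame, meta: pd.DataFrame,
                      probes: pd.DataFrame, sd_limit: float = 3.0) -> list[dict]:
    """Flag subjects via the polymorphism-in-probe signal (genotype levels)."""
    hits = probes.index[probes[ROLE] == "snp"]
    hits = hits[hits.isin(expr.index)]
    if len(hits) == 0:
        raise ValueError("no probe with role snp")
    out = []
    for rec in _mixup_flags(expr, meta, hits[0], sd_limit):
        rec["detector"] = "snp"
        rec["probe"] = hits[0]
        out.append(rec)
    return out


def detect_mixups(expr: pd.DataFrame, meta: pd.DataFrame,
                  probes: pd.DataFrame, sd_limit: float = 3.0) -> list[dict]:
    """Run the sex rule, then the SNP rule on the full set; merge by subject.

    A subject visible to both detectors is reported once with both labels.
    """
    merged: dict[int, dict] = {}
    for rec in (detect_mixups_sex(expr, meta, probes, sd_limit)
                + detect_mixups_snp(expr, meta, probes, sd_limit)):
        s = rec["subject_id"]
        if s not in merged:
            merged[s] = {"subject_id": s, "detectors": []}
        if rec["detector"] not in merged[s]["detectors"]:
            merged[s]["detectors"].append(rec["detector"])
    return list(merged.values())


def quantile_normalize(expr: pd.DataFrame,
                       groups: pd.Series | None = None) -> pd.DataFrame:
    """Quantile-normalize columns, separately within each group.

    Within a group, every column's sorted values are replaced by the mean of
    the group's sorted columns; tied entries receive the average of their
    target positions, so within-column ranking is preserved.
    """
    if groups is None:
        groups = pd.Series("all", index=expr.columns)
    groups = groups.reindex(expr.columns)
    out = expr.copy()
    for _, cols in groups.groupby(groups).groups.items():
        cols = list(cols)
        if len(cols) < 2:
            raise ValueError("quantile normalization needs >= 2 samples per group")
        block = expr[cols].to_numpy()
        ref = np.sort(block, axis=0).mean(axis=1)
        normed = np.empty_like(block)
        for j in range(block.shape[1]):
            order = np.argsort(block[:, j], kind="stable")
            svals = block[order, j]
            target = ref.copy()
            # average the reference over each tie block
            starts = np.flatnonzero(np.r_[True, svals[1:] != svals[:-1]])
            ends = np.r_[starts[1:], len(svals)]
            for s, e in zip(starts, ends):
                if e - s > 1:
                    target[s:e] = ref[s:e].mean()
            normed[order, j] = target
        out[cols] = normed
    return out


def run_qc(expr: pd.DataFrame, meta: pd.DataFrame, probes: pd.DataFrame,
           snr_min: float = 6.0, sd_limit: float = 3.0,
           dabg_alpha: float = 0.05, expressed_fraction: float = 0.10,
           mixup_sd: float = 3.0, min_detected_probes: int = 6000,
           ) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Full QC cascade; returns (filtered matrix, filtered metadata, report).

    Order: sample filters -> shared-probe intersection -> detection calling ->
    expressed-probe filter -> mix-up removal.  (Quantile normalization is a
    correction-stage option, not part of QC proper.)
    """
    expr, report = filter_samples(expr, meta, snr_min=snr_min, sd_limit=sd_limit)
    meta = meta.loc[expr.columns]

    bl_cols = meta.index[meta[BATCH] == "BL"]
    fu_cols = meta.index[meta[BATCH] == "FU"]
    bl, fu = intersect_shared_probes(expr[bl_cols], expr[fu_cols], probes)
    expr = pd.concat([bl, fu], axis=1)[list(meta.index)]

    detections = detection_call(expr, probes)
    if min_detected_probes >= expr.shape[0]:
        # the detected-probe cut presupposes a panel larger than the cut;
        # on a smaller panel it would exclude every sample vacuously
        logger.warning(
            "detected-probe threshold (%d) is not below the panel size (%d); "
            "skipping the low-detection filter", min_detected_probes,
            expr.shape[0])
        report.low_detection_samples = []
    else:
        report.low_detection_samples = low_detection_samples(
            detections, alpha=dabg_alpha, min_detected=min_detected_probes)
    if report.low_detection_samples:
        logger.warning("%d samples below the detected-probe threshold",
                       len(report.low_detection_samples))
        drop = set(report.low_detection_samples)
        for s in report.low_detection_samples:
            report.excluded_samples.append({"sample_id": s, "reason": "low-detection"})
        expr = expr[[c for c in expr.columns if c not in drop]]
        meta = meta.loc[expr.columns]
        detections = detections[expr.columns]

    batches = meta[BATCH]
    frac = pd.DataFrame({
        b: (detections[batches.index[batches == b]] < dabg_alpha).mean(axis=1)
        for b in ("BL", "FU")})
    report.detection_fraction = frac

    # keep special probes regardless of expression filtering: they are needed
    # by the mix-up detectors and by replicate RUV (negative controls)
    kept = filter_expressed(detections, meta, alpha=dabg_alpha,
                            fraction=expressed_fraction)
    special = probes.index[(probes[ROLE] != "regular")
                           | probes[IS_NEGATIVE_CONTROL].astype(bool)]
    kept_index = expr.index[expr.index.isin(set(kept) | set(special))]
    report.kept_probes = kept_index.tolist()
    expr = expr.loc[kept_index]

    report.mixup_pairs = detect_mixups(expr, meta, probes, sd_limit=mixup_sd)
    flagged = {m["subject_id"] for m in report.mixup_pairs}
    if flagged:
        drop_cols = meta.index[meta[SUBJECT].isin(flagged)]
        expr = expr.drop(columns=drop_cols)
        meta = meta.drop(index=drop_cols)
    return expr, meta, report
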