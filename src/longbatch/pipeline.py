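"""Pipeline orchestration: simulate -> qc -> correct -> evaluate.

A :class:`PipelineConfig` carries every tunable threshold (defaults are the
published study values), the correction method, and one global seed which is
expanded into fixed per-stage substreams so that toggling a stage never
perturbs another stage's randomness.  :func:`run_pipeline` executes the
enabled stages and returns a manifest of what happened.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io, qc
from .containers import BATCH, GROUP, validate_expression, validate_meta, validate_probes
from .correction import correct
from .simulate import (
    BatchShift, PhenotypeModel, SimulationConfig, simulate_cohort,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

_STAGE_IDS = {"simulate": 0, "qc": 1, "correct": 2, "evaluate": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2**31)."""
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Stage toggles, method selection and the published default thresholds."""

    # stages
    simulate: bool = True
    run_qc: bool = True
    run_correction: bool = True
    run_evaluation: bool = True
    # simulation
    sim_kind: str = "replicates"  # or "cohort"
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig
    # correction
    method: str = "combat"
    qn_first: bool = True
    k: int | None = None
    lam: float = 1.0
    # thresholds (study defaults)
    snr_min: float = 6.0
    dabg_alpha: float = 0.05
    expressed_fraction: float = 0.10
    mixup_sd: float = 3.0
    fdr: float = 0.05
    pvca_threshold: float = 0.60
    pair_iterations: int = 22
    pair_subset: int = 50
    min_detected_probes: int = 6000
    # io
    seed: int = 0
    expr_path: str | None = None
    meta_path: str | None = None
    probes_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("snr_min", "dabg_alpha", "expressed_fraction", "mixup_sd",
                     "fdr", "pvca_threshold", "pair_iterations", "pair_subset",
                     "min_detected_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        overrides = dict(self.sim)
        if "batch_shift" in overrides and isinstance(overrides["batch_shift"], dict):
            overrides["batch_shift"] = BatchShift(**overrides["batch_shift"])
        if "phenotype_model" in overrides and isinstance(overrides["phenotype_model"], dict):
            overrides["phenotype_model"] = PhenotypeModel(**overrides["phenotype_model"])
        overrides.setdefault("seed", stage_seed(self.seed, "simulate"))
        return SimulationConfig(**overrides)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    counts: dict[str, dict]
    results: dict
    started: float
    finished: float

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "counts": self.counts,
            "results": self.results,
            "started": self.started,
            "finished": self.finished,
        }

    def comparable(self) -> dict:
        """Manifest content without timestamps (for determinism checks)."""
        d = self.to_dict()
        d.pop("started")
        d.pop("finished")
        return d


def _evaluate(expr: pd.DataFrame, meta: pd.DataFrame,
              config: PipelineConfig) -> dict:
    results: dict = {}
    groups = meta[GROUP]
    bl = meta.index[groups == "BL_rep"]
    fu = meta.index[groups == "BLFU_rep"]
    if len(bl) >= 2 and len(fu) >= 2:
        de = evaluation.differential_expression(expr, bl, fu, alpha=config.fdr)
        results["de"] = {
            "n_significant_bh": de.n_significant_bh,
            "n_significant_bonferroni": de.n_significant_bonferroni,
            "total_probes": de.total_probes,
            "fraction_bh": de.fraction_significant_bh,
        }
        rep_cols = meta.index[groups.isin(["BL_rep", "BLFU_rep", "FU_rep"])]
        pv = evaluation.pvca(expr[rep_cols], meta.loc[rep_cols],
                             variance_threshold=config.pvca_threshold)
        results["pvca"] = {"n_retained_pcs": pv.n_retained_pcs,
                           "proportions": pv.proportions}
        rep2 = meta.index[groups.isin(["BL_rep", "BLFU_rep"])]
        dc = evaluation.dendrogram_classify(expr[rep2], meta.loc[rep2])
        results["cluster"] = {
            str(k): v for k, v in dc.classification.items()}
    if (groups == "cohort").any():
        cohort = meta.index[groups == "cohort"]
        subjects_both = meta.loc[cohort].groupby("subject_id")[BATCH].nunique()
        n_both = int((subjects_both == 2).sum())
        subset = min(config.pair_subset, n_both)
        if subset >= 2:
            pp = evaluation.pair_proximity_statistic(
                expr[cohort], meta.loc[cohort],
                n_iterations=config.pair_iterations, subset_size=subset,
                seed=stage_seed(config.seed, "evaluate"))
            results["pair_proximity"] = {
                "mean_proportion": pp.mean_proportion,
                "per_iteration": pp.per_iteration_proportions,
            }
    return results


def run_pipeline(config: PipelineConfig, out_dir=None,
                 expr: pd.DataFrame | None = None,
                 meta: pd.DataFrame | None = None,
                 probes: pd.DataFrame | None = None) -> RunManifest:
    """Execute the enabled stages in order; returns the run manifest.

    Inputs can be passed in memory or read from the configured paths; when
    the simulate stage is enabled it produces them.  A stage failure aborts
    the run with the failing stage named; outputs of completed stages are
    retained on disk.
    """
    started = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stages, counts = [], {}
    results: dict = {}

    def _record(stage: str, e: pd.DataFrame) -> None:
        counts[stage] = {"n_probes": int(e.shape[0]), "n_samples": int(e.shape[1])}

    try:
        if config.simulate:
            sim_config = config.simulation_config()
            ds = (simulate_dataset(sim_config) if config.sim_kind == "replicates"
                  else simulate_cohort(sim_config))
            expr, meta, probes = ds.expression, ds.meta, ds.probes
            stages.append("simulate")
            _record("simulate", expr)
            if out is not None:
                io.write_expression(expr, out / "expression_raw.tsv")
                io.write_meta(meta, out / "meta.tsv")
                io.write_probes(probes, out / "probes.tsv")
                io.write_json({k: v for k, v in ds.truth.items()
                               if k in ("variance_shares", "mixup_pairs",
                                        "shift_x0", "config")},
                              out / "truth.json")
        else:
            if expr is None:
                expr = io.read_expression(config.expr_path)
            if meta is None:
                meta = io.read_meta(config.meta_path, expr)
            if probes is None:
                probes = io.read_probes(config.probes_path, expr)
        validate_expression(expr)
        validate_meta(meta, expr)
        validate_probes(probes, expr)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'simulate/load' failed: {err}") from err

    if config.run_qc:
        try:
            expr, meta, report = qc.run_qc(
                expr, meta, probes, snr_min=config.snr_min,
                sd_limit=config.mixup_sd, dabg_alpha=config.dabg_alpha,
                expressed_fraction=config.expressed_fraction,
                mixup_sd=config.mixup_sd,
                min_detected_probes=config.min_detected_probes)
            stages.append("qc")
            _record("qc", expr)
            results["qc"] = {"n_excluded": len(report.excluded_samples),
                             "n_mixups": len(report.mixup_pairs)}
            if out is not None:
                io.write_json(report.to_dict(), out / "qc_report.json")
                io.write_expression(expr, out / "expression_qc.tsv")
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'qc' failed: {err}") from err

    if config.run_correction:
        try:
            expr, model = correct(expr, meta, config.method,
                                  qn_first=config.qn_first, probes=probes,
                                  k=config.k, lam=config.lam)
            stages.append("correct")
            _record("correct", expr)
            results["correction"] = {"method": config.method,
                                     "qn_first": config.qn_first}
            if out is not None:
                io.write_expression(expr, out / "expression_corrected.tsv")
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'correct' failed: {err}") from err

    if config.run_evaluation:
        try:
            results["evaluation"] = _evaluate(expr, meta, config)
            stages.append("evaluate")
            _record("evaluate", expr)
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'evaluate' failed: {err}") from err

    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           stages=stages, counts=counts, results=results,
                           started=started, finished=time.time())
    if out is not None:
        io.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
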