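"""Seeded generator for synthetic longitudinal microarray cohorts.

The generator emulates the statistical structure of a two-visit (baseline BL,
5-year follow-up FU) monocyte expression study in which RNA extracted at BL was
re-hybridized at FU, yielding three technical-replicate groups per subject:

* ``BL_rep``  -- extracted at BL, measured at BL,
* ``BLFU_rep`` -- extracted at BL, measured at FU (pure batch contrast to BL_rep),
* ``FU_rep``  -- extracted at FU, measured at FU.

Per probe ``g``, subject ``s`` and measurement ``m`` the model is additive on
the log2 scale::

    Y = mu_g + u_{g,s} + t_g * [extraction == FU] + f_g * [batch == FU]
        + beta_g * phenotype_s + c_chip(m) + eps

with a subject-specific profile ``u``, a biological five-year drift ``t``, an
intensity-dependent batch shift ``f`` (largest for weakly expressed probes,
see :class:`BatchShift`), a phenotype effect on a sparse probe subset, a
random chip intercept and i.i.d. technical noise.  Negative-control probes
receive the batch shift and noise only; one female- and one male-specific sex
probe and one polymorphism-in-probe (SNP) probe are included for the mix-up
detectors.  Sample mix-ups are injected by swapping the FU-extraction columns
of subject pairs of opposite sex (and, where possible, different genotype).

Everything is drawn from a single :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``, so identical configurations give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    AGE, BATCH, CHIP, GROUP, IS_NEGATIVE_CONTROL, ON_V3, ON_V4, PHENOTYPE,
    ROLE, SEX, SUBJECT, TIMEPOINT,
)

__all__ = [
    "BatchShift",
    "PhenotypeModel",
    "SimulationConfig",
    "SimulatedDataset",
    "generate_replicate_design",
    "design_totals",
    "median_replicates_per_sample",
    "default_ruv_k",
    "simulate_dataset",
    "simulate_cohort",
]

# Published replicate design: per subject the number of BL_rep / BLFU_rep /
# FU_rep measurements.  Column sums 35 / 43 / 54, grand total 132.
_REPLICATE_DESIGN = (
    (1, 2, 3, 3),
    (2, 2, 3, 3),
    (3, 3, 2, 3),
    (4, 2, 3, 4),
    (5, 2, 3, 4),
    (6, 2, 3, 4),
    (7, 2, 3, 4),
    (8, 2, 3, 4),
    (9, 2, 3, 4),
    (10, 2, 2, 4),
    (11, 3, 3, 4),
    (12, 3, 3, 2),
    (13, 2, 3, 4),
    (14, 3, 3, 4),
    (15, 3, 3, 3),
)

_GENOTYPE_MEANS = {"AA": 6.5, "AG": 8.8, "GG": 9.9}  # polymorphism-in-probe levels
_SNP_MAF = 0.47
_SEX_PROBE_LEVELS = {
    "sex_female": {"F": 10.0, "M": 5.0},  # XIST-like
    "sex_male": {"F": 5.0, "M": 9.0},     # EIF1AY-like
}


def generate_replicate_design() -> pd.DataFrame:
    """Return the 15-subject replicate design (counts per replicate group).

    Columns: ``subject_id``, ``n_bl_rep``, ``n_blfu_rep``, ``n_fu_rep``.
    """
    return pd.DataFrame(
        _REPLICATE_DESIGN,
        columns=["subject_id", "n_bl_rep", "n_blfu_rep", "n_fu_rep"],
    )


def design_totals(design: pd.DataFrame) -> dict[str, int]:
    """Group totals and the grand total of a replicate design."""
    totals = {
        "BL_rep": int(design["n_bl_rep"].sum()),
        "BLFU_rep": int(design["n_blfu_rep"].sum()),
        "FU_rep": int(design["n_fu_rep"].sum()),
    }
    totals["total"] = sum(totals.values())
    return totals


def median_replicates_per_sample(design: pd.DataFrame) -> float:
    """Median per-subject count of BL_rep + BLFU_rep measurements.

    This is the replicate count of the BL aliquot, the quantity behind the
    default number of unwanted factors k for replicate-based RUV.
    """
    return float((design["n_bl_rep"] + design["n_blfu_rep"]).median())


def default_ruv_k(design: pd.DataFrame) -> int:
    """Default k for replicate RUV: min(n_samples // 4, median replicates)."""
    totals = design_totals(design)
    return int(min(totals["total"] // 4, median_replicates_per_sample(design)))


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    needed = {"subject_id", "n_bl_rep", "n_blfu_rep", "n_fu_rep"}
    if not needed <= set(design.columns):
        raise ValueError(f"replicate design needs columns {sorted(needed)}")
    counts = design[["n_bl_rep", "n_blfu_rep", "n_fu_rep"]].to_numpy()
    if not np.isin(counts, (2, 3, 4)).all():
        raise ValueError("replicate counts must each be in {2, 3, 4}")
    return design


@dataclass(frozen=True)
class BatchShift:
    """Monotone non-increasing intensity-dependent additive batch shift.

    ``f(x) = floor + (amplitude - floor) / (1 + exp((x - x0) / width))``

    ``amplitude`` is the shift (log2 units) at low intensities -- the default
    1.2 reproduces the >2-fold inflation of weakly expressed probes in the
    later batch -- and ``floor`` the asymptote at high intensities, a small
    global upward shift of the later batch.  ``x0`` defaults to the lower
    tertile of the baseline means; ``jitter_sd`` is the sigma of a per-probe
    lognormal factor so that the shift is not perfectly deterministic.
    """

    amplitude: float = 1.2
    floor: float = 0.3
    x0: float | None = None  # None: lower-tertile boundary of baseline means
    width: float = 0.5
    jitter_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.floor < 0 or self.amplitude < self.floor:
            raise ValueError(
                "batch shift must be monotone non-increasing and non-negative: "
                "need amplitude >= floor >= 0"
            )
        if self.width <= 0:
            raise ValueError("batch shift width must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    def __call__(self, x: np.ndarray, x0: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.floor + (self.amplitude - self.floor) / (
            1.0 + np.exp((x - x0) / self.width)
        )


@dataclass(frozen=True)
class PhenotypeModel:
    """Sparse probe associations with a continuous BMI-like phenotype."""

    n_associated_probes: int = 20
    effect_size: float = 0.05  # log2 units per phenotype unit
    mean: float = 26.0
    sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n_associated_probes < 0 or self.sd < 0:
            raise ValueError("invalid phenotype model")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, seeded parameterization of the synthetic generator."""

    n_subjects: int = 15
    n_probes: int = 2000
    n_negative_controls: int = 100
    baseline_mean_location: float = 6.0
    baseline_mean_scale: float = 1.2  # exponential tail: most probes sit low
    subject_effect_sd: float = 0.3
    timepoint_effect_sd: float = 0.1  # biological 5-year drift, log2 units
    batch_shift: BatchShift = field(default_factory=BatchShift)
    technical_noise_sd: float = 0.15
    chip_effect_sd: float = 0.03
    chip_size: int = 12  # samples per HT-12-style chip
    n_mixups: int = 0
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_effect_sd", "timepoint_effect_sd",
                     "technical_noise_sd", "chip_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_negative_controls >= self.n_probes:
            raise ValueError("n_negative_controls must be < n_probes")
        if self.chip_size < 1:
            raise ValueError("chip_size must be >= 1")
        if self.n_mixups > self.n_subjects // 2:
            raise ValueError("n_mixups must be <= n_subjects / 2")


@dataclass
class SimulatedDataset:
    """A raw (pre-QC) synthetic dataset plus the injected ground truth."""

    expression: pd.DataFrame  # probes x samples, log2
    meta: pd.DataFrame        # sample metadata
    probes: pd.DataFrame      # probe annotation
    truth: dict

    def config_record(self) -> dict:
        return dict(self.truth.get("config", {}))


def _sample_plan_from_design(design: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for rec in design.itertuples(index=False):
        sid = int(rec.subject_id)
        for group, count in (("BL_rep", rec.n_bl_rep),
                             ("BLFU_rep", rec.n_blfu_rep),
                             ("FU_rep", rec.n_fu_rep)):
            tp = "BL" if group in ("BL_rep", "BLFU_rep") else "FU"
            batch = "BL" if group == "BL_rep" else "FU"
            for i in range(int(count)):
                rows.append({
                    "sample_id": f"S{sid:02d}_{group}_{i + 1}",
                    SUBJECT: sid, TIMEPOINT: tp, BATCH: batch, GROUP: group,
                })
    return pd.DataFrame(rows)


def _sample_plan_cohort(n_subjects: int) -> pd.DataFrame:
    rows = []
    for sid in range(1, n_subjects + 1):
        rows.append({"sample_id": f"S{sid:03d}_BL", SUBJECT: sid,
                     TIMEPOINT: "BL", BATCH: "BL", GROUP: "cohort"})
        rows.append({"sample_id": f"S{sid:03d}_FU", SUBJECT: sid,
                     TIMEPOINT: "FU", BATCH: "FU", GROUP: "cohort"})
    return pd.DataFrame(rows)


def _build_probe_annotation(config: SimulationConfig) -> pd.DataFrame:
    n = config.n_probes
    n_nc = config.n_negative_controls
    if n - n_nc < 4:
        raise ValueError("need at least 4 regular probes beyond the controls")
    probe_ids = [f"P{i + 1:05d}" for i in range(n)]
    roles = np.array(["regular"] * n, dtype=object)
    is_nc = np.zeros(n, dtype=bool)
    # special probes first, then negative controls, then regular probes
    roles[0] = "sex_female"
    roles[1] = "sex_male"
    roles[2] = "snp"
    is_nc[3:3 + n_nc] = True
    return pd.DataFrame(
        {IS_NEGATIVE_CONTROL: is_nc, ROLE: roles, ON_V3: True, ON_V4: True},
        index=pd.Index(probe_ids, name="probe_id"),
    )


def _assign_chips(plan: pd.DataFrame, chip_size: int) -> list[str]:
    chips = pd.Series(index=plan.index, dtype=object)
    for batch in ("BL", "FU"):
        idx = plan.index[plan[BATCH] == batch]
        for pos, i in enumerate(idx):
            chips[i] = f"{batch}_chip{pos // chip_size + 1:02d}"
    return chips.tolist()


def _pick_mixup_pairs(subjects: pd.DataFrame, n_mixups: int,
                      rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pairs of opposite sex, preferring different SNP genotype."""
    pairs: list[tuple[int, int]] = []
    available = subjects.copy()
    for _ in range(n_mixups):
        females = available.index[available[SEX] == "F"].to_numpy()
        males = available.index[available[SEX] == "M"].to_numpy()
        if len(females) == 0 or len(males) == 0:
            raise ValueError("not enough opposite-sex subjects for mix-up injection")
        f = int(rng.choice(females))
        geno_f = available.loc[f, "genotype"]
        diff = [m for m in males if available.loc[m, "genotype"] != geno_f]
        m = int(rng.choice(diff if diff else males))
        pairs.append((f, m))
        available = available.drop(index=[f, m])
    return pairs


def _simulate(config: SimulationConfig, plan: pd.DataFrame) -> SimulatedDataset:
    rng = np.random.default_rng(config.seed)
    probes = _build_probe_annotation(config)
    n_probes = config.n_probes
    n_samples = len(plan)
    probe_ids = probes.index
    roles = probes[ROLE].to_numpy()
    is_nc = probes[IS_NEGATIVE_CONTROL].to_numpy()
    regular = (roles == "regular") & ~is_nc

    subject_ids = sorted(plan[SUBJECT].unique())
    n_subj = len(subject_ids)
    subj_pos = {s: i for i, s in enumerate(subject_ids)}

    # subject-level covariates
    sex = rng.choice(["F", "M"], size=n_subj)
    age = rng.uniform(35, 74, size=n_subj).round(1)
    phen = rng.normal(config.phenotype_model.mean, config.phenotype_model.sd,
                      size=n_subj)
    geno = rng.choice(
        ["AA", "AG", "GG"],
        size=n_subj,
        p=[(1 - _SNP_MAF) ** 2, 2 * _SNP_MAF * (1 - _SNP_MAF), _SNP_MAF ** 2],
    )
    subjects = pd.DataFrame({SEX: sex, AGE: age, PHENOTYPE: phen, "genotype": geno},
                            index=pd.Index(subject_ids, name=SUBJECT))

    # per-probe baselines: right-skewed, with controls in the background band
    mu = config.baseline_mean_location + rng.exponential(
        config.baseline_mean_scale, size=n_probes)
    mu[is_nc] = rng.normal(config.baseline_mean_location - 1.0, 0.3, is_nc.sum())
    # reference intensity used by the intensity-dependent batch shift
    ref = mu.copy()
    ref[roles == "sex_female"] = np.mean(list(_SEX_PROBE_LEVELS["sex_female"].values()))
    ref[roles == "sex_male"] = np.mean(list(_SEX_PROBE_LEVELS["sex_male"].values()))
    snp_mean = sum(
        _GENOTYPE_MEANS[g] * p for g, p in zip(
            ("AA", "AG", "GG"),
            [(1 - _SNP_MAF) ** 2, 2 * _SNP_MAF * (1 - _SNP_MAF), _SNP_MAF ** 2])
    )
    ref[roles == "snp"] = snp_mean

    x0 = config.batch_shift.x0
    if x0 is None:
        x0 = float(np.quantile(mu[regular], 1.0 / 3.0))
    shift = config.batch_shift(ref, x0)
    if config.batch_shift.jitter_sd > 0:
        shift = shift * rng.lognormal(0.0, config.batch_shift.jitter_sd, n_probes)

    # per-probe random effects (regular probes only)
    u = np.zeros((n_probes, n_subj))
    u[regular] = rng.normal(0.0, config.subject_effect_sd,
                            size=(int(regular.sum()), n_subj))
    t = np.zeros(n_probes)
    t[regular] = rng.normal(0.0, config.timepoint_effect_sd, int(regular.sum()))

    beta = np.zeros(n_probes)
    pm = config.phenotype_model
    reg_idx = np.flatnonzero(regular)
    if pm.n_associated_probes > len(reg_idx):
        raise ValueError("more associated probes requested than regular probes")
    assoc = rng.choice(reg_idx, size=pm.n_associated_probes, replace=False)
    beta[assoc] = pm.effect_size * rng.choice([-1.0, 1.0], pm.n_associated_probes)

    # design vectors over samples
    subj_col = plan[SUBJECT].map(subj_pos).to_numpy()
    is_fu_extract = (plan[TIMEPOINT] == "FU").to_numpy()
    is_fu_batch = (plan[BATCH] == "FU").to_numpy()
    chips = _assign_chips(plan, config.chip_size)
    chip_levels = sorted(set(chips))
    chip_effect = dict(zip(chip_levels,
                           rng.normal(0.0, config.chip_effect_sd, len(chip_levels))))
    chip_vec = np.array([chip_effect[c] for c in chips])

    # additive components, each probes x samples
    base = np.tile(mu[:, None], (1, n_samples))
    subject_term = u[:, subj_col]
    # sex and SNP probes: genotype/sex-determined levels replace baseline+subject
    for role, levels in _SEX_PROBE_LEVELS.items():
        g = np.flatnonzero(roles == role)[0]
        base[g, :] = 0.0
        subject_term[g, :] = [levels[subjects.loc[s, SEX]] for s in plan[SUBJECT]]
    g_snp = np.flatnonzero(roles == "snp")[0]
    base[g_snp, :] = 0.0
    subject_term[g_snp, :] = [_GENOTYPE_MEANS[subjects.loc[s, "genotype"]]
                              for s in plan[SUBJECT]]

    timepoint_term = np.outer(t, is_fu_extract.astype(float))
    batch_term = np.outer(shift, is_fu_batch.astype(float))
    phen_term = np.outer(beta, phen[subj_col])
    chip_term = np.tile(chip_vec, (n_probes, 1))
    noise = rng.normal(0.0, config.technical_noise_sd, size=(n_probes, n_samples))

    values = (base + subject_term + timepoint_term + batch_term
              + phen_term + chip_term + noise)

    # variance bookkeeping: mean over probes of per-probe column variance of
    # each additive component (exact for the realized draws)
    components = {
        "subject": subject_term, "timepoint": timepoint_term,
        "batch": batch_term, "phenotype": phen_term,
        "chip": chip_term, "noise": noise,
    }
    comp_var = {k: float(np.mean(np.var(v, axis=1))) for k, v in components.items()}
    total = sum(comp_var.values())
    variance_shares = {k: (v / total if total > 0 else 0.0)
                       for k, v in comp_var.items()}

    expr = pd.DataFrame(values, index=probe_ids, columns=plan["sample_id"].tolist())
    meta = plan.set_index("sample_id").copy()
    meta[SEX] = [subjects.loc[s, SEX] for s in meta[SUBJECT]]
    meta[AGE] = [subjects.loc[s, AGE] for s in meta[SUBJECT]]
    meta[PHENOTYPE] = [subjects.loc[s, PHENOTYPE] for s in meta[SUBJECT]]
    meta[CHIP] = chips

    # inject mix-ups: swap the *contents* of FU-extraction columns between
    # subject pairs; labels stay, so the labels are now wrong (as in a real
    # sample swap)
    mixup_pairs = _pick_mixup_pairs(subjects, config.n_mixups, rng)
    for a, b in mixup_pairs:
        cols_a = meta.index[(meta[SUBJECT] == a) & (meta[TIMEPOINT] == "FU")]
        cols_b = meta.index[(meta[SUBJECT] == b) & (meta[TIMEPOINT] == "FU")]
        for ca, cb in zip(cols_a, cols_b):
            tmp = expr[ca].copy()
            expr[ca] = expr[cb]
            expr[cb] = tmp

    truth = {
        "batch_shift": pd.Series(shift, index=probe_ids),
        "betas": pd.Series(beta, index=probe_ids),
        "timepoint_effects": pd.Series(t, index=probe_ids),
        "mixup_pairs": mixup_pairs,
        "variance_shares": variance_shares,
        "subjects": subjects,
        "shift_x0": x0,
        "config": asdict(config),
    }
    return SimulatedDataset(expression=expr, meta=meta, probes=probes, truth=truth)


def simulate_dataset(config: SimulationConfig,
                     design: pd.DataFrame | None = None) -> SimulatedDataset:
    """Simulate the technical-replicate design (three groups per subject)."""
    if design is None:
        design = generate_replicate_design()
    design = _validate_design(design)
    return _simulate(config, _sample_plan_from_design(design))


def simulate_cohort(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a paired cohort: one BL and one FU column per subject."""
    if config.n_subjects < 2:
        raise ValueError("cohort simulation needs at least 2 subjects")
    return _simulate(config, _sample_plan_cohort(config.n_subjects))
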