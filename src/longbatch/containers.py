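"""In-memory containers and their validation.

The package works on three plain :class:`pandas.DataFrame` objects rather than a
custom class hierarchy, mirroring how expression matrices are handled in
limma-style workflows:

* **expression** -- probes x samples matrix of log2 intensities; the index holds
  unique probe IDs, the columns unique sample IDs, every cell finite.
* **sample metadata** -- one row per sample (indexed by sample ID) with the
  design labels: subject, extraction time point, measurement batch, replicate
  group, plus covariates (sex, age, a BMI-like phenotype, chip ID).
* **probe annotation** -- one row per probe (indexed by probe ID) with
  negative-control flags, the special probe roles and chip-version flags.

The validators below are called by readers and by the pipeline entry points so
that downstream numerical code can assume clean input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# metadata column names
SUBJECT = "subject_id"
TIMEPOINT = "extraction_timepoint"  # {BL, FU}: when RNA was extracted
BATCH = "measurement_batch"         # {BL, FU}: when the array was hybridized/scanned
GROUP = "replicate_group"           # {BL_rep, BLFU_rep, FU_rep, cohort}
SEX = "sex"
AGE = "age"
PHENOTYPE = "phenotype"
CHIP = "chip_id"

META_COLUMNS = (SUBJECT, TIMEPOINT, BATCH, GROUP, SEX, AGE, PHENOTYPE, CHIP)

# probe annotation column names
IS_NEGATIVE_CONTROL = "is_negative_control"
ROLE = "role"                       # {regular, sex_female, sex_male, snp}
ON_V3 = "on_version3"
ON_V4 = "on_version4"

PROBE_COLUMNS = (IS_NEGATIVE_CONTROL, ROLE, ON_V3, ON_V4)

TIMEPOINTS = ("BL", "FU")
GROUPS = ("BL_rep", "BLFU_rep", "FU_rep", "cohort")
ROLES = ("regular", "sex_female", "sex_male", "snp")

# (extraction_timepoint, measurement_batch) implied by each replicate group
GROUP_DESIGN = {
    "BL_rep": ("BL", "BL"),
    "BLFU_rep": ("BL", "FU"),
    "FU_rep": ("FU", "FU"),
}


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a probes x samples log2 expression matrix."""
    _check_unique(expr.index, "probe IDs")
    _check_unique(expr.columns, "sample IDs")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric cells")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at probe {expr.index[bad[0]]!r}, "
            f"sample {expr.columns[bad[1]]!r}"
        )
    return expr


def validate_meta(meta: pd.DataFrame, expr: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate sample metadata; optionally check 1:1 match with a matrix."""
    _check_unique(meta.index, "sample IDs in metadata")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    for col, allowed in ((TIMEPOINT, TIMEPOINTS), (BATCH, TIMEPOINTS), (GROUP, GROUPS)):
        bad = set(meta[col]) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} values {sorted(bad)}")
    for group, (tp, batch) in GROUP_DESIGN.items():
        rows = meta[meta[GROUP] == group]
        if not ((rows[TIMEPOINT] == tp) & (rows[BATCH] == batch)).all():
            raise ValueError(
                f"replicate group {group} must have extraction={tp}, batch={batch}"
            )
    if expr is not None:
        if set(meta.index) != set(expr.columns):
            raise ValueError("metadata sample IDs do not match expression columns")
    return meta


def validate_probes(probes: pd.DataFrame, expr: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate probe annotation; optionally check coverage of a matrix."""
    _check_unique(probes.index, "probe IDs in annotation")
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe annotation is missing columns {missing}")
    bad_roles = set(probes[ROLE]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"invalid probe roles {sorted(bad_roles)}")
    nc_roles = probes.loc[probes[IS_NEGATIVE_CONTROL].astype(bool), ROLE]
    if (nc_roles != "regular").any():
        raise ValueError("negative-control probes must have role 'regular'")
    if expr is not None:
        uncovered = expr.index.difference(probes.index)
        if len(uncovered):
            raise ValueError(f"annotation does not cover probes {list(uncovered[:5])}")
    return probes
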