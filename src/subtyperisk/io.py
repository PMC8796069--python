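"""Reading, writing and validation of the cohort and config formats.

All tables are UTF-8 CSV with a header row; missing values are encoded as
empty fields and survive a write/read round trip unchanged.  The cohort
schema is validated on read: enumerations, the study inclusion window of
ages 18-79, and the constraint that controls carry no tumor fields.
"""

from __future__ import annotations

import dataclasses

import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS
from .config import GENES, GeneratorConfig
from .subtyping import MISSING

_ENUMS = {
    "status": {"case", "control"},
    "er": {"neg", "pos", MISSING},
    "pr": {"neg", "pos", MISSING},
    "erbb2": {"neg", "pos", MISSING},
    "grade": {"1", "2", "3", MISSING},
    "carrier_class": {"PTV", "MSV", MISSING},
    "size_cat": {"<2cm", "2-5cm", ">5cm", MISSING},
    "node": {"neg", "pos", MISSING},
    "stage": {"I", "II", "III", MISSING},
}
_TUMOR_FIELDS = ["er", "pr", "erbb2", "grade", "size_cat", "node", "stage",
                 "true_subtype"]
AGE_MIN, AGE_MAX = 18, 79


class CohortValidationError(ValueError):
    """A cohort row violates the schema; the message carries the row number."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")
    for col, allowed in _ENUMS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(df.index[bad][0])
            raise CohortValidationError(
                f"row {row}: invalid {col} value {df[col].iloc[row]!r}")
    valid_genes = set(GENES) | {MISSING}
    bad = ~df["gene"].isin(valid_genes)
    if bad.any():
        row = int(df.index[bad][0])
        raise CohortValidationError(
            f"row {row}: unknown gene {df['gene'].iloc[row]!r}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = ages.isna() | (ages < AGE_MIN) | (ages > AGE_MAX)
    if bad.any():
        row = int(df.index[bad][0])
        raise CohortValidationError(
            f"row {row}: age {df['age'].iloc[row]!r} outside the inclusion "
            f"window — women aged between {AGE_MIN} and {AGE_MAX} years")
    ctrl = df["status"] == "control"
    for col in _TUMOR_FIELDS:
        bad = ctrl & (df[col] != MISSING)
        if bad.any():
            row = int(df.index[bad][0])
            raise CohortValidationError(
                f"row {row}: control has nonempty tumor field {col!r}")
    out = df.copy()
    out["age"] = ages.astype(int)
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (empty field == missing)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV; round-trips through :func:`read_cohort` exactly."""
    out = df.copy()
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    out[cols + extra].to_csv(path, index=False)


def _cell_key(cell) -> str:
    return ",".join(cell)


def _parse_cell(key: str) -> tuple:
    return tuple(key.split(","))


def save_config(config: GeneratorConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["marker_given_subtype"] = {
        s: {_cell_key(c): p for c, p in dist.items()}
        for s, dist in d["marker_given_subtype"].items()
    }
    d["age_bounds"] = list(d["age_bounds"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> GeneratorConfig:
    """Load a generator config from YAML; omitted keys keep their defaults."""
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    if "marker_given_subtype" in d:
        d["marker_given_subtype"] = {
            s: {_parse_cell(k): p for k, p in dist.items()}
            for s, dist in d["marker_given_subtype"].items()
        }
    if "age_bounds" in d:
        d["age_bounds"] = tuple(d["age_bounds"])
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return GeneratorConfig(**d).validate()


def write_or_table(df: pd.DataFrame, path) -> None:
    """Tidy association results: gene, outcome_category, OR, CI, p, ..."""
    df.to_csv(path, index=False)
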