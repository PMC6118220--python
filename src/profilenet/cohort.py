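"""Cohort table I/O and validation.

The canonical on-disk format is long: one row per participant per wave,
with columns ``participant_id, group, wave, age, iq`` followed by the 24
variable codes.  Validation enforces a complete-case design — every
participant observed in every wave exactly once, no missing values, and a
group label constant within participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import VariableSchema, default_schema

GROUPS = ("on-track", "delayed")
WAVES = ("T1", "T2")
ID_COLS = ["participant_id", "group", "wave", "age", "iq"]


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the completeness contract."""


@dataclass
class CohortTable:
    """Validated long-format cohort: participants x waves x 24 measures."""

    data: pd.DataFrame
    schema: VariableSchema

    def __post_init__(self) -> None:
        self.data = validate_cohort(self.data, self.schema)

    @property
    def participants(self) -> list:
        return list(self.data["participant_id"].unique())

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    def wave(self, wave: str) -> pd.DataFrame:
        """Rows of one wave, indexed by participant_id, in participant order."""
        if wave not in WAVES:
            raise ValueError(f"unknown wave {wave!r}; expected one of {WAVES}")
        sub = self.data[self.data["wave"] == wave].set_index("participant_id")
        return sub.loc[self.participants]

    def values(self, wave: str) -> pd.DataFrame:
        """Participants x 24 measurement matrix for one wave."""
        return self.wave(wave)[self.schema.codes]

    def groups(self, wave: str = "T1") -> pd.Series:
        """Group label per participant (constant across waves)."""
        return self.wave(wave)["group"]

    def covariates(self, wave: str) -> pd.DataFrame:
        return self.wave(wave)[["age", "iq"]]


def validate_cohort(df: pd.DataFrame, schema: VariableSchema) -> pd.DataFrame:
    missing_cols = [c for c in ID_COLS + schema.codes if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")
    df = df[ID_COLS + schema.codes].copy()

    bad_group = sorted(set(df["group"]) - set(GROUPS))
    if bad_group:
        raise CohortValidationError(f"unknown group labels: {bad_group}")
    bad_wave = sorted(set(df["wave"]) - set(WAVES))
    if bad_wave:
        raise CohortValidationError(f"unknown wave labels: {bad_wave}")

    dup = df.duplicated(subset=["participant_id", "wave"])
    if dup.any():
        pairs = df.loc[dup, ["participant_id", "wave"]].to_records(index=False)
        raise CohortValidationError(f"duplicate participant x wave rows: {list(pairs)[:10]}")

    counts = df.groupby("participant_id")["wave"].nunique()
    incomplete = counts[counts != len(WAVES)]
    if len(incomplete):
        raise CohortValidationError(
            "participants missing a wave: "
            f"{sorted(incomplete.index.tolist())[:10]}"
        )

    ngroups = df.groupby("participant_id")["group"].nunique()
    switched = ngroups[ngroups > 1]
    if len(switched):
        raise CohortValidationError(
            f"group label changes within participant: {sorted(switched.index.tolist())[:10]}"
        )

    numeric = ["age", "iq"] + schema.codes
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = df.index[vals.isna()].tolist()[:10]
            raise CohortValidationError(
                f"non-numeric or missing values in column {col!r} at rows {rows}"
            )
        df[col] = vals.astype(np.float64)
    return df.reset_index(drop=True)


def read_cohort(path: str | Path, schema: VariableSchema | None = None) -> CohortTable:
    """Read and validate a long-format cohort table (TSV or CSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str},
                     float_precision="round_trip")
    return CohortTable(df, schema or default_schema())


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table in the same long dialect it is read from."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    cohort.data.to_csv(path, sep=sep, index=False)
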