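"""Reading, validating and writing tidy hormone and morphometric tables.

The package works on two tidy CSV layouts:

* **hormone tables** — one row per animal per measurement occasion, with
  columns ``id, age_class, treatment, testosterone, true_sex`` and the
  optional ``year, fsh_dose, pair_key``;
* **morphometric tables** — one row per animal, with the five core shell
  measurements ``MCL, SH, CW, PMIN, PMAX`` (mm), the optional
  hatchling-only measurements ``AW, AN, GW, TL``, and ``true_sex``.

Units are fixed: pg/mL for testosterone, mm for linear measurements.
Rows that violate an invariant are rejected with row-level diagnostics —
a :class:`~endosex.exceptions.ValidationError` lists every offending row
and the rule it broke.  Because supplementary data files in the wild name
their columns freely, every reader accepts a ``column_map`` translating
file column names to the canonical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

AGE_CLASSES = ("neonate", "hatchling", "juvenile")
TREATMENTS = ("naive", "postFSH", "saline")
SEXES = ("F", "M", "unknown")

HORMONE_REQUIRED = ("id", "age_class", "treatment", "testosterone", "true_sex")
HORMONE_OPTIONAL = ("year", "fsh_dose", "pair_key")

MORPH_CORE = ("MCL", "SH", "CW", "PMIN", "PMAX")
MORPH_HATCHLING = ("AW", "AN", "GW", "TL")
MORPH_REQUIRED = ("id",) + MORPH_CORE

_SEX_ALIASES = {
    "f": "F", "female": "F",
    "m": "M", "male": "M",
    "unknown": "unknown", "u": "unknown", "": "unknown",
}
_TREATMENT_ALIASES = {t.lower(): t for t in TREATMENTS}


@dataclass
class SexingDataset:
    """Container for validated hormone and/or morphometric records.

    Either table may be ``None``; both are plain pandas DataFrames with
    canonical column names, so downstream modules can use ordinary pandas
    idioms.  ``metadata`` carries free-form provenance notes.
    """

    hormone: pd.DataFrame | None = None
    morph: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def hormone_values(
        self,
        sex: str,
        age_class: str | None = None,
        treatment: str | None = None,
    ) -> np.ndarray:
        """Testosterone values (pg/mL) for one sex, optionally filtered."""
        if self.hormone is None:
            raise ValueError("dataset has no hormone table")
        df = self.hormone
        mask = df["true_sex"] == sex
        if age_class is not None:
            mask &= df["age_class"] == age_class
        if treatment is not None:
            mask &= df["treatment"] == treatment
        return df.loc[mask, "testosterone"].to_numpy(dtype=float)

    def known_sex_counts(self) -> dict[str, int]:
        if self.hormone is None:
            return {}
        counts = self.hormone["true_sex"].value_counts()
        return {s: int(counts.get(s, 0)) for s in ("F", "M")}


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], kind: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table is missing required column(s): {', '.join(missing)}"
        )


def normalize_sex(value) -> str | None:
    """Map a free-form sex label to one of F / M / unknown, or None if bad."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    return _SEX_ALIASES.get(str(value).strip().lower())


def read_hormone_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> SexingDataset:
    """Read and validate a tidy hormone CSV.

    Parameters
    ----------
    path
        CSV file with a header row, UTF-8, "." decimal separator.
    column_map
        Optional mapping ``canonical_name -> file_column_name`` for files
        whose headers differ from the canonical schema.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    df = _apply_column_map(df, column_map)
    _require_columns(df, HORMONE_REQUIRED, "hormone")

    diagnostics: list[tuple] = []
    df = df.copy()
    df["id"] = df["id"].astype(str)

    sex_norm = df["true_sex"].map(normalize_sex)
    for idx in df.index[sex_norm.isna()]:
        diagnostics.append((idx, "true_sex", f"row {idx}: unrecognized sex label {df.at[idx, 'true_sex']!r}"))
    df["true_sex"] = sex_norm

    ac = df["age_class"].astype(str).str.strip().str.lower()
    for idx in df.index[~ac.isin(AGE_CLASSES)]:
        diagnostics.append((idx, "age_class", f"row {idx}: unknown age_class {df.at[idx, 'age_class']!r}"))
    df["age_class"] = ac

    tr = df["treatment"].astype(str).str.strip().str.lower().map(_TREATMENT_ALIASES)
    for idx in df.index[tr.isna()]:
        diagnostics.append((idx, "treatment", f"row {idx}: unknown treatment {df.at[idx, 'treatment']!r}"))
    df["treatment"] = tr

    t = pd.to_numeric(df["testosterone"], errors="coerce")
    bad_t = ~(np.isfinite(t) & (t > 0))
    for idx in df.index[bad_t]:
        diagnostics.append((
            idx, "testosterone",
            f"row {idx} (id {df.at[idx, 'id']}): testosterone must be finite and > 0, "
            f"got {df.at[idx, 'testosterone']!r}",
        ))
    df["testosterone"] = t

    if "fsh_dose" in df.columns:
        dose = pd.to_numeric(df["fsh_dose"], errors="coerce")
        for idx in df.index[dose.notna() & (dose < 0)]:
            diagnostics.append((idx, "fsh_dose", f"row {idx}: fsh_dose must be >= 0"))

    dup = df.duplicated(subset=["id", "treatment"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["id", "treatment"]].drop_duplicates()
        for _, row in keys.iterrows():
            diagnostics.append((
                None, "unique(id, treatment)",
                f"duplicate (id, treatment) key: ({row['id']}, {row['treatment']})",
            ))

    if diagnostics:
        raise ValidationError(
            f"{len(diagnostics)} invalid row(s) in hormone table {path}:\n"
            + "\n".join(d[2] for d in diagnostics),
            diagnostics=diagnostics,
        )

    return SexingDataset(hormone=df, metadata={"source": str(path)})


def read_morph_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> SexingDataset:
    """Read and validate a tidy morphometric CSV (mm measurements)."""
    df = pd.read_csv(path, delimiter=delimiter)
    df = _apply_column_map(df, column_map)
    _require_columns(df, MORPH_REQUIRED, "morphometric")

    diagnostics: list[tuple] = []
    df = df.copy()
    df["id"] = df["id"].astype(str)

    if "true_sex" in df.columns:
        sex_norm = df["true_sex"].map(normalize_sex)
        for idx in df.index[sex_norm.isna()]:
            diagnostics.append((idx, "true_sex", f"row {idx}: unrecognized sex label {df.at[idx, 'true_sex']!r}"))
        df["true_sex"] = sex_norm
    else:
        df["true_sex"] = "unknown"

    measured = [c for c in MORPH_CORE + MORPH_HATCHLING if c in df.columns]
    for col in measured:
        vals = pd.to_numeric(df[col], errors="coerce")
        present = df[col].notna()
        bad = present & ~(np.isfinite(vals) & (vals > 0))
        for idx in df.index[bad]:
            diagnostics.append((
                idx, col,
                f"row {idx} (id {df.at[idx, 'id']}): {col} must be finite and > 0, "
                f"got {df.at[idx, col]!r}",
            ))
        df[col] = vals

    both = df["PMIN"].notna() & df["PMAX"].notna()
    for idx in df.index[both & (df["PMIN"] > df["PMAX"])]:
        diagnostics.append((
            idx, "PMIN<=PMAX",
            f"row {idx} (id {df.at[idx, 'id']}): PMIN ({df.at[idx, 'PMIN']}) exceeds "
            f"PMAX ({df.at[idx, 'PMAX']})",
        ))

    if df["id"].duplicated().any():
        for dup_id in df.loc[df["id"].duplicated(), "id"].unique():
            diagnostics.append((None, "unique(id)", f"duplicate id: {dup_id}"))

    if diagnostics:
        raise ValidationError(
            f"{len(diagnostics)} invalid row(s) in morphometric table {path}:\n"
            + "\n".join(d[2] for d in diagnostics),
            diagnostics=diagnostics,
        )

    return SexingDataset(morph=df, metadata={"source": str(path)})


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table to CSV.

    Numeric fields are written with 10 significant digits so that a
    write-then-read round trip preserves values well past the 6
    significant digits the package guarantees.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty report table")
    table.to_csv(path, index=False, float_format="%.10g")
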