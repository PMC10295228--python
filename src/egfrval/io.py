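"""Cohort file handling: schema-checked CSV reading, writing, validity filtering.

The cohort CSV schema (column names, units, which columns are mandatory)
is shipped as ``data/cohort_schema.json``.  Reading is available-case
friendly: rows with unparseable *mandatory* fields are rejected with
row-numbered diagnostics, while missing *optional* fields are retained and
merely tracked in per-column missing counts — each downstream statistic
then uses the rows complete for its own inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .equations import bsa_dubois, normalize_gfr

logger = logging.getLogger("egfrval")

__all__ = ["CohortTable", "SchemaError", "PipelineAbort", "read_cohort", "write_cohort", "filter_valid", "load_schema"]

MANDATORY = ("subject_id", "age", "sex")
NUMERIC_OPTIONAL = ("height_cm", "weight_kg", "scr_mg_dl", "scys_mg_l", "raw_clearance_ml_min", "mgfr")

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}
_SEX_MAP = {"f": "female", "female": "female", "m": "male", "male": "male"}


class SchemaError(ValueError):
    pass


class PipelineAbort(RuntimeError):
    pass


def load_schema() -> dict:
    """The shipped cohort CSV schema document."""
    text = resources.files("egfrval.data").joinpath("cohort_schema.json").read_text()
    return json.loads(text)


@dataclass
class CohortTable:
    """A typed cohort with provenance and per-column missing counts."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    schema_version: str = "1"
    rejected_rows: list = field(default_factory=list)

    @property
    def missing_counts(self) -> dict[str, int]:
        return {c: int(self.df[c].isna().sum()) for c in self.df.columns}

    def __len__(self) -> int:
        return len(self.df)


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series.astype("boolean")
    out = []
    for v in series:
        if pd.isna(v):
            out.append(pd.NA)
            continue
        s = str(v).strip().lower()
        if s in _TRUE:
            out.append(True)
        elif s in _FALSE:
            out.append(False)
        else:
            raise SchemaError(f"column {column!r}: cannot parse boolean value {v!r}")
    return pd.Series(out, index=series.index, dtype="boolean")


def read_cohort(path: Union[str, Path], schema: Optional[dict] = None) -> CohortTable:
    """Read and type-check a cohort CSV.

    Mandatory columns: subject_id, age, sex, and mGFR either directly
    (``mgfr``) or derivable from ``raw_clearance_ml_min`` + ``height_cm`` +
    ``weight_kg`` via Dubois indexing.  Rows whose mandatory fields do not
    parse are dropped with row-numbered diagnostics; optional fields parse
    to NaN and stay.
    """
    path = Path(path)
    schema = schema or load_schema()
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing_cols = [c for c in MANDATORY if c not in raw.columns]
    has_mgfr_path = "mgfr" in raw.columns or {"raw_clearance_ml_min", "height_cm", "weight_kg"} <= set(raw.columns)
    if missing_cols or not has_mgfr_path:
        expected = list(MANDATORY) + ["mgfr (or raw_clearance_ml_min + height_cm + weight_kg)"]
        raise SchemaError(
            f"cohort file {path.name} lacks mandatory columns {missing_cols or ['mgfr']}; expected: {expected}"
        )

    df = pd.DataFrame(index=raw.index)
    df["subject_id"] = raw["subject_id"].astype(str)
    df["age"] = pd.to_numeric(raw["age"], errors="coerce")
    sex = raw["sex"].str.strip().str.lower().map(_SEX_MAP)
    df["sex"] = sex

    for col in NUMERIC_OPTIONAL:
        if col in raw.columns and col not in df.columns:
            df[col] = pd.to_numeric(raw[col], errors="coerce")
    known = set(df.columns) | {"valid"}
    for col in raw.columns:
        if col in known:
            continue
        if col.startswith("egfr_"):
            df[col] = pd.to_numeric(raw[col], errors="coerce")
        else:
            df[col] = _coerce_bool(raw[col], col)
    df["valid"] = _coerce_bool(raw["valid"], "valid").fillna(True) if "valid" in raw.columns else True

    if "mgfr" not in df.columns:
        df["mgfr"] = np.nan
    derivable = df["mgfr"].isna()
    for c in ("raw_clearance_ml_min", "height_cm", "weight_kg"):
        derivable &= df[c].notna() if c in df.columns else False
    if derivable.any():
        sub = df.loc[derivable]
        df.loc[derivable, "mgfr"] = normalize_gfr(
            sub["raw_clearance_ml_min"].to_numpy(), bsa_dubois(sub["height_cm"].to_numpy(), sub["weight_kg"].to_numpy())
        )

    bad = df["age"].isna() | (df["age"] <= 0) | df["sex"].isna() | (raw["subject_id"].isna())
    rejected = []
    for i in df.index[bad]:
        reason = "unparseable age" if pd.isna(df.at[i, "age"]) or df.at[i, "age"] <= 0 else "unparseable sex/id"
        rejected.append({"row": int(i) + 2, "reason": reason})  # +2: header + 1-based
        logger.warning("W-ROW-REJECT: row %d rejected (%s)", int(i) + 2, reason)
    df = df.loc[~bad].reset_index(drop=True)

    for col in ("scr_mg_dl", "scys_mg_l", "mgfr"):
        if col in df.columns:
            nonpos = df[col] <= 0
            if nonpos.any():
                logger.warning("W-NONPOSITIVE: %d non-positive %s values set to missing", int(nonpos.sum()), col)
                df.loc[nonpos, col] = np.nan

    table = CohortTable(
        df=df,
        provenance={"input_path": str(path)},
        schema_version=schema.get("schema_version", "1"),
        rejected_rows=rejected,
    )
    return table


def write_cohort(table: Union[CohortTable, pd.DataFrame], path: Union[str, Path]) -> None:
    """Write a cohort table to CSV in the shipped schema layout."""
    df = table.df if isinstance(table, CohortTable) else table
    df.to_csv(path, index=False)


def filter_valid(table: Union[CohortTable, pd.DataFrame]) -> tuple[CohortTable, list[dict]]:
    """Keep valid rows with a usable mGFR; log every exclusion with a reason.

    Aborts (:class:`PipelineAbort`) when no analyzable rows remain.
    """
    if isinstance(table, pd.DataFrame):
        table = CohortTable(df=table)
    df = table.df
    valid = df["valid"].astype(bool) if "valid" in df.columns else pd.Series(True, index=df.index)
    has_mgfr = df["mgfr"].notna() if "mgfr" in df.columns else pd.Series(False, index=df.index)
    exclusions = []
    for i in df.index:
        if not valid.loc[i]:
            exclusions.append({"row": int(i), "subject_id": str(df.at[i, "subject_id"]), "reason": "flagged invalid"})
        elif not has_mgfr.loc[i]:
            exclusions.append({"row": int(i), "subject_id": str(df.at[i, "subject_id"]), "reason": "missing mGFR"})
    keep = valid & has_mgfr
    kept = df.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        raise PipelineAbort(
            f"no analyzable rows remain after validity filtering ({len(df)} rows, {len(exclusions)} excluded)"
        )
    for e in exclusions:
        logger.info("N-EXCLUDE: row %s subject %s: %s", e["row"], e["subject_id"], e["reason"])
    out = CohortTable(
        df=kept,
        provenance={**table.provenance, "n_input": len(df), "n_excluded": len(exclusions)},
        schema_version=table.schema_version,
        rejected_rows=table.rejected_rows,
    )
    return out, exclusions
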