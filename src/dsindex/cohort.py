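"""Cohort table reading/writing, inclusion filters and APOE derivation."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .variables import RESERVED_COLUMNS, VariableSpec

logger = logging.getLogger(__name__)

APOE_GENOTYPES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")

#: columns derived from the genotype; re-derive after masking the genotype
APOE_DERIVED = ("apoe_e2_carrier", "apoe_e4_carrier", "apoe_e3e3")

_AUX_BOOL = ("died_within_2y", "autopsy_available", "baseline_dementia")


@dataclass
class CohortTable:
    """A subject-by-variable table plus per-read parse diagnostics."""

    data: pd.DataFrame
    specs: list[VariableSpec]
    warnings: int = 0

    def __len__(self) -> int:
        return len(self.data)


def _coerce_column(col: pd.Series, spec: VariableSpec) -> tuple[pd.Series, int]:
    """Coerce raw text values to the spec's kind; unparseable cells become
    missing and are counted."""
    if spec.kind == "categorical":
        out = col.where(col.notna() & (col.astype(str).str.strip() != ""), None)
        out = out.map(lambda v: str(v).strip() if v is not None else None)
        return out.astype(object), 0
    numeric = pd.to_numeric(col, errors="coerce")
    bad = int((numeric.isna() & col.notna() &
               (col.astype(str).str.strip() != "")).sum())
    if spec.kind == "binary":
        invalid = numeric.notna() & ~numeric.isin([0, 1])
        bad += int(invalid.sum())
        numeric = numeric.where(~invalid)
    return numeric.astype(float), bad


def read_cohort(path: str, specs: Sequence[VariableSpec],
                missing_token: str = "") -> CohortTable:
    """Read a delimited cohort table, coercing values per variable spec.

    The file must have a header row and a ``subject_id`` column; missing
    cells are encoded by ``missing_token`` (default: empty cell).  Columns
    not declared in ``specs`` (other than the reserved bookkeeping columns)
    raise an error; unparseable cells become missing with a counted warning.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({missing_token: None}) if missing_token != "" else \
        raw.replace({"": None})
    by_name = {s.name: s for s in specs}
    unknown = [c for c in raw.columns
               if c not in by_name and c not in RESERVED_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in cohort file: {unknown}")
    if "subject_id" not in raw.columns:
        raise ValueError("cohort file lacks a subject_id column")
    dup = raw["subject_id"][raw["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id values: {sorted(set(dup))}")

    out = pd.DataFrame(index=raw.index)
    out["subject_id"] = raw["subject_id"].astype(str)
    warnings = 0
    if "outcome" in raw.columns:
        y = pd.to_numeric(raw["outcome"], errors="coerce")
        if not y.dropna().isin([0, 1]).all():
            raise ValueError("outcome column contains values other than 0/1")
        out["outcome"] = y
    if "follow_up_years" in raw.columns:
        out["follow_up_years"] = pd.to_numeric(raw["follow_up_years"],
                                               errors="coerce")
    for aux in _AUX_BOOL:
        if aux in raw.columns:
            v = pd.to_numeric(raw[aux], errors="coerce")
            out[aux] = v.fillna(0).astype(int).astype(bool)
    for name, spec in by_name.items():
        if name not in raw.columns:
            continue
        col, bad = _coerce_column(raw[name], spec)
        out[name] = col
        if bad:
            logger.warning("column %s: %d unparseable cells set missing",
                           name, bad)
            warnings += bad
    return CohortTable(data=out, specs=list(by_name.values()),
                       warnings=warnings)


def write_cohort(data: pd.DataFrame, path: str) -> None:
    """Write a cohort table as UTF-8 CSV with empty cells for missing."""
    df = data.copy()
    for aux in _AUX_BOOL:
        if aux in df.columns:
            df[aux] = df[aux].astype(int)
    df.to_csv(path, index=False, na_rep="")


def apply_inclusion_filters(cohort: Union[CohortTable, pd.DataFrame],
                            model_kind: str) -> tuple[pd.DataFrame, dict]:
    """Apply the study's inclusion filters and return (filtered, tally).

    ``dementia``: exclude subjects with baseline dementia and subjects who
    died within the first 2 years of follow-up.  ``pathology``: exclude
    baseline dementia and subjects without autopsy data.  The tally records
    how many rows each rule removed.
    """
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    if model_kind not in ("dementia", "pathology"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    needed = ["baseline_dementia"] + (
        ["died_within_2y"] if model_kind == "dementia" else ["autopsy_available"])
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"auxiliary flag column {col!r} missing")
    tally = {"input": len(df)}
    keep = ~df["baseline_dementia"].astype(bool)
    tally["excluded_baseline_dementia"] = int((~keep).sum())
    if model_kind == "dementia":
        drop = df["died_within_2y"].astype(bool) & keep
        tally["excluded_died_within_2y"] = int(drop.sum())
        keep &= ~df["died_within_2y"].astype(bool)
    else:
        drop = ~df["autopsy_available"].astype(bool) & keep
        tally["excluded_no_autopsy"] = int(drop.sum())
        keep &= df["autopsy_available"].astype(bool)
    out = df.loc[keep].copy()
    tally["included"] = len(out)
    logger.info("inclusion filters (%s): %s", model_kind, tally)
    return out, tally


def derive_apoe_factors(genotype) -> dict:
    """Derive carrier binaries from an APOE genotype.

    Returns ``apoe_e2_carrier``, ``apoe_e4_carrier``, ``apoe_e3e3`` (each
    0/1, NaN when the genotype is missing) plus the genotype passthrough.
    """
    if genotype is None or (isinstance(genotype, float) and math.isnan(genotype)):
        return {"apoe_e2_carrier": float("nan"), "apoe_e4_carrier": float("nan"),
                "apoe_e3e3": float("nan"), "apoe_genotype": None}
    g = str(genotype)
    if g not in APOE_GENOTYPES:
        raise ValueError(f"unknown APOE genotype {g!r}; "
                         f"expected one of {APOE_GENOTYPES}")
    return {
        "apoe_e2_carrier": float("e2" in g),
        "apoe_e4_carrier": float("e4" in g),
        "apoe_e3e3": float(g == "e3e3"),
        "apoe_genotype": g,
    }


def add_apoe_columns(df: pd.DataFrame,
                     genotype_col: str = "apoe_genotype") -> pd.DataFrame:
    """Append (or refresh) the derived APOE columns of a cohort table."""
    derived = [derive_apoe_factors(g) for g in df[genotype_col]]
    out = df.copy()
    for key in APOE_DERIVED:
        out[key] = [d[key] for d in derived]
    return out
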