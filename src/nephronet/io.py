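"""CSV-based table I/O with sidecar schema files.

Cohort tables travel as plain CSV (patients as rows, indicator columns,
empty cell or ``NA`` for missing) next to a ``*.schema.csv`` sidecar listing
name/role/kind/units per indicator.  Survival and omics tables are plain
CSV; omics QC replicate injections are rows whose index starts with ``QC_``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .omics import OmicsTable
from .schema import CohortTable, IndicatorSchema

NA_TOKENS = ["", "NA", "NaN", "nan"]


def schema_sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".schema.csv")


def write_cohort(table: CohortTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index_label="patient_id", na_rep="NA")
    table.schema.to_frame().to_csv(schema_sidecar_path(path), index=False)


def read_cohort(path: str | Path, schema: IndicatorSchema | None = None,
                allow_extra: bool = False) -> CohortTable:
    path = Path(path)
    if schema is None:
        sidecar = schema_sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"schema sidecar not found: {sidecar}")
        schema = IndicatorSchema.from_frame(pd.read_csv(sidecar))
    data = pd.read_csv(path, index_col="patient_id",
                       na_values=NA_TOKENS, keep_default_na=False)
    unknown = [c for c in data.columns if c not in schema.names]
    if unknown and not allow_extra:
        raise ValueError(f"unknown column(s) {unknown}; pass allow_extra to keep")
    for col in schema.names:
        if col not in data.columns:
            raise ValueError(f"missing indicator column {col!r}")
        try:
            data[col] = pd.to_numeric(data[col])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"cannot coerce column {col!r}: {exc}") from exc
    return CohortTable(data[schema.names], schema)


def write_survival(records: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index_label="patient_id", na_rep="NA")


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="patient_id",
                     na_values=NA_TOKENS, keep_default_na=False)
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table lacks {col!r}")
    df["time_months"] = pd.to_numeric(df["time_months"])
    df["event"] = df["event"].astype(str).str.lower().isin(["1", "true", "t", "yes"]) \
        if df["event"].dtype == object else df["event"].astype(bool)
    return df


def write_omics(table: OmicsTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    combined = table.data if table.qc is None else pd.concat([table.data, table.qc])
    combined.to_csv(path, index_label="sample_id", na_rep="NA")


def read_omics(path: str | Path, modality: str = "metabolite") -> OmicsTable:
    df = pd.read_csv(path, index_col="sample_id",
                     na_values=NA_TOKENS, keep_default_na=False)
    df = df.apply(pd.to_numeric)
    is_qc = df.index.astype(str).str.startswith("QC_")
    qc = df[is_qc] if is_qc.any() else None
    return OmicsTable(data=df[~is_qc], qc=qc, modality=modality)


def write_labels(strata: pd.Series, scheme_tag: str, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = strata.rename("stratum").to_frame()
    out["scheme"] = scheme_tag
    out.to_csv(path, index_label="patient_id")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col="patient_id")
    return df["stratum"].astype(int)
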