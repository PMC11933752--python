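"""Indicator schema and typed cohort tables.

An :class:`IndicatorSchema` names the clinical indicators a cohort records and
tags each with a *role* (demographic, renal, extrarenal) and a *value kind*
(continuous, binary, ordinal).  Role filters drive the three indicator sets
used by the stratification schemes: demographic+renal only, everything, or the
network feature vectors derived from everything.

The default schema holds the 40 indicators a biopsy-proven IgA nephropathy
work-up typically yields: demographics and lifestyle, renal chemistry and
urinalysis, the Oxford MEST-C biopsy scores with immunofluorescence
intensities, plus extrarenal panels (liver function, lipids, haematology,
comorbidities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("demographic", "renal", "extrarenal")
KINDS = ("continuous", "binary", "ordinal")


@dataclass(frozen=True)
class Indicator:
    name: str
    role: str
    kind: str
    units: str = ""
    #: valid coded levels for binary/ordinal indicators (None for continuous)
    levels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.kind != "continuous" and self.levels is None:
            object.__setattr__(self, "levels", (0, 1))


@dataclass(frozen=True)
class IndicatorSchema:
    """Ordered collection of indicators with unique names."""

    indicators: tuple[Indicator, ...]

    def __post_init__(self) -> None:
        names = [ind.name for ind in self.indicators]
        if len(set(names)) != len(names):
            raise ValueError("indicator names must be unique")

    @property
    def names(self) -> list[str]:
        return [ind.name for ind in self.indicators]

    def __len__(self) -> int:
        return len(self.indicators)

    def __getitem__(self, name: str) -> Indicator:
        for ind in self.indicators:
            if ind.name == name:
                return ind
        raise KeyError(name)

    def by_role(self, *roles: str) -> "IndicatorSchema":
        for r in roles:
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r}")
        return IndicatorSchema(
            tuple(ind for ind in self.indicators if ind.role in roles)
        )

    def names_by_kind(self, kind: str) -> list[str]:
        return [ind.name for ind in self.indicators if ind.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "role": [i.role for i in self.indicators],
                "kind": [i.kind for i in self.indicators],
                "units": [i.units for i in self.indicators],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IndicatorSchema":
        inds = []
        for _, row in frame.iterrows():
            inds.append(
                Indicator(
                    name=str(row["name"]),
                    role=str(row["role"]),
                    kind=str(row["kind"]),
                    units=str(row.get("units", "") or ""),
                )
            )
        return cls(tuple(inds))


def _c(name: str, role: str, units: str = "") -> Indicator:
    return Indicator(name, role, "continuous", units)


def _b(name: str, role: str) -> Indicator:
    return Indicator(name, role, "binary")


def _o(name: str, role: str, levels: tuple[int, ...]) -> Indicator:
    return Indicator(name, role, "ordinal", levels=levels)


def default_schema() -> IndicatorSchema:
    """The default 40-indicator IgA nephropathy schema.

    5 demographic, 20 renal, 15 extrarenal indicators.  The renal set covers
    chemistry (creatinine, eGFR, urea, uric acid, cystatin C), urinalysis
    (24 h protein, urinary red cells), blood pressure, the Oxford MEST-C
    scores, sclerosis measures and immunofluorescence deposit intensities.
    """
    return IndicatorSchema(
        (
            # demographic / lifestyle
            _c("age", "demographic", "years"),
            _b("sex", "demographic"),
            _c("bmi", "demographic", "kg/m2"),
            _b("smoking", "demographic"),
            _b("drinking", "demographic"),
            # renal chemistry, urinalysis, blood pressure
            _c("serum_creatinine", "renal", "umol/L"),
            _c("egfr", "renal", "mL/min/1.73m2"),
            _c("urine_protein_24h", "renal", "g/24h"),
            _c("urine_rbc", "renal", "cells/uL"),
            _c("blood_urea_nitrogen", "renal", "mmol/L"),
            _c("uric_acid", "renal", "umol/L"),
            _c("cystatin_c", "renal", "mg/L"),
            _c("sbp", "renal", "mmHg"),
            _c("dbp", "renal", "mmHg"),
            # Oxford MEST-C and pathology
            _o("mest_m", "renal", (0, 1)),
            _o("mest_e", "renal", (0, 1)),
            _o("mest_s", "renal", (0, 1)),
            _o("mest_t", "renal", (0, 1, 2)),
            _o("mest_c", "renal", (0, 1, 2)),
            _c("global_sclerosis_pct", "renal", "%"),
            _b("arteriolar_sclerosis", "renal"),
            _o("iga_intensity", "renal", (0, 1, 2, 3)),
            _o("igg_intensity", "renal", (0, 1, 2, 3)),
            _o("igm_intensity", "renal", (0, 1, 2, 3)),
            _o("c3_intensity", "renal", (0, 1, 2, 3)),
            # extrarenal panels
            _c("hemoglobin", "extrarenal", "g/L"),
            _c("albumin", "extrarenal", "g/L"),
            _c("alt", "extrarenal", "U/L"),
            _c("ast", "extrarenal", "U/L"),
            _c("total_bilirubin", "extrarenal", "umol/L"),
            _c("direct_bilirubin", "extrarenal", "umol/L"),
            _c("total_cholesterol", "extrarenal", "mmol/L"),
            _c("triglycerides", "extrarenal", "mmol/L"),
            _c("hdl_cholesterol", "extrarenal", "mmol/L"),
            _c("ldl_cholesterol", "extrarenal", "mmol/L"),
            _c("fasting_glucose", "extrarenal", "mmol/L"),
            _c("platelet_count", "extrarenal", "1e9/L"),
            _c("serum_iga", "extrarenal", "g/L"),
            _b("diabetes", "extrarenal"),
            _b("hepatitis_b", "extrarenal"),
        )
    )


@dataclass
class CohortTable:
    """A samples-by-indicators table bound to a schema.

    ``data`` rows are patients (index = patient id), columns are exactly the
    schema's indicators in schema order.  Missing values are NaN.
    """

    data: pd.DataFrame
    schema: IndicatorSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise ValueError(f"table lacks schema indicators: {missing}")
        self.data = self.data[self.schema.names]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean())

    def subset(self, roles: tuple[str, ...]) -> "CohortTable":
        sub = self.schema.by_role(*roles)
        return CohortTable(self.data[sub.names].copy(), sub)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)
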