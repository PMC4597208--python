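"""Tabular input/output and validation for the signature pipeline.

The pipeline operates on two tables keyed by patient identifier:

* a wide-format protein quantification matrix of iTRAQ-style abundance
  ratios (patient x protein, strictly positive, dimensionless), and
* a clinical table carrying index-day and next-day C-reactive protein
  (CRP, mg/L) plus donor/recipient covariates.

The binary outcome -- did next-day CRP increase? -- is derived here and
nowhere else, so every downstream module agrees on the event definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CohortValidationError",
    "ProteinMatrix",
    "ClinicalTable",
    "OutcomeVector",
    "read_protein_matrix",
    "write_protein_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "derive_outcome",
    "align_tables",
    "CLINICAL_COLUMNS",
    "CATEGORY_VOCABULARY",
]


class CohortValidationError(ValueError):
    """A table failed schema or value validation; message names the cell."""


#: Required clinical columns and their dtypes/semantics.
CLINICAL_COLUMNS = {
    "crp_index": "index-day C-reactive protein, mg/L (>= 0)",
    "crp_next": "next-day C-reactive protein, mg/L (>= 0)",
    "donor_age": "donor age, years",
    "donor_sex": "donor sex, {female, male}",
    "donor_status": "donor status, {living, deceased}",
    "recipient_age": "recipient age, years",
    "recipient_sex": "recipient sex, {female, male}",
    "dialysis_months": "duration of dialysis before transplantation, months",
    "methylprednisolone": "methylprednisolone given, {0, 1}",
    "hospitalization_days": "days until hospital discharge (>= 0)",
    "hla_mismatches": "number of HLA mismatches, 0-6",
}

CATEGORY_VOCABULARY = {
    "donor_sex": ("female", "male"),
    "recipient_sex": ("female", "male"),
    "donor_status": ("living", "deceased"),
}


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicated {what} identifier(s): {dups[:5]}")


@dataclass(frozen=True)
class ProteinMatrix:
    """Patient x protein abundance-ratio table.

    ``values`` is a DataFrame indexed by patient identifier with one column
    per protein identifier; every entry is a strictly positive ratio against
    the pooled-control channel.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index, "patient")
        _check_unique(df.columns, "protein")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise CohortValidationError(f"non-numeric protein column(s): {list(bad)[:5]}")
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise CohortValidationError(
                f"missing abundance ratio at patient {df.index[i]!r}, protein {df.columns[j]!r}"
            )
        if (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise CohortValidationError(
                f"non-positive abundance ratio ({arr[i, j]}) at patient "
                f"{df.index[i]!r}, protein {df.columns[j]!r}"
            )

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClinicalTable:
    """Per-patient clinical covariates, indexed by patient identifier."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index, "patient")
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"clinical table missing column(s): {missing}")
        for col in ("crp_index", "crp_next", "hospitalization_days", "dialysis_months"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.index[vals.isna()].tolist()
                raise CohortValidationError(f"non-numeric {col} for patient(s): {bad[:5]}")
            if (vals < 0).any():
                bad = df.index[vals < 0].tolist()
                raise CohortValidationError(f"negative {col} for patient(s): {bad[:5]}")
        for col, vocab in CATEGORY_VOCABULARY.items():
            bad = ~df[col].isin(vocab)
            if bad.any():
                raise CohortValidationError(
                    f"{col} outside vocabulary {vocab} for patient(s): "
                    f"{df.index[bad].tolist()[:5]}"
                )
        hla = pd.to_numeric(df["hla_mismatches"], errors="coerce")
        if hla.isna().any() or (hla < 0).any() or (hla > 6).any():
            raise CohortValidationError("hla_mismatches must be integers in 0-6")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class OutcomeVector:
    """Per-patient CRP change and derived binary event flag.

    ``event`` is True when next-day CRP strictly increased; a tie
    (delta_crp == 0) counts as a non-event.
    """

    delta_crp: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        if not self.delta_crp.index.equals(self.event.index):
            raise CohortValidationError("delta_crp and event indices differ")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.delta_crp.index)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_nonevents(self) -> int:
        return int((~self.event).sum())

    @property
    def prevalence(self) -> float:
        return float(self.event.mean())


_SEPS = {"csv": ",", "tsv": "\t"}


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith(".tsv") else "csv"
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return _SEPS[dialect]


def read_protein_matrix(path: str | Path, dialect: str | None = None) -> ProteinMatrix:
    """Read a wide-format protein matrix (first column = patient identifier)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise CohortValidationError(
                f"non-numeric cell at patient {df.index[bad.argmax()]!r}, protein {col!r}"
            )
        df[col] = coerced
    return ProteinMatrix(df)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path, dialect: str | None = None) -> None:
    matrix.values.to_csv(path, sep=_sep_for(path, dialect), index_label="patient_id")


def read_clinical_table(path: str | Path, dialect: str | None = None) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path, dialect: str | None = None) -> None:
    table.values.to_csv(path, sep=_sep_for(path, dialect), index_label="patient_id")


def derive_outcome(clinical: ClinicalTable) -> OutcomeVector:
    """Next-day minus index-day CRP and the strict-increase event flag.

    Deterministic and order-preserving: output rows follow the clinical
    table. delta_crp == 0 is a non-event.
    """
    df = clinical.values
    missing = df["crp_index"].isna() | df["crp_next"].isna()
    if missing.any():
        raise CohortValidationError(
            f"missing CRP for patient(s): {df.index[missing].tolist()[:10]}"
        )
    delta = (df["crp_next"] - df["crp_index"]).astype(float).rename("delta_crp")
    event = (delta > 0).rename("event")
    return OutcomeVector(delta_crp=delta, event=event)


def align_tables(
    matrix: ProteinMatrix, clinical: ClinicalTable
) -> tuple[ProteinMatrix, ClinicalTable, list[str]]:
    """Restrict both tables to their common patients, preserving matrix order.

    Returns the aligned matrix, the aligned clinical table (reordered to the
    matrix), and the identifiers dropped from either side.
    """
    m_ids = pd.Index(matrix.patient_ids)
    c_ids = pd.Index(clinical.patient_ids)
    common = m_ids.intersection(c_ids)
    if len(common) == 0:
        raise CohortValidationError("no patient identifiers shared between tables")
    keep = [pid for pid in m_ids if pid in set(common)]
    dropped = sorted(set(m_ids.symmetric_difference(c_ids)))
    return (
        ProteinMatrix(matrix.values.loc[keep]),
        ClinicalTable(clinical.values.loc[keep]),
        dropped,
    )
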