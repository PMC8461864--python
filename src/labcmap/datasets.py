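"""In-memory containers and TSV/CSV contracts for the pipeline's tables.

Three tables flow through the pipeline:

* the longitudinal EHR-style table — one row per (patient, measurement
  index, lab) with a 0/1 exposure column per drug,
* the survey-style case/control table — one row per subject with a
  ``status_<disease>`` column per disease and a numeric column per lab,
* the gold standard — two-column (disease_id, drug_id) CSV.

All tables are UTF-8 with a header row.  Disease status columns carry the
``status_`` prefix so survey tables are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: columns of the longitudinal table that precede the per-drug exposure block
EHR_FIXED_COLUMNS = ("patient_id", "meas_index", "lab_id", "value")

STATUS_PREFIX = "status_"


@dataclass
class LongitudinalDataset:
    """Per-patient lab measurements with binary drug exposures.

    ``table`` holds one row per (patient, measurement index, lab): columns
    ``patient_id``, ``meas_index``, ``lab_id``, ``value`` and one 0/1 column
    per drug id.  The exposure indicators describe which drugs the patient
    was on at the time the measurement was taken.
    """

    table: pd.DataFrame
    drugs: list[str]
    labs: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in EHR_FIXED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"longitudinal table missing columns {missing}")
        for d in self.drugs:
            if d not in self.table.columns:
                raise ValueError(f"exposure column for drug {d!r} missing")
            col = self.table[d]
            if len(col) and not col.isin([0, 1]).all():
                raise ValueError(f"exposure column {d!r} must be 0/1")
        key = self.table[["patient_id", "lab_id", "meas_index"]]
        if key.duplicated().any():
            raise ValueError("duplicate (patient, lab, measurement index) rows")

    @property
    def n_patients(self) -> int:
        return self.table["patient_id"].nunique()

    def patients_exposed(self, drug: str) -> int:
        """Number of distinct patients ever exposed to ``drug``."""
        t = self.table
        return t.loc[t[drug] == 1, "patient_id"].nunique()

    def to_tsv(self, path: str | Path) -> None:
        cols = list(EHR_FIXED_COLUMNS) + list(self.drugs)
        self.table[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LongitudinalDataset":
        table = pd.read_csv(path, sep="\t")
        drugs = [c for c in table.columns if c not in EHR_FIXED_COLUMNS]
        labs = sorted(table["lab_id"].astype(str).unique())
        table["lab_id"] = table["lab_id"].astype(str)
        table["patient_id"] = table["patient_id"].astype(str)
        return cls(table=table, drugs=drugs, labs=labs)


@dataclass
class CaseControlDataset:
    """Survey subjects with per-disease case/control status and lab values.

    ``table`` has a ``subject_id`` column, one ``status_<disease>`` column
    per disease (1 = case, 0 = control) and one numeric column per lab.
    Missing lab values are allowed (NaN) and dropped pairwise per lab.
    """

    table: pd.DataFrame
    diseases: list[str]
    labs: list[str]

    def __post_init__(self) -> None:
        if "subject_id" not in self.table.columns:
            raise ValueError("survey table missing subject_id column")
        if not self.labs:
            raise ValueError("survey table needs at least one lab column")
        for dz in self.diseases:
            col = STATUS_PREFIX + dz
            if col not in self.table.columns:
                raise ValueError(f"status column for disease {dz!r} missing")
            vals = self.table[col].dropna()
            if len(vals) and not vals.isin([0, 1]).all():
                raise ValueError(f"status column {col!r} must be 0/1")

    def split(self, disease: str, lab: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (case values, control values) for one lab, NaNs dropped."""
        if disease not in self.diseases:
            raise KeyError(f"unknown disease {disease!r}")
        if lab not in self.labs:
            raise KeyError(f"unknown lab {lab!r}")
        status = self.table[STATUS_PREFIX + disease]
        vals = self.table[lab]
        case = vals[status == 1].dropna().to_numpy(dtype=float)
        control = vals[status == 0].dropna().to_numpy(dtype=float)
        return case, control

    def to_tsv(self, path: str | Path) -> None:
        cols = (
            ["subject_id"]
            + [STATUS_PREFIX + d for d in self.diseases]
            + list(self.labs)
        )
        self.table[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CaseControlDataset":
        table = pd.read_csv(path, sep="\t")
        diseases = [
            c[len(STATUS_PREFIX):]
            for c in table.columns
            if c.startswith(STATUS_PREFIX)
        ]
        labs = [
            c
            for c in table.columns
            if c != "subject_id" and not c.startswith(STATUS_PREFIX)
        ]
        return cls(table=table, diseases=diseases, labs=labs)


@dataclass
class GoldStandard:
    """Known indications: disease id -> set of indicated drug ids."""

    indications: dict[str, set[str]] = field(default_factory=dict)

    def drugs_for(self, disease: str) -> set[str]:
        return set(self.indications.get(disease, set()))

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"disease_id": dz, "drug_id": dr}
            for dz in sorted(self.indications)
            for dr in sorted(self.indications[dz])
        ]
        pd.DataFrame(rows, columns=["disease_id", "drug_id"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GoldStandard":
        df = pd.read_csv(path)
        out: dict[str, set[str]] = {}
        for dz, dr in zip(df["disease_id"].astype(str), df["drug_id"].astype(str)):
            out.setdefault(dz, set()).add(dr)
        return cls(indications=out)
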