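"""Seeded generators for EHR-style and survey-style synthetic datasets.

The longitudinal generator draws data exactly from the linear fixed-effects
model the CSCCS estimator assumes:

    y_ij = alpha_i + beta' x_ij + eps_ij,   eps_ij ~ N(0, sigma^2) iid,

with a per-patient, per-lab baseline ``alpha_i``, a sparse drug-effect
matrix ``beta`` and i.i.d. Bernoulli drug exposures at each measurement
time.  The survey generator draws case and control lab values from normal
distributions with a per-lab mean shift in the case group.  Both are fully
determined by their seed, so every downstream stage is testable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from labcmap.datasets import (
    STATUS_PREFIX,
    CaseControlDataset,
    GoldStandard,
    LongitudinalDataset,
)

__all__ = [
    "EHRSimConfig",
    "TrueDrugEffects",
    "SurveySimConfig",
    "generate_ehr",
    "generate_survey",
    "generate_gold_standard",
]


def drug_ids(n: int) -> list[str]:
    return [f"drug_{i:03d}" for i in range(n)]


def lab_ids(n: int) -> list[str]:
    return [f"lab_{i:02d}" for i in range(n)]


@dataclass(frozen=True)
class EHRSimConfig:
    """World description for the longitudinal generator.

    Parameters
    ----------
    n_patients, n_drugs, n_labs
        Panel dimensions (N, M, L).
    measurements_per_patient
        Inclusive (low, high) range for the per-patient panel length J_i,
        drawn uniformly to exercise unbalanced panels.
    baseline_mean, baseline_sd
        Distribution of the per-patient, per-lab baseline alpha_i.  The
        baseline is a nuisance parameter; any dispersed choice is valid.
    noise_sd
        Standard deviation sigma of the iid Gaussian measurement noise.
    exposure_prob
        Probability that a patient is on any given drug at a measurement
        time; exposures are independent Bernoulli draws per drug per
        measurement.
    """

    n_patients: int
    n_drugs: int
    n_labs: int
    measurements_per_patient: tuple[int, int] = (5, 10)
    baseline_mean: float = 50.0
    baseline_sd: float = 10.0
    noise_sd: float = 1.0
    exposure_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_drugs, self.n_labs) < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.measurements_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("measurements_per_patient must be a range with 1 <= lo <= hi")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.exposure_prob <= 1.0:
            raise ValueError("exposure_prob must be in [0, 1]")


@dataclass
class TrueDrugEffects:
    """Planted drug x lab effect matrix beta (sparse by construction)."""

    matrix: np.ndarray  # shape (n_drugs, n_labs)
    drugs: list[str]
    labs: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.drugs), len(self.labs)):
            raise ValueError("effects matrix shape does not match drug/lab ids")

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.matrix)

    @classmethod
    def random_sparse(
        cls,
        n_drugs: int,
        n_labs: int,
        n_effects: int,
        magnitude: float = 1.0,
        seed: int = 0,
    ) -> "TrueDrugEffects":
        """Plant ``n_effects`` distinct (drug, lab) effects of |beta| = magnitude
        with random signs; all other entries exactly zero."""
        if n_effects > n_drugs * n_labs:
            raise ValueError("more effects than matrix cells")
        rng = np.random.default_rng(seed)
        mat = np.zeros((n_drugs, n_labs))
        cells = rng.choice(n_drugs * n_labs, size=n_effects, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_effects)
        mat.flat[cells] = signs * magnitude
        return cls(matrix=mat, drugs=drug_ids(n_drugs), labs=lab_ids(n_labs))


def generate_ehr(config: EHRSimConfig, effects: TrueDrugEffects) -> LongitudinalDataset:
    """Draw a longitudinal dataset exactly from the generative linear model.

    One record per (patient, measurement index, lab).  The drug-exposure
    vector is drawn once per measurement time and shared by all labs
    measured at that time.  Identical (config, effects) with the same seed
    give byte-identical output.
    """
    if effects.matrix.shape != (config.n_drugs, config.n_labs):
        raise ValueError(
            f"effects shape {effects.matrix.shape} does not match config "
            f"({config.n_drugs} drugs, {config.n_labs} labs)"
        )
    rng = np.random.default_rng(config.seed)
    N, M, L = config.n_patients, config.n_drugs, config.n_labs
    lo, hi = config.measurements_per_patient

    J = rng.integers(lo, hi + 1, size=N)
    total = int(J.sum())
    alpha = rng.normal(config.baseline_mean, config.baseline_sd, size=(N, L))
    X = (rng.random(size=(total, M)) < config.exposure_prob).astype(np.int8)
    noise = rng.normal(0.0, config.noise_sd, size=(total, L)) if config.noise_sd > 0 else np.zeros((total, L))

    patient_of_row = np.repeat(np.arange(N), J)
    meas_index = np.concatenate([np.arange(j) for j in J]) if N else np.array([], dtype=int)
    # (total, L) matrix of values: baseline + planted effect + noise
    values = alpha[patient_of_row] + X @ effects.matrix + noise

    pid = np.array([f"p{i:05d}" for i in range(N)])
    frames = []
    for li, lab in enumerate(effects.labs):
        frame = pd.DataFrame(
            {
                "patient_id": pid[patient_of_row],
                "meas_index": meas_index,
                "lab_id": lab,
                "value": values[:, li],
            }
        )
        for mi, drug in enumerate(effects.drugs):
            frame[drug] = X[:, mi]
        frames.append(frame)
    if frames:
        table = pd.concat(frames, ignore_index=True)
        table = table.sort_values(
            ["patient_id", "lab_id", "meas_index"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        cols = ["patient_id", "meas_index", "lab_id", "value"] + list(effects.drugs)
        table = pd.DataFrame(columns=cols)
    return LongitudinalDataset(table=table, drugs=list(effects.drugs), labs=list(effects.labs))


@dataclass(frozen=True)
class SurveySimConfig:
    """World description for one disease's case/control survey sample.

    Cases are drawn from Normal(lab_means + disease_shifts, lab_sds) and
    controls from Normal(lab_means, lab_sds), one column per lab.
    """

    disease_id: str
    n_cases: int
    n_controls: int
    lab_means: tuple[float, ...]
    lab_sds: tuple[float, ...]
    disease_shifts: tuple[float, ...]
    labs: tuple[str, ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be >= 0")
        if any(s < 0 for s in self.lab_sds):
            raise ValueError("lab_sds must be >= 0")
        if not len(self.lab_means) == len(self.lab_sds) == len(self.disease_shifts):
            raise ValueError("lab_means, lab_sds, disease_shifts must have equal length")
        if self.labs and len(self.labs) != len(self.lab_means):
            raise ValueError("labs must match lab_means length")
        if not self.labs:
            object.__setattr__(self, "labs", tuple(lab_ids(len(self.lab_means))))


def generate_survey(config: SurveySimConfig) -> CaseControlDataset:
    """Draw one disease's case/control survey table; seeded and reproducible."""
    rng = np.random.default_rng(config.seed)
    means = np.asarray(config.lab_means, dtype=float)
    sds = np.asarray(config.lab_sds, dtype=float)
    shifts = np.asarray(config.disease_shifts, dtype=float)
    L = len(means)

    case_vals = rng.normal(means + shifts, sds, size=(config.n_cases, L))
    control_vals = rng.normal(means, sds, size=(config.n_controls, L))

    n = config.n_cases + config.n_controls
    table = pd.DataFrame(
        np.vstack([case_vals, control_vals]) if n else np.empty((0, L)),
        columns=list(config.labs),
    )
    table.insert(0, "subject_id", [f"s{i:05d}" for i in range(n)])
    table.insert(
        1,
        STATUS_PREFIX + config.disease_id,
        np.r_[np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)],
    )
    return CaseControlDataset(
        table=table, diseases=[config.disease_id], labs=list(config.labs)
    )


def generate_gold_standard(
    drug_effects: TrueDrugEffects,
    disease_shifts: Mapping[str, Sequence[float]],
) -> GoldStandard:
    """Gold standard implied by the planted truth.

    A drug is listed as indicated for a disease iff the repurposing score of
    the *true* sign patterns, -sign(beta_drug) . sign(shift_disease), is
    strictly positive — i.e. the drug's planted effects are net complementary
    to the disease's planted lab shifts.  Ties at zero are excluded.
    """
    drug_signs = drug_effects.signs
    out: dict[str, set[str]] = {}
    for dz, shifts in disease_shifts.items():
        shifts = np.asarray(shifts, dtype=float)
        if shifts.shape != (len(drug_effects.labs),):
            raise ValueError(
                f"disease {dz!r} shifts have length {shifts.shape}, "
                f"expected {len(drug_effects.labs)}"
            )
        scores = -(drug_signs @ np.sign(shifts))
        out[dz] = {d for d, s in zip(drug_effects.drugs, scores) if s > 0}
    return GoldStandard(indications=out)
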