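import numpy as np
import pandas as pd
import pytest

from labcmap.datasets import LongitudinalDataset
from labcmap.synthetic import EHRSimConfig, TrueDrugEffects, generate_ehr


@pytest.fixture
def small_effects() -> TrueDrugEffects:
    """Three drugs, two labs, one planted effect: drug_000 raises lab_00 by 2."""
    mat = np.zeros((3, 2))
    mat[0, 0] = 2.0
    return TrueDrugEffects(
        matrix=mat,
        drugs=["drug_000", "drug_001", "drug_002"],
        labs=["lab_00", "lab_01"],
    )


@pytest.fixture
def noise_free_dataset(small_effects) -> LongitudinalDataset:
    config = EHRSimConfig(
        n_patients=10,
        n_drugs=3,
        n_labs=2,
        measurements_per_patient=(4, 6),
        noise_sd=0.0,
        exposure_prob=0.4,
        seed=7,
    )
    return generate_ehr(config, small_effects)


def manual_dataset(records, drugs, labs) -> LongitudinalDataset:
    """Build a LongitudinalDataset from (patient, j, lab, value, exposures) tuples."""
    rows = []
    for patient, j, lab, value, exposures in records:
        row = {"patient_id": patient, "meas_index": j, "lab_id": lab, "value": value}
        row.update(dict(zip(drugs, exposures)))
        rows.append(row)
    return LongitudinalDataset(table=pd.DataFrame(rows), drugs=list(drugs), labs=list(labs))
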