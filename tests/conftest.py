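import numpy as np
import pandas as pd
import pytest

from statin_adherence import SimulationConfig, generate_cohort


def rx_frame(days, tablets, patient_id=0):
    """Prescription table for one patient from parallel day/tablet lists."""
    days = list(days)
    if np.isscalar(tablets):
        tablets = [tablets] * len(days)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "date_day": days,
            "n_tablets": list(tablets),
            "drug": "atorvastatin",
            "dose_band": "medium",
        }
    )


def ldl_frame(days, values, patient_id=0):
    return pd.DataFrame(
        {"patient_id": patient_id, "date_day": list(days), "ldl_mmol_l": list(values)}
    )


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_patients=5000, seed=20260901)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest clean cohort used by several table-level tests."""
    return generate_cohort(SimulationConfig(n_patients=300, seed=42))
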