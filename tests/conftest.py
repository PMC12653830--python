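import numpy as np
import pandas as pd
import pytest

from dceqc.extract import extract_cohort
from dceqc.phantom import generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 phantom cohort with volumes in memory (no disk)."""
    manifest, volumes = generate_cohort(8, seed=7)
    labels = dict(zip(manifest["patient_id"], manifest["label"]))
    return manifest, volumes, labels


@pytest.fixture(scope="session")
def small_feature_table(small_cohort) -> pd.DataFrame:
    """Middle-slice combined-ROI feature table for the small cohort."""
    _, volumes, labels = small_cohort
    return extract_cohort(volumes, labels, scenario="middle_slice",
                          roi_mode="combined")
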