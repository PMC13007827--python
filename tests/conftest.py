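import numpy as np
import pandas as pd
import pytest

from epimap.synthetic import (CohortConfig, IEEGConfig, ModalityModel,
                              make_parcellation)


@pytest.fixture(scope="session")
def small_cohort() -> CohortConfig:
    """Desk-scale cohort for fast tests."""
    return CohortConfig(n_controls=30, n_patients=6, n_rois=20, n_deep_rois=2,
                        seed=5)


@pytest.fixture(scope="session")
def small_parcellation(small_cohort):
    return make_parcellation(small_cohort)


@pytest.fixture(scope="session")
def small_ieeg() -> IEEGConfig:
    return IEEGConfig(n_normative_subjects=10, contacts_per_roi=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def gaussian_feature_table(n_subjects=100, n_rois=10, seed=0, mean=0.0, sd=1.0,
                           batch="b0"):
    """Plain Gaussian control table with uninformative demographics."""
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        age = float(r.uniform(20, 60))
        sex = "M" if r.random() < 0.5 else "F"
        vals = r.normal(mean, sd, n_rois)
        for j in range(n_rois):
            rows.append({"subject_id": f"s{i:03d}", "roi_id": f"r{j:02d}",
                         "modality": "GM_volume", "value": vals[j],
                         "age": age, "sex": sex, "batch": batch})
    return pd.DataFrame(rows)
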