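import numpy as np
import pandas as pd
import pytest

from coadmark.containers import OmicsMatrix, SurvivalTable
from coadmark.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture
def small_cohort_config():
    return CohortConfig(
        n_samples=80,
        n_features_per_omics={"gene": 40, "exon": 40, "methylation": 40, "mutation": 30},
        n_planted_per_omics={"gene": 4, "exon": 4, "methylation": 4, "mutation": 4},
        seed=11,
    )


def make_survival(os_days, events, **covariates):
    idx = [f"P{i}" for i in range(len(os_days))]
    df = pd.DataFrame({"os_days": os_days, "event": events}, index=idx)
    for k, v in covariates.items():
        df[k] = v
    return SurvivalTable(df)


def make_matrix(values, omics_type="gene", features=None, samples=None):
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"P{i}" for i in range(arr.shape[1])]
    return OmicsMatrix(omics_type, pd.DataFrame(arr, index=features, columns=samples))
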