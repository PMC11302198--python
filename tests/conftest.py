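import numpy as np
import pandas as pd
import pytest

from stroopsense import CohortSpec, FeatureTable, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 3)."""
    return generate_cohort(CohortSpec(seed=3))


@pytest.fixture(scope="session")
def small_spec():
    """A light cohort spec: same structure, far fewer features, for fast screening tests."""
    return CohortSpec(
        n_features_per_modality={"EDA": 12, "HRV": 8, "ST": 4},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def blobs():
    """Two well-separated Gaussian classes (CG 45 / EG 35, 8 dims)."""
    rng = np.random.default_rng(42)
    x = np.vstack([rng.normal(0, 1, (45, 8)), rng.normal(4, 1, (35, 8))])
    y = np.array(["CG"] * 45 + ["EG"] * 35)
    return x, y


def make_table(values, modalities, participants, tests, groups):
    """Assemble a FeatureTable from a (participants*tests, features) value array.

    Rows are ordered participant-major, test-minor; ``groups`` gives the
    group per participant.
    """
    names = [f for ns in modalities.values() for f in ns]
    rows = [
        (pid, grp, t)
        for pid, grp in zip(participants, groups)
        for t in tests
    ]
    df = pd.DataFrame(rows, columns=["participant_id", "group", "test"])
    df = pd.concat([df, pd.DataFrame(np.asarray(values, float), columns=names)], axis=1)
    return FeatureTable(df, modalities)
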