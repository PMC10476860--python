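import numpy as np
import pandas as pd
import pytest

from breathpanel.containers import FeatureTable
from breathpanel.synthetic_data import CohortSpec, generate_feature_table


@pytest.fixture(scope="session")
def default_cohort():
    """The default 382-sample study-scale synthetic cohort and its truth."""
    return generate_feature_table(CohortSpec(rng_seed=7))


@pytest.fixture()
def small_spec():
    """A small, fast cohort spec for unit-level checks."""
    return CohortSpec(
        n_per_class={"CRC": 6, "AA": 20, "NAA": 18, "control": 16},
        n_features=40,
        n_markers=4,
        rng_seed=11,
    )


def make_table(values: np.ndarray, classes, batches=None, sample_ids=None, feature_ids=None):
    """Build a FeatureTable from raw pieces (test helper)."""
    n, p = np.asarray(values).shape
    sidx = pd.Index(sample_ids or [f"S{i}" for i in range(n)], name="sample")
    fidx = pd.Index(feature_ids or [f"F{j}" for j in range(p)], name="feature")
    meta = pd.DataFrame(
        {
            "class": list(classes),
            "batch": list(batches) if batches is not None else ["B0"] * n,
        },
        index=sidx,
    )
    return FeatureTable(pd.DataFrame(values, index=sidx, columns=fidx), meta)
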