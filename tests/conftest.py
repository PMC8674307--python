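import numpy as np
import pandas as pd
import pytest

from fcharmonize import (
    FCFeatureTable,
    PhenotypeTable,
    SimulationConfig,
    simulate_features,
    upper_triangle_pairs,
)


@pytest.fixture(scope="session")
def toy_cohort():
    """Default desk-scale cohort: 4 sites, 200 subjects, V=190, seed 7."""
    return simulate_features(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_table(rng):
    """10 subjects x 6 features (R=4), plain Gaussian values."""
    pairs = upper_triangle_pairs(4)
    values = rng.normal(0.3, 0.2, (10, len(pairs)))
    sids = [f"sub-{i:02d}" for i in range(10)]
    return FCFeatureTable(sids, pairs, values, provenance=["fisher_z"])


@pytest.fixture()
def small_phenotypes(rng):
    """Phenotypes matching small_table: 2 sites, mixed diagnosis."""
    return PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": [f"sub-{i:02d}" for i in range(10)],
                "site": ["A"] * 5 + ["B"] * 5,
                "diagnosis": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
                "age": rng.uniform(20, 50, 10).round(1),
                "sex": [0, 1] * 5,
            }
        )
    )
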