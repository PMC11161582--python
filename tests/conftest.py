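import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pangotrace as pt

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_table():
    """3 individuals x 2 loci with one missing call, two populations."""
    calls = np.array([
        [[100, 102], [120, 120]],
        [[100, 100], [0, 0]],
        [[102, 104], [122, 124]],
    ])
    meta = pd.DataFrame({
        "population": ["north", "north", "south"],
        "cls": "reference",
        "lon": [10.0, 10.1, 11.5],
        "lat": [4.0, 4.1, 5.5],
    }, index=["i1", "i2", "i3"])
    return pt.GenotypeTable(["i1", "i2", "i3"], ["L1", "L2"], calls, meta)


@pytest.fixture
def small_model():
    return pt.simulate_model(n_pops=3, n_loci=4, alleles_per_locus=5,
                             concentration=30.0, seed=11,
                             private_spec=[("P01", "L01", 301, 0.3)])


@pytest.fixture
def small_table(small_model):
    return pt.simulate_genotypes(
        small_model, {p: 25 for p in small_model.populations}, seed=12)
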