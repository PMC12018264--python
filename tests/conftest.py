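import numpy as np
import pytest

import cropscs as c


def const_monthly(value, shape=(2, 2), name="climate"):
    """Monthly climatology with the same value in all 12 months."""
    return c.monthly_climatology(np.full((12, *shape), float(value)), name)


def monthly_from_values(values, shape=(1, 1), name="climate"):
    """Monthly climatology from a 12-vector, broadcast over the grid."""
    arr = np.asarray(values, dtype=float)[:, None, None] * np.ones((1, *shape))
    return c.monthly_climatology(arr, name)


@pytest.fixture(scope="session")
def world():
    """A small synthetic world shared by the read-only tests."""
    cfg = c.WorldConfig(
        grid_rows=30,
        grid_cols=60,
        n_crops=3,
        n_gcms=3,
        warming_deltas=(1.0, 2.5),
        precip_scale_factors=(0.97, 0.93),
        seed=11,
    )
    return c.generate_world(cfg)


@pytest.fixture(scope="session")
def result(world):
    return c.run_pipeline(world)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
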