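import numpy as np
import pytest

from vmatqa import DoseGrid, SiteTemplate, make_plan


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_grid_pair(rng):
    """A random co-registered 2D reference/evaluated pair on a 3 mm grid."""
    ref = DoseGrid((0, 0, 0), (3, 3, 3), rng.uniform(0.5, 2.0, (12, 12, 1)))
    ev = ref.with_values(ref.values * (1 + rng.normal(0, 0.02, ref.values.shape)))
    return ref, ev


@pytest.fixture(scope="session")
def prostate_plan():
    """One full-size synthetic prostate plan (dose grid + masks), fixed seed."""
    grid, masks = make_plan(SiteTemplate.prostate(), seed=42)
    return grid, {m.name: m for m in masks}
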