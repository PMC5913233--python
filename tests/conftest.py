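"""Shared fixtures: design patterns and small simulated fields.

Simulated fixtures use shortened acquisitions (1,500-3,000 frames instead of
15,000) so the unit suite stays fast; the acceptance tests run the full-size
conditions.
"""

import numpy as np
import pytest

import paintqc as pq
from paintqc import simulate as sim


@pytest.fixture(scope="session")
def grid_pattern():
    return pq.build_grid_20nm()


@pytest.fixture(scope="session")
def bs_pair():
    return pq.build_bs_pair()


@pytest.fixture(scope="session")
def variant_library():
    return pq.build_variant_library()


@pytest.fixture(scope="session")
def short_imaging():
    """2,000-frame acquisition: ~31 binding events (~105 locs) per site."""
    return sim.ImagingModel(n_frames=2000)


@pytest.fixture(scope="session")
def grid_field(grid_pattern, short_imaging):
    """20 grid structures, every site present, short acquisition."""
    population = sim.StructurePopulation(pattern=grid_pattern, n_structures=20)
    return sim.simulate_field(population, imaging=short_imaging, seed=12345)


@pytest.fixture(scope="session")
def grid_template():
    return pq.render_template(
        pq.build_grid_20nm(), pq.TemplateSpec(render_sigma=3.0, bin_size=2.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
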