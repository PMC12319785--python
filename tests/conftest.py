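import numpy as np
import pytest

from retestconn.datatypes import PlantedEdge
from retestconn.synthgen import null_design, simulate_dataset, strong_effect_design


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """~60-point study with one strongly planted, behaviorally coupled edge."""
    design = null_design(seed=11, n_grid_points=80)
    design.n_parcels_per_hemi = 3
    geometry_probe = simulate_dataset(design)  # to discover included parcels
    parc = geometry_probe.parcellation.table
    left = parc[(parc.hemisphere == "left") & parc.included].parcel_id.tolist()
    right = parc[(parc.hemisphere == "right") & parc.included].parcel_id.tolist()
    edge = PlantedEdge(left[0], right[0], "theta", "0-400", mu=0.05, sigma_b=0.02)
    design.planted_edges = [edge]
    design.behavior_coupling = [(edge, 1.0)]
    return simulate_dataset(design)


@pytest.fixture(scope="session")
def strong_dataset():
    return simulate_dataset(strong_effect_design(seed=2))
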