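import numpy as np
import pytest

from perisylvian import ModelParams
from perisylvian.connectivity import AreaGraph, NetworkInstance, build_synapses
from perisylvian.stimuli import generate_patterns


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


def make_toy_instance(seed=0, side=5, n_areas=2, n_patterns=2,
                      cells_per_pattern=3, sigma=2.0, p0=0.6,
                      tag="HA") -> NetworkInstance:
    """Small chain network for fast protocol/dynamics tests."""
    areas = tuple(f"X{i}" for i in range(n_areas))
    graph = AreaGraph.chain(areas)
    rng = np.random.default_rng(seed)
    syn = build_synapses(graph, sigma=sigma, p0=p0, rng=rng, side=side)
    patterns = generate_patterns(n_patterns, cells_per_pattern, rng,
                                 area_cells=side * side)
    return NetworkInstance(tag, graph, syn, patterns, seed)


@pytest.fixture
def toy_instance() -> NetworkInstance:
    return make_toy_instance()
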