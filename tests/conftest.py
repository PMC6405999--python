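import numpy as np
import pytest

from labelgame import (
    ModelParams,
    SimState,
    Strategy,
    assign_labels_gradient,
    assign_labels_uniform,
    build_cylinder,
    build_torus,
)


def make_state(graph, labels, strategies, seed=0):
    return SimState(
        graph=graph,
        labels=np.asarray(labels, dtype=np.uint8),
        strategies=np.asarray(strategies, dtype=np.uint8),
        rng=np.random.default_rng(seed),
    )


def random_state(graph, seed=0):
    """Uniformly random labels and strategies on a given graph."""
    rng = np.random.default_rng(seed)
    return SimState(
        graph=graph,
        labels=rng.integers(2, size=graph.n_agents).astype(np.uint8),
        strategies=rng.integers(4, size=graph.n_agents).astype(np.uint8),
        rng=rng,
    )


@pytest.fixture
def small_torus():
    return build_torus(6, 6)


@pytest.fixture
def gradient_state():
    g = build_cylinder(10, 10)
    labels = assign_labels_gradient(g, 42)
    return make_state(g, labels, np.full(100, Strategy.DEFECT_ALL), seed=42)
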