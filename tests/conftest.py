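from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from modulenet import ExpressionMatrix, GeneNetwork, SampleAnnotation


def network_from_edges(edges, isolated=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(isolated)
    return GeneNetwork.from_graph(g)


@pytest.fixture
def toy_net():
    """10-node graph with three degree-3 hubs g1, g5, g9.

    Initialized modules: U1={g1,g2,g3,g4}, U2={g5,g6,g7,g8},
    U3={g9,g2,g6,g10}; the only seed set is {U1,U2}.
    """
    return network_from_edges(
        [("g1", "g2"), ("g1", "g3"), ("g1", "g4"),
         ("g5", "g6"), ("g5", "g7"), ("g5", "g8"),
         ("g9", "g2"), ("g9", "g6"), ("g9", "g10")]
    )


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(11)
    genes = [f"G{i}" for i in range(5)]
    samples = [f"S{j}" for j in range(10)]
    return ExpressionMatrix(genes, samples, rng.standard_normal((5, 10)))


def make_annotations(days_events, prefix="s"):
    """Build annotations from (survival_days, event) pairs."""
    return [
        SampleAnnotation(sample_id=f"{prefix}{i}", survival_days=d, event=e)
        for i, (d, e) in enumerate(days_events)
    ]


@pytest.fixture(scope="session")
def recovery_data():
    """Two-hub synthetic cohort used by the support/module recovery checks:
    30 genes, 2 hubs of degree 8, 5 background edges, 1000 samples/class."""
    from modulenet import make_model, sample_expression

    model = make_model(p=30, n_hubs=2, hub_degree=8, background_edges=5, seed=7)
    mat, ann, labels = sample_expression(model, n_per_class=1000, seed=7)
    return model, mat, ann, labels
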