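import numpy as np
import pandas as pd
import pytest

import connkit as ck


@pytest.fixture
def tiny_graph():
    """3 neurons, 2 edges, with region breakdowns."""
    g = ck.ConnectomeGraph()
    g.add_neuron(1, type_name="A", roi_counts={"EB": (3, 0), "PB": (2, 1)})
    g.add_neuron(2, type_name="A", roi_counts={"EB": (0, 3)})
    g.add_neuron(3, type_name="B", roi_counts={"PB": (1, 2)})
    g.add_edge(1, 2, 3, {"EB": 3})
    g.add_edge(1, 3, 2, {"PB": 2})
    return g


@pytest.fixture
def graph_files(tmp_path, tiny_graph):
    paths = ck.write_connectome(tiny_graph, tmp_path)
    return paths


def random_graph(n, p, seed, w_max=20):
    """Small random directed graph with random integer weights (no
    reciprocity structure); used for oracle comparisons."""
    rng = np.random.default_rng(seed)
    g = ck.ConnectomeGraph()
    for i in range(1, n + 1):
        g.add_neuron(i)
    for u in range(1, n + 1):
        for v in range(1, n + 1):
            if u != v and rng.random() < p:
                g.add_edge(u, v, int(rng.integers(1, w_max + 1)))
    return g


@pytest.fixture
def chain_graph():
    """A -> B -> C."""
    g = ck.ConnectomeGraph()
    for i in (1, 2, 3):
        g.add_neuron(i)
    g.add_edge(1, 2, 1)
    g.add_edge(2, 3, 1)
    return g


@pytest.fixture
def simple_skeleton():
    """3-node unbranched skeleton in a straight line."""
    nodes = pd.DataFrame({
        "node_id": [1, 2, 3], "struct_type": [0, 0, 0],
        "x": [0.0, 1.0, 2.0], "y": [0.0] * 3, "z": [0.0] * 3,
        "radius": [0.5, 0.5, 0.5], "parent_id": [-1, 1, 2],
        "label": ["A", "A", "B"],
    })
    return ck.Skeleton(nodes)


def labelled_path_skeleton(labels, step=1.0, radius=0.5):
    """Unbranched skeleton with the given node label sequence."""
    n = len(labels)
    nodes = pd.DataFrame({
        "node_id": range(1, n + 1), "struct_type": [0] * n,
        "x": [i * step for i in range(n)], "y": [0.0] * n, "z": [0.0] * n,
        "radius": [radius] * n,
        "parent_id": [-1] + list(range(1, n)),
        "label": list(labels),
    })
    return ck.Skeleton(nodes)
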