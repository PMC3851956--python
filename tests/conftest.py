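import numpy as np
import networkx as nx
import pytest

from netq.netio import Mapping, Network, NodeSimilarity


def random_network(rng: np.random.Generator, n: int, p: float = 0.3, name: str = "r") -> Network:
    """Small Erdős–Rényi network with string node ids (for oracles)."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    relabel = {i: f"n{i:02d}" for i in g.nodes}
    return Network(name=name, graph=nx.relabel_nodes(g, relabel))


def random_connected_network(rng: np.random.Generator, n: int, name: str = "r") -> Network:
    """Connected scale-free network (Barabási–Albert, always connected)."""
    g = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2**31)))
    relabel = {i: f"n{i:03d}" for i in g.nodes}
    return Network(name=name, graph=nx.relabel_nodes(g, relabel))


def identity_similarity(net: Network) -> NodeSimilarity:
    return NodeSimilarity(
        left=net.name,
        right=net.name,
        scores={(u, u): 1.0 for u in net.nodes},
    )


def random_sparse_similarity(
    rng: np.random.Generator, left: Network, right: Network, cands: int = 3
) -> NodeSimilarity:
    """Up to ``cands`` positive candidate scores per left node."""
    sim = NodeSimilarity(left=left.name, right=right.name)
    targets = right.sorted_nodes()
    for u in left.sorted_nodes():
        k = int(rng.integers(0, cands + 1))
        if k == 0:
            continue
        chosen = rng.choice(targets, size=min(k, len(targets)), replace=False)
        for v in chosen:
            sim.set(u, str(v), float(np.round(rng.uniform(0.05, 1.0), 3)))
    return sim


def random_mapping(rng: np.random.Generator, left: Network, right: Network) -> Mapping:
    """Random injective partial mapping between two node sets."""
    lt = left.sorted_nodes()
    rt = right.sorted_nodes()
    k = int(rng.integers(0, min(len(lt), len(rt)) + 1))
    us = rng.choice(lt, size=k, replace=False)
    vs = rng.choice(rt, size=k, replace=False)
    return Mapping.from_pairs(
        zip(map(str, us), map(str, vs)), direction=(left.name, right.name)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
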