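"""CRF model construction and MAP inference."""

import math

import numpy as np
import pytest

from netq.crfquery import (
    GAP,
    Labeling,
    QueryParams,
    build_crf,
    edge_compat,
    edge_feature,
    enumerate_map,
    labeling_score,
    map_infer,
    net_query,
    node_feature,
)
from netq.netio import Network, NodeSimilarity

from conftest import random_network, random_sparse_similarity

P = QueryParams()


def line(*nodes):
    return Network.from_edges(list(zip(nodes, nodes[1:])), nodes=nodes, name="q")


def test_query_params_validation():
    with pytest.raises(ValueError):
        QueryParams(top_k=0)
    with pytest.raises(ValueError):
        QueryParams(decay=0.0)
    with pytest.raises(ValueError):
        QueryParams(floor_eps=0.5, gap_score=0.01)


def test_node_feature_is_similarity_gap_and_floor():
    sim = NodeSimilarity(scores={("a", "x"): 0.8})
    assert node_feature(sim, "a", "x", P) == 0.8
    assert node_feature(sim, "a", GAP, P) == P.gap_score
    assert node_feature(sim, "a", "y", P) == P.floor_eps  # zero floored


def test_edge_compat_distance_decay():
    target = Network.from_edges([("x", "y"), ("y", "z")])
    assert edge_compat(target, "x", "y", P) == 1.0            # decay**0
    assert edge_compat(target, "x", "z", P) == 0.5            # decay**1 at d=2
    assert edge_compat(target, "x", "x", P) == P.floor_eps    # collision rule
    assert edge_compat(target, "x", GAP, P) == 1.0            # gap neutral
    far = Network.from_edges([("x", "y"), ("z", "w")])
    assert edge_compat(far, "x", "z", P) == P.floor_eps       # unreachable


def test_edge_feature_arithmetic_mean_times_w():
    target = Network.from_edges([("x", "y")])
    sim = NodeSimilarity(scores={("a", "x"): 0.8, ("b", "y"): 0.6})
    assert edge_feature(sim, "a", "b", "x", "y", target, P) == pytest.approx(0.7)
    assert edge_feature(sim, "a", "b", GAP, GAP, target, P) == pytest.approx(P.gap_score)
    # perfect similarities but unreachable labels floor out
    far = Network.from_edges([("x", "y"), ("z", "w")])
    sim2 = NodeSimilarity(scores={("a", "x"): 1.0, ("b", "z"): 1.0})
    assert edge_feature(sim2, "a", "b", "x", "z", far, P) == P.floor_eps


def test_build_crf_domains():
    target = Network.from_edges([("x", "y"), ("y", "z")])
    query = line("a")
    sim = NodeSimilarity(scores={("a", "x"): 0.9, ("a", "y"): 0.5, ("a", "z"): 0.2})
    model = build_crf(query, target, sim, QueryParams(top_k=2))
    assert model.domains["a"] == ["x", "y", GAP]   # 2 best + GAP
    # no positive score -> GAP only
    model2 = build_crf(line("b"), target, NodeSimilarity(), P)
    assert model2.domains["b"] == [GAP]
    # top_k=1 tie keeps the lexicographically smaller label
    sim3 = NodeSimilarity(scores={("a", "x"): 0.9, ("a", "w"): 0.9})
    target3 = Network.from_edges([("x", "w")])
    model3 = build_crf(line("a"), target3, sim3, QueryParams(top_k=1))
    assert model3.domains["a"] == ["w", GAP]


def test_build_crf_rejects_empty_query():
    with pytest.raises(ValueError):
        build_crf(Network(), Network.from_edges([("x", "y")]), NodeSimilarity(), P)


def test_labeling_score_single_factor_and_hand_product():
    target = Network.from_edges([("x", "y")])
    sim = NodeSimilarity(scores={("a", "x"): 0.8, ("b", "y"): 0.6})
    # single node: log f_N
    m1 = build_crf(line("a"), target, sim, P)
    assert labeling_score(m1, Labeling({"a": "x"})) == pytest.approx(math.log(0.8))
    # 2-node path: product of three factors multiplied by hand
    m2 = build_crf(line("a", "b"), target, sim, P)
    expect = math.log(0.8) + math.log(0.6) + math.log((0.8 + 0.6) / 2 * 1.0)
    assert labeling_score(m2, Labeling({"a": "x", "b": "y"})) == pytest.approx(expect)


def test_labeling_score_rejects_label_outside_domain():
    target = Network.from_edges([("x", "y")])
    model = build_crf(line("a"), target, NodeSimilarity(scores={("a", "x"): 1.0}), P)
    with pytest.raises(ValueError):
        labeling_score(model, Labeling({"a": "y"}))


def test_score_difference_independent_of_scaling():
    """Multiplying all potentials by a constant (Z-invariance) shifts every
    labeling's log-score equally, so the MAP labeling is unchanged."""
    target = Network.from_edges([("x", "y"), ("y", "z")])
    sim = NodeSimilarity(scores={("a", "x"): 0.9, ("a", "y"): 0.4, ("b", "y"): 0.7})
    model = build_crf(line("a", "b"), target, sim, P)
    base = map_infer(model, P)
    scaled = build_crf(line("a", "b"), target, sim, P)
    for u in scaled.log_node_pot:
        scaled.log_node_pot[u] = scaled.log_node_pot[u] + math.log(7.5)
    for e in scaled.log_edge_pot:
        scaled.log_edge_pot[e] = scaled.log_edge_pot[e] + math.log(7.5)
    assert map_infer(scaled, P).assignment == base.assignment


def test_single_node_query_is_argmax():
    target = Network.from_edges([("x", "y")])
    sim = NodeSimilarity(scores={("a", "x"): 0.3, ("a", "y"): 0.9})
    m = net_query(line("a"), target, sim, P)
    assert m.sorted_pairs() == [("a", "y")]


def test_path_query_equals_enumeration():
    """3-node path, 2 candidates each + GAP: exact DP == brute force."""
    target = Network.from_edges([("x1", "x2"), ("x2", "x3"), ("x1", "y1")])
    sim = NodeSimilarity(
        scores={
            ("a", "x1"): 0.9, ("a", "y1"): 0.6,
            ("b", "x2"): 0.8, ("b", "y1"): 0.7,
            ("c", "x3"): 0.9, ("c", "x1"): 0.3,
        }
    )
    model = build_crf(line("a", "b", "c"), target, sim, P)
    got = map_infer(model, P)
    _, best = enumerate_map(model)
    assert labeling_score(model, got) == pytest.approx(best, abs=1e-9)


def test_triangle_query_matches_enumeration_in_strong_signal_regime():
    """Loopy BP equals brute force when the optimum leads by > 1%."""
    tri = Network.from_edges([("a", "b"), ("b", "c"), ("c", "a")], name="q")
    target = Network.from_edges(
        [("x", "y"), ("y", "z"), ("z", "x"), ("x", "w"), ("w", "y")]
    )
    sim = NodeSimilarity(
        scores={
            ("a", "x"): 0.95, ("a", "w"): 0.4,
            ("b", "y"): 0.9, ("b", "w"): 0.35,
            ("c", "z"): 0.9, ("c", "w"): 0.3,
        }
    )
    model = build_crf(tri, target, sim, P)
    import itertools

    scores = sorted(
        labeling_score(model, Labeling(dict(zip(sorted(model.domains), combo))))
        for combo in itertools.product(
            *(model.domains[u] for u in sorted(model.domains))
        )
    )
    best, runner = scores[-1], scores[-2]
    assert abs(best - runner) > 0.01 * abs(best)  # strong-signal premise
    got = map_infer(model, P)
    assert labeling_score(model, got) == pytest.approx(best, abs=1e-9)


def test_query_triangle_in_itself_identity():
    tri = Network.from_edges([("a", "b"), ("b", "c"), ("c", "a")], name="q")
    sim = NodeSimilarity(scores={(u, u): 1.0 for u in "abc"})
    m = net_query(tri, tri, sim, P)
    assert m.sorted_pairs() == [("a", "a"), ("b", "b"), ("c", "c")]


def test_all_zero_similarity_maps_everything_to_gap():
    tri = Network.from_edges([("a", "b"), ("b", "c"), ("c", "a")], name="q")
    m = net_query(tri, tri, NodeSimilarity(), P)
    assert len(m) == 0


def test_many_to_one_allowed_without_query_edges():
    """Two disconnected query nodes sharing one perfect hit both map to it."""
    query = Network.from_edges([], nodes=["a", "b"], name="q")
    target = Network.from_edges([("x", "y")])
    sim = NodeSimilarity(scores={("a", "x"): 1.0, ("b", "x"): 1.0})
    model = build_crf(query, target, sim, P)
    lab, _ = enumerate_map(model)
    assert lab.assignment == {"a": "x", "b": "x"}  # enumeration confirms
    m = net_query(query, target, sim, P)
    assert m.assignment == {"a": "x", "b": "x"}


def _random_forest_instance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 6))
    # random forest: attach node i to a random earlier node (or leave isolated)
    edges, nodes = [], [f"q{k}" for k in range(n)]
    for i in range(1, n):
        if rng.random() < 0.8:
            j = int(rng.integers(0, i))
            edges.append((f"q{j}", f"q{i}"))
    query = Network.from_edges(edges, nodes=nodes, name="q")
    target = random_network(rng, int(rng.integers(3, 10)), 0.4, name="t")
    sim = random_sparse_similarity(rng, query, target, cands=4)
    return query, target, sim


@pytest.mark.parametrize("seed", range(40))
def test_forest_map_inference_equals_enumeration(seed):
    query, target, sim = _random_forest_instance(seed)
    model = build_crf(query, target, sim, P)
    got = map_infer(model, P)
    _, best = enumerate_map(model)
    assert labeling_score(model, got) == pytest.approx(best, abs=1e-9)


def test_inference_is_deterministic():
    query, target, sim = _random_forest_instance(7)
    runs = [net_query(query, target, sim, P).sorted_pairs() for _ in range(3)]
    assert runs[0] == runs[1] == runs[2]


def test_monotonicity_raising_a_map_score_keeps_the_pair():
    """Once (v, y*) is in the MAP labeling, increasing S(v, y*) keeps it."""
    for seed in range(25):
        query, target, sim = _random_forest_instance(seed)
        m = net_query(query, target, sim, P)
        for u, y in list(m.sorted_pairs())[:2]:
            sim2 = sim.copy()
            sim2.set(u, y, sim.get(u, y) + 0.5)
            assert net_query(query, target, sim2, P).get(u) == y
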