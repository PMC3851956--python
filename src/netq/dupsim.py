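"""Gene-duplication network evolution simulator and benchmark harness.

Starting from a base PPI network G, a duplicated network G' is grown by
repeated single-gene duplication events: a not-yet-affected node v is
copied to v' with the same interaction pattern, both copies lose edge
fractions (p1 for the copy, p2 for the original, p1 >= p2, reflecting
redundancy-driven interaction loss), and finally a small background
fraction p3 of all edges is removed at random. Duplications never hit a
node twice nor two adjacent nodes, so individual events stay uncorrelated.
The true alignment of G' onto G (every node's origin) is recorded, giving
alignment benchmarks with known ground truth.

Duplicated nodes carry their original's similarity row ("same sequence"),
so sequence evidence alone cannot tell a duplicate from its original —
the deliberate ambiguity that structural alignment must resolve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .aligner import (
    AlignParams,
    best_hit_align,
    best_hit_query,
    extract_one_to_one,
    net_align,
)
from .crfquery import QueryParams, net_query
from .netio import Mapping, Network, NodeSimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "TrueAlignment",
    "DUP_SUFFIX",
    "duplicate_network",
    "synth_similarity",
    "accuracy_dup",
    "accuracy_all",
    "preferential_attachment_network",
    "run_benchmark",
    "summarize_benchmark",
    "METHODS",
]

DUP_SUFFIX = "__dup"


@dataclass(frozen=True)
class SimParams:
    """Duplication-model parameters.

    N: maximum number of duplication events.
    p1: edge-loss fraction of the duplicated copy v'.
    p2: edge-loss fraction of the original v (p1 >= p2).
    p3: background random edge-loss fraction (expected p2 >> p3).
    link_duplicate: also add the v-v' edge (heterodimerization); off by
        default — duplication copies the interaction pattern only.
    """

    N: int = 100
    p1: float = 0.2
    p2: float = 0.1
    p3: float = 0.005
    seed: int = 0
    link_duplicate: bool = False

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.p1 < self.p2:
            raise ValueError(f"p1 ({self.p1}) must be >= p2 ({self.p2})")
        if self.p3 > self.p2:
            warnings.warn(
                f"expected p2 >> p3 but got p2={self.p2}, p3={self.p3}",
                stacklevel=2,
            )


@dataclass
class TrueAlignment:
    """Simulator ground truth for aligning G' back onto G.

    ``origin`` maps every node of G' to its base node (identity for
    non-duplicates); ``duplicated`` is the set D of base nodes that were
    copied; ``adjacent``/``remaining`` are the bookkeeping sets A and R at
    termination; ``removed`` tallies edges deleted per loss channel.
    """

    origin: dict[str, str] = field(default_factory=dict)
    duplicated: set[str] = field(default_factory=set)
    adjacent: set[str] = field(default_factory=set)
    remaining: set[str] = field(default_factory=set)
    removed: dict[str, int] = field(default_factory=lambda: {"p1": 0, "p2": 0, "p3": 0})

    def dup_of(self, v: str) -> str:
        if v not in self.duplicated:
            raise KeyError(f"{v!r} was not duplicated")
        return v + DUP_SUFFIX

    def duplicate_nodes(self) -> set[str]:
        return {self.dup_of(v) for v in self.duplicated}

    def validate(self, G: Network, Gp: Network) -> None:
        """Assert every structural invariant of the ground truth."""
        assert Gp.number_of_nodes() == G.number_of_nodes() + len(self.duplicated)
        assert set(self.origin) == Gp.nodes
        assert set(self.origin.values()) == G.nodes, "origin must be surjective"
        for v in self.duplicated:
            for w in self.duplicated:
                if v != w:
                    assert not G.has_edge(v, w), "adjacent duplications"
        assert not (self.duplicated & self.adjacent)
        for w in Gp.nodes:
            base = self.origin[w]
            assert base in G.nodes
            if w != base:
                assert w == base + DUP_SUFFIX and base in self.duplicated


def _round(x: float) -> int:
    # banker's rounding keeps the expected removed fraction closest to p
    return int(round(x))


def duplicate_network(G: Network, p: SimParams) -> tuple[Network, TrueAlignment]:
    """Evolve G into a duplicated network G' with known true alignment.

    Steps: (1) start with D = A = empty, R = V; (2) pick v uniformly from
    R and add v' with v's interaction pattern; (3) remove round(p1*deg)
    of v''s edges and round(p2*deg) of v's; (4) move v to D, N(v) to A,
    drop both from R; (5) repeat until N events or R empty; (6) remove
    round(p3*|E'|) edges uniformly from the whole network.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("base network is empty")
    rng = np.random.default_rng(p.seed)
    H: nx.Graph = G.graph.copy()
    truth = TrueAlignment(origin={u: u for u in G.nodes})
    R = set(G.nodes)
    n = 0
    while n < p.N and R:
        v = str(rng.choice(sorted(R)))
        vd = v + DUP_SUFFIX
        neigh = sorted(H.neighbors(v))  # untouched so far: equals N_G(v)
        H.add_node(vd)
        H.add_edges_from((vd, w) for w in neigh)
        if p.link_duplicate:
            H.add_edge(v, vd)
        deg = len(neigh)
        # step 3: independent interaction loss on the copy and the original
        for node, frac, tally in ((vd, p.p1, "p1"), (v, p.p2, "p2")):
            k = _round(frac * deg)
            if k > 0:
                targets = [w for w in neigh if H.has_edge(node, w)]
                drop = rng.choice(targets, size=k, replace=False)
                H.remove_edges_from((node, str(w)) for w in drop)
                truth.removed[tally] += k
        truth.origin[vd] = v
        truth.duplicated.add(v)
        truth.adjacent.update(neigh)
        R -= {v, *neigh}
        n += 1
    # step 6: background loss over the final edge multiset
    k3 = _round(p.p3 * H.number_of_edges())
    if k3 > 0:
        edges = sorted(tuple(sorted(e)) for e in H.edges)
        idx = rng.choice(len(edges), size=k3, replace=False)
        H.remove_edges_from(edges[i] for i in idx)
        truth.removed["p3"] = k3
    truth.remaining = R
    Gp = Network(name=(G.name + "_dup") if G.name else "dup", graph=H)
    logger.info(
        "simulated %d duplications on %r (removed: %s)",
        len(truth.duplicated), G.name, truth.removed,
    )
    return Gp, truth


def synth_similarity(
    G: Network,
    Gp: Network,
    truth: TrueAlignment,
    background: float = 0.0,
    noise_pairs: int = 0,
    seed: int = 0,
) -> NodeSimilarity:
    """Origin-based 0/1 similarity: S(u, w) = 1 whenever origin(w) = u.

    Every duplicate carries its original's similarity row, so a duplicated
    base node has two perfect hits (itself and its copy). Optionally adds
    ``noise_pairs`` random extra entries scored ``background``.
    """
    sim = NodeSimilarity(left=G.name, right=Gp.name)
    for w in sorted(Gp.nodes):
        base = truth.origin[w]
        sim.set(base, w, 1.0)
    if noise_pairs > 0:
        rng = np.random.default_rng(seed)
        left = sorted(G.nodes)
        right = sorted(Gp.nodes)
        added = 0
        while added < noise_pairs:
            u = str(rng.choice(left))
            w = str(rng.choice(right))
            if (u, w) not in sim.scores:
                sim.set(u, w, background)
                added += 1
    return sim


def accuracy_dup(m: Mapping, truth: TrueAlignment) -> float:
    """Fraction of duplicated base nodes correctly resolved.

    A duplicated node v counts as correct iff the alignment maps v to v
    itself AND its copy v' is aligned with gap (not the image of any base
    node). Returns 1.0 when nothing was duplicated.
    """
    if not truth.duplicated:
        return 1.0
    image = m.image()
    correct = sum(
        1
        for v in truth.duplicated
        if m.get(v) == v and truth.dup_of(v) not in image
    )
    return correct / len(truth.duplicated)


def accuracy_all(m: Mapping, truth: TrueAlignment) -> float:
    """Fraction of all base nodes correctly aligned.

    Non-duplicated nodes must map to themselves; duplicated nodes follow
    the duplication criterion of :func:`accuracy_dup`.
    """
    base_nodes = set(truth.origin.values())
    if not base_nodes:
        return 0.0
    image = m.image()
    correct = 0
    for v in base_nodes:
        if v in truth.duplicated:
            correct += m.get(v) == v and truth.dup_of(v) not in image
        else:
            correct += m.get(v) == v
    return correct / len(base_nodes)


def preferential_attachment_network(
    n: int, m: int = 3, seed: int = 0, name: str = "base"
) -> Network:
    """Scale-free (Barabási–Albert) base network with zero-padded node ids.

    A desk-scale stand-in for real PPI networks, which share the heavy-
    tailed degree distribution.
    """
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    width = len(str(n - 1))
    relabel = {i: f"g{i:0{width}d}" for i in g.nodes}
    return Network(name=name, graph=nx.relabel_nodes(g, relabel))


METHODS = ("cnetq", "cneta", "blastq", "blasta")


def _run_method(
    method: str,
    G: Network,
    Gp: Network,
    sim: NodeSimilarity,
    qp: QueryParams,
    max_rounds: int,
) -> Mapping:
    ap = AlignParams(query_params=qp, max_rounds=max_rounds)
    if method == "cnetq":
        return extract_one_to_one(net_query(G, Gp, sim, qp))
    if method == "cneta":
        return net_align(G, Gp, sim, ap)[0]
    if method == "blastq":
        return extract_one_to_one(best_hit_query(G, Gp, sim))
    if method == "blasta":
        return best_hit_align(G, Gp, sim, ap)[0]
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    G: Network,
    settings: list[tuple[float, float]],
    reps: int = 10,
    N: int = 100,
    p3: float = 0.005,
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    query_params: QueryParams | None = None,
    max_rounds: int = 20,
) -> pd.DataFrame:
    """Simulate-and-align benchmark over a (p1, p2) grid.

    For every setting and replicate: evolve G, build the origin-based
    similarity, run each method and score it (MP, EC, LCCS, duplication
    and overall accuracy). Returns one row per (setting, replicate,
    method); fully deterministic given ``seed``.
    """
    from .evalsuite import edge_correctness, lccs, mp  # local: avoid cycle

    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    qp = query_params or QueryParams()
    rng = np.random.default_rng(seed)
    rows = []
    for p1, p2 in settings:
        for rep in range(reps):
            sim_seed = int(rng.integers(2**31))
            sp = SimParams(N=N, p1=p1, p2=p2, p3=p3, seed=sim_seed)
            Gp, truth = duplicate_network(G, sp)
            sim = synth_similarity(G, Gp, truth)
            for method in methods:
                m = _run_method(method, G, Gp, sim, qp, max_rounds)
                n_lccs, e_lccs = lccs(G, Gp, extract_one_to_one(m))
                rows.append(
                    {
                        "p1": p1,
                        "p2": p2,
                        "rep": rep,
                        "method": method,
                        "mp": mp(m),
                        "ec": edge_correctness(G, Gp, m),
                        "lccs_nodes": n_lccs,
                        "lccs_edges": e_lccs,
                        "acc_dup": accuracy_dup(m, truth),
                        "acc_all": accuracy_all(m, truth),
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs.update({"N": N, "p3": p3, "reps": reps, "seed": seed})
    return df


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Per-method means of every numeric measure (the shape of a summary table)."""
    return (
        df.groupby("method")[["mp", "ec", "lccs_nodes", "lccs_edges", "acc_dup", "acc_all"]]
        .mean()
        .reset_index()
    )
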