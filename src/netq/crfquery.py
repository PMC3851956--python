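"""Network querying as conditional-random-field MAP inference.

A query network G is matched into a target network G' by treating the
target's nodes as a label set: each query node v_i receives a label
y_i in V' or the special GAP label (unmatched). The CRF assigns

    Pr(Y | G) = 1/Z(G) * prod_i f_N(y_i) * prod_(i,j) f_E(y_i, y_j)

with node feature f_N(y_i) = S(v_i, y_i) (the input node similarity) and
edge feature f_E(y_i, y_j) = (S(v_i,y_i) + S(v_j,y_j))/2 * W(y_i, y_j),
where W rewards label pairs that are close in the target. The labeling
maximizing Pr(Y|G) is the query result; Z(G) is never computed since MAP
inference is invariant to it.

Inference is exact max-product dynamic programming when the query graph is
a forest, and damped loopy max-product belief propagation otherwise. All
tie-breaks are lexicographic on node identifier so runs are reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np

from .netio import Mapping, Network, NodeSimilarity, bounded_distances

logger = logging.getLogger(__name__)

__all__ = [
    "GAP",
    "QueryParams",
    "CRFModel",
    "Labeling",
    "node_feature",
    "edge_compat",
    "edge_feature",
    "build_crf",
    "labeling_score",
    "map_infer",
    "net_query",
]


class _Gap:
    """Singleton label meaning "unmatched" (node insertion/deletion)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "GAP"


GAP = _Gap()

Label = object  # str target node or GAP


def _label_sort_key(y: Label) -> tuple[int, str]:
    # real labels sort before GAP, lexicographically among themselves
    return (1, "") if y is GAP else (0, str(y))


@dataclass(frozen=True)
class QueryParams:
    """Tunable parameters of the CRF querying model.

    top_k
        candidate target labels kept per query node (by similarity).
    gap_score
        constant potential of the GAP label.
    dmax
        maximum target distance at which two labels still count as
        structurally compatible.
    decay
        per-hop decay of the edge compatibility W = decay**(d-1).
    floor_eps
        strictly positive floor replacing zero potentials, keeping
        log-space scores finite.
    bp_max_iters, bp_damping
        loopy belief-propagation schedule (cyclic query graphs only).
    """

    top_k: int = 10
    gap_score: float = 0.01
    dmax: int = 2
    decay: float = 0.5
    floor_eps: float = 1e-6
    bp_max_iters: int = 100
    bp_damping: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.dmax < 1:
            raise ValueError("dmax must be >= 1")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        if not (0 < self.floor_eps < self.gap_score):
            raise ValueError("floor_eps must satisfy 0 < floor_eps < gap_score")
        if not (0 <= self.bp_damping < 1):
            raise ValueError("bp_damping must be in [0, 1)")


def node_feature(sim: NodeSimilarity, i: str, y: Label, p: QueryParams) -> float:
    """Node potential f_N(y_i) = S(v_i, y_i), floored; GAP scores gap_score."""
    if y is GAP:
        return p.gap_score
    return max(sim.get(i, y), p.floor_eps)


def edge_compat(
    target: Network,
    y_i: Label,
    y_j: Label,
    p: QueryParams,
    dist: dict[str, int] | None = None,
) -> float:
    """Structural compatibility W(y_i, y_j) of two target labels.

    GAP is neutral (W = 1); identical labels are penalized to the floor to
    discourage adjacent query nodes collapsing onto one target node;
    otherwise W = decay**(d-1) for target distance d <= dmax, else the
    floor. ``dist`` may carry precomputed bounded distances from y_i.
    """
    if y_i is GAP or y_j is GAP:
        return 1.0
    if y_i == y_j:
        return p.floor_eps
    if dist is None:
        dist = bounded_distances(target, y_i, p.dmax)
    d = dist.get(y_j)
    if d is None or d > p.dmax:
        return p.floor_eps
    return p.decay ** (d - 1)


def edge_feature(
    sim: NodeSimilarity,
    i: str,
    j: str,
    y_i: Label,
    y_j: Label,
    target: Network,
    p: QueryParams,
    dist: dict[str, int] | None = None,
) -> float:
    """Edge potential f_E = (S(v_i,y_i) + S(v_j,y_j))/2 * W(y_i, y_j).

    A GAP label contributes gap_score to the similarity average.
    """
    s_i = p.gap_score if y_i is GAP else sim.get(i, y_i)
    s_j = p.gap_score if y_j is GAP else sim.get(j, y_j)
    w = edge_compat(target, y_i, y_j, p, dist=dist)
    return max((s_i + s_j) / 2.0 * w, p.floor_eps)


@dataclass
class Labeling:
    """One label per query node (GAP counts as assigned)."""

    assignment: dict[str, Label] = field(default_factory=dict)

    def matched_pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (u, y) for u, y in self.assignment.items() if y is not GAP
        )


@dataclass
class CRFModel:
    """A grounded CRF: candidate domains plus log node/edge potentials.

    ``log_node_pot[u]`` is an array over ``domains[u]``;
    ``log_edge_pot[(u, v)]`` (u < v) is a |D_u| x |D_v| matrix. The
    normalization factor Z(G) is symbolic only — it shifts every
    labeling's log-score by the same constant.
    """

    query: Network
    target: Network
    params: QueryParams
    domains: dict[str, list[Label]] = field(default_factory=dict)
    log_node_pot: dict[str, np.ndarray] = field(default_factory=dict)
    log_edge_pot: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def domain_index(self, u: str, y: Label) -> int:
        dom = self.domains[u]
        for k, lab in enumerate(dom):
            if lab is y or lab == y:
                return k
        raise ValueError(f"label {y!r} not in domain of query node {u!r}")


def _candidate_labels(sim: NodeSimilarity, u: str, p: QueryParams) -> list[Label]:
    row = sim.row(u)
    positive = [(v, s) for v, s in row.items() if s > 0]
    # score descending, then lexicographic for determinism
    positive.sort(key=lambda kv: (-kv[1], kv[0]))
    labels: list[Label] = [v for v, _ in positive[: p.top_k]]
    labels.sort()
    labels.append(GAP)
    return labels


def build_crf(
    query: Network, target: Network, sim: NodeSimilarity, p: QueryParams
) -> CRFModel:
    """Ground the CRF for a query/target pair.

    Each query node's label domain is its top_k positively scored target
    nodes plus GAP; node and edge potentials are tabulated in log space.
    """
    if query.number_of_nodes() == 0:
        raise ValueError("query network is empty")
    model = CRFModel(query=query, target=target, params=p)
    for u in query.sorted_nodes():
        dom = _candidate_labels(sim, u, p)
        model.domains[u] = dom
        model.log_node_pot[u] = np.log(
            [node_feature(sim, u, y, p) for y in dom]
        )

    # bounded-BFS distance rows, one per distinct candidate label
    dist_cache: dict[str, dict[str, int]] = {}

    def dist_row(y: Label) -> dict[str, int] | None:
        if y is GAP:
            return None
        if y not in dist_cache:
            dist_cache[y] = bounded_distances(target, y, p.dmax)
        return dist_cache[y]

    for u, v in query.sorted_edges():
        dom_u, dom_v = model.domains[u], model.domains[v]
        mat = np.empty((len(dom_u), len(dom_v)))
        for a, y_u in enumerate(dom_u):
            row = dist_row(y_u)
            for b, y_v in enumerate(dom_v):
                mat[a, b] = edge_feature(
                    sim, u, v, y_u, y_v, target, p, dist=row
                )
        model.log_edge_pot[(u, v)] = np.log(mat)
    return model


def labeling_score(model: CRFModel, labeling: Labeling) -> float:
    """Log-potential of a labeling: sum of log f_N plus log f_E terms.

    Strictly monotone in Pr(Y|G) because Z(G) is constant per model.
    """
    total = 0.0
    for u in model.domains:
        if u not in labeling.assignment:
            raise ValueError(f"query node {u!r} is unassigned")
        total += model.log_node_pot[u][model.domain_index(u, labeling.assignment[u])]
    for (u, v), mat in model.log_edge_pot.items():
        a = model.domain_index(u, labeling.assignment[u])
        b = model.domain_index(v, labeling.assignment[v])
        total += mat[a, b]
    return float(total)


def enumerate_map(model: CRFModel) -> tuple[Labeling, float]:
    """Exhaustive MAP by enumerating every labeling (oracle; tiny models only)."""
    nodes = sorted(model.domains)
    best: Labeling | None = None
    best_score = -math.inf
    for combo in product(*(model.domains[u] for u in nodes)):
        lab = Labeling(dict(zip(nodes, combo)))
        s = labeling_score(model, lab)
        if s > best_score + 1e-12:
            best, best_score = lab, s
    assert best is not None
    return best, best_score


def _decode_argmax(dom: list[Label], scores: np.ndarray, tol: float = 1e-9) -> int:
    """Index of the max score; near-ties resolved lexicographically."""
    m = float(np.max(scores))
    tied = [k for k in range(len(dom)) if scores[k] >= m - tol]
    return min(tied, key=lambda k: _label_sort_key(dom[k]))


def _edge_logpot(model: CRFModel, u: str, v: str) -> np.ndarray:
    """Log edge potential oriented as (domain of u) x (domain of v)."""
    if (u, v) in model.log_edge_pot:
        return model.log_edge_pot[(u, v)]
    return model.log_edge_pot[(v, u)].T


def _infer_forest(model: CRFModel) -> Labeling:
    """Exact max-product dynamic programming on a forest query graph."""
    g = model.query.graph
    assignment: dict[str, Label] = {}
    for comp in nx.connected_components(g):
        root = min(comp)
        order = list(nx.dfs_preorder_nodes(g, root))
        parent = {root: None}
        for u in order:
            for w in g.neighbors(u):
                if w not in parent:
                    parent[w] = u
        # upward pass (leaves first)
        up_msg: dict[str, np.ndarray] = {}  # child -> array over parent's domain
        up_ptr: dict[str, np.ndarray] = {}  # child -> argmax child label index
        for u in reversed(order):
            if parent[u] is None:
                continue
            par = parent[u]
            # score of each child label = node pot + children messages
            local = model.log_node_pot[u].copy()
            for w in g.neighbors(u):
                if w != par and parent.get(w) == u:
                    local = local + up_msg[w]
            pot = _edge_logpot(model, u, par)  # |D_u| x |D_par|
            table = local[:, None] + pot
            up_msg[u] = table.max(axis=0)
            # per parent label, lexicographically-smallest argmax child label
            dom_u = model.domains[u]
            ptr = np.empty(table.shape[1], dtype=int)
            for b in range(table.shape[1]):
                ptr[b] = _decode_argmax(dom_u, table[:, b], tol=0.0)
            up_ptr[u] = ptr
        # decode root, then downward
        root_score = model.log_node_pot[root].copy()
        for w in g.neighbors(root):
            root_score = root_score + up_msg[w]
        idx = {root: _decode_argmax(model.domains[root], root_score, tol=0.0)}
        for u in order:
            if parent[u] is not None:
                idx[u] = int(up_ptr[u][idx[parent[u]]])
            assignment[u] = model.domains[u][idx[u]]
    return Labeling(assignment)


def _infer_loopy(model: CRFModel) -> Labeling:
    """Damped loopy max-product BP, decoded by per-node max-marginals."""
    p = model.params
    g = model.query.graph
    nodes = sorted(model.domains)
    # directed messages (i -> j): array over domain of j
    msgs: dict[tuple[str, str], np.ndarray] = {}
    for u, v in model.log_edge_pot:
        msgs[(u, v)] = np.zeros(len(model.domains[v]))
        msgs[(v, u)] = np.zeros(len(model.domains[u]))
    for it in range(p.bp_max_iters):
        delta = 0.0
        for u in nodes:
            base = model.log_node_pot[u] + sum(
                msgs[(w, u)] for w in g.neighbors(u)
            )
            for v in sorted(g.neighbors(u)):
                out = base - msgs[(v, u)]
                new = (out[:, None] + _edge_logpot(model, u, v)).max(axis=0)
                new = new - new.max()  # normalize for stability
                new = (1.0 - p.bp_damping) * new + p.bp_damping * msgs[(u, v)]
                delta = max(delta, float(np.max(np.abs(new - msgs[(u, v)]))))
                msgs[(u, v)] = new
        if delta < 1e-9:
            logger.debug("loopy BP converged after %d sweeps", it + 1)
            break
    else:
        logger.debug("loopy BP hit bp_max_iters=%d (delta=%.2e)", p.bp_max_iters, delta)
    assignment: dict[str, Label] = {}
    for u in nodes:
        belief = model.log_node_pot[u] + sum(msgs[(w, u)] for w in g.neighbors(u))
        assignment[u] = model.domains[u][_decode_argmax(model.domains[u], belief)]
    return Labeling(assignment)


def map_infer(model: CRFModel, p: QueryParams | None = None) -> Labeling:
    """MAP labeling of the grounded CRF.

    Exact on forests (max-product dynamic programming); damped loopy
    max-product otherwise. Always returns a complete labeling.
    """
    if nx.is_forest(model.query.graph):
        return _infer_forest(model)
    return _infer_loopy(model)


def net_query(
    query: Network,
    target: Network,
    sim: NodeSimilarity,
    p: QueryParams | None = None,
) -> Mapping:
    """Query ``query`` in ``target``: the MAP labeling as a node mapping.

    GAP-labeled nodes are unmatched; the result may be many-to-one.
    """
    p = p or QueryParams()
    model = build_crf(query, target, sim, p)
    labeling = map_infer(model, p)
    score = labeling_score(model, labeling)
    m = Mapping.from_pairs(labeling.matched_pairs(), direction=(query.name, target.name))
    logger.info(
        "net_query %r in %r: %d/%d nodes matched, log-score %.4f",
        query.name, target.name, len(m), query.number_of_nodes(), score,
    )
    return m
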