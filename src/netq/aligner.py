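"""One-to-one pairwise network alignment by iterative bi-directional mapping.

A single CRF query is asymmetric (querying G in G' differs from querying
G' in G) and may be many-to-one. The aligner repairs both: at each round
it queries in both directions, fixes the reciprocal (common) pairs, clamps
them in the similarity table, and repeats until no new reciprocal pair
appears. Only fixed pairs are returned, so the result is injective in
both directions by construction.

Best-hit baselines are provided for comparison: ``best_hit_query`` maps
each node to its highest-similarity partner (sequence-only), and
``best_hit_align`` wraps it in the same iterative bi-directional loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .crfquery import QueryParams, net_query
from .netio import Mapping, Network, NodeSimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "AlignParams",
    "AlignTrace",
    "extract_one_to_one",
    "common_pairs",
    "fix_and_update",
    "net_align",
    "best_hit_query",
    "best_hit_align",
]


@dataclass(frozen=True)
class AlignParams:
    """Parameters of the iterative bi-directional loop.

    ``boost`` is the similarity assigned to fixed pairs; it must exceed
    every observed score so clamped pairs dominate their rows. The default
    (None) resolves to 1 + max observed similarity at run time.
    """

    query_params: QueryParams = field(default_factory=QueryParams)
    max_rounds: int = 20
    boost: float | None = None

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class RoundRecord:
    round: int
    forward_size: int
    backward_size: int
    new_fixed: int


@dataclass
class AlignTrace:
    """Per-round sizes of the iterative loop (for diagnostics)."""

    rounds: list[RoundRecord] = field(default_factory=list)

    def total_fixed(self) -> int:
        return sum(r.new_fixed for r in self.rounds)


def extract_one_to_one(m: Mapping) -> Mapping:
    """Drop every pair whose target is shared by >= 2 query nodes.

    The standard protocol for many-to-one methods: only one-to-one
    matching pairs are kept as final results. Idempotent; the result is
    injective.
    """
    counts: dict[str, int] = {}
    for _, v in m.pairs:
        counts[v] = counts.get(v, 0) + 1
    return Mapping.from_pairs(
        ((u, v) for u, v in m.sorted_pairs() if counts[v] == 1),
        direction=m.direction,
    )


def common_pairs(fwd: Mapping, bwd: Mapping) -> set[tuple[str, str]]:
    """Reciprocal pairs: {(u, v) : fwd(u) = v and bwd(v) = u}.

    Necessarily one-to-one. Directions must be opposite.
    """
    if fwd.direction != (bwd.direction[1], bwd.direction[0]):
        raise ValueError(
            f"direction mismatch: {fwd.direction} vs {bwd.direction}"
        )
    return {(u, v) for u, v in fwd.pairs if bwd.get(v) == u}


def fix_and_update(
    sim: NodeSimilarity, fixed: set[tuple[str, str]], p: AlignParams
) -> NodeSimilarity:
    """Clamp fixed pairs in the similarity table.

    For each fixed (u, v): S(u, v) = boost while the rest of row u and
    column v are zeroed, so u and v drop out of every other node's
    candidate domain in subsequent rounds.
    """
    fixed_left = {u for u, _ in fixed}
    fixed_right = {v for _, v in fixed}
    if len(fixed_left) != len(fixed) or len(fixed_right) != len(fixed):
        raise ValueError("fixed pair set is not one-to-one")
    boost = p.boost if p.boost is not None else 1.0 + sim.max_score()
    scores = {
        (u, v): s
        for (u, v), s in sim.scores.items()
        if u not in fixed_left and v not in fixed_right
    }
    for u, v in fixed:
        scores[(u, v)] = boost
    return NodeSimilarity(left=sim.left, right=sim.right, scores=scores)


def _iterative_align(
    G: Network,
    Gp: Network,
    sim: NodeSimilarity,
    p: AlignParams,
    query_fn,
) -> tuple[Mapping, AlignTrace]:
    """The iterative bi-directional loop shared by CRF and best-hit aligners."""
    if p.boost is not None and p.boost <= sim.max_score():
        raise ValueError("boost must exceed the maximum observed similarity")
    sim_t = sim
    fixed: set[tuple[str, str]] = set()
    trace = AlignTrace()
    for rnd in range(1, p.max_rounds + 1):
        fwd = query_fn(G, Gp, sim_t)
        bwd = query_fn(Gp, G, sim_t.transpose())
        new = common_pairs(fwd, bwd) - fixed
        trace.rounds.append(RoundRecord(rnd, len(fwd), len(bwd), len(new)))
        if not new:
            break
        fixed |= new
        sim_t = fix_and_update(sim_t, fixed, p)
    else:
        logger.warning("alignment hit max_rounds=%d before converging", p.max_rounds)
    result = Mapping.from_pairs(sorted(fixed), direction=(G.name, Gp.name))
    assert result.is_one_to_one(), "fixed set lost injectivity"
    logger.info(
        "alignment %r-%r: %d fixed pairs in %d rounds",
        G.name, Gp.name, len(result), len(trace.rounds),
    )
    return result, trace


def net_align(
    G: Network,
    Gp: Network,
    sim: NodeSimilarity,
    p: AlignParams | None = None,
) -> tuple[Mapping, AlignTrace]:
    """CRF-based one-to-one alignment (iterative bi-directional CRF queries).

    Returns the accumulated reciprocal pairs — injective in both
    directions — and the per-round trace.
    """
    p = p or AlignParams()

    def query_fn(a: Network, b: Network, s: NodeSimilarity) -> Mapping:
        return net_query(a, b, s, p.query_params)

    return _iterative_align(G, Gp, sim, p, query_fn)


def best_hit_query(
    G: Network,
    Gp: Network,
    sim: NodeSimilarity,
    ties: str = "drop",
) -> Mapping:
    """Sequence-only baseline: map each node to its best similarity hit.

    A node whose row is all zero is unmatched. When the maximum is tied
    among several targets the hits are indistinguishable on similarity
    alone; with ``ties="drop"`` (default) the node is left unmatched —
    mirroring a best-hit list that reports all tied hits, none of which
    survives one-to-one extraction — while ``ties="lexicographic"`` keeps
    the smallest identifier. The result may be many-to-one; apply
    ``extract_one_to_one`` for final one-to-one results.
    """
    if ties not in ("drop", "lexicographic"):
        raise ValueError(f"unknown tie policy {ties!r}")
    pairs = []
    for u in G.sorted_nodes():
        row = sim.row(u)
        positive = {v: s for v, s in row.items() if s > 0 and v in Gp}
        if not positive:
            continue
        best = max(positive.values())
        hits = sorted(v for v, s in positive.items() if s == best)
        if len(hits) > 1 and ties == "drop":
            continue
        pairs.append((u, hits[0]))
    return Mapping.from_pairs(pairs, direction=(G.name, Gp.name))


def best_hit_align(
    G: Network,
    Gp: Network,
    sim: NodeSimilarity,
    p: AlignParams | None = None,
    ties: str = "drop",
) -> tuple[Mapping, AlignTrace]:
    """Best-hit baseline wrapped in the iterative bi-directional loop."""
    p = p or AlignParams()

    def query_fn(a: Network, b: Network, s: NodeSimilarity) -> Mapping:
        return best_hit_query(a, b, s, ties=ties)

    return _iterative_align(G, Gp, sim, p, query_fn)
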