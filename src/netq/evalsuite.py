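"""Structural and biological evaluation measures for network alignments.

Structural measures need only the two networks and the mapping: matching
pairs (MP), edge correctness (EC), the edge accumulated coverage curve
EAC(k) (EC relaxed to allow mapped endpoints within target distance k),
and the largest common connected subgraph (LCCS). Biological measures
additionally need annotation inputs: GO-term sharing (SGO curve and
per-domain GO coverage at term depth >= 3), KEGG pathway statistics
(hit pathways HP and pathway average coverage PAC) and known ortholog
pairs (OP).

GO depth and domain are consumed as precomputed input columns; ontology
parsing is out of scope. The GO-coverage and PAC formulas are this
package's documented reconstructions (see docs/methods.md) and are each
isolated behind a single function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import networkx as nx

from .netio import Mapping, Network, bounded_distances, _data_lines

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "PathwayDB",
    "OrthologList",
    "EvaluationReport",
    "mp",
    "edge_correctness",
    "eac_curve",
    "lccs",
    "sgo_curve",
    "go_coverage",
    "pathway_stats",
    "ortholog_pairs",
    "evaluate",
    "read_annotations",
    "read_pathways",
    "read_orthologs",
]

GO_DOMAINS = ("MF", "BP", "CC")


@dataclass
class AnnotationTable:
    """Per node: a set of (GO term, domain, depth) annotations."""

    terms: dict[str, set[tuple[str, str, int]]] = field(default_factory=dict)

    def add(self, node: str, term: str, domain: str, depth: int) -> None:
        if domain not in GO_DOMAINS:
            raise ValueError(f"unknown GO domain {domain!r} (expected one of {GO_DOMAINS})")
        if depth < 0:
            raise ValueError("GO term depth must be >= 0")
        self.terms.setdefault(node, set()).add((term, domain, depth))

    def term_ids(self, node: str) -> set[str]:
        return {t for t, _, _ in self.terms.get(node, set())}

    def deep_terms(self, node: str, domain: str, min_depth: int) -> set[str]:
        return {
            t
            for t, dom, depth in self.terms.get(node, set())
            if dom == domain and depth >= min_depth
        }


@dataclass
class PathwayDB:
    """Per pathway id: member sets on each side of the alignment."""

    members: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)

    def add(self, pathway: str, side: str, node: str) -> None:
        a, b = self.members.setdefault(pathway, (set(), set()))
        if side == "A":
            a.add(node)
        elif side == "B":
            b.add(node)
        else:
            raise ValueError(f"pathway side must be 'A' or 'B', got {side!r}")

    def validate(self) -> None:
        for pid, (a, b) in self.members.items():
            if not a or not b:
                raise ValueError(f"pathway {pid!r} lacks members on one side")


@dataclass
class OrthologList:
    """Known cross-network ortholog pairs (directed left -> right)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)


def mp(m: Mapping) -> int:
    """Number of matching pairs (MP)."""
    return len(m)


def _conserved_edges(G: Network, Gp: Network, m: Mapping) -> list[tuple[str, str]]:
    out = []
    for u, v in G.sorted_edges():
        mu, mv = m.get(u), m.get(v)
        if mu is not None and mv is not None and Gp.has_edge(mu, mv):
            out.append((u, v))
    return out


def _matched_edges(G: Network, m: Mapping) -> list[tuple[str, str]]:
    return [
        (u, v)
        for u, v in G.sorted_edges()
        if m.get(u) is not None and m.get(v) is not None
    ]


def edge_correctness(
    G: Network, Gp: Network, m: Mapping, denom_mode: str = "matched_edges"
) -> float:
    """Edge correctness (EC), in percent.

    Numerator: query edges whose endpoint images are adjacent in the
    target. Denominator: query edges with both endpoints matched
    (default, fair for partial mappings) or all query edges
    (``denom_mode="all_edges"``, the whole-network convention).
    """
    num = len(_conserved_edges(G, Gp, m))
    if denom_mode == "matched_edges":
        den = len(_matched_edges(G, m))
    elif denom_mode == "all_edges":
        den = G.number_of_edges()
    else:
        raise ValueError(f"unknown denom_mode {denom_mode!r}")
    return 100.0 * num / den if den else 0.0


def eac_curve(
    G: Network, Gp: Network, m: Mapping, kmax: int, denom_mode: str = "matched_edges"
) -> list[float]:
    """Edge accumulated coverage EAC(k) for k = 1..kmax, in percent.

    EAC(k) counts query edges whose endpoint images lie within target
    distance k; EAC(1) equals EC under the same denominator mode.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    matched = _matched_edges(G, m)
    if denom_mode == "matched_edges":
        den = len(matched)
    elif denom_mode == "all_edges":
        den = G.number_of_edges()
    else:
        raise ValueError(f"unknown denom_mode {denom_mode!r}")
    if den == 0:
        return [0.0] * kmax
    dist_cache: dict[str, dict[str, int]] = {}
    counts = [0] * (kmax + 1)
    for u, v in matched:
        mu, mv = m.get(u), m.get(v)
        if mu not in dist_cache:
            dist_cache[mu] = bounded_distances(Gp, mu, kmax)
        d = dist_cache[mu].get(mv)
        if d is not None and 1 <= d <= kmax:
            counts[d] += 1
        elif d == 0:  # both endpoints mapped to one node: not a conserved edge
            continue
    acc = 0
    curve = []
    for k in range(1, kmax + 1):
        acc += counts[k]
        curve.append(100.0 * acc / den)
    return curve


def lccs(G: Network, Gp: Network, m: Mapping) -> tuple[int, int]:
    """Largest common connected subgraph: (node count, edge count).

    The conserved graph has one vertex per matched pair and an edge where
    the pair's endpoints are adjacent in BOTH networks; its largest
    connected component is reported (ties broken by edge count, then by
    lexicographically smallest member).
    """
    if not m.is_one_to_one():
        raise ValueError("lccs requires an injective mapping")
    if len(m) == 0:
        return (0, 0)
    cg = nx.Graph()
    cg.add_nodes_from(m.sorted_pairs())
    for u, v in _conserved_edges(G, Gp, m):
        cg.add_edge((u, m.get(u)), (v, m.get(v)))
    best = max(
        (cg.subgraph(c) for c in nx.connected_components(cg)),
        key=lambda s: (s.number_of_nodes(), s.number_of_edges(), min(s.nodes)),
    )
    return (best.number_of_nodes(), best.number_of_edges())


def sgo_curve(m: Mapping, ann: AnnotationTable, kmax: int) -> list[float]:
    """SGO(k): percent of matched pairs sharing >= k GO terms (pooled domains)."""
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if len(m) == 0:
        return [0.0] * kmax
    shared = [
        len(ann.term_ids(u) & ann.term_ids(v)) for u, v in m.sorted_pairs()
    ]
    return [100.0 * sum(s >= k for s in shared) / len(m) for k in range(1, kmax + 1)]


def go_coverage(
    m: Mapping, ann: AnnotationTable, domain: str, min_depth: int = 3
) -> float:
    """Percent of eligible matched pairs sharing a deep term of ``domain``.

    A pair is eligible when both nodes carry at least one term of the
    domain at depth >= min_depth. Returns 0 (with a warning) when no pair
    is eligible.
    """
    if domain not in GO_DOMAINS:
        raise ValueError(f"unknown GO domain {domain!r}")
    eligible = 0
    sharing = 0
    for u, v in m.sorted_pairs():
        tu = ann.deep_terms(u, domain, min_depth)
        tv = ann.deep_terms(v, domain, min_depth)
        if tu and tv:
            eligible += 1
            sharing += bool(tu & tv)
    if eligible == 0:
        logger.warning("go_coverage(%s): no eligible pair at depth >= %d", domain, min_depth)
        return 0.0
    return 100.0 * sharing / eligible


def pathway_stats(m: Mapping, pdb: PathwayDB) -> tuple[int, float]:
    """Hit pathways (HP) and pathway average coverage (PAC, percent).

    A pathway is hit when at least one matched pair lands inside it on
    both sides; its coverage is 2 * (such pairs) / (|P_A| + |P_B|). PAC
    averages coverage over hit pathways (0 when none is hit).
    """
    coverages = []
    for pid in sorted(pdb.members):
        a, b = pdb.members[pid]
        inside = sum(1 for u, v in m.pairs if u in a and v in b)
        if inside > 0:
            coverages.append(100.0 * 2.0 * inside / (len(a) + len(b)))
    hp = len(coverages)
    pac = sum(coverages) / hp if hp else 0.0
    return hp, pac


def ortholog_pairs(m: Mapping, orth: OrthologList) -> int:
    """Number of matched pairs that are known orthologs (OP)."""
    return len(m.pairs & orth.pairs)


@dataclass
class EvaluationReport:
    """Bundle of all measures; fields stay None when inputs were absent."""

    mp: int | None = None
    ec: float | None = None
    eac: list[float] | None = None
    lccs_nodes: int | None = None
    lccs_edges: int | None = None
    sgo: list[float] | None = None
    go_coverage: dict[str, float] | None = None
    hp: int | None = None
    pac: float | None = None
    op: int | None = None
    acc_dup: float | None = None
    acc_all: float | None = None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in fields(self):
                val = getattr(self, f.name)
                if val is None:
                    continue
                if isinstance(val, list):
                    text = ",".join(f"{x:.6g}" for x in val)
                elif isinstance(val, dict):
                    text = ",".join(f"{k}:{v:.6g}" for k, v in sorted(val.items()))
                else:
                    text = f"{val:.6g}" if isinstance(val, float) else str(val)
                fh.write(f"{f.name}\t{text}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EvaluationReport":
        rep = cls()
        int_fields = {"mp", "lccs_nodes", "lccs_edges", "hp", "op"}
        for _, tokens in _data_lines(path):
            key, text = tokens[0], tokens[1] if len(tokens) > 1 else ""
            if key in ("eac", "sgo"):
                setattr(rep, key, [float(x) for x in text.split(",")])
            elif key == "go_coverage":
                setattr(
                    rep,
                    key,
                    {kv.split(":")[0]: float(kv.split(":")[1]) for kv in text.split(",")},
                )
            elif key in int_fields:
                setattr(rep, key, int(text))
            else:
                setattr(rep, key, float(text))
        return rep


def evaluate(
    G: Network,
    Gp: Network,
    m: Mapping,
    ann: AnnotationTable | None = None,
    pdb: PathwayDB | None = None,
    orth: OrthologList | None = None,
    truth=None,
    kmax: int = 5,
    denom_mode: str = "matched_edges",
    min_depth: int = 3,
) -> EvaluationReport:
    """Compute every measure whose inputs are present."""
    rep = EvaluationReport(
        mp=mp(m),
        ec=edge_correctness(G, Gp, m, denom_mode),
        eac=eac_curve(G, Gp, m, kmax, denom_mode),
    )
    one2one = m if m.is_one_to_one() else None
    if one2one is None:
        from .aligner import extract_one_to_one

        one2one = extract_one_to_one(m)
    rep.lccs_nodes, rep.lccs_edges = lccs(G, Gp, one2one)
    if ann is not None:
        rep.sgo = sgo_curve(m, ann, kmax)
        rep.go_coverage = {
            dom: go_coverage(m, ann, dom, min_depth) for dom in GO_DOMAINS
        }
    if pdb is not None:
        rep.hp, rep.pac = pathway_stats(m, pdb)
    if orth is not None:
        rep.op = ortholog_pairs(m, orth)
    if truth is not None:
        from .dupsim import accuracy_all, accuracy_dup

        rep.acc_dup = accuracy_dup(m, truth)
        rep.acc_all = accuracy_all(m, truth)
    return rep


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a (node, term, domain, depth) TSV into an AnnotationTable."""
    ann = AnnotationTable()
    for lineno, tokens in _data_lines(path):
        if len(tokens) < 4:
            raise ValueError(f"{path}:{lineno}: expected 'node term domain depth'")
        ann.add(tokens[0], tokens[1], tokens[2], int(tokens[3]))
    return ann


def read_pathways(path: str | Path) -> PathwayDB:
    """Read a (pathway, side, node) TSV into a PathwayDB."""
    pdb = PathwayDB()
    for lineno, tokens in _data_lines(path):
        if len(tokens) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'pathway side node'")
        pdb.add(tokens[0], tokens[1], tokens[2])
    pdb.validate()
    return pdb


def read_orthologs(
    path: str | Path, left: Network | None = None, right: Network | None = None
) -> OrthologList:
    """Read a (nodeA, nodeB) TSV; unknown nodes are dropped with a warning."""
    orth = OrthologList()
    for lineno, tokens in _data_lines(path):
        if len(tokens) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'nodeA nodeB'")
        u, v = tokens[0], tokens[1]
        if (left is not None and u not in left) or (right is not None and v not in right):
            logger.warning("%s:%d: dropping ortholog pair (%r, %r)", path, lineno, u, v)
            continue
        orth.pairs.add((u, v))
    return orth
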