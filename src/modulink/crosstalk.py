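"""Pathway-crosstalk network construction, filtering, and module detection.

Two significantly enriched pathways "crosstalk" when they share at least two
candidate genes. Each retained pair is scored by the mean of the Jaccard
coefficient JC = |A∩B|/|A∪B| and the overlap coefficient
OC = |A∩B|/min(|A|,|B|); the network is then pruned to the top-scoring
fraction of edges and partitioned into modules by weighted greedy modularity
maximization. By default A and B are the pathways' *observed candidate* gene
sets (query ∩ pathway); pass ``membership`` to score full pathway
memberships instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from .enrichment import EnrichmentRecord
from .geneio import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkEdge",
    "CrosstalkNetwork",
    "jaccard",
    "overlap_coefficient",
    "crosstalk_score",
    "build_crosstalk_edges",
    "select_top_fraction",
    "detect_modules",
    "export_graph",
    "read_sif",
    "read_graphml",
]


def jaccard(A, B) -> float:
    """Jaccard coefficient |A∩B| / |A∪B| of two finite gene sets."""
    A, B = set(A), set(B)
    if not A and not B:
        raise ValidationError("Jaccard coefficient undefined for two empty sets")
    return len(A & B) / len(A | B)


def overlap_coefficient(A, B) -> float:
    """Overlap (Szymkiewicz-Simpson) coefficient |A∩B| / min(|A|, |B|)."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValidationError("overlap coefficient undefined for an empty set")
    return len(A & B) / min(len(A), len(B))


def crosstalk_score(A, B) -> float:
    """Mean of Jaccard and overlap coefficients."""
    return (jaccard(A, B) + overlap_coefficient(A, B)) / 2.0


@dataclass(frozen=True)
class CrosstalkEdge:
    """An undirected crosstalk link between two pathways (a < b)."""

    pathway_a: str
    pathway_b: str
    shared: frozenset[str]
    jc: float
    oc: float
    score: float

    def __post_init__(self) -> None:
        if not self.pathway_a < self.pathway_b:
            raise ValidationError(
                f"edge endpoints must satisfy a < b: {self.pathway_a!r}, {self.pathway_b!r}"
            )
        if len(self.shared) < 2:
            raise ValidationError("crosstalk edges require >= 2 shared genes")
        if not 0.0 <= self.jc <= self.oc <= 1.0:
            raise ValidationError(f"need 0 <= jc <= oc <= 1, got jc={self.jc}, oc={self.oc}")
        if not math.isclose(self.score, (self.jc + self.oc) / 2.0, rel_tol=1e-12):
            raise ValidationError("score must be the mean of jc and oc")


@dataclass(frozen=True)
class CrosstalkNetwork:
    """Pathway nodes, scored crosstalk edges, and (optionally) module labels."""

    edges: tuple[CrosstalkEdge, ...]
    modules: dict[str, int] = field(default_factory=dict)
    bridges: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(self.edges))
        nodes = self.nodes
        for n in self.modules:
            if n not in nodes:
                raise ValidationError(f"module label for unknown node {n!r}")

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.pathway_a)
            out.add(e.pathway_b)
        return frozenset(out)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in sorted(self.nodes):
            g.add_node(n)
            if self.modules:
                g.nodes[n]["module"] = int(self.modules[n])
            if self.bridges:
                g.nodes[n]["bridge"] = bool(n in self.bridges)
        for e in self.edges:
            g.add_edge(
                e.pathway_a, e.pathway_b,
                jc=float(e.jc), oc=float(e.oc), score=float(e.score),
                weight=float(e.score), shared_count=int(len(e.shared)),
                shared_genes=";".join(sorted(e.shared)),
            )
        return g


def _edge_sort_key(e: CrosstalkEdge):
    return (-e.score, e.pathway_a, e.pathway_b)


def build_crosstalk_edges(
    records: list[EnrichmentRecord],
    min_shared: int = 2,
    membership: dict[str, frozenset[str]] | None = None,
) -> list[CrosstalkEdge]:
    """Enumerate scored crosstalk edges between significant pathways.

    Considers every unordered pair of significant pathways; pairs sharing
    fewer than ``min_shared`` genes are removed. Gene sets default to the
    observed candidate sets carried on the records; ``membership`` (pathway_id
    -> full gene set) switches to full-membership scoring. Output is sorted
    descending by score, ties broken by (pathway_a, pathway_b).
    """
    sig = [r for r in records if r.significant]
    if len(sig) < 2:
        raise ValidationError(f"need >= 2 significant pathways, have {len(sig)}")
    sets = {
        r.pathway_id: (membership[r.pathway_id] if membership else r.observed)
        for r in sig
    }
    ids = sorted(sets)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = frozenset(sets[a] & sets[b])
            if len(shared) < min_shared:
                continue
            jc, oc = jaccard(sets[a], sets[b]), overlap_coefficient(sets[a], sets[b])
            edges.append(CrosstalkEdge(a, b, shared, jc, oc, (jc + oc) / 2.0))
    edges.sort(key=_edge_sort_key)
    return edges


def select_top_fraction(edges: list[CrosstalkEdge], fraction: float) -> list[CrosstalkEdge]:
    """Keep the ceil(fraction * n) highest-scoring edges, retaining cutoff ties.

    Any edge whose score equals the cutoff score is kept, which makes the
    selection deterministic and independent of the input ordering of tied
    edges.
    """
    if not edges:
        raise ValidationError("cannot select from an empty edge list")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    ranked = sorted(edges, key=_edge_sort_key)
    k = math.ceil(fraction * len(ranked))
    cutoff = ranked[k - 1].score
    return [e for e in ranked if e.score >= cutoff]


def detect_modules(network: CrosstalkNetwork) -> CrosstalkNetwork:
    """Partition pathway nodes into modules by weighted greedy modularity.

    Edge weights are the crosstalk scores. Nodes with neighbors in two or
    more distinct modules are flagged as bridges (the connector role a single
    pathway can play between otherwise separate modules). Deterministic: the
    graph is built over sorted nodes and module labels are assigned in order
    of each community's smallest member.
    """
    if not network.edges:
        raise ValidationError("module detection requires at least one edge")
    g = network.to_networkx()
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    modules = {n: i for i, comm in enumerate(communities) for n in comm}
    bridges = frozenset(
        n for n in g.nodes
        if len({modules[nbr] for nbr in g.neighbors(n)}) >= 2
    )
    return replace(network, modules=modules, bridges=bridges)


def export_graph(network: CrosstalkNetwork, fmt: str, path: str | Path) -> Path:
    """Write the network as SIF (``a crosstalk b`` lines) or GraphML.

    GraphML carries jc/oc/score/shared_count edge attributes and the module
    label as a node attribute; scores round-trip losslessly to >= 5 decimals
    through :func:`read_graphml`.
    """
    path = Path(path)
    fmt_l = fmt.lower()
    if fmt_l == "sif":
        with path.open("w") as fh:
            for e in network.edges:
                fh.write(f"{e.pathway_a}\tcrosstalk\t{e.pathway_b}\n")
    elif fmt_l == "graphml":
        if not network.modules:
            logger.warning("exporting GraphML without module labels")
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValidationError(f"unknown export format {fmt!r} (use 'SIF' or 'GraphML')")
    return path


def read_sif(path: str | Path) -> list[tuple[str, str]]:
    """Read back a SIF export as a list of (a, b) pathway pairs."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        a, _rel, b = line.split("\t")
        pairs.append((a, b))
    return pairs


def read_graphml(path: str | Path) -> CrosstalkNetwork:
    """Read back a GraphML export into a :class:`CrosstalkNetwork`."""
    g = nx.read_graphml(path)
    edges = []
    for a, b, d in g.edges(data=True):
        a, b = sorted((a, b))
        shared = frozenset(d["shared_genes"].split(";"))
        edges.append(
            CrosstalkEdge(a, b, shared, float(d["jc"]), float(d["oc"]),
                          (float(d["jc"]) + float(d["oc"])) / 2.0)
        )
    edges.sort(key=_edge_sort_key)
    modules = {
        n: int(d["module"]) for n, d in g.nodes(data=True) if "module" in d
    }
    bridges = frozenset(n for n, d in g.nodes(data=True) if d.get("bridge"))
    return CrosstalkNetwork(tuple(edges), modules=modules, bridges=bridges)
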