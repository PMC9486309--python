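"""Interactome-based candidate-gene prioritization.

Given an undirected, unweighted interactome and a set of disease *seed*
genes, each gene ``v`` receives a seed-pair betweenness: the total number of
geodesics (hop-count shortest paths) between unordered pairs of seed genes
on which ``v`` lies as an interior node,

    B(v) = sum over seed pairs (s, t) of sigma_st(v),

with sigma_st(v) = sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t) and 0
otherwise (the standard geodesic-counting identity). All geodesics per pair
are counted; disconnected pairs contribute nothing; endpoints score 0 for
their own pairs but may score as interior nodes of other pairs, so seeds can
appear among the candidates.

Because a gene's betweenness partly reflects raw topology (cut vertices and
hubs score high for *any* seed placement), significance is assessed against
a permutation null: the same number of seeds is redrawn uniformly at random
R times and betweenness recomputed. Per gene,

    FDR_i = #(null betweenness > actual betweenness) / R          (strict >)

and genes are retained when betweenness_actual > b_min, FDR_i < fdr_max, and
the gene's hub statistic stays below hub_max (the hub-exclusion rule).

The hub statistic defaults to the gene's *mean null betweenness* — the
number of shortest paths through the gene expected under random seed
placement — because that is what distinguishes topological hubs (thousands
of random paths) from module-specific linkers (almost none). An alternative
statistic, the number of replicates with any nonzero null betweenness
(``positive_count``), is available but is strongly degree-confounded: on
graphs of this size most mid-degree nodes lie on *some* random-pair geodesic
in most replicates, so it rejects far more than true hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .geneio import CandidateTable, GeneSet, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "BetweennessRecord",
    "read_interactome",
    "write_interactome",
    "seed_pair_betweenness",
    "permutation_null",
    "permutation_fdr",
    "select_candidates",
    "annotate_candidates",
    "export_candidate_subnetwork",
]


@dataclass(frozen=True)
class Interactome:
    """An undirected simple graph over gene symbols (no loops, no multiedges)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("interactome must not contain self-loops")

    @classmethod
    def from_edges(cls, edges) -> "Interactome":
        g = nx.Graph()
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_interactome(path: str | Path) -> Interactome:
    """Read a two-column TSV edge list into an :class:`Interactome`.

    Symbols are normalized; self-loops and duplicate (including reversed)
    edges are dropped with logged counts. ``#`` comment lines are allowed.
    """
    g = nx.Graph()
    n_loops = n_dupes = 0
    n_lines = 0
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        u = normalize_symbol(fields[0], context=f"{path}:{lineno}")
        v = normalize_symbol(fields[1], context=f"{path}:{lineno}")
        n_lines += 1
        if u == v:
            n_loops += 1
            continue
        if g.has_edge(u, v):
            n_dupes += 1
            continue
        g.add_edge(u, v)
    if n_lines == 0:
        raise ValidationError(f"{path}: no edges found")
    if n_loops or n_dupes:
        logger.info("%s: dropped %d self-loop(s) and %d duplicate edge(s)",
                    path, n_loops, n_dupes)
    return Interactome(g)


def write_interactome(interactome: Interactome, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in interactome.graph.edges):
            fh.write(f"{u}\t{v}\n")
    return path


# ---------------------------------------------------------------------------
# Geodesic counting
# ---------------------------------------------------------------------------

class _IndexedGraph:
    """CSR adjacency over a fixed, sorted node order (built once per analysis)."""

    def __init__(self, interactome: Interactome):
        self.nodes: list[str] = sorted(interactome.graph.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.adj = nx.to_scipy_sparse_array(
            interactome.graph, nodelist=self.nodes, dtype=np.float64, format="csr"
        )

    def bfs_counts(self, source: int) -> tuple[np.ndarray, np.ndarray]:
        """Level-synchronous BFS returning (distance, geodesic count) per node.

        Unreachable nodes get distance -1 and count 0. Counts are float64;
        exact for counts below 2**53, far beyond anything arising here.
        """
        n = len(self.nodes)
        dist = np.full(n, -1, dtype=np.int32)
        sigma = np.zeros(n, dtype=np.float64)
        dist[source] = 0
        sigma[source] = 1.0
        frontier = np.zeros(n, dtype=np.float64)
        frontier[source] = 1.0
        d = 0
        while True:
            pushed = self.adj @ frontier
            newly = (dist < 0) & (pushed > 0)
            if not newly.any():
                return dist, sigma
            d += 1
            dist[newly] = d
            sigma[newly] = pushed[newly]
            frontier = np.zeros(n, dtype=np.float64)
            frontier[newly] = pushed[newly]

    def pair_betweenness(self, seed_indices: list[int]) -> np.ndarray:
        """Seed-pair interior geodesic counts for every node (float64 vector)."""
        n = len(self.nodes)
        m = len(seed_indices)
        dist = np.empty((m, n), dtype=np.int32)
        sigma = np.empty((m, n), dtype=np.float64)
        for row, s in enumerate(seed_indices):
            dist[row], sigma[row] = self.bfs_counts(s)
        betw = np.zeros(n, dtype=np.float64)
        for i in range(m):
            di, si = dist[i], sigma[i]
            for j in range(i + 1, m):
                dj, sj = dist[j], sigma[j]
                d_st = di[seed_indices[j]]
                if d_st < 0:
                    continue  # disconnected pair
                interior = (di >= 0) & (dj >= 0) & (di + dj == d_st)
                interior[seed_indices[i]] = False
                interior[seed_indices[j]] = False
                betw[interior] += si[interior] * sj[interior]
        return betw


def _present_seeds(indexed: _IndexedGraph, seeds: GeneSet) -> list[int]:
    present = sorted(seeds.genes & set(indexed.index))
    absent = sorted(seeds.genes - set(indexed.index))
    if absent:
        logger.warning("%d seed gene(s) absent from interactome: %s",
                       len(absent), ", ".join(absent[:10]))
    if len(present) < 2:
        raise ValidationError(
            f"need >= 2 seed genes present in the interactome, have {len(present)}"
        )
    return [indexed.index[s] for s in present]


def seed_pair_betweenness(interactome: Interactome, seeds: GeneSet) -> dict[str, int]:
    """Number of seed-pair geodesics through each gene as an interior node."""
    indexed = _IndexedGraph(interactome)
    betw = indexed.pair_betweenness(_present_seeds(indexed, seeds))
    return {g: int(round(b)) for g, b in zip(indexed.nodes, betw)}


def permutation_null(
    interactome: Interactome,
    n_seeds: int,
    n_perm: int = 100,
    rng_seed: int = 0,
    degree_weighted: bool = False,
) -> dict[str, np.ndarray]:
    """Null betweenness from random seed draws.

    Each of the ``n_perm`` replicates draws ``n_seeds`` nodes uniformly
    without replacement (or degree-weighted when ``degree_weighted``) and
    records every gene's seed-pair betweenness. Replicate r uses an
    independent stream derived from (rng_seed, r), so results are
    reproducible and independent of evaluation order.
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    indexed = _IndexedGraph(interactome)
    n = len(indexed.nodes)
    if n_seeds > n:
        raise ValidationError(f"n_seeds={n_seeds} exceeds node count {n}")
    p = None
    if degree_weighted:
        deg = np.asarray(indexed.adj.sum(axis=1)).ravel()
        p = deg / deg.sum()
    null = np.zeros((n_perm, n), dtype=np.int64)
    for r in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(r,)))
        picks = rng.choice(n, size=n_seeds, replace=False, p=p)
        null[r] = np.rint(indexed.pair_betweenness(sorted(int(i) for i in picks)))
    return {g: null[:, i].copy() for i, g in enumerate(indexed.nodes)}


@dataclass(frozen=True)
class BetweennessRecord:
    """One gene's actual betweenness, permutation null, and derived statistics."""

    gene: str
    betweenness_actual: int
    null_values: tuple[int, ...]
    fdr: float | None
    positive_perm_count: int
    selected: bool = False
    is_seed: bool = False

    @property
    def null_mean(self) -> float | None:
        """Mean null betweenness (expected random shortest paths through the gene)."""
        if not self.null_values:
            return None
        return float(np.mean(self.null_values))

    def __post_init__(self) -> None:
        if self.betweenness_actual < 0:
            raise ValidationError(f"{self.gene}: negative betweenness")
        if self.null_values:
            n_r = len(self.null_values)
            expect = sum(v > self.betweenness_actual for v in self.null_values) / n_r
            if self.fdr is None or abs(self.fdr - expect) > 1e-12:
                raise ValidationError(f"{self.gene}: fdr inconsistent with null values")
            if self.positive_perm_count != sum(v > 0 for v in self.null_values):
                raise ValidationError(f"{self.gene}: positive_perm_count inconsistent")


def permutation_fdr(
    actual: dict[str, int], null: dict[str, np.ndarray]
) -> list[BetweennessRecord]:
    """Combine actual and null betweenness into per-gene records.

    FDR_i = #(null > actual) / R with a strict inequality, so FDR lies on the
    grid {0, 1/R, ..., 1}. positive_perm_count counts replicates in which the
    gene had any null betweenness at all (the hub diagnostic).
    """
    if set(actual) != set(null):
        only_a = sorted(set(actual) - set(null))[:5]
        only_n = sorted(set(null) - set(actual))[:5]
        raise ValidationError(
            f"actual/null gene mismatch (actual-only: {only_a}, null-only: {only_n})"
        )
    records = []
    for gene in sorted(actual):
        nv = np.asarray(null[gene])
        records.append(
            BetweennessRecord(
                gene=gene,
                betweenness_actual=int(actual[gene]),
                null_values=tuple(int(v) for v in nv),
                fdr=float(np.mean(nv > actual[gene])),
                positive_perm_count=int(np.sum(nv > 0)),
            )
        )
    return records


def select_candidates(
    records: list[BetweennessRecord],
    b_min: int = 1000,
    fdr_max: float = 0.05,
    hub_max: float = 50,
    seeds: GeneSet | None = None,
    hub_statistic: str = "mean_null",
) -> CandidateTable:
    """Apply the selection rule: betweenness > b_min, FDR < fdr_max, hub stat < hub_max.

    All three comparisons are strict. ``hub_statistic`` is either
    ``"mean_null"`` (default: mean null betweenness, the expected number of
    random shortest paths through the gene) or ``"positive_count"`` (number
    of replicates with nonzero null betweenness). Records without a
    permutation null (``fdr is None``) are filtered on betweenness only,
    with a warning. Output is sorted descending by betweenness, with seed
    membership flagged.
    """
    if hub_statistic not in ("mean_null", "positive_count"):
        raise ValidationError(f"unknown hub_statistic {hub_statistic!r}")
    no_null = [r for r in records if r.fdr is None]
    if no_null:
        logger.warning("%d record(s) lack a permutation null; filtering on "
                       "betweenness only for those", len(no_null))
    kept = []
    for r in records:
        hub_stat = r.null_mean if hub_statistic == "mean_null" else r.positive_perm_count
        ok = r.betweenness_actual > b_min and (
            r.fdr is None or (r.fdr < fdr_max and hub_stat < hub_max)
        )
        if ok:
            kept.append(replace(r, selected=True,
                                is_seed=bool(seeds and r.gene in seeds)))
    kept.sort(key=lambda r: (-r.betweenness_actual, r.gene))
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in kept],
            "betweenness": [r.betweenness_actual for r in kept],
            "fdr": [r.fdr for r in kept],
            "null_mean": [r.null_mean for r in kept],
            "positive_perm_count": [
                r.positive_perm_count if r.null_values else None for r in kept
            ],
            "is_seed": [r.is_seed for r in kept],
        }
    )
    return CandidateTable(df)


def annotate_candidates(
    candidates: CandidateTable, seeds: GeneSet
) -> tuple[CandidateTable, int]:
    """Flag candidate genes that are themselves seeds; return the overlap count."""
    df = candidates.frame.copy()
    df["is_seed"] = df["gene"].isin(set(seeds.genes))
    overlap = int(df["is_seed"].sum())
    return CandidateTable(df), overlap


def export_candidate_subnetwork(
    interactome: Interactome,
    candidates: CandidateTable,
    seeds: GeneSet,
    path: str | Path,
) -> Path:
    """GraphML of the subgraph induced by candidates + present seeds."""
    keep = set(candidates.genes) | (seeds.genes & interactome.nodes)
    sub = interactome.graph.subgraph(sorted(keep)).copy()
    for n in sub.nodes:
        sub.nodes[n]["is_seed"] = bool(n in seeds)
        sub.nodes[n]["is_candidate"] = bool(n in candidates.genes)
    nx.write_graphml(sub, Path(path))
    return Path(path)
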