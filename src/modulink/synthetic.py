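"""Synthetic study generator: planted disease modules in scale-free graphs.

The generator emulates the three inputs the pipeline consumes — an
interactome, a curated seed-gene list, and a pathway annotation collection —
with known ground truth, so that recovery of planted signal can be measured.

Interactome
    A preferential-attachment (Barabasi-Albert) background graph; the
    heavy-tailed degree distribution is what makes the pipeline's
    hub-exclusion rule meaningful. An Erdos-Renyi mode exists for null
    experiments. A connected "linker" scaffold of background nodes is
    designated, and each seed is added as a *new* node wired only to
    ``linker_attach`` distinct linkers (plus, in diluted mode, a few random
    background nodes), so seed-to-seed geodesics are forced through linkers.
    Attachments are dealt round-robin over a shuffled linker cycle, which
    guarantees every linker is shared by at least two seeds and therefore
    carries at least one seed-pair geodesic (the planted truth).

Annotations
    ``n_pathways`` gene sets drawn from a gene universe. A chosen fraction is
    "enriched": those receive ``enrichment_boost`` forced seed genes (their
    remaining members are drawn from non-seed genes, so the excess over the
    hypergeometric expectation is of known size). Designated consecutive
    pathway pairs share ``overlap_rate`` forced genes so the crosstalk stage
    has signal; a disjoint mode partitions the universe instead.

All randomness flows from one master seed through named child streams, so
every artifact is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .geneio import AnnotationCollection, GeneSet, PathwayEntry, ValidationError, write_gmt
from .prioritize import Interactome, write_interactome

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "StudyBundle",
    "generate_interactome",
    "generate_annotations",
    "generate_study",
]

_STREAMS = {"graph": 1, "linkers": 2, "seeds": 3, "annotations": 4}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the desk-scale study conditions."""

    n_nodes: int = 2000
    attachment_m: int = 3
    n_seeds: int = 60
    n_linkers: int = 20
    linker_attach: int = 2
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (10, 40)
    enriched_fraction: float = 0.3
    enrichment_boost: int = 6
    overlap_rate: int = 3
    overlap_mode: str = "random"  # "random" | "disjoint"
    topology: str = "scale_free"  # "scale_free" | "erdos_renyi"
    dilution: int = 0  # extra random background attachments per seed
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.attachment_m < 1:
            raise ValidationError("attachment_m must be >= 1")
        if self.n_linkers > self.n_nodes:
            raise ValidationError("n_linkers exceeds n_nodes")
        if self.linker_attach > self.n_linkers:
            raise ValidationError("linker_attach exceeds n_linkers")
        if self.n_seeds < max(2, self.n_linkers):
            raise ValidationError(
                "need n_seeds >= max(2, n_linkers) so the seed cycle covers "
                "every linker (the planted-truth invariant)"
            )
        if self.n_linkers > 1 and self.linker_attach < 2:
            raise ValidationError("linker_attach must be >= 2 when n_linkers > 1")
        lo, hi = self.pathway_size_range
        if lo < 3 or hi < lo:
            raise ValidationError("pathway sizes must be >= 3 and lo <= hi")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValidationError("enriched_fraction must be in [0, 1]")
        if self.overlap_mode not in ("random", "disjoint"):
            raise ValidationError(f"unknown overlap_mode {self.overlap_mode!r}")
        if self.topology not in ("scale_free", "erdos_renyi"):
            raise ValidationError(f"unknown topology {self.topology!r}")

    def stream(self, name: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=(_STREAMS[name],))
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated study."""

    seeds: GeneSet
    linkers: GeneSet
    enriched_pathway_ids: frozenset[str]
    config: SyntheticConfig

    def __post_init__(self) -> None:
        if self.seeds.genes & self.linkers.genes:
            raise ValidationError("seeds and linkers must be disjoint")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seeds": sorted(self.seeds.genes),
                "linkers": sorted(self.linkers.genes),
                "enriched_pathway_ids": sorted(self.enriched_pathway_ids),
                "config": asdict(self.config),
            },
            indent=2,
        )


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def _background_graph(config: SyntheticConfig) -> nx.Graph:
    seed_int = int(config.stream("graph").integers(2**31))
    if config.topology == "scale_free":
        g = nx.barabasi_albert_graph(config.n_nodes, config.attachment_m, seed=seed_int)
    else:
        p = 2.0 * config.attachment_m / (config.n_nodes - 1)  # match BA edge density
        g = nx.gnp_random_graph(config.n_nodes, p, seed=seed_int)
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        for prev, comp in zip(comps, comps[1:]):  # stitch components deterministically
            g.add_edge(min(prev), min(comp))
    return nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes})


def generate_interactome(config: SyntheticConfig) -> tuple[Interactome, SyntheticTruth]:
    """Build the background graph and plant the seed/linker disease module."""
    g = _background_graph(config)
    background = sorted(g.nodes)

    # Linker choice: peripheral (lowest-degree) background nodes. A disease
    # module's hidden linkers are ordinary genes, not topological hubs;
    # picking hubs would make the planted signal indistinguishable from the
    # background betweenness the permutation null is designed to remove.
    rng_l = config.stream("linkers")
    degree = dict(g.degree())
    peripheral = sorted(background, key=lambda n: (degree[n], n))
    pool = peripheral[: max(4 * config.n_linkers, config.n_linkers)]
    picks = rng_l.choice(len(pool), size=config.n_linkers, replace=False)
    linkers = [pool[int(i)] for i in picks]

    # Seeds: new nodes attached only to linkers. The first n_linkers seeds
    # form a cycle over the linkers (seed i bridges linkers i and i+1 mod n),
    # which guarantees (a) the planted module is connected and (b) every
    # linker is shared by two seeds, hence lies on at least one length-2
    # seed-to-seed geodesic. Remaining seeds pick their linkers at random.
    rng_s = config.stream("seeds")
    order = [linkers[int(i)] for i in rng_s.permutation(config.n_linkers)]
    seeds = [f"S{i:03d}" for i in range(config.n_seeds)]
    nl = config.n_linkers
    for i, s in enumerate(seeds):
        if i < nl and nl > 1:
            wanted = {order[i % nl], order[(i + 1) % nl]}
            while len(wanted) < config.linker_attach:
                wanted.add(order[int(rng_s.integers(nl))])
        else:
            picks = rng_s.choice(nl, size=config.linker_attach, replace=False)
            wanted = {order[int(k)] for k in picks}
        for l in sorted(wanted):
            g.add_edge(s, l)
        if config.dilution:
            extra = rng_s.choice(len(background), size=config.dilution, replace=False)
            for k in extra:
                g.add_edge(s, background[int(k)])

    truth = SyntheticTruth(
        seeds=GeneSet("seeds", frozenset(seeds)),
        linkers=GeneSet("linkers", frozenset(linkers)),
        enriched_pathway_ids=frozenset(),
        config=config,
    )
    return Interactome(g), truth


def generate_annotations(
    config: SyntheticConfig,
    universe: GeneSet,
    seeds: GeneSet | None = None,
) -> tuple[AnnotationCollection, frozenset[str]]:
    """Draw pathway gene sets with controlled enrichment and pairwise overlap.

    Returns the collection and the ids of the planted-enriched pathways.
    """
    lo, hi = config.pathway_size_range
    if len(universe) < hi:
        raise ValidationError("universe smaller than the largest pathway size")
    n_enriched = int(round(config.enriched_fraction * config.n_pathways))
    if n_enriched and seeds is None:
        raise ValidationError("seeds required when enriched_fraction > 0")
    seed_pool = sorted(seeds.genes & universe.genes) if seeds else []
    nonseed_pool = sorted(universe.genes - (seeds.genes if seeds else set()))
    rng = config.stream("annotations")

    enriched_ids = frozenset(
        f"PW{int(i):03d}"
        for i in rng.choice(config.n_pathways, size=n_enriched, replace=False)
    )
    members: list[set[str]] = []
    planted: list[set[str]] = []  # boosted seed genes, protected from eviction
    disjoint_cursor = 0
    all_sorted = sorted(universe.genes)
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        pid = f"PW{i:03d}"
        if config.overlap_mode == "disjoint":
            chunk = all_sorted[disjoint_cursor:disjoint_cursor + size]
            if len(chunk) < size:
                raise ValidationError("universe too small for disjoint pathways")
            disjoint_cursor += size
            members.append(set(chunk))
            planted.append(set())
            continue
        chosen: set[str] = set()
        if pid in enriched_ids:
            boost = min(config.enrichment_boost, size, len(seed_pool))
            chosen |= {seed_pool[k] for k in rng.choice(len(seed_pool), size=boost,
                                                        replace=False)}
            pool = nonseed_pool  # keep the seed excess exactly `boost`
        else:
            pool = all_sorted
        need = size - len(chosen)
        chosen |= {pool[k] for k in rng.choice(len(pool), size=need, replace=False)}
        while len(chosen) < size:  # rare collision with the boosted seeds
            chosen.add(pool[int(rng.integers(len(pool)))])
        members.append(chosen)
        planted.append(set(chosen) & set(seed_pool) if pid in enriched_ids else set())

    if config.overlap_mode == "random" and config.overlap_rate > 0:
        # designated consecutive pairs (0,1), (2,3), ... share forced genes
        for i in range(0, config.n_pathways - 1, 2):
            donor = sorted(members[i])
            share = {donor[k] for k in rng.choice(len(donor),
                                                  size=min(config.overlap_rate, len(donor)),
                                                  replace=False)}
            recipient = members[i + 1]
            for g in sorted(share - recipient):
                victims = sorted(recipient - members[i] - planted[i + 1])
                if victims:
                    recipient.discard(victims[int(rng.integers(len(victims)))])
                recipient.add(g)

    entries = tuple(
        PathwayEntry(f"PW{i:03d}", f"synthetic pathway {i}",
                     GeneSet(f"PW{i:03d}", frozenset(m)), source="synthetic")
        for i, m in enumerate(members)
    )
    return AnnotationCollection(entries), enriched_ids


@dataclass(frozen=True)
class StudyBundle:
    """In-memory objects plus on-disk paths of one generated study."""

    interactome: Interactome
    annotations: AnnotationCollection
    truth: SyntheticTruth
    paths: dict[str, Path] = field(default_factory=dict)


def generate_study(config: SyntheticConfig, out_dir: str | Path | None = None) -> StudyBundle:
    """Generate a full study; optionally write the pipeline's input files.

    Writes ``interactome.tsv``, ``seeds.txt``, ``pathways.gmt``,
    ``truth.json`` and ``config.yaml`` under *out_dir* when given.
    """
    interactome, truth = generate_interactome(config)
    universe = GeneSet("universe", frozenset(interactome.nodes))
    annotations, enriched_ids = generate_annotations(config, universe, truth.seeds)
    truth = SyntheticTruth(truth.seeds, truth.linkers, enriched_ids, config)

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["interactome"] = write_interactome(interactome, out / "interactome.tsv")
        seeds_path = out / "seeds.txt"
        seeds_path.write_text("\n".join(sorted(truth.seeds.genes)) + "\n")
        paths["seeds"] = seeds_path
        paths["gmt"] = write_gmt(annotations, out / "pathways.gmt")
        truth_path = out / "truth.json"
        truth_path.write_text(truth.to_json() + "\n")
        paths["truth"] = truth_path
        cfg_path = out / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
        paths["config"] = cfg_path
    return StudyBundle(interactome, annotations, truth, paths)
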