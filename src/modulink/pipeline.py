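"""Pipeline orchestration: enrich -> crosstalk -> prioritize from one config.

One RunConfig record holds every threshold of the analysis chain with the
study defaults: alpha = 0.05 on the BH-adjusted p, min_observed = 2
candidate genes per tested pathway, min_shared = 2 shared genes per
crosstalk edge, top_fraction = 0.5 of edges retained, n_perm = 100
permutations, betweenness cutoff b_min = 1000, fdr_max = 0.05, and
hub_max = 50 positive-null replicates. Every rule is a count-changing
filter; the run report logs records-in/records-out at each one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version
from pathlib import Path

import yaml

from . import crosstalk as ct
from . import enrichment as en
from . import geneio, prioritize as pr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "audit_fixture_tables"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and offending input."""


@dataclass(frozen=True)
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    out_dir: str
    seeds_path: str | None = None
    gmt_paths: tuple[str, ...] = ()
    interactome_path: str | None = None
    candidate_table_path: str | None = None  # table-audit mode for prioritization
    background_path: str | None = None
    alpha: float = 0.05
    min_observed: int = 2
    require_raw_p: bool = False
    min_shared: int = 2
    top_fraction: float = 0.5
    b_min: int = 1000
    fdr_max: float = 0.05
    hub_max: float = 50
    hub_statistic: str = "mean_null"  # or "positive_count"
    n_perm: int = 100
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.alpha <= 1.0, "alpha in (0, 1]"),
            (self.min_observed >= 0, "min_observed >= 0"),
            (self.min_shared >= 0, "min_shared >= 0"),
            (0.0 < self.top_fraction <= 1.0, "top_fraction in (0, 1]"),
            (self.b_min >= 0, "b_min >= 0"),
            (0.0 <= self.fdr_max <= 1.0, "fdr_max in [0, 1]"),
            (self.hub_max >= 0, "hub_max >= 0"),
            (self.n_perm >= 0, "n_perm >= 0"),
        ]
        for ok, rule in checks:
            if not ok:
                raise geneio.ValidationError(f"RunConfig violates {rule}")
        if self.n_perm > 0 and self.interactome_path and self.rng_seed is None:
            raise geneio.ValidationError("rng_seed required whenever n_perm > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise geneio.ValidationError(f"{path}: config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise geneio.ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "gmt_paths" in raw:
            raw["gmt_paths"] = tuple(raw["gmt_paths"])
        return cls(**raw)


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise annotated
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; write outputs and a JSON run report.

    Stages run only when their inputs are configured: enrichment needs seeds
    and at least one GMT; crosstalk needs enrichment; prioritization needs
    either an interactome (full permutation analysis) or a pre-computed
    candidate table (audit mode, betweenness filter only).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "versions": {"modulink": version("modulink")},
        "rng_seed": config.rng_seed,
        "counts": {},
        "outputs": {},
    }
    counts = report["counts"]

    seeds = None
    if config.seeds_path:
        seeds = _stage("read_seeds", geneio.read_gene_list, config.seeds_path)
        counts["seed_genes"] = len(seeds)

    # --- enrichment (per collection; BH within each) ---
    all_records: list[en.EnrichmentRecord] = []
    if seeds and config.gmt_paths:
        background = (
            geneio.read_gene_list(config.background_path)
            if config.background_path else None
        )
        for gmt_path in config.gmt_paths:
            annotations = _stage("read_gmt", geneio.read_gmt, gmt_path)
            records = _stage(
                "enrich", en.enrich, seeds, annotations,
                background=background, alpha=config.alpha,
                min_observed=config.min_observed, require_raw_p=config.require_raw_p,
            )
            all_records.extend(records)
            counts.setdefault("pathways_in", 0)
            counts["pathways_in"] += len(annotations)
        counts["pathways_tested"] = len(all_records)
        counts["pathways_significant"] = sum(r.significant for r in all_records)
        p = en.write_enrichment_table(all_records, out / "enrichment.tsv")
        report["outputs"]["enrichment"] = str(p)

    # --- crosstalk ---
    if counts.get("pathways_significant", 0) >= 2:
        edges = _stage("build_crosstalk_edges", ct.build_crosstalk_edges,
                       all_records, min_shared=config.min_shared)
        counts["crosstalk_edges_all"] = len(edges)
        if edges:
            kept = _stage("select_top_fraction", ct.select_top_fraction,
                          edges, config.top_fraction)
            counts["crosstalk_edges_kept"] = len(kept)
            network = ct.detect_modules(ct.CrosstalkNetwork(tuple(kept)))
            counts["crosstalk_modules"] = len(set(network.modules.values()))
            _write_edges_tsv(kept, out / "crosstalk.tsv")
            ct.export_graph(network, "SIF", out / "crosstalk.sif")
            ct.export_graph(network, "GraphML", out / "crosstalk.graphml")
            report["outputs"]["crosstalk"] = str(out / "crosstalk.tsv")

    # --- prioritization ---
    if config.interactome_path and seeds:
        interactome = _stage("read_interactome", pr.read_interactome,
                             config.interactome_path)
        counts["interactome_nodes"] = interactome.n_nodes
        counts["interactome_edges"] = interactome.n_edges
        actual = _stage("seed_pair_betweenness", pr.seed_pair_betweenness,
                        interactome, seeds)
        if config.n_perm > 0:
            n_present = len(seeds.genes & interactome.nodes)
            null = _stage("permutation_null", pr.permutation_null, interactome,
                          n_present, n_perm=config.n_perm, rng_seed=config.rng_seed)
            records = pr.permutation_fdr(actual, null)
        else:
            logger.warning("n_perm=0: no permutation null; FDR column will be empty")
            records = [
                pr.BetweennessRecord(g, b, (), None, 0)
                for g, b in sorted(actual.items())
            ]
        counts["genes_scored"] = len(records)
        table = _stage("select_candidates", pr.select_candidates, records,
                       b_min=config.b_min, fdr_max=config.fdr_max,
                       hub_max=config.hub_max, seeds=seeds,
                       hub_statistic=config.hub_statistic)
        table, overlap = pr.annotate_candidates(table, seeds)
        counts["candidate_count"] = len(table)
        counts["seed_overlap"] = overlap
        geneio.write_candidate_table(table, out / "candidates.tsv")
        pr.export_candidate_subnetwork(interactome, table, seeds,
                                       out / "candidates.graphml")
        report["outputs"]["candidates"] = str(out / "candidates.tsv")
    elif config.candidate_table_path and seeds:
        table = _stage("read_candidate_table", geneio.read_candidate_table,
                       config.candidate_table_path)
        counts["candidates_in"] = len(table)
        kept = table.frame[table.frame["betweenness"] > config.b_min]
        table = geneio.CandidateTable(
            kept.sort_values(["betweenness", "gene"],
                             ascending=[False, True]).reset_index(drop=True)
        )
        table, overlap = pr.annotate_candidates(table, seeds)
        counts["candidate_count"] = len(table)
        counts["seed_overlap"] = overlap
        geneio.write_candidate_table(table, out / "candidates.tsv")
        report["outputs"]["candidates"] = str(out / "candidates.tsv")

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report["outputs"]["report"] = str(report_path)
    return report


def _write_edges_tsv(edges: list[ct.CrosstalkEdge], path: Path) -> Path:
    with path.open("w") as fh:
        fh.write("pathway_a\tpathway_b\tshared_count\tshared_genes\tjc\toc\tscore\n")
        for e in edges:
            fh.write(
                f"{e.pathway_a}\t{e.pathway_b}\t{len(e.shared)}\t"
                f"{';'.join(sorted(e.shared))}\t{e.jc:.5f}\t{e.oc:.5f}\t{e.score:.5f}\n"
            )
    return path


def audit_fixture_tables(b_min: int = 1000) -> dict[str, int | bool]:
    """Recompute the worked-example counts from the packaged fixtures alone.

    Returns the curated seed-set size, the candidate count after the
    betweenness filter, the candidate/seed overlap, and the smallest
    candidate betweenness.
    """
    seeds = geneio.load_amd_genes()
    table = geneio.load_candidate_table()
    kept = table.frame[table.frame["betweenness"] > b_min]
    overlap = sorted(set(kept["gene"]) & seeds.genes)
    return {
        "amdgset_size": len(seeds),
        "candidate_count_after_filter": int(len(kept)),
        "seed_overlap_count": len(overlap),
        "seed_overlap_genes": overlap,
        "min_candidate_betweenness": int(table.frame["betweenness"].min()),
    }
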