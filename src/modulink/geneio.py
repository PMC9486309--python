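"""Containers and I/O for gene sets, pathway annotations, and candidate tables.

Everything downstream works on plain HGNC-style symbols. Normalization is
deliberately minimal — uppercase and strip — because the packaged fixtures are
verbatim transcriptions of printed tables and must stay byte-comparable to
them. An optional user-supplied alias table can be applied before
normalization for inputs that use non-canonical symbols.

File formats:

* gene lists: one symbol per line, ``#`` comments allowed;
* annotation collections: GMT (tab-separated; id, description, members...);
* candidate tables: TSV with ``gene`` and ``betweenness`` columns.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "GeneSet",
    "PathwayEntry",
    "AnnotationCollection",
    "CandidateTable",
    "normalize_symbol",
    "read_alias_table",
    "read_gene_list",
    "read_gmt",
    "write_gmt",
    "read_candidate_table",
    "write_candidate_table",
    "load_amd_genes",
    "load_enriched_pathways",
    "load_candidate_table",
    "load_published_crosstalk",
]


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


def normalize_symbol(raw: str, *, context: str | None = None) -> str:
    """Canonicalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent. Raises :class:`ValidationError` on empty/whitespace-only
    input, naming the offending record via *context* when given.
    """
    sym = str(raw).strip() if raw is not None else ""
    if not sym:
        where = f" ({context})" if context else ""
        raise ValidationError(f"empty or whitespace-only gene symbol{where}")
    return sym.upper()


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (alias, symbol) TSV mapping, applied pre-normalization."""
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: alias table needs exactly 2 columns")
        mapping[fields[0].strip()] = fields[1].strip()
    return mapping


@dataclass(frozen=True)
class GeneSet:
    """A named, finite set of normalized gene symbols."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        for g in self.genes:
            if not g or g != g.strip() or g != g.upper():
                raise ValidationError(
                    f"gene set {self.name!r}: symbol {g!r} is not normalized"
                )

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[str],
                      alias: dict[str, str] | None = None) -> "GeneSet":
        """Build a set from raw symbols, aliasing (optional) then normalizing."""
        out = set()
        for raw in symbols:
            raw = alias.get(str(raw).strip(), raw) if alias else raw
            out.add(normalize_symbol(raw, context=f"gene set {name!r}"))
        return cls(name, frozenset(out))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, item: object) -> bool:
        return item in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))


@dataclass(frozen=True)
class PathwayEntry:
    """One annotation record: a pathway and its member gene set."""

    pathway_id: str
    display_name: str
    members: GeneSet
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValidationError("pathway_id must be non-empty")
        if len(self.members) == 0:
            raise ValidationError(f"pathway {self.pathway_id!r} has no members")


@dataclass(frozen=True)
class AnnotationCollection:
    """An ordered collection of pathways with unique ids."""

    entries: tuple[PathwayEntry, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        seen: set[str] = set()
        for e in self.entries:
            if e.pathway_id in seen:
                raise ValidationError(f"duplicate pathway_id {e.pathway_id!r}")
            seen.add(e.pathway_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PathwayEntry]:
        return iter(self.entries)

    def __getitem__(self, pathway_id: str) -> PathwayEntry:
        for e in self.entries:
            if e.pathway_id == pathway_id:
                return e
        raise KeyError(pathway_id)

    def ids(self) -> list[str]:
        return [e.pathway_id for e in self.entries]

    def universe(self) -> GeneSet:
        """Union of all member genes (the default enrichment background)."""
        genes: set[str] = set()
        for e in self.entries:
            genes |= e.members.genes
        return GeneSet("universe", frozenset(genes))


@dataclass(frozen=True)
class CandidateTable:
    """Ranked candidate genes with integer betweenness and optional flags.

    Backed by a DataFrame with at least ``gene`` and ``betweenness`` columns;
    extra boolean columns (``is_seed``, ``selected``, ...) ride along.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("gene", "betweenness"):
            if col not in df.columns:
                raise ValidationError(f"candidate table missing column {col!r}")
        if df["gene"].duplicated().any():
            dupes = sorted(df.loc[df["gene"].duplicated(), "gene"])
            raise ValidationError(f"duplicate candidate genes: {dupes}")
        b = df["betweenness"]
        if (b < 0).any() or not (b == b.astype(int)).all():
            raise ValidationError("betweenness must be non-negative integers")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame["gene"])


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, line) skipping blanks and '#' comments."""
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, line.rstrip("\n")


def read_gene_list(path: str | Path, name: str | None = None,
                   alias: dict[str, str] | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list into a :class:`GeneSet`.

    Duplicate lines (after normalization) are dropped with a logged count.
    A file with zero valid symbols is an error.
    """
    name = name or Path(path).stem
    symbols: set[str] = set()
    n_lines = 0
    for lineno, line in _data_lines(path):
        raw = line.strip()
        raw = alias.get(raw, raw) if alias else raw
        symbols.add(normalize_symbol(raw, context=f"{path}:{lineno}"))
        n_lines += 1
    if not symbols:
        raise ValidationError(f"{path}: no valid gene symbols found")
    if n_lines > len(symbols):
        logger.info("%s: dropped %d duplicate symbol line(s)", path, n_lines - len(symbols))
    return GeneSet(name, frozenset(symbols))


def read_gmt(path: str | Path, source: str | None = None) -> AnnotationCollection:
    """Read a GMT file (id, description, then member symbols; tab-separated)."""
    source = source or str(path)
    entries: list[PathwayEntry] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3"
            )
        pid, desc = fields[0].strip(), fields[1].strip()
        if pid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate pathway_id {pid!r}")
        seen.add(pid)
        members = GeneSet.from_iterable(pid, (f for f in fields[2:] if f.strip()))
        if len(members) == 0:
            raise ValidationError(f"{path}:{lineno}: pathway {pid!r} has no members")
        entries.append(PathwayEntry(pid, desc, members, source))
    return AnnotationCollection(tuple(entries))


def write_gmt(collection: AnnotationCollection, path: str | Path) -> Path:
    """Write a collection as GMT; inverse of :func:`read_gmt` up to member order."""
    path = Path(path)
    with path.open("w") as fh:
        for e in collection:
            fh.write("\t".join([e.pathway_id, e.display_name, *sorted(e.members)]) + "\n")
    return path


def read_candidate_table(path: str | Path) -> CandidateTable:
    """Read a (gene, betweenness, flags...) TSV into a :class:`CandidateTable`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene" not in df.columns or "betweenness" not in df.columns:
        raise ValidationError(f"{path}: expected 'gene' and 'betweenness' columns")
    df["gene"] = [normalize_symbol(g, context=str(path)) for g in df["gene"]]
    df["betweenness"] = df["betweenness"].astype(int)
    return CandidateTable(df)


def write_candidate_table(table: CandidateTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Packaged fixtures (transcriptions of the source study's printed tables)
# ---------------------------------------------------------------------------

def _fixture(name: str) -> Path:
    return Path(resources.files("modulink").joinpath("data", name))  # type: ignore[arg-type]


def load_amd_genes() -> GeneSet:
    """The 176-gene curated AMD-associated seed set (AMDgset)."""
    return read_gene_list(_fixture("amd_seed_genes.txt"), name="AMDgset")


def load_enriched_pathways() -> AnnotationCollection:
    """The 24 printed enriched pathways with their candidate-gene members."""
    return read_gmt(_fixture("enriched_pathways.gmt"), source="fixture")


def load_candidate_table() -> CandidateTable:
    """The 42 shortest-path candidate genes with printed betweenness values."""
    return read_candidate_table(_fixture("candidate_betweenness.tsv"))


def load_published_crosstalk() -> pd.DataFrame:
    """Published crosstalk scores (non-authoritative; transcription is unreliable)."""
    return pd.read_csv(_fixture("published_crosstalk_scores.tsv"), sep="\t", comment="#")
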