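"""Over-representation analysis (ORA) with Benjamini-Hochberg correction.

The test statistic is the hypergeometric upper tail P(X >= k) for an overlap
of k query genes with a pathway of K genes, drawing n query genes from a
background universe of N genes — identical to a one-sided Fisher exact test
on the 2x2 overlap table. Over-representation is the only direction tested.

Pathways with fewer than ``min_observed`` query genes are dropped *before*
BH correction, and BH is computed within one annotation collection at a time
(not pooled across collections).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from statsmodels.stats.multitest import multipletests

from .geneio import AnnotationCollection, GeneSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's over-representation result."""

    pathway_id: str
    display_name: str
    observed: frozenset[str]
    observed_count: int
    p_raw: float
    p_bh: float
    significant: bool
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= self.p_bh <= 1.0:
            raise ValidationError(
                f"{self.pathway_id}: need 0 <= p_raw <= p_bh <= 1, "
                f"got p_raw={self.p_raw}, p_bh={self.p_bh}"
            )
        if self.observed_count != len(self.observed):
            raise ValidationError(f"{self.pathway_id}: observed_count mismatch")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact hypergeometric upper-tail probability P(X >= k).

    X counts the overlap when n items are drawn without replacement from a
    universe of N items of which K are marked. Computed with exact integer
    combinatorics (no floating-point cancellation), then rounded once to the
    nearest float.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValidationError(f"inconsistent counts: K={K}, n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValidationError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return float(Fraction(num, math.comb(N, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i}(p_(j) * m / j) clipped at 1, over the ascending
    order statistics of the m input p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: GeneSet,
    annotations: AnnotationCollection,
    background: GeneSet | None = None,
    alpha: float = 0.05,
    min_observed: int = 2,
    require_raw_p: bool = False,
) -> list[EnrichmentRecord]:
    """Test each pathway for over-representation of the query gene set.

    Parameters
    ----------
    query : the candidate/disease gene set.
    annotations : pathway collection to test against.
    background : gene universe; defaults to the union of all annotation
        members. Query genes outside the background are dropped and logged.
    alpha : significance level applied to the BH-adjusted p.
    min_observed : pathways sharing fewer query genes than this are not
        tested (and do not enter the BH family).
    require_raw_p : if True, significance additionally requires p_raw < alpha.

    Returns records sorted ascending by p_raw, ties broken by pathway_id.
    """
    if len(annotations) == 0:
        raise ValidationError("empty annotation collection")
    bg = (background or annotations.universe()).genes
    q = query.genes & bg
    dropped = len(query.genes) - len(q)
    if dropped:
        logger.info("enrich: dropped %d query gene(s) absent from background", dropped)
    if not q:
        raise ValidationError("query and background share no genes")

    N, n = len(bg), len(q)
    rows = []
    for entry in annotations:
        members = entry.members.genes & bg
        observed = frozenset(q & members)
        if len(observed) < min_observed:
            continue
        p = hypergeom_upper_tail(len(observed), len(members), n, N)
        rows.append((entry, observed, p))

    p_bh = bh_adjust([p for _, _, p in rows])
    records = [
        EnrichmentRecord(
            pathway_id=entry.pathway_id,
            display_name=entry.display_name,
            observed=observed,
            observed_count=len(observed),
            p_raw=p,
            p_bh=float(q_),
            significant=bool(q_ < alpha and (p < alpha or not require_raw_p)),
            alpha=alpha,
        )
        for (entry, observed, p), q_ in zip(rows, p_bh)
    ]
    records.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return records


def write_enrichment_table(records: list[EnrichmentRecord], path: str | Path) -> Path:
    """Write enrichment records as a TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("pathway_id\tname\tobserved_count\tobserved_genes\tp_raw\tp_bh\tsignificant\n")
        for r in records:
            fh.write(
                f"{r.pathway_id}\t{r.display_name}\t{r.observed_count}\t"
                f"{';'.join(sorted(r.observed))}\t{r.p_raw:.6g}\t{r.p_bh:.6g}\t"
                f"{r.significant}\n"
            )
    return path
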