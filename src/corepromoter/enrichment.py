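"""Hypergeometric gene-set enrichment and a term-similarity network.

A term is significant when its raw upper-tail hypergeometric p is below the
cutoff (default 0.05) *and* the query/term overlap is at least 3 genes; no
multiple-testing correction is applied by default (a BH option exists).
Significant terms are linked into a network by member-set similarity
(Jaccard by default, Cohen's kappa optionally) above a cutoff (default 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from .expression import bh_adjust

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "term_similarity_network",
]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.term_id}: empty gene set")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    significant: bool
    overlap_genes: Tuple[str, ...] = ()


def read_gmt(path) -> List[GeneSet]:
    """Standard GMT: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


def hypergeom_pvalue(
    overlap: int, universe_size: int, set_size: int, query_size: int
) -> float:
    """Upper-tail ``P(X >= overlap)`` for a hypergeometric draw of
    *query_size* genes from a universe with *set_size* successes."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def hypergeom_enrich(
    query_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    p_cutoff: float = 0.05,
    min_overlap: int = 3,
    bh_correct: bool = False,
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of *query_genes* in each set.

    Each term is intersected with the universe before testing; the p-value is
    ``P(X >= overlap)`` for a hypergeometric draw of ``|query|`` genes from a
    universe containing ``|term ∩ universe|`` successes.  Results are sorted
    by p.  ``bh_correct=True`` applies the significance rule to BH-adjusted
    p-values instead of raw ones.
    """
    universe_set = set(universe)
    query = set(query_genes) & universe_set
    if not universe_set or not query:
        raise ValueError("universe and query must be non-empty (query ⊆ universe)")

    results = []
    for gs in gene_sets:
        members = gs.members & universe_set
        if not members:
            continue
        overlap_genes = tuple(sorted(query & members))
        k = len(overlap_genes)
        p = hypergeom_pvalue(k, len(universe_set), len(members), len(query))
        results.append(
            EnrichmentResult(
                term_id=gs.term_id,
                term_name=gs.term_name,
                overlap=k,
                set_size=len(members),
                query_size=len(query),
                universe_size=len(universe_set),
                p_value=p,
                significant=False,
                overlap_genes=overlap_genes,
            )
        )
    ps = [r.p_value for r in results]
    effective = bh_adjust(ps) if (bh_correct and ps) else ps
    for r, pe in zip(results, effective):
        r.significant = bool(pe < p_cutoff and r.overlap >= min_overlap)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def _jaccard(a: Set[str], b: Set[str]) -> float:
    u = a | b
    return len(a & b) / len(u) if u else 0.0


def _kappa(a: Set[str], b: Set[str], universe_size: int) -> float:
    """Cohen's kappa of term membership over the universe."""
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = universe_size - n11 - n10 - n01
    n = universe_size
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    return (po - pe) / (1 - pe) if pe != 1 else 0.0


def term_similarity_network(
    significant: Sequence[EnrichmentResult],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    cutoff: float = 0.3,
    metric: str = "jaccard",
) -> List[Tuple[str, str, float]]:
    """Edges (term_i, term_j, score) between significant terms whose
    member-set similarity (restricted to the universe) exceeds the cutoff.

    The network is symmetric and self-loop-free; each unordered pair appears
    once, ordered by term id.
    """
    if len(significant) < 2:
        raise ValueError("need at least two significant terms")
    if metric not in ("jaccard", "kappa"):
        raise ValueError("metric must be 'jaccard' or 'kappa'")
    universe_set = set(universe)
    members = {
        gs.term_id: gs.members & universe_set
        for gs in gene_sets
    }
    terms = sorted({r.term_id for r in significant if r.significant or True})
    edges = []
    for i, ti in enumerate(terms):
        for tj in terms[i + 1 :]:
            if metric == "jaccard":
                score = _jaccard(members[ti], members[tj])
            else:
                score = _kappa(members[ti], members[tj], len(universe_set))
            if score > cutoff:
                edges.append((ti, tj, score))
    return edges


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "significant": r.significant,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in results
        ]
    )
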