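"""Set-algebra comparison of two cohorts' mutation results.

Comparisons run at four levels — distinct variants, mutated genes, genes
with mutation-linked altered expression, and enriched functional terms —
always by exact identity of canonical keys (a variant is shared only when
chrom, position, ref and alt all agree after normalization; position-only
matching is deliberately rejected).  Shared percentages are rounded half-up
to one decimal, the convention used for figures like "13.6% of cohort A".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Set, Tuple

__all__ = ["VennResult", "compare_cohorts", "gene_union_overlap"]

LEVELS = ("variant", "gene", "de_gene", "go_term")


def _round1_half_up(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10


@dataclass
class VennResult:
    level: str
    var_class: str
    only_a: int
    only_b: int
    shared: int
    pct_of_a: float
    pct_of_b: float

    @property
    def size_a(self) -> int:
        return self.only_a + self.shared

    @property
    def size_b(self) -> int:
        return self.only_b + self.shared

    def to_dict(self) -> Dict[str, object]:
        return {
            "level": self.level,
            "class": self.var_class,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "shared": self.shared,
            "pct_of_a": self.pct_of_a,
            "pct_of_b": self.pct_of_b,
        }


def compare_cohorts(
    set_a: Iterable, set_b: Iterable, level: str = "variant", var_class: str = "somatic"
) -> VennResult:
    """Exact two-set overlap with percentages of each cohort's total.

    Elements must already be canonical keys (``VariantKey`` for the variant
    level, gene ids / term ids otherwise).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    a, b = set(set_a), set(set_b)
    _check_uniform(a | b)
    shared = a & b
    pct_a = _round1_half_up(100 * len(shared) / len(a)) if a else 0.0
    pct_b = _round1_half_up(100 * len(shared) / len(b)) if b else 0.0
    return VennResult(
        level=level,
        var_class=var_class,
        only_a=len(a - shared),
        only_b=len(b - shared),
        shared=len(shared),
        pct_of_a=pct_a,
        pct_of_b=pct_b,
    )


def _check_uniform(elements: Set) -> None:
    kinds = {type(e).__name__ for e in elements}
    if len(kinds) > 1:
        raise ValueError(
            f"mixed element types {sorted(kinds)}: comparing sets at different levels"
        )


def gene_union_overlap(
    somatic_genes: Iterable[str],
    germline_genes: Iterable[str],
    genome_gene_total: int = 20000,
) -> Tuple[int, int, float]:
    """Genes carrying both mutation classes, the union size, and the union
    as a half-up one-decimal percentage of the genome gene total."""
    s, g = set(somatic_genes), set(germline_genes)
    shared = len(s & g)
    union = len(s | g)
    fraction = _round1_half_up(100 * union / genome_gene_total)
    return shared, union, fraction
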