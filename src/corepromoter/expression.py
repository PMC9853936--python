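"""Linking promoter mutations to differential gene expression.

The differential-expression (DE) table is an upstream input (e.g. a DESeq2
results export): one row per gene with a fold change and a
Benjamini-Hochberg adjusted p-value.  A gene counts as *altered* when
``padj < 0.05`` and the fold-change magnitude is ``>= 1.5`` (both
configurable); direction is kept as an explicit up/down flag because a
printed "+22.4 / -46.4" display cannot be a ratio and a sign at once.
Association between mutation and altered expression is tested with a
two-sided Fisher exact test on the mutated x altered 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DERecord",
    "LinkSummary",
    "read_de_table",
    "classify_de",
    "link_mutations_to_de",
    "stemness_correlation",
    "bh_adjust",
]


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result.

    ``fold_change`` is the magnitude (>= 0); ``direction`` is 'up' or 'down'.
    """

    gene_id: str
    fold_change: float
    direction: str
    padj: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.fold_change < 0:
            raise ValueError("fold_change is a magnitude, must be >= 0")
        if math.isnan(self.padj) or not 0 <= self.padj <= 1:
            raise ValueError(f"{self.gene_id}: padj must be in [0, 1]")

    @classmethod
    def from_log2fc(cls, gene_id: str, log2fc: float, padj: float) -> "DERecord":
        return cls(
            gene_id=gene_id,
            fold_change=2 ** abs(log2fc),
            direction="up" if log2fc >= 0 else "down",
            padj=padj,
        )


def classify_de(
    record: DERecord, fc_threshold: float = 1.5, padj_threshold: float = 0.05
) -> str:
    """'increased', 'decreased' or 'unchanged' under the significance rule."""
    if record.padj < padj_threshold and record.fold_change >= fc_threshold:
        return "increased" if record.direction == "up" else "decreased"
    return "unchanged"


@dataclass
class LinkSummary:
    n_mutated_genes: int
    n_altered: int
    n_increased: int
    n_decreased: int
    pct_altered: float
    contingency: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    fisher_p: float
    missing_genes: List[str]

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_mutated_genes": self.n_mutated_genes,
            "n_altered": self.n_altered,
            "n_increased": self.n_increased,
            "n_decreased": self.n_decreased,
            "pct_altered": self.pct_altered,
            "contingency": [list(r) for r in self.contingency],
            "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
            "missing_genes": list(self.missing_genes),
        }


def _round1_half_up(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10


def fisher_exact_2x2(table) -> Tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table; returns the *sample*
    odds ratio (ad/bc, inf when bc is 0) and the p-value.

    Shared by :func:`link_mutations_to_de`; the p sums all tables with the
    observed margins whose probability does not exceed the observed one.
    """
    t = np.asarray(table, dtype=int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    (a, b), (c, d) = t
    odds = (a * d) / (b * c) if b * c else float("inf")
    return float(odds), float(p)


def link_mutations_to_de(
    mutated_genes: Iterable[str],
    de_table: Sequence[DERecord],
    fc_threshold: float = 1.5,
    padj_threshold: float = 0.05,
) -> LinkSummary:
    """Cross mutated genes with the DE table and test the association.

    Gene identifiers are matched exactly after case-folding.  Mutated genes
    absent from the DE table are excluded from the contingency and reported
    in ``missing_genes``.  The 2x2 table is built over all genes in the DE
    table; the sample odds ratio and a two-sided Fisher exact p are returned.
    """
    de_by_gene = {r.gene_id.casefold(): r for r in de_table}
    mutated = {g.casefold(): g for g in mutated_genes}
    if not set(mutated) & set(de_by_gene):
        raise ValueError("no mutated gene found in the DE table")

    missing = sorted(g for cf, g in mutated.items() if cf not in de_by_gene)
    inc = dec = 0
    table = np.zeros((2, 2), dtype=int)  # rows: mutated yes/no; cols: altered yes/no
    for cf, rec in de_by_gene.items():
        call = classify_de(rec, fc_threshold, padj_threshold)
        altered = call != "unchanged"
        is_mut = cf in mutated
        table[0 if is_mut else 1][0 if altered else 1] += 1
        if is_mut and call == "increased":
            inc += 1
        elif is_mut and call == "decreased":
            dec += 1

    sample_or, p = fisher_exact_2x2(table)
    a, b = table[0]
    c, d = table[1]
    n_mut_in_de = a + b
    n_alt = inc + dec
    return LinkSummary(
        n_mutated_genes=n_mut_in_de,
        n_altered=n_alt,
        n_increased=inc,
        n_decreased=dec,
        pct_altered=_round1_half_up(100 * n_alt / n_mut_in_de) if n_mut_in_de else 0.0,
        contingency=((a, b), (c, d)),
        odds_ratio=float(sample_or),
        fisher_p=float(p),
        missing_genes=missing,
    )


def stemness_correlation(
    expression: Sequence[float], stemness_index: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation between log2(x + 0.001)-transformed expression and
    a per-sample stemness index; two-sided p from the t-distribution."""
    x = np.asarray(expression, dtype=float)
    y = np.asarray(stemness_index, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D vectors of length >= 3")
    xt = np.log2(x + 0.001)
    if np.allclose(xt.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("zero variance after transform; correlation undefined")
    r, p = stats.pearsonr(xt, y)
    return float(r), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in raw-p rank)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def read_de_table(path) -> List[DERecord]:
    """Read a DE results TSV: ``gene_id`` plus either ``log2fc`` or
    ``fold_change``+``direction``, and ``padj``."""
    df = pd.read_csv(path, sep="\t")
    if "padj" not in df.columns or "gene_id" not in df.columns:
        raise ValueError("DE table needs gene_id and padj columns")
    out = []
    for row in df.itertuples(index=False):
        if pd.isna(row.padj):
            continue  # DESeq2-style filtered gene: no test performed
        if hasattr(row, "log2fc"):
            out.append(DERecord.from_log2fc(str(row.gene_id), float(row.log2fc), float(row.padj)))
        else:
            out.append(
                DERecord(str(row.gene_id), float(row.fold_change),
                         str(row.direction), float(row.padj))
            )
    return out


def volcano_data(de_table: Sequence[DERecord]) -> pd.DataFrame:
    """Plot-ready table: signed log2 fold on x, -log10 padj on y."""
    rows = []
    for r in de_table:
        sign = 1 if r.direction == "up" else -1
        log2fc = sign * math.log2(r.fold_change) if r.fold_change > 0 else 0.0
        y = -math.log10(r.padj) if r.padj > 0 else math.inf
        rows.append({"gene_id": r.gene_id, "log2fc": log2fc, "neg_log10_padj": y})
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "neg_log10_padj"])
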