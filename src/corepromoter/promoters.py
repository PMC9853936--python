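"""Core-promoter regions anchored at annotated transcription start sites.

Coordinate convention
---------------------
All TSS-relative positions are signed integers with **no position 0**:
``+1`` is the TSS base itself, ``-1`` the base immediately upstream
(5' of the TSS on the gene's strand), ``+2`` the base after the TSS, and
so on.  A window of ``upstream_bp`` and ``downstream_bp`` therefore spans
relative positions ``-upstream_bp .. -1, +1 .. +downstream_bp + 1`` — exactly
``upstream_bp + downstream_bp + 1`` bases.  Genomic coordinates are 1-based
(VCF-style); BED output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional

import pandas as pd

__all__ = [
    "PromoterRegion",
    "PromoterSet",
    "OutOfWindowError",
    "read_promoter_table",
    "promoters_to_bed",
]

DEFAULT_UPSTREAM = 100
DEFAULT_DOWNSTREAM = 100


class OutOfWindowError(ValueError):
    """A genomic position does not fall inside a promoter window."""


def _rel_to_linear(rel: int) -> int:
    """Map a no-zero relative coordinate onto a gapless integer axis.

    -1 -> -1, +1 -> 0, +2 -> 1 ...  Useful for interval arithmetic where the
    missing 0 would otherwise inflate lengths.
    """
    if rel == 0:
        raise ValueError("relative position 0 does not exist in this scheme")
    return rel if rel < 0 else rel - 1


def _linear_to_rel(lin: int) -> int:
    return lin if lin < 0 else lin + 1


@dataclass(frozen=True)
class PromoterRegion:
    """A gene's core-promoter window centred on its TSS.

    Parameters
    ----------
    gene_id : str
        Gene identifier (unique within a :class:`PromoterSet`).
    chrom : str
        Chromosome name.
    tss : int
        1-based genomic position of the TSS base.
    strand : str
        ``'+'`` or ``'-'``.
    upstream_bp, downstream_bp : int
        Window extent on the gene's own strand.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    upstream_bp: int = DEFAULT_UPSTREAM
    downstream_bp: int = DEFAULT_DOWNSTREAM

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")
        if self.tss < 1:
            raise ValueError("tss must be a positive 1-based coordinate")

    # -- genomic extent ----------------------------------------------------
    @property
    def genomic_start(self) -> int:
        """1-based inclusive start of the window on the reference."""
        if self.strand == "+":
            return self.tss - self.upstream_bp
        return self.tss - self.downstream_bp

    @property
    def genomic_end(self) -> int:
        """1-based inclusive end of the window on the reference."""
        if self.strand == "+":
            return self.tss + self.downstream_bp
        return self.tss + self.upstream_bp

    @property
    def width(self) -> int:
        return self.upstream_bp + self.downstream_bp + 1

    def contains(self, genomic_pos: int) -> bool:
        return self.genomic_start <= genomic_pos <= self.genomic_end

    # -- coordinate conversion --------------------------------------------
    def to_relative(self, genomic_pos: int) -> int:
        """Convert a genomic position to a signed TSS-relative position.

        On the + strand the TSS maps to +1 and ``tss - 1`` to -1; on the
        - strand the TSS maps to +1 and ``tss + 1`` to -1.  Raises
        :class:`OutOfWindowError` outside the window.
        """
        if not self.contains(genomic_pos):
            raise OutOfWindowError(
                f"position {self.chrom}:{genomic_pos} outside promoter window "
                f"of {self.gene_id} ({self.chrom}:{self.genomic_start}-"
                f"{self.genomic_end})"
            )
        offset = genomic_pos - self.tss if self.strand == "+" else self.tss - genomic_pos
        return _linear_to_rel(offset)

    def to_genomic(self, rel_pos: int) -> int:
        """Inverse of :meth:`to_relative`; exact round-trip for in-window positions."""
        offset = _rel_to_linear(rel_pos)
        pos = self.tss + offset if self.strand == "+" else self.tss - offset
        if not self.contains(pos):
            raise OutOfWindowError(
                f"relative position {rel_pos:+d} outside window of {self.gene_id}"
            )
        return pos

    @property
    def rel_min(self) -> int:
        """Most upstream relative position in the window (``-upstream_bp`` or +1)."""
        return -self.upstream_bp if self.upstream_bp > 0 else 1

    @property
    def rel_max(self) -> int:
        """Most downstream relative position (``+downstream_bp + 1``)."""
        return self.downstream_bp + 1

    def relative_positions(self) -> Iterator[int]:
        """All relative positions in the window, upstream to downstream."""
        for lin in range(_rel_to_linear(self.rel_min), self.downstream_bp + 1):
            yield _linear_to_rel(lin)


@dataclass
class PromoterSet:
    """A collection of promoter regions keyed by gene, plus the genome-wide
    gene total used as the denominator of genome-fraction statements."""

    regions: Dict[str, PromoterRegion] = field(default_factory=dict)
    genome_gene_total: int = 20000

    def add(self, region: PromoterRegion) -> None:
        if region.gene_id in self.regions:
            raise ValueError(f"duplicate gene_id {region.gene_id!r}")
        self.regions[region.gene_id] = region

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[PromoterRegion]:
        return iter(self.regions.values())

    def __getitem__(self, gene_id: str) -> PromoterRegion:
        return self.regions[gene_id]

    def regions_containing(self, chrom: str, pos: int) -> List[PromoterRegion]:
        """Every region whose window contains the position.

        Overlapping promoters are legitimate: a variant inside two windows is
        annotated once per gene.
        """
        return [
            r for r in self.regions.values() if r.chrom == chrom and r.contains(pos)
        ]


def read_promoter_table(path) -> PromoterSet:
    """Read a promoter definition TSV.

    Required columns: ``gene_id``, ``chrom``, ``tss`` (1-based), ``strand``;
    optional ``upstream_bp`` / ``downstream_bp`` per-gene overrides.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"promoter table missing columns: {sorted(missing)}")
    pset = PromoterSet()
    for row in df.itertuples(index=False):
        pset.add(
            PromoterRegion(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                tss=int(row.tss),
                strand=str(row.strand),
                upstream_bp=int(getattr(row, "upstream_bp", DEFAULT_UPSTREAM)),
                downstream_bp=int(getattr(row, "downstream_bp", DEFAULT_DOWNSTREAM)),
            )
        )
    return pset


def write_promoter_table(pset: PromoterSet, path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "tss": r.tss,
            "strand": r.strand,
            "upstream_bp": r.upstream_bp,
            "downstream_bp": r.downstream_bp,
        }
        for r in pset
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def promoters_to_bed(pset: PromoterSet, path=None) -> str:
    """Render the promoter set as BED6 (0-based half-open), sorted by
    chromosome then start.  Returns the text; writes it if *path* is given."""
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    recs = sorted(pset, key=lambda r: (r.chrom, r.genomic_start))
    for r in recs:
        lines.append(
            f"{r.chrom}\t{r.genomic_start - 1}\t{r.genomic_end}\t"
            f"{r.gene_id}\t0\t{r.strand}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
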