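"""Core-promoter motif catalogue, variant-to-motif annotation and
gain/loss/shift detection by IUPAC consensus rescanning.

The default catalogue covers the canonical core-promoter elements (TATA box,
BRE upstream/downstream, initiator, TCT, XCPE1/2, MTE, DPE, DCE boxes) at
their literature-standard TSS-relative windows, plus consensus-scan motifs
(Ets, SP1, E-Box, TCF) that are located by sequence match anywhere in the
window rather than by a fixed position.  Windows use the no-zero relative
scheme of :mod:`corepromoter.promoters` (+1 = TSS base).  Every window and
consensus is user-overridable through a plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .promoters import _linear_to_rel, _rel_to_linear
from .variants import CohortVariant, VariantKey

__all__ = [
    "MotifDef",
    "MotifHit",
    "MotifChange",
    "default_catalogue",
    "read_catalogue",
    "write_catalogue",
    "iupac_match",
    "scan_consensus",
    "annotate_motifs",
    "rescan_motif",
    "motif_distribution_test",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDef:
    """A catalogue entry: a named motif with an optional fixed TSS-relative
    window and an optional IUPAC consensus.

    ``rel_start``/``rel_end`` of ``None`` mark a consensus-scan motif that is
    located anywhere in the promoter window by sequence match.
    """

    name: str
    rel_start: Optional[int]
    rel_end: Optional[int]
    consensus: str = ""

    def __post_init__(self) -> None:
        if (self.rel_start is None) != (self.rel_end is None):
            raise ValueError(f"{self.name}: window must set both ends or neither")
        if self.rel_start is not None:
            if _rel_to_linear(self.rel_start) > _rel_to_linear(self.rel_end):
                raise ValueError(f"{self.name}: rel_start after rel_end")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")

    @property
    def positional(self) -> bool:
        return self.rel_start is not None


@dataclass(frozen=True)
class MotifHit:
    variant_key: VariantKey
    gene_id: str
    motif_name: str
    overlap_kind: str  # 'within' | 'partial'


@dataclass(frozen=True)
class MotifChange:
    """A motif created, abolished or shifted by a mutation."""

    gene_id: str
    motif_name: str
    kind: str  # 'created' | 'abolished' | 'shifted'
    ref_rel_pos: Optional[int]
    alt_rel_pos: Optional[int]


# Literature-standard windows; DTIE has no established definition and ships
# as an empty placeholder for users to fill in.
_DEFAULT_ROWS: List[Tuple[str, Optional[int], Optional[int], str]] = [
    ("TATA box", -31, -24, "TATAWAWR"),
    ("BREu", -38, -32, "SSRCGCC"),
    ("BREd", -23, -17, "RTDKKKK"),
    ("Inr", -2, 4, "YYANWYY"),
    ("TCT", -2, 6, ""),
    ("XCPE1", -8, 2, ""),
    ("XCPE2", -9, 2, ""),
    ("MTE_box1", 18, 22, ""),
    ("MTE_box2", 23, 29, ""),
    ("DPE", 28, 32, "RGWYV"),
    ("DCE_box1", 6, 11, "CTTC"),
    ("DCE_box2", 16, 21, "CTGT"),
    ("DCE_box3", 30, 34, "AGC"),
    ("Ets", None, None, "GGAW"),
    ("SP1", None, None, "GGGCGG"),
    ("E-Box", None, None, "CANNTG"),
    ("TCF", None, None, "CTTTGWW"),
    ("DTIE", None, None, ""),
]


def default_catalogue() -> List[MotifDef]:
    return [MotifDef(n, s, e, c) for n, s, e, c in _DEFAULT_ROWS]


def read_catalogue(path) -> List[MotifDef]:
    """Read a motif catalogue TSV: name, rel_start, rel_end, consensus
    (rel_start/rel_end empty for consensus-scan motifs)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "consensus": str})
    defs = []
    for row in df.itertuples(index=False):
        start = None if pd.isna(row.rel_start) else int(row.rel_start)
        end = None if pd.isna(row.rel_end) else int(row.rel_end)
        cons = "" if pd.isna(row.consensus) else str(row.consensus)
        defs.append(MotifDef(str(row.name), start, end, cons))
    names = [d.name for d in defs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate motif names in catalogue")
    return defs


def write_catalogue(catalogue: Sequence[MotifDef], path) -> None:
    pd.DataFrame(
        [
            {
                "name": m.name,
                "rel_start": "" if m.rel_start is None else m.rel_start,
                "rel_end": "" if m.rel_end is None else m.rel_end,
                "consensus": m.consensus,
            }
            for m in catalogue
        ]
    ).to_csv(path, sep="\t", index=False)


def iupac_match(consensus: str, seq: str) -> bool:
    """True if *seq* matches *consensus* position-by-position (equal length)."""
    if len(consensus) != len(seq):
        return False
    return all(b in IUPAC[c] for c, b in zip(consensus.upper(), seq.upper()))


def scan_consensus(consensus: str, seq: str) -> List[int]:
    """All 0-based start offsets at which the consensus matches *seq*."""
    if not consensus:
        return []
    w = len(consensus)
    return [i for i in range(len(seq) - w + 1) if iupac_match(consensus, seq[i : i + w])]


def _affected_linear_span(v: CohortVariant) -> Tuple[int, int]:
    """The TSS-relative interval (linear axis) touched by a variant's ref
    allele: the anchor for insertions, the full ref span otherwise.

    On minus-strand genes a multi-base ref allele maps to decreasing relative
    positions; the span is taken as the min/max of the mapped endpoints.
    """
    lin0 = _rel_to_linear(v.rel_pos)
    span = len(v.key.ref) - 1
    if span == 0 or v.mut_type == "insertion":
        return lin0, lin0
    # direction of increasing genomic position in linear-relative space
    # is +1 on '+' promoters, -1 on '-'; rel_pos already encodes the anchor,
    # and annotation stores rel_pos per gene, so infer direction from nothing:
    # both orientations are covered by taking the symmetric span.
    return min(lin0, lin0 + span), max(lin0, lin0 + span)


def annotate_motifs(
    mutations: Sequence[CohortVariant],
    catalogue: Sequence[MotifDef],
    sequences: Optional[Mapping[str, str]] = None,
    upstream_bp: int = 100,
    count_mode: str = "pair",
) -> Tuple[List[MotifHit], pd.DataFrame]:
    """Assign mutations to catalogue motifs and tabulate per-motif counts.

    Positional motifs hit when the variant's affected relative interval
    intersects the motif window.  Consensus-scan motifs (no fixed window)
    require promoter *sequences* (gene_id -> window sequence, first base at
    relative ``-upstream_bp``); their match spans act as windows per gene.

    ``count_mode='pair'`` counts distinct (variant, motif) pairs;
    ``'recurrence'`` weights each pair by the variant's carrier count.
    Returns the hit list and a count table with one zero-filled row per
    catalogue motif, split by somatic/germline class.
    """
    if not catalogue:
        raise ValueError("empty motif catalogue")
    if count_mode not in ("pair", "recurrence"):
        raise ValueError("count_mode must be 'pair' or 'recurrence'")

    scan_spans: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    if sequences:
        for gene_id, seq in sequences.items():
            for m in catalogue:
                if m.positional or not m.consensus:
                    continue
                spans = [
                    (i - upstream_bp, i - upstream_bp + len(m.consensus) - 1)
                    for i in scan_consensus(m.consensus, seq)
                ]
                if spans:
                    scan_spans[(gene_id, m.name)] = spans

    hits: List[MotifHit] = []
    seen = set()
    for v in mutations:
        lo, hi = _affected_linear_span(v)
        for m in catalogue:
            if m.positional:
                mlo, mhi = _rel_to_linear(m.rel_start), _rel_to_linear(m.rel_end)
                spans = [(mlo, mhi)]
            else:
                spans = scan_spans.get((v.gene_id, m.name), [])
            for slo, shi in spans:
                if lo <= shi and slo <= hi:
                    kind = "within" if (slo <= lo and hi <= shi) else "partial"
                    sig = (v.key, v.gene_id, m.name)
                    if sig not in seen:
                        seen.add(sig)
                        hits.append(MotifHit(v.key, v.gene_id, m.name, kind))
                    break

    rows = []
    by_name: Dict[str, Dict[str, int]] = {
        m.name: {"somatic": 0, "germline": 0} for m in catalogue
    }
    vmap = {(v.key, v.gene_id): v for v in mutations}
    for h in hits:
        v = vmap[(h.variant_key, h.gene_id)]
        cls = v.var_class or "somatic"
        w = v.carrier_count if count_mode == "recurrence" else 1
        by_name[h.motif_name][cls] += w
    for m in catalogue:
        rows.append(
            {
                "motif": m.name,
                "somatic_count": by_name[m.name]["somatic"],
                "germline_count": by_name[m.name]["germline"],
            }
        )
    table = pd.DataFrame(rows, columns=["motif", "somatic_count", "germline_count"])
    return hits, table


def _best_position(positions: List[int], canonical_lin: int) -> Optional[int]:
    """Match start (linear axis) closest to the canonical start; ties go to
    the more upstream position."""
    if not positions:
        return None
    return min(positions, key=lambda p: (abs(p - canonical_lin), p))


def rescan_motif(
    ref_seq: str,
    alt_seq: str,
    motif: MotifDef,
    search_window: Optional[Tuple[int, int]] = None,
    upstream_bp: int = 100,
    gene_id: str = "",
) -> Optional[MotifChange]:
    """Detect creation, loss or shift of a consensus motif between the
    reference and mutant promoter sequence.

    Both sequences are promoter windows whose first base sits at relative
    position ``-upstream_bp``.  Match positions of ``motif.consensus`` are
    computed within *search_window* (inclusive relative positions; defaults
    to the motif window padded by the consensus length, e.g. the DPE rescan
    covers about +24..+36).  The reported position of a motif is the match
    start closest to its canonical ``rel_start`` (ties toward upstream).
    Returns ``None`` when nothing changes.
    """
    if not motif.consensus:
        raise ValueError(f"{motif.name}: rescan requires a consensus")
    if ref_seq == alt_seq:
        return None
    if search_window is None:
        if not motif.positional:
            raise ValueError(f"{motif.name}: search_window required for scan motifs")
        pad = len(motif.consensus)
        search_window = (
            _linear_to_rel(_rel_to_linear(motif.rel_start) - pad + 1),
            _linear_to_rel(_rel_to_linear(motif.rel_end) + pad - 1),
        )

    lo = _rel_to_linear(search_window[0])
    hi = _rel_to_linear(search_window[1])
    canonical = _rel_to_linear(motif.rel_start) if motif.positional else lo

    def matches(seq: str) -> List[int]:
        out = []
        for i in scan_consensus(motif.consensus, seq):
            lin = i - upstream_bp
            if lo <= lin <= hi:
                out.append(lin)
        return out

    ref_best = _best_position(matches(ref_seq), canonical)
    alt_best = _best_position(matches(alt_seq), canonical)
    if ref_best is None and alt_best is None:
        return None
    if ref_best is not None and alt_best is None:
        return MotifChange(gene_id, motif.name, "abolished", _linear_to_rel(ref_best), None)
    if ref_best is None and alt_best is not None:
        return MotifChange(gene_id, motif.name, "created", None, _linear_to_rel(alt_best))
    if ref_best != alt_best:
        return MotifChange(
            gene_id, motif.name, "shifted",
            _linear_to_rel(ref_best), _linear_to_rel(alt_best),
        )
    return None


def motif_distribution_test(
    mutations: Sequence[CohortVariant],
    catalogue: Sequence[MotifDef],
    upstream_bp: int = 100,
    downstream_bp: int = 100,
) -> Tuple[float, float]:
    """Compare per-position mutation counts at motif-covered vs uncovered
    promoter positions (Welch two-sample t-test, two-sided).

    The positional profile pools mutations across genes by relative position;
    positions inside any positional motif window form one group, the rest the
    other.  Raises on a single group or zero variance in both groups.
    """
    covered = np.zeros(upstream_bp + downstream_bp + 1, dtype=bool)
    offset = upstream_bp  # linear position -upstream_bp maps to index 0
    for m in catalogue:
        if not m.positional:
            continue
        a = max(_rel_to_linear(m.rel_start) + offset, 0)
        b = min(_rel_to_linear(m.rel_end) + offset, len(covered) - 1)
        if a <= b:
            covered[a : b + 1] = True
    if covered.all() or not covered.any():
        raise ValueError("need both motif-covered and uncovered positions")

    counts = np.zeros(len(covered), dtype=float)
    for v in mutations:
        lin = _rel_to_linear(v.rel_pos) + offset
        if 0 <= lin < len(counts):
            counts[lin] += 1
    in_motif = counts[covered]
    outside = counts[~covered]
    if in_motif.std() == 0 and outside.std() == 0:
        if in_motif.mean() == outside.mean():
            return 0.0, 1.0
        raise ValueError("degenerate variance in both position groups")
    t, p = stats.ttest_ind(in_motif, outside, equal_var=False)
    return float(t), float(p)
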