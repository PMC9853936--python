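"""Germline/somatic classification and polymorphism filtering of promoter variants.

The filtering procedure mirrors a database-membership design: a cohort of
tumor exomes without matched normals, where a variant seen in any population
database (dbSNP, 1000 Genomes, ESP, ExAC, gnomAD, ClinVar) is treated as
germline and an unmatched variant as somatic.  Candidate mutations are then
cleaned in three ordered steps:

1. variants present in a population core-promoter polymorphism panel are
   eliminated (``eliminated_panel``);
2. variants carried by more than a class-specific fraction of the cohort
   (default 50% for somatic, 5% for germline, strict ``>`` on
   ``ceil(fraction x N)``) are eliminated as normal polymorphisms
   (``eliminated_polymorphic``);
3. variants private to a single case are eliminated
   (``eliminated_private``).

Everything that survives — necessarily recurrent, i.e. carried by >= 2
cases — is the retained mutation set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .promoters import PromoterSet

__all__ = [
    "DB_SOURCES",
    "VariantKey",
    "CohortVariant",
    "CohortSummary",
    "normalize_alleles",
    "classify_type",
    "classify_origin",
    "polymorphism_threshold",
    "run_filters",
    "summarize_cohort",
    "read_flag_table",
    "read_cohort_vcf",
    "write_retained_table",
    "read_retained_table",
]

#: Database sources whose membership defines a germline call.
DB_SOURCES = ("dbSNP", "KG1000", "ESP", "ExAC", "gnomAD", "ClinVar")

STATUSES = (
    "retained",
    "eliminated_panel",
    "eliminated_polymorphic",
    "eliminated_private",
)

_VALID = set("ACGT")


def normalize_alleles(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Canonicalize an allele pair: trim shared suffix, then shared prefix
    (keeping at least one base of each), adjusting the anchored position.

    Makes indel keys comparable across callers so that identity comparisons
    between cohorts and against flag tables are exact.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """A distinct variant: chromosome, 1-based anchored position, ref and alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - _VALID or set(self.alt) - _VALID:
            raise ValueError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        pos, ref, alt = normalize_alleles(pos, ref.upper(), alt.upper())
        return cls(chrom, pos, ref, alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def classify_type(key: VariantKey) -> str:
    """Substitution / insertion / deletion by allele-length comparison."""
    if len(key.ref) == len(key.alt):
        return "substitution"
    return "insertion" if len(key.alt) > len(key.ref) else "deletion"


@dataclass
class CohortVariant:
    """One distinct variant observed in a cohort, with carrier set,
    database-membership flags and (after filtering) a status."""

    key: VariantKey
    gene_id: str
    rel_pos: int
    carriers: FrozenSet[str]
    db_flags: Dict[str, bool]
    cosmic_flag: bool = False
    panel_flag: bool = False
    var_class: Optional[str] = None  # 'germline' | 'somatic'
    status: Optional[str] = None

    @property
    def mut_type(self) -> str:
        return classify_type(self.key)

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)


def classify_origin(variant: CohortVariant) -> str:
    """Germline iff the variant is present in any population database."""
    missing = [s for s in DB_SOURCES if s not in variant.db_flags]
    if missing:
        raise ValueError(
            f"{variant.key}: database flags must be explicit; missing {missing}"
        )
    return "germline" if any(variant.db_flags[s] for s in DB_SOURCES) else "somatic"


def polymorphism_threshold(n_samples: int, fraction: float) -> int:
    """Carrier-count cutoff ``ceil(fraction x n_samples)``.

    A variant is eliminated as a normal polymorphism when its carrier count
    strictly exceeds this value: for a 116-sample cohort the 50% rule gives
    58 (eliminate >58 carriers) and the 5% rule gives 6 (eliminate >6).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return math.ceil(fraction * n_samples)


def run_filters(
    variants: Iterable[CohortVariant],
    n_samples: int,
    somatic_fraction: float = 0.50,
    germline_fraction: float = 0.05,
) -> List[CohortVariant]:
    """Assign origin class and filter status to every variant.

    Order of application: panel -> cohort frequency -> private.  The four
    statuses partition the input; only ``retained`` variants (necessarily
    with >= 2 carriers) feed downstream analysis.
    """
    if n_samples < 2:
        raise ValueError("recurrence is undefined for cohorts of < 2 samples")
    thresholds = {
        "somatic": polymorphism_threshold(n_samples, somatic_fraction),
        "germline": polymorphism_threshold(n_samples, germline_fraction),
    }
    out: List[CohortVariant] = []
    for v in variants:
        var_class = classify_origin(v)
        if v.panel_flag:
            status = "eliminated_panel"
        elif v.carrier_count > thresholds[var_class]:
            status = "eliminated_polymorphic"
        elif v.carrier_count == 1:
            status = "eliminated_private"
        else:
            status = "retained"
        out.append(replace(v, var_class=var_class, status=status))
    return out


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Per-class cohort totals in the layout of a 'general features' table."""

    n_samples: int
    per_class: Dict[str, Dict[str, object]]

    def to_dict(self) -> Dict[str, object]:
        return {"n_samples": self.n_samples, **self.per_class}


def summarize_cohort(
    variants: Sequence[CohortVariant],
    n_samples: int,
    promoter_set: Optional[PromoterSet] = None,
) -> CohortSummary:
    """Summarize the *retained* mutations per origin class.

    ``total`` is the mutation load (sum of carrier counts over distinct
    retained variants); ``mean_per_case`` is total / n_samples rounded half
    away from zero; promoters are counted as distinct (chrom, tss, strand)
    windows so two gene ids sharing a TSS count one promoter.
    """
    retained = [v for v in variants if v.status == "retained"]
    per_class: Dict[str, Dict[str, object]] = {}
    for cls in ("somatic", "germline"):
        sub = [v for v in retained if v.var_class == cls]
        distinct_keys = {v.key for v in sub}
        total = sum(
            len(set.union(set(), *(set(v.carriers) for v in sub if v.key == k)))
            for k in distinct_keys
        )
        genes = {v.gene_id for v in sub}
        if promoter_set is not None:
            promoters = {
                (r.chrom, r.tss, r.strand)
                for v in sub
                if (r := promoter_set.regions.get(v.gene_id)) is not None
            }
        else:
            promoters = genes
        type_counts = {"substitution": 0, "insertion": 0, "deletion": 0}
        cosmic_absent = 0
        seen = set()
        for v in sub:
            if v.key in seen:
                continue
            seen.add(v.key)
            type_counts[v.mut_type] += 1
            if not v.cosmic_flag:
                cosmic_absent += 1
        per_class[cls] = {
            "total": total,
            "distinct": len(distinct_keys),
            "promoters_with_variants": len(promoters),
            "genes_affected": len(genes),
            "absent_in_cosmic": cosmic_absent,
            "type_counts": type_counts,
            "mean_per_case": _round_half_up(total / n_samples) if total else 0,
        }
    return CohortSummary(n_samples=n_samples, per_class=per_class)


# ---------------------------------------------------------------------------
# I/O


def read_flag_table(path) -> Dict[VariantKey, Dict[str, bool]]:
    """Read a sidecar membership-flag TSV keyed by variant.

    Columns: chrom, pos, ref, alt, then 0/1 flags for each database source,
    COSMIC and the polymorphism panel.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos", "ref", "alt", "COSMIC", "panel", *DB_SOURCES}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"flag table missing columns: {sorted(missing)}")
    table: Dict[VariantKey, Dict[str, bool]] = {}
    for row in df.itertuples(index=False):
        key = VariantKey.normalized(str(row.chrom), int(row.pos), row.ref, row.alt)
        flags = {s: bool(int(getattr(row, s))) for s in DB_SOURCES}
        flags["COSMIC"] = bool(int(row.COSMIC))
        flags["panel"] = bool(int(row.panel))
        table[key] = flags
    return table


def read_cohort_vcf(
    vcf_paths,
    promoter_set: PromoterSet,
    flag_table: Mapping[VariantKey, Mapping[str, bool]],
) -> List[CohortVariant]:
    """Ingest one multi-sample VCF (or several per-sample VCFs) restricted to
    promoter windows.

    Carriers are samples with at least one alternate allele; multi-allelic
    records are split per ALT; alleles are normalized before key lookup.  A
    variant inside two overlapping windows yields one record per gene.  A
    called variant absent from the flag table is an error (flags must be
    explicit, never defaulted).
    """
    from cyvcf2 import VCF

    if isinstance(vcf_paths, (str, bytes)) or hasattr(vcf_paths, "__fspath__"):
        vcf_paths = [vcf_paths]

    # carriers accumulated per (key, gene)
    acc: Dict[Tuple[VariantKey, str], set] = {}
    relpos: Dict[Tuple[VariantKey, str], int] = {}
    for path in vcf_paths:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        for rec in vcf:
            for ai, alt in enumerate(rec.ALT):
                if not alt or set(alt.upper()) - _VALID:
                    continue  # symbolic / spanning-deletion alleles ignored
                key = VariantKey.normalized(rec.CHROM, rec.POS, rec.REF, alt)
                regions = promoter_set.regions_containing(key.chrom, key.pos)
                if not regions:
                    continue
                carriers = {
                    samples[si]
                    for si, gt in enumerate(rec.genotypes)
                    if (ai + 1) in gt[:-1]
                }
                if not carriers:
                    continue
                for region in regions:
                    k = (key, region.gene_id)
                    acc.setdefault(k, set()).update(carriers)
                    relpos[k] = region.to_relative(key.pos)

    out: List[CohortVariant] = []
    for (key, gene_id), carriers in sorted(acc.items()):
        flags = flag_table.get(key)
        if flags is None:
            raise ValueError(f"flag table missing called variant {key}")
        out.append(
            CohortVariant(
                key=key,
                gene_id=gene_id,
                rel_pos=relpos[(key, gene_id)],
                carriers=frozenset(carriers),
                db_flags={s: bool(flags[s]) for s in DB_SOURCES},
                cosmic_flag=bool(flags.get("COSMIC", False)),
                panel_flag=bool(flags.get("panel", False)),
            )
        )
    return out


def write_retained_table(variants: Sequence[CohortVariant], path) -> pd.DataFrame:
    """Write the retained-mutation TSV (one row per distinct variant x gene)."""
    rows = [
        {
            "chrom": v.key.chrom,
            "pos": v.key.pos,
            "ref": v.key.ref,
            "alt": v.key.alt,
            "gene_id": v.gene_id,
            "rel_pos": v.rel_pos,
            "var_class": v.var_class,
            "mut_type": v.mut_type,
            "carrier_count": v.carrier_count,
            "carrier_ids": ";".join(sorted(v.carriers)),
        }
        for v in variants
        if v.status == "retained"
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "rel_pos",
            "var_class", "mut_type", "carrier_count", "carrier_ids",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_retained_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def cohort_variants_from_table(df: pd.DataFrame) -> List[CohortVariant]:
    """Rebuild retained :class:`CohortVariant` records from a retained-mutation
    TSV (database flags are reduced to the recorded class)."""
    out = []
    for row in df.itertuples(index=False):
        carriers = frozenset(str(row.carrier_ids).split(";")) if row.carrier_ids else frozenset()
        flags = {s: False for s in DB_SOURCES}
        if row.var_class == "germline":
            flags["dbSNP"] = True
        out.append(
            CohortVariant(
                key=VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt),
                gene_id=str(row.gene_id),
                rel_pos=int(row.rel_pos),
                carriers=carriers,
                db_flags=flags,
                var_class=str(row.var_class),
                status="retained",
            )
        )
    return out
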