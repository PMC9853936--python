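"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the shape of the study inputs: a promoter table over
a synthetic genome, one multi-sample VCF per cohort restricted to promoter
windows, a sidecar database/panel membership flag table, a coupled
differential-expression table and a small GMT of fabricated gene sets.  It
plants four kinds of variants with known expected filter status:

* *true* somatic/germline mutations — 2 <= carriers <= the class threshold,
  database flags consistent with the class (germline carries at least one
  database hit, somatic none), not in the polymorphism panel ->
  expected ``retained``;
* *panel* background — present in a population core-promoter panel ->
  ``eliminated_panel``;
* *polymorphic* background — carriers strictly above the class threshold ->
  ``eliminated_polymorphic``;
* *private* background — exactly one carrier -> ``eliminated_private``.

Everything is deterministic given the seed; per-component generators are
split from one root ``numpy.random.SeedSequence`` so partial re-runs are
reproducible.  No reads are simulated: variants are emitted directly as
VCF 4.2 records, since alignment and calling sit outside the procedure
under test.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .enrichment import GeneSet, write_gmt
from .expression import DERecord
from .motifs import IUPAC, MotifDef, default_catalogue
from .promoters import PromoterRegion, PromoterSet, write_promoter_table
from .variants import (
    DB_SOURCES,
    CohortVariant,
    VariantKey,
    polymorphism_threshold,
)

__all__ = ["SimConfig", "PlantedVariant", "SimResult", "simulate", "write_fixture_suite"]

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Study conditions for a synthetic two-cohort experiment.

    Defaults mirror the real study's shape: a 116-sample discovery cohort, a
    279-sample comparison cohort, +/-100 bp promoter windows, a transition
    probability of 0.45 (the discovery cohort's doubled Ts/Tv of about 1.6
    corresponds to a transition fraction near 0.44), motif-position
    enrichment of 2, roughly 15% cross-cohort sharing of planted mutations
    and a 25% chance that a mutated gene shows altered expression against a
    5% background alteration rate.
    """

    seed: int = 0
    n_samples_a: int = 116
    n_samples_b: int = 279
    n_genes: int = 60
    window: Tuple[int, int] = (100, 100)
    n_true_somatic: int = 40
    n_true_germline: int = 12
    transition_prob: float = 0.45
    motif_enrichment: float = 2.0
    n_polymorphic_background: int = 20
    n_private_background: int = 20
    shared_fraction: float = 0.15
    de_coupling: float = 0.25
    de_background_rate: float = 0.05
    de_fc_range: Tuple[float, float] = (1.5, 25.0)
    somatic_fraction: float = 0.50
    germline_fraction: float = 0.05
    # type mix for planted mutations, per class (sub, ins, del); the
    # defaults follow the observed shares in the two mutation classes
    somatic_type_probs: Tuple[float, float, float] = (0.57, 0.19, 0.24)
    germline_type_probs: Tuple[float, float, float] = (0.23, 0.39, 0.38)

    def validate(self) -> None:
        if any(
            x < 0
            for x in (
                self.n_true_somatic, self.n_true_germline, self.n_genes,
                self.n_polymorphic_background, self.n_private_background,
            )
        ):
            raise ValueError("counts must be non-negative")
        for p in (self.transition_prob, self.shared_fraction,
                  self.de_coupling, self.de_background_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.motif_enrichment < 1:
            raise ValueError("motif_enrichment must be >= 1")
        n_variants = (
            self.n_true_somatic + self.n_true_germline
            + self.n_polymorphic_background + self.n_private_background
        )
        if n_variants > 0 and self.n_genes == 0:
            raise ValueError("infeasible config: variants requested with zero genes")
        capacity = self.n_genes * (self.window[0] + self.window[1] + 1)
        if n_variants > capacity:
            raise ValueError(
                f"infeasible config: {n_variants} variants exceed "
                f"{capacity} available window positions"
            )


@dataclass
class PlantedVariant:
    """One simulated variant with its construction-time expected status."""

    key: VariantKey
    gene_id: str
    rel_pos: int
    carriers: FrozenSet[str]
    db_flags: Dict[str, bool]
    cosmic_flag: bool
    panel_flag: bool
    true_class: str  # 'germline' | 'somatic'
    expected_status: str

    def to_cohort_variant(self) -> CohortVariant:
        return CohortVariant(
            key=self.key,
            gene_id=self.gene_id,
            rel_pos=self.rel_pos,
            carriers=self.carriers,
            db_flags=dict(self.db_flags),
            cosmic_flag=self.cosmic_flag,
            panel_flag=self.panel_flag,
        )


def _concrete(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in consensus.upper())


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimResult:
    """In-memory simulation output; ``write`` materializes the file suite."""

    def __init__(
        self,
        config: SimConfig,
        promoter_set: PromoterSet,
        sequences: Dict[str, str],
        cohorts: Dict[str, List[PlantedVariant]],
        de_table: List[DERecord],
        gene_sets: List[GeneSet],
    ):
        self.config = config
        self.promoter_set = promoter_set
        self.sequences = sequences  # gene-strand promoter window sequences
        self.cohorts = cohorts
        self.de_table = de_table
        self.gene_sets = gene_sets

    # -- ground truth ------------------------------------------------------
    def expected_retained(self, cohort: str = "a") -> Set[Tuple[str, int, str, str]]:
        return {
            (v.key.chrom, v.key.pos, v.key.ref, v.key.alt)
            for v in self.cohorts[cohort]
            if v.expected_status == "retained"
        }

    def ground_truth(self) -> Dict[str, object]:
        out: Dict[str, object] = {"config": _config_dict(self.config), "cohorts": {}}
        for name, planted in self.cohorts.items():
            out["cohorts"][name] = [
                {
                    "chrom": v.key.chrom,
                    "pos": v.key.pos,
                    "ref": v.key.ref,
                    "alt": v.key.alt,
                    "gene_id": v.gene_id,
                    "rel_pos": v.rel_pos,
                    "n_carriers": len(v.carriers),
                    "true_class": v.true_class,
                    "expected_status": v.expected_status,
                }
                for v in planted
            ]
        out["de"] = {
            r.gene_id: {"fold_change": r.fold_change, "direction": r.direction,
                        "padj": r.padj}
            for r in self.de_table
        }
        return out

    def to_cohort_variants(self, cohort: str = "a") -> List[CohortVariant]:
        return [v.to_cohort_variant() for v in self.cohorts[cohort]]

    def n_samples(self, cohort: str = "a") -> int:
        return self.config.n_samples_a if cohort == "a" else self.config.n_samples_b

    # -- serialization -----------------------------------------------------
    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "promoters": outdir / "promoters.tsv",
            "sequences": outdir / "promoter_sequences.tsv",
            "de": outdir / "de_table.tsv",
            "gmt": outdir / "gene_sets.gmt",
            "truth": outdir / "ground_truth.json",
        }
        write_promoter_table(self.promoter_set, paths["promoters"])
        pd.DataFrame(
            sorted(self.sequences.items()), columns=["gene_id", "sequence"]
        ).to_csv(paths["sequences"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "fold_change": r.fold_change,
                    "direction": r.direction,
                    "padj": r.padj,
                }
                for r in self.de_table
            ]
        ).to_csv(paths["de"], sep="\t", index=False)
        write_gmt(self.gene_sets, paths["gmt"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.ground_truth(), fh, indent=1, sort_keys=True)
        for name in self.cohorts:
            vcf = outdir / f"cohort_{name}.vcf"
            flags = outdir / f"flags_{name}.tsv"
            self._write_vcf(name, vcf)
            self._write_flags(name, flags)
            paths[f"vcf_{name}"] = vcf
            paths[f"flags_{name}"] = flags
        return paths

    def _sample_names(self, cohort: str) -> List[str]:
        n = self.n_samples(cohort)
        return [f"{cohort.upper()}{i + 1:04d}" for i in range(n)]

    def _write_vcf(self, cohort: str, path) -> None:
        samples = self._sample_names(cohort)
        planted = sorted(self.cohorts[cohort], key=lambda v: (v.key, v.gene_id))
        chrom_max: Dict[str, int] = {}
        for v in planted:
            end = v.key.pos + len(v.key.ref)
            chrom_max[v.key.chrom] = max(chrom_max.get(v.key.chrom, 0), end)
        lines = ["##fileformat=VCFv4.2", "##source=corepromoter-simulate"]
        for chrom in sorted(chrom_max):
            lines.append(f"##contig=<ID={chrom},length={chrom_max[chrom] + 1000}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
        seen = set()
        for v in planted:
            if v.key in seen:  # same variant annotated to 2 genes: one record
                continue
            seen.add(v.key)
            gts = "\t".join("0/1" if s in v.carriers else "0/0" for s in samples)
            lines.append(
                f"{v.key.chrom}\t{v.key.pos}\t.\t{v.key.ref}\t{v.key.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def _write_flags(self, cohort: str, path) -> None:
        rows = []
        seen = set()
        for v in sorted(self.cohorts[cohort], key=lambda v: (v.key, v.gene_id)):
            if v.key in seen:
                continue
            seen.add(v.key)
            row = {
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
            }
            row.update({s: int(v.db_flags[s]) for s in DB_SOURCES})
            row["COSMIC"] = int(v.cosmic_flag)
            row["panel"] = int(v.panel_flag)
            rows.append(row)
        cols = ["chrom", "pos", "ref", "alt", *DB_SOURCES, "COSMIC", "panel"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _config_dict(cfg: SimConfig) -> Dict[str, object]:
    d = asdict(cfg)
    d["window"] = list(cfg.window)
    d["de_fc_range"] = list(cfg.de_fc_range)
    return d


# ---------------------------------------------------------------------------
# generation


def _make_promoters(
    cfg: SimConfig, rng: np.random.Generator, catalogue: Sequence[MotifDef]
) -> Tuple[PromoterSet, Dict[str, str]]:
    """Random non-overlapping promoters with planted consensus motifs."""
    up, down = cfg.window
    width = up + down + 1
    pset = PromoterSet()
    sequences: Dict[str, str] = {}
    spacing = 2 * width + 500
    n_chroms = max(1, min(5, cfg.n_genes // 12 + 1))
    for i in range(cfg.n_genes):
        gene = f"GENE{i + 1:04d}"
        chrom = f"chr{i % n_chroms + 1}"
        tss = 5000 + (i // n_chroms) * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        region = PromoterRegion(gene, chrom, tss, strand, up, down)
        seq = list(rng.choice(list(_BASES), size=width))
        for m in catalogue:
            if not m.positional or not m.consensus:
                continue
            start = m.rel_start
            idx = (start if start < 0 else start - 1) + up
            word = _concrete(m.consensus, rng)
            if 0 <= idx and idx + len(word) <= width:
                seq[idx : idx + len(word)] = list(word)
        pset.add(region)
        sequences[gene] = "".join(seq)
    return pset, sequences


def _genomic_ref(
    region: PromoterRegion, seq: str, genomic_pos: int, length: int = 1
) -> str:
    """Reference-strand bases at genomic_pos..genomic_pos+length-1 derived
    from the gene-strand window sequence."""
    bases = []
    for p in range(genomic_pos, genomic_pos + length):
        rel = region.to_relative(p)
        idx = (rel if rel < 0 else rel - 1) + region.upstream_bp
        b = seq[idx]
        bases.append(b if region.strand == "+" else b.translate(_COMP))
    return "".join(bases)


def _motif_covered_linear(catalogue: Sequence[MotifDef], up: int, down: int) -> np.ndarray:
    covered = np.zeros(up + down + 1, dtype=bool)
    for m in catalogue:
        if not m.positional:
            continue
        a = (m.rel_start if m.rel_start < 0 else m.rel_start - 1) + up
        b = (m.rel_end if m.rel_end < 0 else m.rel_end - 1) + up
        a, b = max(a, 0), min(b, len(covered) - 1)
        if a <= b:
            covered[a : b + 1] = True
    return covered


class _VariantFactory:
    """Draws variant sites/alleles consistent with the promoter sequences."""

    def __init__(
        self,
        cfg: SimConfig,
        pset: PromoterSet,
        sequences: Mapping[str, str],
        rng: np.random.Generator,
        catalogue: Sequence[MotifDef],
    ):
        self.cfg = cfg
        self.pset = pset
        self.seqs = sequences
        self.rng = rng
        up, down = cfg.window
        covered = _motif_covered_linear(catalogue, up, down)
        w = np.where(covered, cfg.motif_enrichment, 1.0)
        self.pos_weights = w / w.sum()
        self.up, self.down = up, down
        self.genes = sorted(pset.regions)
        self.used: Set[Tuple[str, int]] = set()  # (chrom, pos) occupied sites

    def draw_site(self, uniform: bool = False) -> Tuple[PromoterRegion, int]:
        for _ in range(10000):
            gene = self.genes[int(self.rng.integers(len(self.genes)))]
            region = self.pset[gene]
            if uniform:
                lin = int(self.rng.integers(self.up + self.down + 1))
            else:
                lin = int(self.rng.choice(len(self.pos_weights), p=self.pos_weights))
            rel = (lin - self.up) if lin < self.up else (lin - self.up + 1)
            pos = region.to_genomic(rel)
            # leave headroom inside the window for deletion ref spans
            if pos + 4 > region.genomic_end:
                continue
            if (region.chrom, pos) not in self.used:
                self.used.add((region.chrom, pos))
                return region, pos
        raise ValueError(
            "infeasible config: could not place variant "
            "(more planted variants than available window positions?)"
        )

    def draw_alleles(self, region, pos, mut_type: str) -> Tuple[str, str]:
        seq = self.seqs[region.gene_id]
        ref1 = _genomic_ref(region, seq, pos, 1)
        if mut_type == "substitution":
            if self.rng.random() < self.cfg.transition_prob:
                return ref1, _TRANSITION[ref1]
            tv = [b for b in _BASES if b != ref1 and b != _TRANSITION[ref1]]
            return ref1, tv[int(self.rng.integers(2))]
        if mut_type == "insertion":
            ins = "".join(self.rng.choice(list(_BASES), size=int(self.rng.integers(1, 4))))
            alt = ref1 + ins
            # avoid a shared trailing base that normalization would trim
            if alt[-1] == ref1 and len(alt) > 1:
                alt = alt[:-1] + ("C" if ref1 != "C" else "G")
            return ref1, alt
        length = int(self.rng.integers(1, 4))
        max_len = region.genomic_end - pos
        length = min(length, max(1, max_len - 1))
        ref = _genomic_ref(region, seq, pos, length + 1)
        if ref[-1] == ref[0] and len(ref) > 1:
            pass  # trailing base equal to anchor is fine: alt is single-base
        return ref, ref[0]

    def make(
        self,
        mut_type: str,
        carriers: FrozenSet[str],
        db_flags: Dict[str, bool],
        cosmic: bool,
        panel: bool,
        true_class: str,
        expected_status: str,
        uniform_site: bool = False,
    ) -> PlantedVariant:
        region, pos = self.draw_site(uniform=uniform_site)
        ref, alt = self.draw_alleles(region, pos, mut_type)
        key = VariantKey.normalized(region.chrom, pos, ref, alt)
        return PlantedVariant(
            key=key,
            gene_id=region.gene_id,
            rel_pos=region.to_relative(key.pos),
            carriers=carriers,
            db_flags=db_flags,
            cosmic_flag=cosmic,
            panel_flag=panel,
            true_class=true_class,
            expected_status=expected_status,
        )


def _draw_type(rng: np.random.Generator, probs: Sequence[float]) -> str:
    return ("substitution", "insertion", "deletion")[
        int(rng.choice(3, p=np.asarray(probs) / np.sum(probs)))
    ]


def _germline_flags(rng: np.random.Generator) -> Dict[str, bool]:
    flags = {s: bool(rng.random() < 0.4) for s in DB_SOURCES}
    if not any(flags.values()):
        flags[DB_SOURCES[int(rng.integers(len(DB_SOURCES)))]] = True
    return flags


def _somatic_flags() -> Dict[str, bool]:
    return {s: False for s in DB_SOURCES}


def _draw_carriers(
    rng: np.random.Generator, samples: Sequence[str], lo: int, hi: int
) -> FrozenSet[str]:
    k = int(rng.integers(lo, hi + 1))
    idx = rng.choice(len(samples), size=k, replace=False)
    return frozenset(samples[i] for i in idx)


def _plant_cohort(
    cfg: SimConfig,
    factory: _VariantFactory,
    rng: np.random.Generator,
    samples: List[str],
    n_samples: int,
    reuse: Optional[List[PlantedVariant]] = None,
) -> List[PlantedVariant]:
    s_thr = polymorphism_threshold(n_samples, cfg.somatic_fraction)
    g_thr = polymorphism_threshold(n_samples, cfg.germline_fraction)
    for cls, thr, n_planted in (
        ("somatic", s_thr, cfg.n_true_somatic),
        ("germline", g_thr, cfg.n_true_germline),
    ):
        if n_planted > 0 and thr < 2:
            raise ValueError(
                f"infeasible config: {cls} threshold {thr} < 2; retained "
                f"(recurrent, non-polymorphic) {cls} mutations cannot exist"
            )
    planted: List[PlantedVariant] = []

    # cross-cohort reuse: same variant identity, carriers redrawn here
    reused_somatic = reused_germline = 0
    if reuse:
        for v in reuse:
            if v.expected_status != "retained":
                continue
            share = rng.random() < cfg.shared_fraction
            if not share:
                continue
            thr = s_thr if v.true_class == "somatic" else g_thr
            planted.append(
                PlantedVariant(
                    key=v.key,
                    gene_id=v.gene_id,
                    rel_pos=v.rel_pos,
                    carriers=_draw_carriers(rng, samples, 2, thr),
                    db_flags=dict(v.db_flags),
                    cosmic_flag=v.cosmic_flag,
                    panel_flag=False,
                    true_class=v.true_class,
                    expected_status="retained",
                )
            )
            factory.used.add((v.key.chrom, v.key.pos))
            if v.true_class == "somatic":
                reused_somatic += 1
            else:
                reused_germline += 1

    for _ in range(cfg.n_true_somatic - reused_somatic):
        planted.append(
            factory.make(
                _draw_type(rng, cfg.somatic_type_probs),
                _draw_carriers(rng, samples, 2, s_thr),
                _somatic_flags(),
                cosmic=bool(rng.random() < 0.01),
                panel=False,
                true_class="somatic",
                expected_status="retained",
            )
        )
    for _ in range(cfg.n_true_germline - reused_germline):
        planted.append(
            factory.make(
                _draw_type(rng, cfg.germline_type_probs),
                _draw_carriers(rng, samples, 2, g_thr),
                _germline_flags(rng),
                cosmic=False,
                panel=False,
                true_class="germline",
                expected_status="retained",
            )
        )

    # background: panel-listed or above-threshold polymorphisms
    for i in range(cfg.n_polymorphic_background):
        as_panel = rng.random() < 0.5
        as_germline = rng.random() < 0.5
        flags = _germline_flags(rng) if as_germline else _somatic_flags()
        cls = "germline" if as_germline else "somatic"
        thr = g_thr if as_germline else s_thr
        if as_panel or thr >= n_samples:  # no room above threshold -> panel
            carriers = _draw_carriers(rng, samples, 1, max(1, thr))
            status = "eliminated_panel"
            panel = True
        else:
            carriers = _draw_carriers(rng, samples, thr + 1, n_samples)
            status = "eliminated_polymorphic"
            panel = False
        planted.append(
            factory.make(
                _draw_type(rng, (0.6, 0.2, 0.2)),
                carriers, flags,
                cosmic=False, panel=panel,
                true_class=cls, expected_status=status,
                uniform_site=True,
            )
        )
    for _ in range(cfg.n_private_background):
        as_germline = rng.random() < 0.5
        flags = _germline_flags(rng) if as_germline else _somatic_flags()
        planted.append(
            factory.make(
                _draw_type(rng, (0.6, 0.2, 0.2)),
                _draw_carriers(rng, samples, 1, 1),
                flags,
                cosmic=False, panel=False,
                true_class="germline" if as_germline else "somatic",
                expected_status="eliminated_private",
                uniform_site=True,
            )
        )
    planted.sort(key=lambda v: (v.key, v.gene_id))
    return planted


def _make_de(
    cfg: SimConfig,
    pset: PromoterSet,
    retained_genes: Set[str],
    rng: np.random.Generator,
) -> List[DERecord]:
    lo, hi = cfg.de_fc_range
    out = []
    for gene in sorted(pset.regions):
        mutated = gene in retained_genes
        rate = cfg.de_coupling if mutated else cfg.de_background_rate
        if rng.random() < rate:
            fold = float(rng.uniform(lo, hi))
            direction = "up" if rng.random() < 0.5 else "down"
            padj = float(rng.uniform(1e-8, 0.049))
        else:
            fold = float(rng.uniform(1.0, 1.45))
            direction = "up" if rng.random() < 0.5 else "down"
            padj = float(rng.uniform(0.05, 1.0))
        out.append(DERecord(gene, fold, direction, padj))
    return out


def _make_gene_sets(
    pset: PromoterSet, retained_genes: Set[str], rng: np.random.Generator
) -> List[GeneSet]:
    genes = sorted(pset.regions)
    sets: List[GeneSet] = []
    mutated = sorted(retained_genes)
    if len(mutated) >= 3:
        k = min(len(mutated), 12)
        idx = rng.choice(len(mutated), size=k, replace=False)
        sets.append(
            GeneSet("SIM:0001", "mutation-coupled process",
                    frozenset(mutated[i] for i in idx))
        )
    for j in range(2, 8):
        k = int(rng.integers(5, max(6, min(15, len(genes)))))
        idx = rng.choice(len(genes), size=min(k, len(genes)), replace=False)
        sets.append(
            GeneSet(f"SIM:{j:04d}", f"random process {j}",
                    frozenset(genes[i] for i in idx))
        )
    return sets


def simulate(config: SimConfig) -> SimResult:
    """Generate a full synthetic study; deterministic given ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("promoters", "cohort_a", "cohort_b", "de", "gene_sets"),
            root.spawn(5),
        )
    }
    catalogue = default_catalogue()
    pset, sequences = _make_promoters(config, streams["promoters"], catalogue)
    factory = _VariantFactory(config, pset, sequences, streams["cohort_a"], catalogue)
    samples_a = [f"A{i + 1:04d}" for i in range(config.n_samples_a)]
    cohort_a = _plant_cohort(
        config, factory, streams["cohort_a"], samples_a, config.n_samples_a
    )
    factory_b = _VariantFactory(config, pset, sequences, streams["cohort_b"], catalogue)
    factory_b.used = set(factory.used)
    samples_b = [f"B{i + 1:04d}" for i in range(config.n_samples_b)]
    cohort_b = _plant_cohort(
        config, factory_b, streams["cohort_b"], samples_b, config.n_samples_b,
        reuse=cohort_a,
    )

    retained_genes = {
        v.gene_id for v in cohort_a if v.expected_status == "retained"
    }
    de_table = _make_de(config, pset, retained_genes, streams["de"])
    gene_sets = _make_gene_sets(pset, retained_genes, streams["gene_sets"])
    return SimResult(config, pset, sequences, {"a": cohort_a, "b": cohort_b},
                     de_table, gene_sets)


# ---------------------------------------------------------------------------
# hand-built regression fixture


def write_fixture_suite(outdir) -> Dict[str, Path]:
    """Write a tiny, fully hand-checkable fixture: 5 genes, 5 samples, one
    variant of every filter status, and a DPE-shift ref/alt promoter pair.

    The expected outputs are spelled out literally in
    ``expected_retained.tsv`` — they were derived by hand from the filter
    rules, not by running the pipeline.
    """
    from .motifs import write_catalogue

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = ["S1", "S2", "S3", "S4", "S5"]
    # 5% threshold on 5 samples is ceil(0.25)=1, so a recurrent germline
    # variant cannot survive at the study fractions; the fixture therefore
    # documents germline_fraction=0.5 (threshold 3) for its expectations.
    promoters = (
        "gene_id\tchrom\ttss\tstrand\n"
        "FTH1L\tchr1\t1000\t+\n"
        "GENEB\tchr1\t2000\t+\n"
        "GENEC\tchr1\t3000\t-\n"
        "GENED\tchr2\t1500\t+\n"
        "GENEE\tchr2\t4000\t-\n"
    )
    (outdir / "promoters.tsv").write_text(promoters)

    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=10000>\n"
        "##contig=<ID=chr2,length=10000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )

    def row(chrom, pos, ref, alt, carriers):
        gts = "\t".join("0/1" if s in carriers else "0/0" for s in samples)
        return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"

    # FTH1L +28 (genomic 1027): the DPE-shift substitution, somatic, 2 carriers -> retained
    # GENEB -50 (genomic 1950): germline (dbSNP), 2 carriers -> retained
    # GENEC +10 (genomic 2991, '-' strand): somatic, 1 carrier -> private
    # GENED -20 (genomic 1480): panel-listed -> eliminated_panel
    # GENEE +1 (genomic 4000): somatic, 4/5 carriers > threshold 3 -> polymorphic
    # GENEB -10 (genomic 1990): somatic insertion, 3 carriers -> retained
    vcf = header
    vcf += row("chr1", 1027, "G", "A", {"S1", "S2"})
    vcf += row("chr1", 1950, "T", "C", {"S2", "S3"})
    vcf += row("chr1", 1990, "A", "ACT", {"S1", "S3", "S5"})
    vcf += row("chr1", 2991, "C", "G", {"S4"})
    vcf += row("chr2", 1480, "A", "T", {"S1", "S2", "S3"})
    vcf += row("chr2", 4000, "G", "T", {"S1", "S2", "S4", "S5"})
    (outdir / "cohort.vcf").write_text(vcf)

    flags = "chrom\tpos\tref\talt\t" + "\t".join(DB_SOURCES) + "\tCOSMIC\tpanel\n"
    flags += "chr1\t1027\tG\tA\t0\t0\t0\t0\t0\t0\t0\t0\n"
    flags += "chr1\t1950\tT\tC\t1\t0\t0\t0\t0\t0\t0\t0\n"
    flags += "chr1\t1990\tA\tACT\t0\t0\t0\t0\t0\t0\t0\t0\n"
    flags += "chr1\t2991\tC\tG\t0\t0\t0\t0\t0\t0\t0\t0\n"
    flags += "chr2\t1480\tA\tT\t1\t1\t0\t0\t0\t0\t0\t1\n"
    flags += "chr2\t4000\tG\tT\t0\t0\t0\t0\t0\t0\t1\t0\n"
    (outdir / "flags.tsv").write_text(flags)

    # expected retained table at somatic_fraction=0.5, germline_fraction=0.5
    expected = (
        "chrom\tpos\tref\talt\tgene_id\trel_pos\tvar_class\tmut_type\tcarrier_count\tcarrier_ids\n"
        "chr1\t1027\tG\tA\tFTH1L\t28\tsomatic\tsubstitution\t2\tS1;S2\n"
        "chr1\t1950\tT\tC\tGENEB\t-50\tgermline\tsubstitution\t2\tS2;S3\n"
        "chr1\t1990\tA\tACT\tGENEB\t-10\tsomatic\tinsertion\t3\tS1;S3;S5\n"
    )
    (outdir / "expected_retained.tsv").write_text(expected)

    # DPE-shift pair: windows of 201 bases (+/-100); only the +24..+36
    # neighbourhood is meaningful, the rest is a fixed non-matching backdrop.
    up = 100
    backdrop = ("CT" * 120)[: up + 101]

    def with_patch(patch: Dict[int, str]) -> str:
        seq = list(backdrop)
        for rel, base in patch.items():
            idx = (rel if rel < 0 else rel - 1) + up
            seq[idx] = base
        return "".join(seq)

    # ref: unique DPE (RGWYV) match at +30; alt (G>A at +28): new match at +26
    ref_patch = {24: "C", 25: "C", 26: "A", 27: "G", 28: "G", 29: "C",
                 30: "A", 31: "G", 32: "A", 33: "T", 34: "G", 35: "C", 36: "C"}
    alt_patch = {**ref_patch, 28: "A"}
    seqs = (
        "gene_id\tsequence\n"
        f"FTH1L_ref\t{with_patch(ref_patch)}\n"
        f"FTH1L_alt\t{with_patch(alt_patch)}\n"
    )
    (outdir / "dpe_shift_sequences.tsv").write_text(seqs)
    write_catalogue(default_catalogue(), outdir / "motif_catalogue.tsv")
    return {
        "promoters": outdir / "promoters.tsv",
        "vcf": outdir / "cohort.vcf",
        "flags": outdir / "flags.tsv",
        "expected_retained": outdir / "expected_retained.tsv",
        "dpe_sequences": outdir / "dpe_shift_sequences.tsv",
        "catalogue": outdir / "motif_catalogue.tsv",
    }
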