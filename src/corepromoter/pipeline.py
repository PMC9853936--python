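"""End-to-end orchestration: classify -> annotate -> spectrum -> expression
-> enrichment -> (optional) cohort comparison, with a structured report.

Every numeric threshold defaults to the study rule (50% somatic / 5%
germline polymorphism cut, fold change >= 1.5 with BH p < 0.05, enrichment
p < 0.05 with overlap >= 3, similarity > 0.3), so a bare run applies the
reference procedure.  The report JSON mirrors a three-section summary table
(A general features, B variation frequency in motifs, C substitution
spectrum and Ts/Tv) and logs every filter's elimination counts.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import compare as compare_mod
from .enrichment import enrichment_table, hypergeom_enrich, read_gmt, term_similarity_network
from .expression import link_mutations_to_de, read_de_table
from .motifs import annotate_motifs, default_catalogue, read_catalogue
from .promoters import read_promoter_table
from .spectrum import spectrum_table, substitution_spectrum
from .variants import (
    CohortVariant,
    read_cohort_vcf,
    read_flag_table,
    run_filters,
    summarize_cohort,
    write_retained_table,
)

__all__ = ["PipelineConfig", "run_all", "classify_cohort", "build_report"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    vcf: object = None  # path or list of paths
    flags: Optional[str] = None
    promoters: Optional[str] = None
    n_samples: int = 0
    outdir: str = "corepromoter_out"
    de_table: Optional[str] = None
    gmt: Optional[str] = None
    catalogue: Optional[str] = None
    sequences: Optional[str] = None
    vcf_b: object = None
    flags_b: Optional[str] = None
    n_samples_b: int = 0
    somatic_fraction: float = 0.50
    germline_fraction: float = 0.05
    fc_threshold: float = 1.5
    padj_threshold: float = 0.05
    enrich_p: float = 0.05
    enrich_min_overlap: int = 3
    similarity_cutoff: float = 0.3
    genome_gene_total: int = 20000
    motif_count_mode: str = "pair"

    def validate(self) -> None:
        if self.vcf is None or self.flags is None or self.promoters is None:
            raise ValueError("vcf, flags and promoters are required")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("somatic_fraction", "germline_fraction",
                     "padj_threshold", "enrich_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def classify_cohort(
    vcf, flags_path, promoters_path, n_samples: int,
    somatic_fraction: float = 0.50, germline_fraction: float = 0.05,
) -> Tuple[List[CohortVariant], object]:
    """Read + filter one cohort; returns (variants with status, promoter set)."""
    pset = read_promoter_table(promoters_path)
    flags = read_flag_table(flags_path)
    called = read_cohort_vcf(vcf, pset, flags)
    filtered = run_filters(called, n_samples, somatic_fraction, germline_fraction)
    return filtered, pset


def build_report(
    filtered: Sequence[CohortVariant],
    n_samples: int,
    pset,
    motif_table: Optional[pd.DataFrame] = None,
) -> Dict[str, object]:
    summary = summarize_cohort(filtered, n_samples, pset)
    retained = [v for v in filtered if v.status == "retained"]
    spec_som = substitution_spectrum(
        {v.key: v for v in retained if v.var_class == "somatic"}.values()
    )
    spec_ger = substitution_spectrum(
        {v.key: v for v in retained if v.var_class == "germline"}.values()
    )
    audit = Counter(v.status for v in filtered)
    report: Dict[str, object] = {
        "A_general_features": summary.to_dict(),
        "C_transition_transversion": {
            "somatic": spec_som.to_dict(),
            "germline": spec_ger.to_dict(),
        },
        "filter_audit": {s: audit.get(s, 0) for s in
                         ("retained", "eliminated_panel",
                          "eliminated_polymorphic", "eliminated_private")},
    }
    if motif_table is not None:
        report["B_variation_frequency_in_motifs"] = motif_table.to_dict("records")
    return report


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full pipeline per the configuration; writes the report and
    stage outputs under ``config.outdir`` and returns the report dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("classify"):
        filtered, pset = classify_cohort(
            config.vcf, config.flags, config.promoters, config.n_samples,
            config.somatic_fraction, config.germline_fraction,
        )
        retained = [v for v in filtered if v.status == "retained"]
        write_retained_table(filtered, outdir / "retained_mutations.tsv")

    with stage("annotate-motifs"):
        catalogue = (
            read_catalogue(config.catalogue) if config.catalogue else default_catalogue()
        )
        sequences = None
        if config.sequences:
            sdf = pd.read_csv(config.sequences, sep="\t")
            sequences = dict(zip(sdf.gene_id.astype(str), sdf.sequence.astype(str)))
        hits, motif_table = annotate_motifs(
            retained, catalogue, sequences=sequences, count_mode=config.motif_count_mode
        )
        motif_table.to_csv(outdir / "motif_counts.tsv", sep="\t", index=False)

    with stage("stats"):
        report = build_report(filtered, config.n_samples, pset, motif_table)
        spec_rows = spectrum_table(
            substitution_spectrum(
                {v.key: v for v in retained if v.var_class == "somatic"}.values()
            ),
            substitution_spectrum(
                {v.key: v for v in retained if v.var_class == "germline"}.values()
            ),
        ) if retained else None
        if spec_rows is not None:
            spec_rows.to_csv(outdir / "spectrum.tsv", sep="\t", index=False)

    mutated_genes = sorted({v.gene_id for v in retained})
    if config.de_table:
        with stage("link-expression"):
            de = read_de_table(config.de_table)
            link = link_mutations_to_de(
                mutated_genes, de, config.fc_threshold, config.padj_threshold
            )
            report["expression_link"] = link.to_dict()

    if config.gmt:
        with stage("enrich"):
            gene_sets = read_gmt(config.gmt)
            universe = sorted(pset.regions)
            results = hypergeom_enrich(
                mutated_genes, gene_sets, universe,
                p_cutoff=config.enrich_p, min_overlap=config.enrich_min_overlap,
            )
            enrichment_table(results).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
            sig = [r for r in results if r.significant]
            report["enrichment"] = {
                "n_terms_tested": len(results),
                "n_significant": len(sig),
                "significant_terms": [r.term_id for r in sig],
            }
            if len(sig) >= 2:
                edges = term_similarity_network(
                    sig, gene_sets, universe, cutoff=config.similarity_cutoff
                )
                pd.DataFrame(
                    edges, columns=["term_i", "term_j", "score"]
                ).to_csv(outdir / "term_network.tsv", sep="\t", index=False)
                report["enrichment"]["n_network_edges"] = len(edges)

    if config.vcf_b:
        with stage("compare"):
            filtered_b, _ = classify_cohort(
                config.vcf_b, config.flags_b, config.promoters, config.n_samples_b,
                config.somatic_fraction, config.germline_fraction,
            )
            retained_b = [v for v in filtered_b if v.status == "retained"]
            comparison = {}
            for cls in ("somatic", "germline"):
                keys_a = {v.key for v in retained if v.var_class == cls}
                keys_b = {v.key for v in retained_b if v.var_class == cls}
                comparison[f"{cls}_variants"] = compare_mod.compare_cohorts(
                    keys_a, keys_b, level="variant", var_class=cls
                ).to_dict()
                genes_a = {v.gene_id for v in retained if v.var_class == cls}
                genes_b = {v.gene_id for v in retained_b if v.var_class == cls}
                comparison[f"{cls}_genes"] = compare_mod.compare_cohorts(
                    genes_a, genes_b, level="gene", var_class=cls
                ).to_dict()
            report["cohort_comparison"] = comparison

    shared, union, fraction = compare_mod.gene_union_overlap(
        {v.gene_id for v in retained if v.var_class == "somatic"},
        {v.gene_id for v in retained if v.var_class == "germline"},
        genome_gene_total=config.genome_gene_total,
    )
    report["gene_overlap"] = {
        "genes_with_both_classes": shared,
        "genes_with_any_mutation": union,
        "pct_of_genome": fraction,
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
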