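"""Annotate mutations against core-promoter motifs and detect a DPE shift.

Reproduces the canonical worked example: a G>A substitution at +28 creates
an upstream DPE consensus match, shifting the element's best position from
+30 to +26.
"""

import tempfile

import pandas as pd

from corepromoter import annotate_motifs, default_catalogue, rescan_motif
from corepromoter.simulate import write_fixture_suite
from corepromoter.variants import CohortVariant, VariantKey

# a few mutations at TSS-relative positions covered by classic elements
muts = [
    CohortVariant(VariantKey("chr1", 1027, "G", "A"), "FTH1L", 28,
                  frozenset({"S1", "S2"}), {}, var_class="germline"),
    CohortVariant(VariantKey("chr1", 972, "T", "C"), "GENEB", -28,
                  frozenset({"S1", "S3"}), {}, var_class="somatic"),
    CohortVariant(VariantKey("chr1", 1090, "A", "T"), "GENEC", 91,
                  frozenset({"S2", "S4"}), {}, var_class="somatic"),
]
hits, table = annotate_motifs(muts, default_catalogue())
print("per-motif counts (non-zero rows):")
print(table[(table.somatic_count > 0) | (table.germline_count > 0)].to_string(index=False))

with tempfile.TemporaryDirectory() as td:
    fx = write_fixture_suite(td)
    sdf = pd.read_csv(fx["dpe_sequences"], sep="\t")
seqs = dict(zip(sdf.gene_id, sdf.sequence))
dpe = next(m for m in default_catalogue() if m.name == "DPE")
change = rescan_motif(seqs["FTH1L_ref"], seqs["FTH1L_alt"], dpe, gene_id="FTH1L")
print(f"\nDPE rescan: {change.kind} {change.ref_rel_pos:+d} -> {change.alt_rel_pos:+d}")
# The +28 variant hits the DPE window (+28..+32); rescanning the mutant
# sequence finds the best consensus match four bases upstream of the
# reference match: a motif shift, not a loss.
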