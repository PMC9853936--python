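# Methods

This note records the models, conventions and numerical choices behind
`corepromoter`, and what the synthetic tests do and do not demonstrate.

## Coordinate scheme

All TSS-relative positions are signed integers with no position 0: `+1`
denotes the TSS base itself, `-1` the base immediately upstream on the
gene's strand. This matches the common usage in the promoter literature,
where both `-41 bp` and `+28 bp` style positions appear but the treatment
of the TSS base is rarely stated; because the convention is ambiguous in
much of the literature, it is fixed here explicitly and used everywhere
(motif windows, variant annotation, rescanning). A window of
`upstream_bp`/`downstream_bp` bases therefore spans
`-upstream_bp … -1, +1 … +downstream_bp+1`, exactly
`upstream_bp + downstream_bp + 1` positions. The default window is
±100 bp, wide enough to contain every catalogue motif and the extreme
positions commonly reported for core-promoter variants (≈ −99 … +92);
it is configurable per gene. Genomic coordinates are 1-based (VCF-style);
BED output is 0-based half-open. Overlapping promoter windows are legal:
a variant inside two genes' windows is annotated once per gene, so
gene-level counts can exceed distinct-variant counts.

## Variant identity and classification

Variants are keyed by (chrom, pos, ref, alt) after canonicalization
(shared-suffix then shared-prefix trimming, keeping one anchor base, with
position adjustment). Cross-cohort sharing and flag-table joins use exact
key equality; matching by position alone is rejected because one site can
carry different alleles.

Classification is purely database-driven: **germline** iff the variant is
present in any of dbSNP, 1000 Genomes, ESP, ExAC, gnomAD or ClinVar;
otherwise **somatic**. This is the appropriate design for cohorts without
matched normal tissue; its known failure modes (novel germline variants
mislabelled somatic, somatic hotspots present in databases mislabelled
germline) are inherited by construction and not corrected for. Membership
flags must be supplied explicitly for every called variant (sidecar TSV);
a missing flag row is an error rather than an implicit "absent".

Filters run in a fixed order — panel, cohort frequency, private — so each
eliminated variant carries a single, auditable status and the four
statuses partition the called set. The frequency cut eliminates variants
with carriers strictly greater than `ceil(fraction × N)`; at the default
fractions and `N = 116` this reproduces the `>58` (somatic, 50%) and `>6`
(germline, 5%) carrier rules. The strict-`>` reading of the germline cut
is a deliberate choice (the two cuts are taken as one rule at two
fractions); both fractions are parameters. Carriers are counted as cases
with any non-reference genotype, without allele-count weighting.
Per-case mutation means are rounded half away from zero. COSMIC
membership is reported (share of retained mutations absent from COSMIC)
but never used for filtering.

## Motif catalogue and rescanning

The default catalogue places the classical elements at their
literature-standard windows — TATA −31..−24 (`TATAWAWR`), BREu −38..−32
(`SSRCGCC`), BREd −23..−17 (`RTDKKKK`), Inr −2..+4 (`YYANWYY`), TCT
−2..+6, XCPE1 −8..+2, XCPE2 −9..+2, MTE boxes +18..+22 and +23..+29, DPE
+28..+32 (`RGWYV`), DCE boxes `CTTC`/`CTGT`/`AGC` at +6..+11, +16..+21,
+30..+34 — while Ets (`GGAW`), SP1 (`GGGCGG`), E-Box (`CANNTG`) and TCF
(`CTTTGWW`) are located by consensus scan anywhere in the window. "DTIE"
has no established definition in the literature; it ships as an empty
catalogue row for users to define. The entire catalogue is a plain TSV
and fully overridable.

A variant hits a positional motif when its affected relative interval —
the anchor for insertions, the full reference-allele span otherwise —
intersects the motif window. Consensus-scan motifs require promoter
sequences and hit on intersection with a match span. The per-motif count
table supports two modes: distinct (variant, motif) pairs (default) or
recurrence-weighted by carrier count; published motif tallies do not
state which mode they use, so both are exposed.

Rescanning compares IUPAC consensus match positions between the reference
and mutant window sequence inside a search window (the motif window
padded by one consensus length, e.g. ≈ +24..+36 for DPE). The reported
position is the match start closest to the motif's canonical start, ties
resolved upstream; present→absent is *abolished*, absent→present
*created*, a changed best position *shifted*. Under these rules a G>A
substitution at +28 that creates an upstream `RGWYV` match shifts the DPE
from +30 to +26 even though the original downstream match persists — the
behavior the worked example encodes.

The motif/non-motif distribution test pools per-position mutation counts
across genes and compares motif-covered against uncovered positions with
a Welch (unequal-variance) two-sample t-test, two-sided. "Student's
t-test" without qualification is ambiguous; Welch is the safer default
for unequal group sizes and variances. Zero variance in both groups with
equal means returns t = 0, p = 1; with unequal means it is an error
rather than a NaN.

## Spectrum

Only single-base substitutions enter the 12-class spectrum, keyed on the
reference strand without pyrimidine folding (G>A and C>T are distinct
classes). Multi-base same-length substitutions count as substitutions in
type totals but not in the spectrum. The headline ratio is the doubled
convention `2 × Ts/Tv` — preserved exactly because it is what the
source tables print (192/240 → 1.60, 28/23 → 2.43) — with the
conventional ratio available for comparison against population values
(whose published 3.25–3.81 range may or may not use the same doubling;
both are therefore reported). Zero transversions raise an explicit
undefined-ratio error.

## Expression linkage

Fold changes are stored as (magnitude, direction) because a printed
"+22.4 / −46.4" display cannot be simultaneously a ratio and a signed
number; ingestion from log2 fold changes converts via
`magnitude = 2^|log2FC|`. A gene is altered when BH-adjusted p < 0.05 and
magnitude ≥ 1.5 (inclusive). The mutated × altered 2×2 table is built
over all genes in the DE table; mutated genes missing from the table are
excluded and logged. The Fisher test is two-sided (sum of all tables with
the observed margins whose probability does not exceed the observed
one); the odds ratio is the unconditional sample estimate ad/bc. The
stemness correlation applies `log2(x + 0.001)` to expression before
Pearson's r; the pseudo-count keeps zero-expression samples finite.

## Enrichment

Upper-tail hypergeometric p over a user universe (default: all genes with
a defined promoter), each term intersected with the universe first.
Significance follows the raw-p rule — p < 0.05 and overlap ≥ 3 — with no
multiple-testing correction by default, mirroring the procedure it
reimplements; a BH option exists. Term similarity defaults to Jaccard on
universe-restricted member sets (transparent and symmetric), with Cohen's
kappa as an option; edges require similarity > 0.3.

## Synthetic cohorts

The generator emulates the *shape* of a two-cohort promoter-mutation
study: a promoter table over a synthetic genome, a multi-sample VCF and
membership-flag TSV per cohort, a coupled DE table and a small GMT.
Defaults mirror the study conditions: cohort sizes 116 and 279, ±100 bp
windows, transition probability 0.45 (a doubled Ts/Tv near 1.6
corresponds to a transition fraction of ≈ 0.44), motif-position
enrichment factor 2, type mixes per class following the observed shares
(somatic ≈ 57/19/24% substitution/insertion/deletion, germline ≈
23/39/38%), 15% cross-cohort sharing, 25% mutation–expression coupling
against a 5% background alteration rate, and fold changes uniform in
[1.5, 25]. Desk-scale tests use smaller cohorts (5–40 samples, 8–300
genes) so the suite completes in seconds; the statistical structure, not
the size, is what the tests exercise.

Each planted variant carries an expected status derived from its
construction (true mutations: 2 ≤ carriers ≤ class threshold, flags
consistent with class; panel background: panel-listed; polymorphic
background: carriers above threshold; private: exactly one carrier), so
pipeline recovery can be asserted exactly. Configurations whose class
threshold falls below 2 cannot host retained recurrent mutations of that
class and are rejected as infeasible — note that the 5% germline cut
implies this for cohorts of ≤ 20 samples, which is why small-cohort tests
raise the germline fraction. Reference promoter sequences are random
ACGT with concrete consensus realizations planted at catalogue positions,
so rescanning has true signal; variant reference alleles are always
consistent with these sequences (strand-aware). Randomness derives from
one root seed split into per-component streams (promoters, each cohort,
DE, gene sets), making outputs byte-identical across runs and partial
re-runs reproducible.

What the generator does **not** model: sequencing reads and their error
modes, alignment and calling artifacts, tumor purity and subclonality,
linkage between nearby variants, realistic gene-length or GC structure,
and population structure behind the database flags. Passing recovery
tests therefore demonstrate the correctness of the classification and
filtering logic under the stated rules, not robustness to upstream
calling noise.

## Numerical conventions

* Percentages print half-up to one decimal; per-case means round half
  away from zero to integers.
* Thresholds use `ceil(fraction × N)` with strict `>` elimination.
* Fisher and hypergeometric p-values come from exact routines
  (scipy), cross-checked in the test suite against exhaustive
  Fraction-arithmetic enumeration over all small tables/configurations.
* Degenerate inputs fail loudly: undefined Ts/Tv (no transversions),
  zero-variance correlation, empty universe/query, cohorts of < 2
  samples (recurrence undefined), flags missing for a called variant.

## Known limitations

* Germline/somatic classification is only as good as the database flags
  supplied; no matched-normal subtraction is available.
* Motif windows and consensi are literature defaults, not learned from
  data; PWM scoring and TFBS databases are out of scope.
* The enrichment module does not traverse the GO graph; terms are flat
  gene sets from GMT files.
* One published gene-total discrepancy is preserved rather than
  resolved: inclusion–exclusion on the reported class gene counts
  (649 + 119 − 21) gives 747, while the source prints 746; likewise a
  germline substitution total quoted as 114 in prose sums to 51 in the
  corresponding table. The implementation always computes exact set
  arithmetic.
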