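# Methods

## The identification problem

Africanized honey bees are New World hybrids of the sub-Saharan
subspecies *Apis mellifera scutellata* and European *A. mellifera*
subspecies. Two properties make them identifiable without nuclear
genotyping: they inherit a distinct maternal (mitochondrial) lineage,
and they are smaller than European workers. This package implements
both routes and the statistics used to turn per-bee calls into
population statements about a hybrid zone.

## Morphometric discriminant

The two discriminant functions are fixed linear combinations of
forewing, hindwing, femur and tibia lengths (mm), one fitted on
individual workers and one on colony means of ten workers. The
coefficients are established constants from the honey bee morphometric
literature and are applied, never refitted, here. Inputs are scored at
full floating precision; output files round to 4 decimals.

The midpoint thresholds that separate the Africanized and European
score ranges depend on reference-population group means that are not
part of this package, so they are explicit configuration
(`Thresholds`), with a shipped default of 0.0 for both formulas — the
discriminant axes are constructed so the two groups straddle zero, but
users reproducing a specific survey must supply that survey's
midpoints. A score exactly at the threshold is classified European:
declaring Africanization requires strictly crossing the midpoint, the
conservative reading of the classification rule. Colony scores are
defined for any n ≥ 1 workers (mean first, then the formula); n ≠ 10
draws a warning because the colony coefficients were derived for
ten-worker means.

## Mitochondrial assays

**cytb–BglII RFLP (in silico).** `digest()` cuts a sequence at every
exact occurrence of the recognition motif (default AGATCT), with the
cut placed `cut_offset` bases into the motif (default 1, matching
BglII's A^GATCT overhang; the offset only changes fragment lengths,
never the band count). Fragments shorter than `min_visible_bp`
(default 50) are suppressed, emulating bands too small to resolve on a
gel; the default is a deliberate, configurable gel-resolution proxy.
Degenerate bases (N) never match the motif — an uncertain site cannot
create a cut. One visible band ⇒ African, two ⇒ European, anything
else ⇒ indeterminate with the band lengths as evidence.

**COI diagnostic SNP.** The diagnostic C/T site is stored as an
annotation on the panel's COI reference (mitogenome coordinate plus
fragment start), not as a hard-coded query offset, because barcode
fragments begin at arbitrary positions. A query is aligned to the
reference with a global aligner whose end gaps are free on both
sequences (match +1, mismatch −2, gap open −5, extend −1), and the
query base paired with the diagnostic coordinate is read: C ⇒ African,
T ⇒ European. A gap at the site, an uncovered site, another base, or
alignment identity below 90% over the aligned region (configurable)
yields an indeterminate call — below that identity the record is
unlikely to be honey bee COI at all.

**COI–COII spacer lineage.** Full phylogenetic placement is replaced by
nearest-reference assignment: global edit distance to each panel
exemplar, normalized by alignment length; the call is the lineage of
the unique minimum, and a tie is indeterminate. This is deterministic
and oracle-checkable, and recovers the generating lineage for any
query within half the minimum pairwise exemplar distance. The panel
schema accepts arbitrary lineage labels, so exemplar sets other than
A/C/M/O can be used.

The bundled panel is synthetic: a random 658-bp "COI" fragment with T
at the annotated site and four mutually distant random 200-bp spacer
exemplars (pairwise edit distances ≈ 105–111). File names and FASTA
headers label them as stand-ins. No invented sequence is presented as
a real haplotype; typing real material requires substituting real
references via `load_panel()`.

## Statistics

All chi-square tests are computed without continuity correction,
because the hive-level comparisons this layer reproduces are one-sample
two-cell goodness-of-fit tests of a count against a reference
proportion (df = 1), and corrected statistics do not match that
convention. Expected cells below 5 warn rather than error — small hive
samples are the realistic use case. The site-heterogeneity test
compares observed counts of sites with 0..k African bees (k = 3 bees
per site in the standard design) against N·Binom(k, p̂) expectations;
its default df is k, the convention used when these tests are reported
in the field, with a stricter df = k−1 option (`DfConvention.
CONSERVATIVE`) since p̂ is estimated from the same data.

The pooled-variance two-sample *t* uses df = nₐ + n_b − 2; one group
of size 1 is tolerated when the other has ≥ 2 so the pooled variance
stays defined. Two-tailed p-values are the default; the one-tailed
option is the tail beyond |t|. Zero pooled variance with equal means
gives t = 0 by convention; with unequal means it is a domain error.

Frequency estimation excludes indeterminate calls (reporting how many)
and attaches a Wilson score interval, chosen for its behavior at
extreme proportions.

## Synthetic-data generator

`SimConfig` encodes the study conditions: African-mitotype frequency
p = 0.65, three bees per site, and a linkage parameter λ = P(nuclear
class = mitotype). λ = 1 is the early-introgression regime (morphology
tracks mitotype); λ = 0 is the fully admixed regime (independent).
Linkage is a single correlation parameter rather than an explicit
mating-system model; that is exactly the contrast the analyses test,
and a pedigree simulator is out of scope.

Because real surveys report discriminant-score means rather than raw
measurement means, group measurement means are **calibrated**:
`calibrate_morph_means` shifts a plausible base vector (9.0, 6.0, 2.6,
3.2 mm — a synthetic placeholder) along the coefficient vector w by
((target − score(base))/w·w)·w, the minimal-norm shift that scores
exactly at the target. Default targets are −0.428 (African class) and
0.902 (European class). The shared measurement covariance (synthetic,
honey-bee-plausible magnitude) is rescaled so the implied score
standard deviation matches a configured misclassification rate
(default 9.9% for the individual discriminant against the midpoint
threshold): σ = d / (2·Φ⁻¹(1 − rate)), where d is the target-score
separation. No within-group measurement variance is reported for real
populations, so this overlap calibration is the generator's only free
scale.

Marker sequences are correct by construction: African cytb amplicons
are motif-free (rejection sampling, retry cap 10,000); European ones
carry exactly one interior motif with both fragments visible; COI
copies the reference with the diagnostic base set per mitotype; the
spacer copies the A exemplar (African) or a random non-A exemplar
(European). Optional extra substitutions avoid the motif span and the
diagnostic site and never change the motif count, so light mutation
cannot flip a call. One root seed feeds per-component child streams
(mitotype, nuclear class, morphometrics, sequences), so disabling one
component does not change the draws of another, and identical configs
give byte-identical output.

What the generator does **not** emulate: measurement error,
within-colony relatedness (bees are i.i.d.), spatial structure among
sites, real haplotype diversity within lineages, and sequencing noise
beyond uniform substitutions. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's logic, not its robustness
to the messiness of real field data.

## Problem sizes and numerical choices

The verification suite uses: 48 workers for the three-marker
concordance check; 1,000 random sequences (50–2,000 bp) for the
digest-vs-brute-force equivalence; 500 surveys of n = 2,000 for Wilson
coverage (≥ 93%, true coverage ≈ 95%); n = 5,000 bees for the
full-linkage *t* and 100 seeds of n = 1,000 for the zero-linkage
non-significance rate; 10,000 bees for the misclassification-rate
calibration check (±2 points). These sizes put Monte-Carlo standard
errors well inside the asserted margins. Coverage replicates sample
mitotype labels directly (sequence attachment off) since the
sequence→call identity at zero mutations is proven separately by the
round-trip properties.

Ties and degenerate inputs: spacer distance ties are indeterminate
(tolerance 1e-12); the classify tie goes European; empty sequences,
motifs containing N, non-PSD covariances, zero coefficient vectors and
empty call lists are domain errors; simulated measurements are clipped
away from zero (at 1 µm) so extreme draws cannot produce non-positive
lengths.

## Known limitations

- Nearest-reference spacer assignment cannot detect novel lineages; a
  query far from all exemplars is still assigned to the closest one
  (the per-lineage distances are in the evidence string for callers who
  want to threshold).
- The RFLP band-count rule cannot distinguish an African mitotype from
  a European amplicon whose second fragment fell below the visibility
  cutoff; `min_visible_bp` makes that trade-off explicit.
- Thresholds for the discriminant midpoints ship as 0.0 placeholders;
  published survey percentages are reproducible only with the original
  midpoints and measurement tables.
- The amplicon boundaries of the cytb fragment are user-supplied; the
  package does not perform in-silico PCR from whole mitogenomes.
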