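# Methods

## Model

The package quantifies, per sample and per coding gene, how much of the
gene's output is *normally spliced transcript*, and flags genes where this
quantity collapses in a patient relative to a control cohort.

**Normal-transcript abundance.** For gene *g* with annotated transcripts
*T_g*, ω_g = Σ_{t∈T_g} w_t x_t, where x_t is the transcript's CPM
(recomputed from estimated counts on load, so upstream TPM conventions
cannot leak in) and w_t is the probability that t is expressed in its
annotated form given the splice-junction evidence. ρ_g = ω_g / Σ x_t is
the normal fraction. ω responds to both expression loss and splicing
loss; ρ isolates splicing.

**Junction support.** The published description of w leaves the estimator
open; this package concretizes it from exactly the quantities the
pipeline observes: for each intron *j* of *t*,

    s_j = a_j / (a_j + c_j + r_j)

with a_j the uniquely mapped reads spanning exactly *j*, c_j reads of any
other junction sharing j's donor or acceptor coordinate, and r_j nonsplit
reads assigned to j's intron (zero when no per-intron coverage is
supplied). Only uniquely mapped reads count; junctions with fewer than 5
supporting reads are discarded before scoring. w_t aggregates s_j across
introns with a **minimum** (default): one fully aberrant junction zeroes
the transcript, which is the correct behavior for a homozygous splice
defect. A product rule is available (`combine="product"`) and the choice
is echoed in output metadata. Two conventions matter:

* *No local evidence ⇒ s_j = 1.* Genes expressed below junction-detection
  depth are not splicing outliers by fiat; their low abundance is exactly
  what the α score measures.
* *Unexpressed gene ⇒ ρ = 0 with a `not_expressed` flag* rather than
  undefined, so β stays computable and reports can separate "not
  expressed" from "all aberrant".

Junction-to-intron matching is exact-coordinate only (two-pass aligners
emit exact junctions; fuzzy matching would hide genuine shifts).

**Baselines and scores.** Controls (RIN ≥ 8.0; patients require RIN ≥
6.0, both strict) yield per-gene second-percentile baselines ω_g(k),
ρ_g(k), computed with linear interpolation between closest ranks
(nearest-rank available; the method is recorded in metadata). The same
percentile q is applied to ω and ρ. A gene absent from a control
contributes ω = 0 there. Patient scores are

    α_g(i) = ω_g(k) / (ω_g(i) + ε),   β_g(i) = ρ_g(k) / (ρ_g(i) + ε),   ε = 0.001.

**Selection.** Candidate iff (α ≥ 3.0 or β ≥ 3.0) and patient *i* is the
strict **maximum** of α among same-tissue patients. The second criterion
exists to suppress genes aberrant in every patient (systematic
artifacts); the printed form of the rule has the opposite inequality,
which would demand every other patient be a stronger outlier and
contradicts the rule's purpose, so the maximum direction is the default
and `cross_patient="printed"` reproduces the printed direction verbatim.
Ties reject the gene for all tied patients. The criterion gates on α
only (β-gating is not applied). Ranks (1 = largest) are assigned per
patient within the candidate set for α and β separately, ties broken
lexicographically on gene id; reports order by max(α, β).

**Autozygome filter.** A candidate survives iff its gene span overlaps a
run-of-homozygosity interval by ≥ 1 bp (containment mode available). A
missing or empty ROH set passes all candidates through with a warning —
the filter only applies where mapping data exist.

**Control-tissue matching.** Among candidate control sets, the one whose
per-gene median ω vector maximizes Spearman correlation with the patient
profile is selected (Pearson on log1p available). Spearman is the default
because expression is heavy-tailed and only the ranking needs to be
faithful. Fewer than 10 shared genes is refused.

## Variant classification

Positions are classified per transcript and aggregated with
most-severe-wins, severity a > b > c > d > e > f. Within a transcript:
intronic positions with |offset| ≤ 2 are class a, all other intronic
positions class c; exon-terminal bases class b; exonic interior positions
class d (class e when CDS annotation places them in a UTR); positions up
to `promoter_window` (default 1000 bp) upstream of the most 5' TSS class
f. Intronic offsets are signed per the HGVS convention (+ from the donor,
− from the acceptor), assigned to the side with the smaller absolute
offset, ties to the donor. Class-c variants carry
`wes_capturable = |offset| ≤ 50`, the typical exome-capture intronic
flank. The HGVS path (`classify_hgvs`) handles intronic-offset strings
only and agrees with the coordinate path by construction (tested by
exhaustive scan of toy genes); non-intronic HGVS is refused toward the
coordinate path. Allele-frequency filtering keeps AF < 0.001 strictly;
records without AF pass flagged `AF_unknown`. Class precedence within a
family: a/b always considered; c/d/e/f only when no a/b TDV and no
alternate candidate exists. The classifier is purely positional:
protein-truncating exclusions are a cohort-bookkeeping flag, not a
classifier decision.

## Cohort statistics

`tally_fraction` computes 100·|num ∧ den|/|den| with half-up rounding at
the requested decimals; a zero denominator is an explicit error.
`class_breakdown` reports per-class counts and shares — half-up at one
decimal for shares ≥ 1%, two decimals *truncated* for sub-percent classes
so rare classes are never overstated. Expression tallies are emitted both
counting and not counting "poorly expressed" as expressed. In-silico
concordance is sensitivity only (tools evaluated on RT-PCR-aberrant
records they actually tested); tool scores are ingested as labels, never
recomputed.

## Synthetic data

The generator emulates the statistical structure of a bulk RNA-seq
diagnostic cohort, not its sequence content:

* **Gene models.** Non-overlapping genes on one chromosome (coordinates
  < 2³¹), 1–4 transcripts each, exon counts 1–8, exons 80–300 bp, introns
  200–2000 bp; alternative isoforms skip one internal exon (or drop the
  second of two). CDS annotations leave 10 bp UTR at each end.
* **Expression.** Per-gene means lognormal (log-mean 5.0 ≈ 150 CPM,
  log-sd 1.0) drawn once per seed and shared by controls and patients;
  isoform shares Dirichlet(8, 1, …) so the canonical isoform carries ~80%
  of the gene, as is typical of expressed genes; per-sample lognormal
  noise (log-sd 0.1, the tight within-tissue variation a homogeneous
  control set is chosen for).
* **Junctions.** Unique-read support is Poisson with mean
  `reads_per_cpm × (CPM of isoforms carrying the junction)`,
  reads_per_cpm = 0.2; all generated junctions are annotated.
* **Aberrations** (one per carrier, severity = fold reduction > 1):
  *exon_skip* moves fraction 1 − 1/severity of both flanking junctions'
  reads onto a novel unannotated skip junction; *low_abundance* divides
  the gene's counts (and junction reads) by severity; *intron_retention*
  adds nonsplit reads sized to (severity − 1)× the junction's support.
  The causal gene is drawn among genes expressed ≥ 50 CPM; for splicing
  aberrations it must additionally offer an event that touches every
  isoform (a skip whose flanking introns occur in all isoforms, or an
  intron shared by all isoforms) and have a dominant-isoform share ≥
  0.75 — i.e. a gene whose control splicing baseline is clean enough
  that a defect of the stated severity is detectable at all, mirroring
  how real positive controls are chosen.
* **ROH.** One interval covering the causal gene (±2 kb) plus decoy
  intervals placed strictly between genes.

All randomness flows through `numpy` generators keyed on the single
config seed; identical seeds give byte-identical outputs (including the
GTF serialization).

What the generator does **not** model: read-level artifacts (mappability,
GC, positional bias), multimapping, cross-isoform quantification error,
batch effects between patient and control cohorts, partially penetrant
or tissue-specific splicing defects, and background splicing noise in
controls. Passing recovery tests therefore demonstrate the correctness
and sensitivity of the scoring machinery under the stated noise model,
not the false-positive behavior expected on real data, where candidate
lists before autozygome filtering are much longer.

## Problem sizes and numerical choices

The recovery experiment runs 100 seeded cohorts of 500 genes, 30
controls, and 7 patients at severity 5 — large enough that baseline
percentiles are meaningful and the cross-patient criterion has bite,
small enough that the full experiment completes in about a minute.
Percentile computation delegates to `numpy.percentile`; score formulas
are closed-form and tested against brute-force re-derivations to 1e-12
relative. Junction evidence is dict-indexed (exact key, per-donor and
per-acceptor totals), making ω computation O(introns) per transcript.
Chromosome names are normalized by stripping `chr` (configurable);
features outside chromosomes 1–22/X are dropped by default on GTF load.

## Known limitations

* w_t's aggregation (min vs product) is a modeling choice the source
  data cannot distinguish; both are implemented, min is default.
* Competing *annotated* junctions (real alternative splicing) depress
  s_j and hence ρ below 1 even in controls; the baseline absorbs this,
  but genes with highly balanced isoform usage have compressed dynamic
  range for splicing outliers.
* Class d cannot distinguish synonymous from missense consequences
  without CDS-frame annotation; none is attempted.
* Enhancer (class f beyond the promoter window) classification requires
  a user-supplied interval file; none is bundled.
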