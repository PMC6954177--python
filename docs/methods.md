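# Methods

This note documents the models, parameter choices, and numerical decisions
behind each analysis arm, and what the synthetic data does and does not
establish about behaviour on real patient data.

## Repertoire statistics

A repertoire sample is a clonotype → template-count table; frequencies are
counts over the sample total. Shannon entropy uses the natural logarithm by
default (a `base` argument gives bits); terms with zero frequency are
omitted. Entropy is only comparable across samples at equal depth, so
cross-sample comparisons use the median entropy of repeated
without-replacement subsamples — a multivariate hypergeometric draw from the
count table — at the minimum total across the samples being compared.
Defaults: 1000 replicates, explicit integer seed. The median is insensitive
to the occasional extreme subsample; 1000 replicates put the Monte-Carlo
error of the median well below the between-timepoint differences of
interest at the depths used here (≥ ~10⁴ templates).

The overlap index is Morisita–Horn on relative abundances. The
count-based classic Morisita estimator behaves almost identically at these
depths, but Morisita–Horn is exactly bounded in [0, 1], reaches exactly 1
for identical composition regardless of depth, and is the standard choice
for repertoire overlap; it is therefore the package's default and only
variant.

Competition ("1224") ranking is used for clone ranks; tied counts share the
minimum rank of their block. Ranks above the cap (default 100) are reported
as cap + 1, which is also the sentinel for clonotypes absent from a sample
when tracking across timepoints (with frequency 0). Membership ties at the
top-N boundary break lexicographically by clonotype id so outputs are
deterministic.

Input tables are assumed pre-filtered to productive rearrangements; a
`productive` column, when present, is honoured and non-productive rows
dropped.

## Absolute clone counts and kinetic patterns

A clone's absolute blood count is its clonotype frequency times the
measured absolute CD8⁺ CAR-T count for that day (cells/µl). Day 0 has no
measurement; the model assumes the infused dose distributes uniformly
through the patient's blood volume, estimated as weight × 65 ml/kg (women)
or 75 ml/kg (men), with the clone's share given by its infusion-product
frequency. The ml → µl factor of 1000 is explicit in the code; all counts
are cells/µl.

The three observed kinetic regimes are defined visually in the source
material, so the classifier makes the rule explicit. With fold threshold
*f* (default 2, exposed as a flag) on a track (day 0, early, late):
increasing ⇔ early > day0·*f* and late ≥ early; transient ⇔ early > day0·*f*
and late < early/*f*; decreasing ⇔ early ≤ day0/*f*; otherwise
indeterminate. Longer tracks classify on (first, second, last). The rule is
scale invariant, so it applies equally to frequency tracks when the total
CAR-T count is stable; when the total count itself contracts sharply,
frequency-increasing clones can legitimately classify as transient in
absolute units (the demo dataset shows this). Tracked clones are the union
of the top-30 of the infusion product and of every post-infusion sample,
an interpretation chosen because each sample's dominant clones are of
interest regardless of where they ranked elsewhere.

## Integration-site clone calling

Reads are LTR + genomic fragment + linker. Identity is everywhere defined
as matched columns / aligned columns with gap columns counting as
mismatches. The stage thresholds (LTR ≥ 0.90 to keep, vector ≥ 0.80 to
discard, alignment length ≥ 30 and alignment start ≤ 10 to keep, secondary
alignments kept within 0.95 of the top score, rescue/merge at ≥ 0.90,
multi-align-ratio ≥ 0.9 as the multi-mapped criterion, ribbon threshold 1%,
fold-change threshold 5) are all exposed on `IsaParams` and the CLI.
Boundary semantics follow the filter definitions: identity exactly 0.90
passes the LTR filter, exactly 0.80 fails the vector filter, length 30 and
start 10 pass the alignment filter.

*LTR filter.* The whole LTR is fitted inside the read (end-gap-free on the
read side) with edlib; the matched span is trimmed. When a linker sequence
is supplied, a linker hit at ≥ 80% identity downstream of the LTR is
trimmed as well, leaving the genomic insert.

*Vector filter.* Best-scoring local alignment of the insert against the
vector (match +1, mismatch −1, gap open −2, extend −1). A bare local
alignment can produce a tiny perfect-identity span by chance, so the reject
rule additionally requires the aligned span to reach 30 columns — the same
floor the genome-alignment length filter uses.

*Genome alignment.* A k-mer seed index (k = 11, genome stride 5, mirroring
BLAT-style tile/step settings) with over-represented k-mers masked by an
occurrence cap (64 at toy-genome scale, standing in for genome-wide repeat
masking); seed diagonals group into banded candidate windows resolved by
Smith–Waterman extension. Both orientations are searched. The reported
locus is the genomic base pairing with the *first insert base* — the
vector–genome junction — extrapolated from the alignment ends when the
first bases did not align, which makes the locus robust to substitutions at
the junction. Coordinates are 0-based half-open internally and 1-based in
all reports (`chr1_8020175_+` style).

*Grouping and consensus.* Reads sharing an identical alignment-site set
form a group (multi-mapped reads group by their full set). The consensus is
a centre-star multiple alignment around the most frequent member sequence
(ties to the lexicographically smallest) with weighted per-column majority
vote, ties resolved to the centre's base; insertions relative to the centre
are ignored and a majority deletion removes the column. This is exact for
substitution-dominated error, which is the generator's default; the
optional indel rate stresses it only mildly at the 1% level.

*Rescue and merging.* Sequence similarity between junction-anchored
fragments is judged by prefix-anchored identity: the shorter sequence is
aligned end-gap-free against the longer and identity taken over that span.
Fragments from one site share their start but end wherever the linker
ligated, so strict global identity would penalise pure length differences
and leave junction artifacts unmerged; prefix identity is the package's
deliberate choice here. Unaligned reads are rescued into the best-identity
group at ≥ 90% (group counts grow; the consensus is not rebuilt — a
rescued read is by construction within 10% of it). Groups then merge in
four ordered passes: (1) ≥ 90% consensus similarity, comparing
highest-count against lowest-count groups; (2) exact alignment-set match
across samples; (3) exact consensus match; (4) multi-mapped groups
(multi-align-ratio ≥ 0.9) with ≥ 90% similar consensus. Merged counts sum
and the representative locus/consensus come from the higher-count member.
All processing orders are (read count descending, then lexicographic), so
the output is invariant to input read order.

*Reporting.* Per-sample clone frequency is the clone's reads over all
clone-assigned reads in that sample. Clones reaching 1% in at least one
sample of a subject get their own ribbon; the rest pool into "other".
Exon/intron/intergenic annotation is strand-agnostic interval lookup
against a BED12 gene model. Fold-change lists use the ratio of post to
infusion-product frequency; a frequency of zero is replaced by half the
smallest nonzero frequency in that sample (or an explicit pseudo-frequency),
so sites absent from one sample can still satisfy the ≥ 5-fold rule without
dividing by zero.

## Single-cell QC and clonotype fate

QC keeps a cell iff detected genes ≥ 200, mitochondrial fraction ≤ 20%,
and UMIs ≤ 40,000; the filter is idempotent and cells without a clonotype
are kept for QC accounting but excluded from fate testing. Fate testing
uses cell counts (not UMI-weighted counts): for each clonotype observed at
either timepoint, a 2×2 table of (clonotype cells, other cells) × (infusion
product, early) is tested with a two-sided Fisher exact test; two-sided is
the conservative choice since no direction is privileged a priori, with
the IRF/DRF direction assigned post hoc from the proportion difference.
Benjamini–Hochberg runs across the clonotypes of one patient (patients are
analysed separately). "Detected" at a later timepoint means ≥ 1 QC-passing
cell carries the clonotype; persistence percentages are
round(100·detected/total), reported as NA (never 0) for an empty label
class. Cluster attribution and detected/not-detected cluster composition
are cell-fraction tables that sum to 1 within each label or partition.

## Synthetic data

The generators emulate exactly the structure the analyses assume, with one
global seed split into independent `SeedSequence` streams:

* **Repertoire timeline** — baseline clone frequencies ∝ rank^(−α)
  (default α = 1), reproducing a heavy-tailed repertoire; each timepoint is
  an independent multinomial draw at the configured depth, so counts sum
  exactly to depth. Planted clones multiply their baseline frequency by
  fold^t (increasing), fold^(−t) (decreasing), or rise to the early
  (second) timepoint and decay symmetrically (transient: multipliers 1, f,
  1, 1/f over four timepoints, matching the early-peak kinetics of CAR-T
  expansion); the vector renormalises each timepoint.
* **ISA reads** — sites drawn uniformly (margin = max fragment length from
  chromosome ends), '+' sites reading rightward and '−' sites leftward
  along the reverse complement; Poisson read counts clipped below at a
  minimum; i.i.d. substitutions (indels optional, off by default); a
  configurable fraction of contaminant reads carry a vector fragment
  instead of a genomic one. Default conditions: 100 kb genome, 50 sites,
  mean 20 / minimum 5 reads per site, fragments 60–150 bp, 1% substitution
  when noise is wanted.
* **Cell table** — per-timepoint cells draw their clonotype from the
  timeline's true frequencies; infusion-product cells of planted expanding
  clonotypes land in designated clusters (default 2 and 4 of 4) with
  probability `irf_cluster_bias` (default 0.85), other cells follow the
  cluster mixture; a configurable fraction of cells violate exactly one QC
  gate. QC scalars are otherwise uniform draws inside the passing region —
  they are placeholders for the gates, not a model of expression.

What passing tests therefore show: the statistics are computed correctly,
the clone caller recovers planted truth under substitution-type error at
realistic coverage, and the fate test is calibrated under the null and
sensitive to 8-fold expansions at 2000 cells per timepoint. What they do
not show: robustness to V(D)J sequencing artefacts, UMI chemistry, PCR
bias in integration-site read counts, genome-scale repeat structure, or
doublets/ambient RNA — none of which the generators model.

## Problem sizes and determinism

The test and acceptance workloads are sized for a single CPU: 100 kb
genome with ~1000 reads for clone calling, depths of 10⁴–10⁵ templates for
repertoire work, 2000 cells per timepoint and 500 clonotypes for fate
calibration, 40 seeds × 50 downsampling replicates for the
entropy-decline check. Every stochastic step takes an explicit seed;
fixed seed ⇒ byte-identical generator output and pipeline results, and the
CLI records seed, parameters, and input checksums in `manifest.json`.

## Known limitations

* The centre-star consensus ignores insertions relative to the centre
  read; at indel rates well above ~1% consensus quality degrades.
* The seed index requires one exact 11-mer hit; inserts shorter than ~15 bp
  of clean sequence (or saturated with errors) fall to the unaligned pool
  and are recovered only by consensus rescue.
* Day-0 absolute counts inherit the uniform-distribution-in-blood
  assumption; real early trafficking (margination, tissue homing) is not
  modelled.
* The fate test treats cells as independent draws; it ignores within-clone
  correlation induced by, e.g., cell-cycle bursts.
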