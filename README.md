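# clonekin

Clonal kinetics of CD19 CAR-T cells, at desk scale.

After a patient is infused with chimeric antigen receptor (CAR) T cells,
individual clones expand, contract, or vanish from the blood. This package
implements the clonotype-resolved analyses used to characterise that
behaviour — for computational immunologists who have clonotype count tables,
integration-site sequencing reads, or single-cell V(D)J calls and want a
tested, reproducible pipeline rather than a pile of notebook cells:

* **Repertoire diversity and overlap** (`clonekin.repertoire`). For a sample
  with clonotype frequencies *p*ᵢ: Shannon entropy *H* = −Σ *p*ᵢ ln *p*ᵢ,
  compared across unequal sequencing depths by downsampling each sample 1000×
  to the common minimum depth and taking the median entropy; the
  Morisita–Horn overlap *C* = 2Σ*p*ᵢ*q*ᵢ / (Σ*p*ᵢ² + Σ*q*ᵢ²) between two
  samples (0 = disjoint, 1 = identical composition); top-N clonotype
  fractions and capped competition ranks for clone tracking.
* **Absolute clone-count kinetics** (`clonekin.kinetics`). Clone frequency ×
  absolute CD8⁺ CAR-T count (cells/µl) gives the clone's blood count; at day 0
  the infused dose is spread over the estimated blood volume
  (weight × 65 ml/kg for women, × 75 ml/kg for men). Tracks over
  (day 0, early, late) are classified as *increasing*, *transient*, or
  *decreasing* with an explicit 2-fold rule.
* **Integration-site clone calling** (`clonekin.isa`). LTR-junction reads are
  filtered (≥ 90% LTR identity, < 80% vector identity), aligned to the genome
  with a k-mer-seeded Smith–Waterman aligner (alignment length ≥ 30,
  alignment start ≤ 10, secondary alignments kept within 95% of the top
  score), grouped by alignment set with majority-vote consensus, rescued and
  merged at ≥ 90% identity, and reported as clones with per-sample
  frequencies, ≥ 1% ribbon tables, exon/intron/intergenic annotation, and
  ≥ 5-fold expanded/contracted site lists.
* **Single-cell clonotype fate** (`clonekin.scfate`). Cells are QC-filtered
  (≥ 200 genes, ≤ 20% mitochondrial, ≤ 40,000 UMIs); each clonotype's cell
  counts in the infusion product vs the early timepoint are tested with a
  two-sided Fisher exact test, Benjamini–Hochberg corrected at FDR 5%, and
  labelled IRF (increased relative frequency) or DRF (decreased); labels are
  linked to infusion-product transcriptional clusters and to persistence at
  later timepoints.
* **Synthetic data** (`clonekin.simdata`). Seeded generators produce
  power-law repertoires with planted clone dynamics, LTR+fragment+linker
  reads from a toy genome with substitution errors and vector contaminants,
  and cell tables with cluster-biased expanding clones — so every stage is
  testable without any patient data.

## Worked example

```bash
clonekin all --seed 7 --out demo/
```

simulates a four-timepoint dataset (500 clonotypes, 10 each planted
increasing/transient/decreasing at 4-fold per step; 50 integration sites in a
100 kb toy genome at 1% substitution error with 5% vector contaminants;
2000 cells per timepoint) and runs every arm. The run prints:

```
wrote demo dataset to demo/data
wrote repertoire metrics for 4 timepoints to demo/repertoire
classified 41 clone tracks -> demo/kinetics/clone_tracks.tsv
called 50 clones from 1030 reads (0 LTR-rejected, 54 vector-rejected, 0 rescued) -> demo/isa
QC removed 175 cells; tested 433 clonotypes, 12 labelled IRF/DRF -> demo/scfate
```

`demo/repertoire/repertoire_metrics.tsv` shows diversity falling after
infusion as the planted expansions take over the repertoire — median
downsampled entropy drops from 4.73 (infusion product) through 4.66 (early)
and 4.10 (late) to 3.18 (very late), while the top-10 clonotype fraction
rises from 0.43 to 0.81:

```
timepoint   total_templates  richness  entropy  median_downsampled_entropy  top10_fraction
IP          30000            500       4.7390   4.7297                      0.4329
early       25000            500       4.6693   4.6634                      0.3640
late        20000            496       4.1092   4.1044                      0.5450
very_late   15000            406       3.1843   3.1843                      0.8094
```

All 50 planted integration sites are recovered at their exact locus and
strand (`demo/isa/clones.tsv`, positions 1-based), and all 54 vector
contaminant reads are removed by the vector filter:

```
clone_id                chromosome  position  strand  multi_align_ratio  read_count
clone0001_chr1_18986_+  chr1        18986     +       0.0                36
clone0002_chr1_11949_+  chr1        11949     +       0.0                32
...
```

The fate analysis labels 11 clonotypes IRF and 1 DRF; the IRF clones sit
overwhelmingly in the designated clusters 2 and 4 of the infusion product
(82% of their cells, vs the 50% those clusters hold overall), and 100% of
IRF clonotypes are still detected at the late timepoint
(`demo/scfate/persistence.tsv`):

```
label  timepoint  n_detected  n_total  percent
IRF    late       11          11       100
IRF    very_late  10          11       91
DRF    late       1           1        100
DRF    very_late  1           1        100
```

In `demo/kinetics/clone_tracks.tsv` the planted frequency-increasing clones
come out *transient* in absolute units — the demo patient's total CAR-T
count contracts 25-fold between day 10 and day 90, so even clones gaining
repertoire share transiently rise and then fall in cells/µl. Classifying
the (scale-invariant) frequency tracks instead recovers the planted labels.

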