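# Methods

## Scanning/reinitiation model

The generator treats post-termination 40S behaviour on a GCN4-like leader
as a race between scanning and ternary-complex (TC) re-acquisition.
Assumptions:

* TC re-acquisition is memoryless per nucleotide scanned, i.e. the
  distance scanned before re-acquisition is exponential with rate
  `lambda_tc / speed_factor` per nt. This is the minimal model consistent
  with the verbal mechanism ("more scanning distance → more time to bind a
  new TC") and makes every downstream probability closed-form.
* Resumption after uORF1 (`p_resume`) and after uORF4 (`p_reinit4`) are
  single Bernoulli events, independent of scanning kinetics.
* eIF4E enters only through `load_rate` (relative cap-dependent loading;
  scales occupancy, never kinetics); eIF4A enters only through
  `speed_factor` (divides the per-nt acquisition rate). This division of
  labour mirrors the biological proposal the model formalizes.
* Elongation on the uORFs and the main ORF is not modelled; footprint
  placement within an ORF is uniform over codons apart from a start-codon
  pile-up (below).

Parameters (defaults):

| parameter | meaning | default | why |
|---|---|---|---|
| `p_resume` | resume scanning after uORF1 | 0.5 | classical measurement for this leader |
| `p_reinit4` | resume after uORF4 | 0.01 | dissociation at uORF4 is near-complete |
| `lambda_tc` | TC acquisition rate (events/nt) | −ln(0.03)/350 ≈ 0.0100 | fixes baseline bypass at ≈3% over `d1` |
| `d1` | uORF1 stop → uORF4 start (nt) | 350 | leader-scale distance; configuration default, not a measured value |
| `d2` | uORF4 stop → main AUG (nt) | 150 | same status as `d1` |
| `speed_factor` | scanning-speed multiplier (eIF4A proxy) | 1 | baseline |
| `load_rate` | relative cap loading (eIF4E proxy) | 1 | baseline |

A Monte-Carlo walker (`monte_carlo_main_orf`) draws the same Bernoulli and
exponential events per ribosome and is the independent oracle for the
closed forms; agreement is tested at 3 binomial standard errors with
n = 10⁵ across random parameter draws. The bypass fraction is conditional
on resumption, so its standard error uses the resumed-subunit count.

**A speed-only ceiling.** Because faster scanning also suppresses TC
acquisition in the `d2` window, `P_main(speed)` has an interior optimum:
with the defaults above the occupancy fold over baseline peaks at ≈4.3
near `speed_factor ≈ 4.5` and declines beyond it. This is a genuine
prediction of the formalization (an over-accelerated subunit overruns the
main AUG unloaded), and it means monotonicity of `P_main` in
`speed_factor` holds only on the physiological grid (tested on
0.5–4); monotonicity in `d1` is global. Consequently the default
de-repressed condition (mutant at 37 °C) cannot reach the 8-fold occupancy
target through speed alone: it combines `speed_factor = 4` with a
focal-gene `load_rate` solved so the occupancy interaction equals exactly
8-fold. The biological reading is that a high-affinity leader retains a
disproportionate share of residual eIF4E-dependent loading when the factor
becomes limiting, on top of the scanning effect.

## Synthetic study design

`SimDesign` defaults mirror the study conditions: 2 strains × 2
temperatures; 2 RPF and 3 RNA replicates per condition (20 samples); 200
genes — 1 GCN4-like focal gene, 20 regulon genes, 30 heat-shock genes, 149
background genes; ≈2 × 10⁶ mean reads per sample; per-sample size factors
lognormal (σ = 0.15). Counts are negative binomial with per-class
dispersions: 0.05 (RNA) and 0.10 (RPF) for background/regulon/heat-shock
genes, and 0.005 for the focal gene — a highly expressed transcript whose
counts replicate tightly, which is also what makes a 2-replicate
interaction estimate meaningful for it. Planted effects: heat-shock genes
+2 log2 at 37 °C in both strains (interaction exactly 0); regulon genes
+1.5 log2 only in the mutant at 37 °C, applied to both assays
(transcriptional induction carries footprints along, TE unchanged); the
focal gene's RPF mean scaled by `P_main × load_rate` of the condition's
scanning parameters (8-fold interaction, RPF only, so its TE change is
3 log2).

Footprint simulation plants per-length 3′-end offsets (14–18 nt over
lengths 21–34), a Gaussian length distribution peaked at 28 nt, a 15%
start-codon pile-up per ORF (the feature that makes offset calibration
identifiable), and 5% ±1-nt frame jitter. uORF1 receives unit density,
uORF4 `p_resume·(1−B)`, the main ORF `P_main`.

What the generator does **not** emulate: nucleotide sequences and their
biases (ligation/PCR bias, codon-level pausing, Kozak context), rRNA/ncRNA
contamination, spliced yeast transcripts (the synthetic annotation is
single-exon; the readers and pseudo-A-site walker nevertheless handle
spliced reads and are tested on them), 40S-specific footprint sizes, and
any coupling between library size and condition. Passing tests therefore
certify the coordinate arithmetic, the estimators, and their calibration
under NB noise — not robustness to real-library artifacts.

## Coverage analyses

* Internal coordinates are 0-based half-open everywhere; GFF3/SAM are
  converted at the format boundary. The pseudo-A-site is the base at
  ordinal `(L−1)//2` from the fragment's 5′ end (the 5′-ward of the two
  central bases when L is even), walked through exonic blocks in
  transcript orientation — the 5′-weighted midpoint rule, applied in
  transcript orientation on the minus strand.
* Offset calibration histograms the 3′-end→CDS-start distances within a
  45-nt window (default) per fragment length; lengths need ≥100 supporting
  reads by default (both exposed as parameters); the modal distance wins
  and ties resolve to the smaller distance and are recorded.
* Feature counting requires ≥50% of the read's aligned length on the
  feature, strandedness enforced; a read split exactly 50/50 counts toward
  both adjacent features. Densities are length-normalized and
  CDS-relative; genes with zero CDS reads are marked undefined, never
  divided. Outliers are flagged at median ± 5·MAD per feature class
  (flag-not-drop); this replaces a proprietary robust-regression outlier
  filter and is the one deliberate divergence in this stage.
* Metagene profiles use genes with all three features ≥100 nt and ≥128 CDS
  reads, per-gene normalization by gene-wide mean coverage, and
  deterministic binning `bin(p) = floor(p·100/L)` into 100 bins per
  feature (300 total). Overlapping genes are dropped by default for
  metagene/density analyses (`unique_features`), not for counting.

## Differential stages

Size factors are median-of-ratios over genes nonzero in all samples,
computed per assay. Dispersion is per-gene pooled within-cell method of
moments on normalized counts, clipped to [10⁻⁴, 10]; there is no
empirical-Bayes trend shrinkage, and no LFC shrinkage — tests and the
acceptance checks use effect sizes and depths where shrinkage is
immaterial. The Wald test uses the normal approximation; with only 2
replicates per cell (RPF) it is visibly anticonservative (empirical
type-I ≈ 0.13 at nominal 0.05 under the default design), while with 3
replicates (RNA) it calibrates to ≈ 0.09; the calibration check therefore
targets the RNA design. TE is the difference of two per-assay interaction
fits rather than a single four-factor model, keeping both standard errors
explicit. BH correction is applied within each result list independently.
The regulon score's permutation null draws same-size gene sets without
replacement; permuted means tie the observed score within 10⁻¹² are
counted as hits, so the degenerate full-universe set gets p = 1.

## Assay formulas

Miller units implement `1000·(A420 − 1.75·A550)/(T·V·OD600)`; the
published rendering of the denominator contains a typeset artifact read
here as T × V × OD600, consistent with the stated units. Negative
activities (turbid blanks) are returned unclamped. Band fold changes use
Welch's unequal-variance t-test even where a plain unpaired test was
reported, since replicate variances are not forced equal.

## Problem sizes

Tests run the simulator at 40–200 genes and 5 × 10³–3 × 10⁴ reads per
stage, and Monte-Carlo checks at n = 10⁵, sizes at which every check
completes in seconds while keeping binomial/NB standard errors well inside
the asserted tolerances. The acceptance script uses the full default
design (200 genes, 2 × 10⁶ reads per sample).
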