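# riboflux

Ribosome-profiling and RNA-seq analysis of uORF-mediated translational
control, built around a mechanistic simulator of *GCN4*-style reinitiation.

Yeast *GCN4* (ATF4 in mammals) is translationally repressed by four upstream
open reading frames (uORFs) in its 5′ leader. After translating uORF1,
roughly half of the 40S subunits stay on the transcript and resume scanning;
whether they reinitiate at the inhibitory uORF4 (and dissociate) or bypass
it and translate the main ORF depends on how quickly they re-acquire
ternary complex (TC) while scanning the leader. Perturbations that deplete
the cap-binding factor eIF4E — or raise the relative concentration of the
scanning helicase eIF4A — can de-repress the main ORF without eIF2α
phosphorylation. This package provides the complete quantitative toolchain
for studying that regulation with sequencing and reporter data:

* **coverage QC** — per-length 3′-end offset calibration against annotated
  CDS starts, 3-nt frame statistics, pseudo-A-site assignment (5′-weighted
  fragment midpoint), feature densities, and 100-bin-per-feature metagene
  profiles;
* **differential analysis** — negative-binomial interaction contrasts
  (strain × temperature), translational efficiency (TE), regulon scoring,
  and transcript-feature correlations;
* **assay formulas** — Miller units, ΔΔCt, dual-luciferase ratios, and
  loading-control band normalization;
* **a synthetic-data generator** whose ground truth drives every test.

It is aimed at computational biologists who want a desk-scale, fully
verifiable implementation of these procedures rather than a cluster
pipeline: alignments are SAM/BED text, annotations GFF3, matrices TSV.

## The models

**Scanning/reinitiation.** A post-uORF1 40S resumes scanning with
probability `p_resume` and re-acquires TC memorylessly at rate
`λ/s` per nucleotide (`s` = scanning-speed factor, the eIF4A proxy).
With `d1` the uORF1→uORF4 distance and `d2` the uORF4→main-AUG distance:

```
B      = exp(−λ d1 / s)                      (bypass uORF4)
A2     = 1 − exp(−λ d2 / s)                  (acquire TC before the main AUG)
P_main = p_resume · [ B·A2 + (1−B)·p_reinit4·A2 ]
```

Ribosome occupancy of the main ORF is `P_main × load_rate`, where
`load_rate` (the eIF4E proxy) scales cap-dependent loading. A Monte-Carlo
walker implementing the same per-ribosome rules serves as an independent
oracle for the closed forms.

**Interaction contrast.** For each gene, counts follow a NB log-linear
model `count ~ strain + temperature + strain:temperature` with
median-of-ratios size-factor offsets. The interaction coefficient is the
37 °C mutant/wild-type ratio normalized by the 25 °C ratio — it cancels the
heat-shock response shared by both strains and isolates the eIF4E-depletion
effect. TE changes are the difference of the RPF and RNA interaction
coefficients, with standard errors combined in quadrature.

## Worked example

```python
from riboflux import (SimDesign, simulate_counts, fit_interaction,
                      translational_efficiency)

exp = simulate_counts(SimDesign(seed=1))          # 200 genes, 20 samples
rpf = fit_interaction(exp.counts, exp.sheet, "RPF")
rna = fit_interaction(exp.counts, exp.sheet, "RNA")
te  = translational_efficiency(rpf, rna)
print(f"{2 ** rpf.loc['g000', 'lfc_interaction']:.2f}-fold occupancy interaction")
print(f"{te.loc['g000', 'lfc_te']:.2f} log2 TE change")
```

prints

```
7.91-fold occupancy interaction
3.19 log2 TE change
```

`g000` is the GCN4-like gene; the generator planted an 8-fold
ribosome-occupancy interaction (3 log2, RPF-only) through the scanning
model, so both recoveries are within estimator noise of the truth.

## Analysis drivers

The `analysis/` scripts run the full study end to end and write plain-text
tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_data.py` | generate counts, annotation, demo SAM, ground-truth JSON |
| `02_coverage_qc.py` | offset/frame calibration, feature densities, metagene, uORF→main-ORF density shift |
| `03_differential_te.py` | interaction fits, TE, regulon score, feature correlations |
| `04_assays.py` | reporter-assay arithmetic on synthetic replicates |

For example, `02_coverage_qc.py` recovers every planted fragment-length
offset with a 0.95 frame-0 fraction, and shows the main-ORF/uORF4
pseudo-A-site density ratio rising from 0.037 (repressed scanning) to 0.259
when scanning is 4× faster.

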