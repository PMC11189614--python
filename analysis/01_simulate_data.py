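#!/usr/bin/env python
"""Generate the synthetic study: annotation, footprints, counts, ground truth.

The simulated experiment mirrors the study design: wild-type and
eIF4E-mutant strains at 25C and 37C, 2 ribosome-profiling and 3 RNA-seq
replicates per condition, 200 genes including a GCN4-like transcript with
four uORFs, a 20-gene co-regulated regulon, and 30 heat-shock genes
induced equally in both strains.  Everything is written as plain text
under results/sim/.
"""

from pathlib import Path

from riboflux import SimDesign, simulate_counts, simulate_footprints
from riboflux.io import write_counts, write_gff3, write_sam, write_sample_sheet
from riboflux.simulate import gcn4_like_model, simple_model, write_ground_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)

design = SimDesign(seed=1)
experiment = simulate_counts(design)

write_counts(experiment.counts, OUT / "counts.tsv")
write_sample_sheet(experiment.sheet, OUT / "sample_sheet.tsv")
write_ground_truth(experiment, OUT / "ground_truth.json")

# a small genome-level annotation: the GCN4-like gene plus three plain genes
focal = gcn4_like_model(gene_id="g000", offset=1000)
background = [simple_model(f"g{i:03d}", "chrI", 4000 + 2000 * i) for i in (1, 2, 3)]
write_gff3([focal] + background, OUT / "annotation.gff3", chrom_lengths={"chrI": 12000})

# demo footprint alignments for the repressed condition (500 reads, SAM text)
reads = simulate_footprints(focal, design.scan_params["WT25"], 500, seed=1,
                            sample_id="RPF_WT_25_r1")
write_sam(reads, OUT / "footprints_demo.sam", {"chrI": 12000})

print(f"wrote {experiment.counts.shape[0]} genes x {experiment.counts.shape[1]} samples")
print(f"focal-gene truth: RPF interaction "
      f"{2 ** experiment.true_interaction_lfc.loc['g000', 'RPF']:.1f}-fold, "
      f"RNA interaction {2 ** experiment.true_interaction_lfc.loc['g000', 'RNA']:.1f}-fold")
print(f"outputs in {OUT}")
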