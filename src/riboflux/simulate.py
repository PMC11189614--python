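"""Mechanistic synthetic data: mini-transcriptome, footprints, count matrices.

The generator embeds one GCN4-like transcript (four uORFs in a long 5'
leader, main-ORF occupancy governed by the scanning/reinitiation model in
:mod:`riboflux.scanmodel`) in a configurable mini-transcriptome together
with a co-regulated regulon class and temperature-responsive genes induced
equally in both strains.  Every downstream stage therefore has ground
truth: planted per-length 3'-offsets for the calibration round-trip,
planted interaction log-fold-changes for the differential stages.

Default study conditions: 2 strains x 2 temperatures, 2 RPF + 3 RNA
replicates, footprints 21-34 nt with 3-nt CDS periodicity, focal-gene
ribosome-occupancy interaction fold of 8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import AlignedRead, GenomicInterval, TranscriptModel
from .scanmodel import (
    ScanParams,
    bypass_probability,
    main_orf_initiation_probability,
    occupancy,
    solve_load_rate_for_fold,
)

CONDITIONS = ("WT25", "WT37", "MUT25", "MUT37")

#: Default planted 3'-end offsets per footprint length (nt).  Roughly the
#: A-site sits ~15-18 nt from the 3' end depending on digestion extent.
DEFAULT_OFFSETS = {L: 14 + (L - 21) // 3 for L in range(21, 35)}

#: Default footprint length distribution over 21-34 nt, peaked at 28.
def default_length_dist() -> dict[int, float]:
    lengths = np.arange(21, 35)
    w = np.exp(-0.5 * ((lengths - 28) / 2.5) ** 2)
    w /= w.sum()
    return dict(zip(lengths.tolist(), w.tolist()))


@dataclass
class SimDesign:
    """Design of the simulated experiment (desk-scale mirror of the study)."""

    n_genes: int = 200
    regulon_gene_count: int = 20
    heatshock_gene_count: int = 30
    replicates: dict = field(default_factory=lambda: {"RPF": 2, "RNA": 3})
    dispersion: dict = field(default_factory=lambda: {
        "background": {"RNA": 0.05, "RPF": 0.10},
        "regulon": {"RNA": 0.05, "RPF": 0.10},
        "heatshock": {"RNA": 0.05, "RPF": 0.10},
        "focal": {"RNA": 0.005, "RPF": 0.005},
    })
    seed: int = 1
    mean_depth: float = 2e6
    scan_params: dict = field(default_factory=dict)  # condition -> ScanParams
    heatshock_temp_lfc: float = 2.0
    regulon_interaction_lfc: float = 1.5
    focal_interaction_fold: float = 8.0
    size_factor_sigma: float = 0.15

    def __post_init__(self) -> None:
        if min(self.n_genes, self.regulon_gene_count, self.heatshock_gene_count) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.regulon_gene_count + self.heatshock_gene_count + 1 > self.n_genes:
            raise ValueError("gene classes exceed n_genes")
        for assay, n in self.replicates.items():
            if n < 1:
                raise ValueError(f"assay {assay}: need at least one replicate per cell")
        if not self.scan_params:
            base = ScanParams()
            mut37 = solve_load_rate_for_fold(
                base, replace(base, speed_factor=4.0), self.focal_interaction_fold
            )
            self.scan_params = {"WT25": base, "WT37": base, "MUT25": base, "MUT37": mut37}

    def gene_classes(self) -> pd.Series:
        """Class label per gene; gene g000 is the GCN4-like focal gene."""
        ids = [f"g{i:03d}" for i in range(self.n_genes)]
        cls = ["background"] * self.n_genes
        cls[0] = "focal"
        for i in range(1, 1 + self.regulon_gene_count):
            cls[i] = "regulon"
        for i in range(1 + self.regulon_gene_count,
                       1 + self.regulon_gene_count + self.heatshock_gene_count):
            cls[i] = "heatshock"
        return pd.Series(cls, index=ids, name="gene_class")

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for assay, nrep in sorted(self.replicates.items()):
            for strain in ("WT", "MUT"):
                for temp in (25, 37):
                    for rep in range(1, nrep + 1):
                        rows.append({
                            "sample_id": f"{assay}_{strain}_{temp}_r{rep}",
                            "assay": assay, "strain": strain,
                            "temperature": temp, "replicate": rep,
                        })
        return pd.DataFrame(rows)


@dataclass
class SimulatedExperiment:
    """Counts plus the ground truth the generator planted."""

    counts: pd.DataFrame
    sheet: pd.DataFrame
    gene_classes: pd.Series
    true_interaction_lfc: pd.DataFrame  # genes x {RPF, RNA}, log2
    true_size_factors: pd.Series
    design: SimDesign


def _condition_multiplier(design: SimDesign, gene_class: str, assay: str,
                          strain: str, temp: int) -> float:
    """Designed mean multiplier for one design cell relative to WT25."""
    mult = 1.0
    if gene_class == "heatshock" and temp == 37:
        mult *= 2.0 ** design.heatshock_temp_lfc
    if gene_class == "regulon" and strain == "MUT" and temp == 37:
        # transcriptional induction downstream of focal-gene de-repression:
        # carries both mRNA and footprints, TE unchanged
        mult *= 2.0 ** design.regulon_interaction_lfc
    if gene_class == "focal" and assay == "RPF":
        cond = f"{strain}{temp}"
        mult *= occupancy(design.scan_params[cond]) / occupancy(design.scan_params["WT25"])
    return mult


def true_interaction_lfc(design: SimDesign) -> pd.DataFrame:
    """Planted strain x temperature interaction (log2) per gene and assay."""
    classes = design.gene_classes()
    out = {}
    for assay in design.replicates:
        vals = []
        for cls in classes:
            m = {f"{s}{t}": _condition_multiplier(design, cls, assay, s, t)
                 for s in ("WT", "MUT") for t in (25, 37)}
            vals.append(np.log2((m["MUT37"] / m["MUT25"]) / (m["WT37"] / m["WT25"])))
        out[assay] = vals
    return pd.DataFrame(out, index=classes.index)


def simulate_counts(design: SimDesign) -> SimulatedExperiment:
    """Draw a negative-binomial genes x samples count matrix from the design.

    count_gs ~ NB(mean = sizefactor_s * depth * share_g * multiplier(cell),
    per-class dispersion); the focal gene's RPF share is scaled by
    occupancy (initiation probability x load rate) for the cell's
    ScanParams.  Fixed seed fixes the output byte for byte.
    """
    rng = np.random.default_rng(design.seed)
    classes = design.gene_classes()
    sheet = design.sample_sheet()

    # baseline relative expression, shared across assays; focal gene pinned
    # to a solidly expressed level so the repressed state still yields counts
    q = rng.lognormal(mean=0.0, sigma=1.2, size=design.n_genes)
    q[0] = 3.0
    size_factors = pd.Series(
        np.exp(rng.normal(0.0, design.size_factor_sigma, size=len(sheet))),
        index=sheet["sample_id"].to_numpy(), name="true_size_factor",
    )

    counts = np.zeros((design.n_genes, len(sheet)), dtype=np.int64)
    share = {assay: q / q.sum() for assay in design.replicates}
    for j, row in sheet.iterrows():
        assay, strain, temp = row["assay"], row["strain"], int(row["temperature"])
        sf = size_factors.iloc[j]
        for g in range(design.n_genes):
            cls = classes.iloc[g]
            mu = (sf * design.mean_depth * share[assay][g]
                  * _condition_multiplier(design, cls, assay, strain, temp))
            alpha = design.dispersion[cls][assay]
            if alpha <= 0:
                counts[g, j] = rng.poisson(mu)
            else:
                n_nb = 1.0 / alpha
                p_nb = n_nb / (n_nb + mu)
                counts[g, j] = rng.negative_binomial(n_nb, p_nb)

    matrix = pd.DataFrame(counts, index=classes.index, columns=sheet["sample_id"])
    matrix.columns.name = None
    return SimulatedExperiment(
        counts=matrix, sheet=sheet, gene_classes=classes,
        true_interaction_lfc=true_interaction_lfc(design),
        true_size_factors=size_factors, design=design,
    )


# ---------------------------------------------------------------------------
# Mini-transcriptome and footprint-level simulation
# ---------------------------------------------------------------------------

def gcn4_like_model(chrom: str = "chrI", offset: int = 1000, strand: str = "+",
                    utr5_len: int = 600, cds_len: int = 843, utr3_len: int = 200,
                    gene_id: str = "g000") -> TranscriptModel:
    """A GCN4-like transcript: long leader with 4 short uORFs, then the main ORF.

    uORF1 sits near the cap, uORF4 ~350 nt downstream (start to start), and
    the main AUG a further ~150 nt past the uORF4 stop, mirroring the
    default ScanParams distances.
    """
    if strand != "+":
        raise NotImplementedError("the built-in focal model is plus-strand")
    utr5 = GenomicInterval(chrom, offset, offset + utr5_len, strand)
    cds = GenomicInterval(chrom, utr5.end, utr5.end + cds_len, strand)
    utr3 = GenomicInterval(chrom, cds.end, cds.end + utr3_len, strand)
    starts_t = (40, 150, 260, 390)  # uORF starts, transcript coords
    uorfs = [GenomicInterval(chrom, offset + s, offset + s + 12, strand) for s in starts_t]
    return TranscriptModel(gene_id=gene_id, utr5=utr5, cds=cds, utr3=utr3,
                           uorfs=uorfs, utr5_source="measured")


def simple_model(gene_id: str, chrom: str, offset: int, strand: str = "+",
                 utr5_len: int = 120, cds_len: int = 600, utr3_len: int = 200) -> TranscriptModel:
    """A plain single-ORF transcript for background genes."""
    a = GenomicInterval(chrom, offset, offset + utr5_len, strand)
    b = GenomicInterval(chrom, a.end, a.end + cds_len, strand)
    c = GenomicInterval(chrom, b.end, b.end + utr3_len, strand)
    if strand == "-":
        a, c = c, a
    return TranscriptModel(gene_id=gene_id, utr5=a, cds=b, utr3=c, utr5_source="measured")


def simulate_footprints(model: TranscriptModel, params: ScanParams, n_reads: int,
                        length_dist: dict[int, float] | None = None,
                        offset_truth: dict[int, int] | None = None,
                        seed: int = 0, frame_jitter: float = 0.05,
                        start_peak: float = 0.15,
                        sample_id: str = "sim") -> list[AlignedRead]:
    """Sample footprints whose pseudo-A-sites follow the reinitiation model.

    A-sites land on uORF1 always (weight 1), on uORF4 with the probability a
    resumed subunit is captured there, and on the main ORF with the
    main-ORF initiation probability, in frame with the local ORF (a
    ``frame_jitter`` fraction is shifted +/-1 nt).  A ``start_peak``
    fraction of each ORF's ribosomes sits on the initiation codon — the
    start-codon pile-up that makes 3'-offset calibration identifiable.
    Each read's span is laid out so its 3' end sits at A-site + planted
    offset for its length.
    """
    length_dist = length_dist or default_length_dist()
    offset_truth = offset_truth or DEFAULT_OFFSETS
    missing = [L for L, p in length_dist.items() if p > 0 and L not in offset_truth]
    if missing:
        raise ValueError(f"offset_truth missing lengths {missing}")
    if abs(sum(length_dist.values()) - 1.0) > 1e-8:
        raise ValueError("length_dist must sum to 1")
    if n_reads == 0:
        return []

    rng = np.random.default_rng(seed)
    regions = []
    weights = []
    if model.uorfs:
        b = bypass_probability(params)
        uorf1, uorf4 = model.uorfs[0], model.uorfs[-1]
        regions.append(uorf1)
        weights.append(1.0)
        regions.append(uorf4)
        weights.append(params.p_resume * (1.0 - b))
        regions.append(model.cds)
        weights.append(main_orf_initiation_probability(params))
    else:
        regions.append(model.cds)
        weights.append(1.0)
    w = np.asarray(weights) / np.sum(weights)

    lengths = np.array(sorted(length_dist))
    lprobs = np.array([length_dist[L] for L in lengths], dtype=float)
    lprobs /= lprobs.sum()
    t_len = len(model.span)

    reads: list[AlignedRead] = []
    attempts = 0
    while len(reads) < n_reads and attempts < 50 * n_reads:
        attempts += 1
        region = regions[rng.choice(len(regions), p=w)]
        start_t = model.to_transcript(region.start if model.strand == "+" else region.end - 1)
        ncodons = len(region) // 3
        if rng.random() < start_peak:
            codon = 0
        else:
            codon = int(rng.integers(ncodons))
        a_t = start_t + 3 * codon
        if frame_jitter > 0 and rng.random() < frame_jitter:
            a_t += int(rng.choice([-1, 1]))
        L = int(lengths[rng.choice(len(lengths), p=lprobs)])
        end3_t = a_t + offset_truth[L]
        start5_t = end3_t - L + 1
        if start5_t < 0 or end3_t >= t_len:
            continue
        g1 = model.to_genomic(start5_t)
        g2 = model.to_genomic(end3_t)
        lo, hi = (g1, g2) if g1 <= g2 else (g2, g1)
        block = GenomicInterval(model.chrom, lo, hi + 1, model.strand)
        reads.append(AlignedRead(blocks=[block], sample_id=sample_id))
    if len(reads) < n_reads:
        raise RuntimeError("could not place requested number of reads on the transcript")
    return reads


def simulate_rna_fragments(model: TranscriptModel, n_reads: int,
                           length_range: tuple[int, int] = (30, 50),
                           seed: int = 0, sample_id: str = "sim") -> list[AlignedRead]:
    """Uniformly positioned RNA-seq fragments across the whole transcript."""
    rng = np.random.default_rng(seed)
    t_len = len(model.span)
    reads = []
    for _ in range(n_reads):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        start_t = int(rng.integers(0, t_len - L + 1))
        g1 = model.to_genomic(start_t)
        g2 = model.to_genomic(start_t + L - 1)
        lo, hi = (g1, g2) if g1 <= g2 else (g2, g1)
        reads.append(AlignedRead(
            blocks=[GenomicInterval(model.chrom, lo, hi + 1, model.strand)],
            sample_id=sample_id))
    return reads


def write_ground_truth(experiment: SimulatedExperiment, path) -> None:
    """Dump planted truth (LFCs, ScanParams, size factors) as JSON."""
    d = experiment.design
    payload = {
        "true_interaction_lfc": {
            assay: experiment.true_interaction_lfc[assay].round(6).to_dict()
            for assay in experiment.true_interaction_lfc.columns
        },
        "gene_classes": experiment.gene_classes.to_dict(),
        "true_size_factors": experiment.true_size_factors.round(6).to_dict(),
        "scan_params": {cond: vars(p).copy() for cond, p in d.scan_params.items()},
        "offsets": DEFAULT_OFFSETS,
        "seed": d.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
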