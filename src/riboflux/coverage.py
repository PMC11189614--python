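"""Genome-mapped read analysis: offsets, pseudo-A-sites, densities, metagene.

Implements the footprint QC stack: per-length 3'-end offset calibration
against annotated CDS starts, pseudo-A-site assignment (5'-weighted
midpoint), per-feature density normalization, and 100-bin-per-feature
metagene profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import AlignedRead, TranscriptModel


class CalibrationError(RuntimeError):
    pass


class EmptyProfileError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Pseudo-A-site
# ---------------------------------------------------------------------------

def pseudo_a_site(read: AlignedRead) -> int:
    """Genomic position of the fragment midpoint, 5'-weighted on even lengths.

    The fragment's bases are ordered 5'->3' (blocks concatenated in
    transcript orientation) and the base at ordinal ``(L - 1) // 2`` is
    returned: the exact midpoint for odd L, the 5'-ward of the two central
    bases for even L.  Spliced reads walk their exonic blocks only.
    """
    k = (read.read_length - 1) // 2  # ordinal from the 5' end
    blocks = read.blocks if read.strand == "+" else read.blocks[::-1]
    for b in blocks:
        if k < len(b):
            return b.start + k if read.strand == "+" else b.end - 1 - k
        k -= len(b)
    raise AssertionError("unreachable: ordinal exceeds read length")


# ---------------------------------------------------------------------------
# Offset calibration
# ---------------------------------------------------------------------------

@dataclass
class OffsetTable:
    """Per-fragment-length offset from the 3' end, with read support."""

    offsets: dict[int, int] = field(default_factory=dict)
    support: dict[int, int] = field(default_factory=dict)
    ties: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for L, off in self.offsets.items():
            if not (0 <= off < L):
                raise ValueError(f"offset {off} out of range for length {L}")

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def __contains__(self, length: int) -> bool:
        return length in self.offsets


@dataclass
class FrameReport:
    """Per-length fractions of CDS reads in frames 0/1/2."""

    table: pd.DataFrame  # index length, columns frame0, frame1, frame2, n_reads

    def frame0_fraction(self) -> float:
        n = self.table["n_reads"]
        if n.sum() == 0:
            return float("nan")
        return float((self.table["frame0"] * n).sum() / n.sum())


class _GeneIndex:
    """Per-chrom/strand lookup of transcript models (linear scan, desk scale)."""

    def __init__(self, models: list[TranscriptModel]):
        self._by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
        for m in models:
            self._by_key.setdefault((m.chrom, m.strand), []).append(m)

    def containing(self, chrom: str, strand: str, pos: int) -> list[TranscriptModel]:
        return [m for m in self._by_key.get((chrom, strand), ())
                if m.span.contains(pos)]


def _three_prime_distance(model: TranscriptModel, pos: int) -> int:
    """Transcript-orientation distance from the CDS start to pos."""
    if model.strand == "+":
        return pos - model.cds.start
    return (model.cds.end - 1) - pos


def calibrate_offsets(reads, models: list[TranscriptModel],
                      search_window: int = 45, min_support: int = 100
                      ) -> tuple[OffsetTable, FrameReport]:
    """Learn per-length 3'-end offsets from the pile-up at CDS starts.

    For each fragment length the histogram of (3' end - CDS start)
    distances within ``[0, search_window)`` is built over all genes; the
    modal distance is the offset (smallest wins on ties, recorded).  Frames
    are then assigned to every CDS read as ``(distance - offset) mod 3``.
    """
    index = _GeneIndex(models)
    hists: dict[int, dict[int, int]] = {}
    cds_dists: dict[int, list[int]] = {}

    for read in reads:
        pos3 = read.three_prime_end
        for m in index.containing(read.chrom, read.strand, pos3):
            d = _three_prime_distance(m, pos3)
            L = read.read_length
            if 0 <= d < search_window:
                hists.setdefault(L, {})
                hists[L][d] = hists[L].get(d, 0) + 1
            if 0 <= d < len(m.cds):
                cds_dists.setdefault(L, []).append(d)

    support = {L: sum(h.values()) for L, h in hists.items()}
    kept = {L for L, n in support.items() if n >= min_support}
    if not kept:
        raise CalibrationError(
            f"no fragment length reached min_support={min_support}; "
            f"per-length support: {dict(sorted(support.items()))}"
        )

    offsets, ties = {}, {}
    for L in sorted(kept):
        h = hists[L]
        best = max(h.values())
        modal = sorted(d for d, n in h.items() if n == best)
        offsets[L] = modal[0]
        if len(modal) > 1:
            ties[L] = modal

    rows = []
    for L in sorted(offsets):
        dists = np.asarray(cds_dists.get(L, []), dtype=int)
        if dists.size == 0:
            rows.append({"length": L, "frame0": np.nan, "frame1": np.nan,
                         "frame2": np.nan, "n_reads": 0})
            continue
        frames = np.mod(dists - offsets[L], 3)
        frac = np.bincount(frames, minlength=3) / dists.size
        rows.append({"length": L, "frame0": frac[0], "frame1": frac[1],
                     "frame2": frac[2], "n_reads": int(dists.size)})
    report = FrameReport(pd.DataFrame(rows).set_index("length"))
    return OffsetTable(offsets=offsets, support={L: support[L] for L in offsets},
                       ties=ties), report


# ---------------------------------------------------------------------------
# Feature assignment and densities
# ---------------------------------------------------------------------------

def drop_overlapping_genes(models: list[TranscriptModel]) -> list[TranscriptModel]:
    """Keep only genes whose span overlaps no other gene's span (any strand)."""
    kept = []
    for m in models:
        s = m.span
        clash = any(
            o is not m and o.chrom == m.chrom
            and max(o.span.start, s.start) < min(o.span.end, s.end)
            for o in models
        )
        if not clash:
            kept.append(m)
    return kept


def _feature_intervals(model: TranscriptModel) -> dict[str, list]:
    feats = {"utr5": [model.utr5], "cds": [model.cds], "utr3": [model.utr3]}
    if model.introns:
        feats["intron"] = list(model.introns)
    return feats


def assign_feature_counts(reads, models: list[TranscriptModel],
                          min_overlap_frac: float = 0.5) -> pd.DataFrame:
    """Count reads per (gene, feature) under the fractional-overlap rule.

    A read counts toward a feature iff at least ``min_overlap_frac`` of its
    aligned length overlaps the feature, with strandedness enforced.  At
    exactly 0.5 an evenly split read counts toward both adjacent features.
    Returns a tidy frame (gene_id, feature, count, length); unassigned
    reads are tallied in ``frame.attrs['n_unassigned']``.
    """
    rows = {}
    for m in models:
        for fname, ivs in _feature_intervals(m).items():
            rows[(m.gene_id, fname)] = {"count": 0, "length": sum(len(iv) for iv in ivs)}

    n_unassigned = 0
    for read in reads:
        hit = False
        L = read.read_length
        for m in models:
            if m.chrom != read.chrom or m.strand != read.strand:
                continue
            for fname, ivs in _feature_intervals(m).items():
                ov = sum(b.overlap(iv) for b in read.blocks for iv in ivs)
                if ov / L >= min_overlap_frac:
                    rows[(m.gene_id, fname)]["count"] += 1
                    hit = True
        if not hit:
            n_unassigned += 1

    out = pd.DataFrame(
        [{"gene_id": g, "feature": f, **v} for (g, f), v in rows.items()]
    )
    out.attrs["n_unassigned"] = n_unassigned
    return out


def feature_densities(counts: pd.DataFrame, models: list[TranscriptModel],
                      mad_k: float = 5.0) -> pd.DataFrame:
    """Length-normalized, CDS-relative feature densities with outlier flags.

    density = (count_f / length_f) / (count_CDS / length_CDS).  Genes with
    zero CDS reads are marked undefined rather than divided.  Within each
    feature class, densities beyond median +/- ``mad_k`` * MAD are flagged
    (not dropped) -- a documented stand-in for the robust-regression
    outlier removal used on the original figures.
    """
    cds = counts[counts["feature"] == "cds"].set_index("gene_id")
    rows = []
    for _, r in counts[counts["feature"] != "cds"].iterrows():
        g = r["gene_id"]
        c_cds, l_cds = cds.loc[g, "count"], cds.loc[g, "length"]
        undefined = c_cds == 0
        density = np.nan if undefined else (r["count"] / r["length"]) / (c_cds / l_cds)
        rows.append({"gene_id": g, "feature": r["feature"], "count": r["count"],
                     "length": r["length"], "density": density, "undefined": undefined})
    out = pd.DataFrame(rows)
    out["outlier"] = False
    for fname, sub in out.groupby("feature"):
        vals = sub["density"].dropna()
        if len(vals) < 3:
            continue
        med = vals.median()
        mad = (vals - med).abs().median()
        if mad == 0:
            continue
        flag = (out["feature"] == fname) & ((out["density"] - med).abs() > mad_k * mad)
        out.loc[flag, "outlier"] = True
    return out


# ---------------------------------------------------------------------------
# Metagene
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """300 bins of mean relative coverage: 100 each for 5'UTR, CDS, 3'UTR."""

    bins: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (300,):
            raise ValueError("metagene profile must have exactly 300 bins")

    def feature_bins(self, feature: str) -> np.ndarray:
        i = {"utr5": 0, "cds": 1, "utr3": 2}[feature]
        return self.bins[100 * i: 100 * (i + 1)]


def _bin_feature(values: np.ndarray) -> np.ndarray:
    """Mean of per-position values in 100 equal-width bins, bin(p) = floor(p*100/L)."""
    L = values.size
    idx = (np.arange(L) * 100) // L
    sums = np.bincount(idx, weights=values, minlength=100)
    cnts = np.bincount(idx, minlength=100)
    return sums / cnts


def metagene(reads, models: list[TranscriptModel], min_feature_len: int = 100,
             min_cds_reads: int = 128, mode: str = "rpf",
             unique_features: bool = True) -> MetageneProfile:
    """Average relative-coverage profile over genes passing the QC filters.

    Genes need 5'UTR, CDS and 3'UTR of at least ``min_feature_len`` nt and
    at least ``min_cds_reads`` reads on the CDS.  Footprint coverage
    (``mode='rpf'``) uses the pseudo-A-site point; RNA coverage
    (``mode='rna'``) increments every covered base.  Per-gene coverage is
    normalized by the gene-wide mean, each feature is split into 100
    equal-width bins, and bins are averaged across genes.
    """
    if mode not in ("rpf", "rna"):
        raise ValueError("mode must be 'rpf' or 'rna'")
    if unique_features:
        models = drop_overlapping_genes(models)

    candidates = [
        m for m in models
        if min(len(m.utr5), len(m.cds), len(m.utr3)) >= min_feature_len
    ]
    diagnostics = {"n_models": len(models), "n_long_enough": len(candidates),
                   "n_enough_reads": 0}

    per_gene_bins = []
    reads = list(reads)
    for m in candidates:
        t_len = len(m.span)
        cov = np.zeros(t_len)
        n_cds = 0
        for read in reads:
            if read.chrom != m.chrom or read.strand != m.strand:
                continue
            if mode == "rpf":
                pos = pseudo_a_site(read)
                if not m.span.contains(pos):
                    continue
                t = m.to_transcript(pos)
                cov[t] += 1
                if m.cds.contains(pos):
                    n_cds += 1
            else:
                ov = 0
                touched = False
                for b in read.blocks:
                    lo, hi = max(b.start, m.span.start), min(b.end, m.span.end)
                    for p in range(lo, hi):
                        cov[m.to_transcript(p)] += 1
                        touched = True
                    ov += max(0, min(b.end, m.cds.end) - max(b.start, m.cds.start))
                if touched and ov / read.read_length >= 0.5:
                    n_cds += 1
        if n_cds < min_cds_reads:
            continue
        diagnostics["n_enough_reads"] += 1
        rel = cov / cov.mean()
        feats = {"utr5": len(m.utr5), "cds": len(m.cds), "utr3": len(m.utr3)}
        start = 0
        gene_bins = []
        for fname in ("utr5", "cds", "utr3"):
            L = feats[fname]
            gene_bins.append(_bin_feature(rel[start:start + L]))
            start += L
        per_gene_bins.append(np.concatenate(gene_bins))

    if not per_gene_bins:
        raise EmptyProfileError(f"no gene passed the metagene filters: {diagnostics}")
    return MetageneProfile(bins=np.mean(per_gene_bins, axis=0),
                           n_genes=len(per_gene_bins))
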