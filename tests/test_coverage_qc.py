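"""Pseudo-A-site placement, offset calibration, densities, metagene."""

import numpy as np
import pytest

from riboflux import (
    AlignedRead,
    GenomicInterval,
    ScanParams,
    calibrate_offsets,
    assign_feature_counts,
    feature_densities,
    metagene,
    pseudo_a_site,
    simulate_footprints,
)
from riboflux.coverage import CalibrationError, EmptyProfileError, drop_overlapping_genes
from riboflux.simulate import simple_model


def _oracle_pseudo_a(read):
    """Brute force: enumerate every base 5'->3' and index the weighted midpoint."""
    bases = [p for b in read.blocks for p in range(b.start, b.end)]
    if read.strand == "-":
        bases = bases[::-1]
    return bases[(len(bases) - 1) // 2]


class TestPseudoASite:
    def test_odd_length_exact_midpoint(self):
        r = AlignedRead([GenomicInterval("c", 100, 129, "+")])
        assert pseudo_a_site(r) == 114

    def test_even_length_five_prime_tiebreak_plus(self):
        r = AlignedRead([GenomicInterval("c", 100, 128, "+")])
        assert pseudo_a_site(r) == 113

    def test_even_length_five_prime_tiebreak_minus(self):
        # 5'->3' on the minus strand runs 127 down to 100; ordinal 13 is 114
        r = AlignedRead([GenomicInterval("c", 100, 128, "-")])
        assert pseudo_a_site(r) == 114

    def test_matches_enumeration_oracle_on_fuzzed_reads(self):
        rng = np.random.default_rng(77)
        for _ in range(10_000):
            L = int(rng.integers(21, 35))
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, 100_000))
            if rng.random() < 0.3:  # spliced
                k = int(rng.integers(1, L))
                gap = int(rng.integers(20, 500))
                blocks = [
                    GenomicInterval("c", start, start + k, strand),
                    GenomicInterval("c", start + k + gap, start + gap + L, strand),
                ]
            else:
                blocks = [GenomicInterval("c", start, start + L, strand)]
            r = AlignedRead(blocks)
            assert pseudo_a_site(r) == _oracle_pseudo_a(r)


class TestCalibrateOffsets:
    def _model(self):
        return simple_model("g1", "chrI", 1000, utr5_len=120, cds_len=600, utr3_len=200)

    def test_constructed_pileup_recovers_offset_and_frame(self):
        """All 28-mers end 15 nt past the CDS start -> offset 15, pure frame 0."""
        m = self._model()
        cds_start = m.cds.start
        reads = [
            AlignedRead([GenomicInterval("chrI", cds_start + 15 - 27 + 3 * k,
                                         cds_start + 15 + 1 + 3 * k, "+")])
            for k in (0,) * 150 for _ in range(1)
        ] + [
            AlignedRead([GenomicInterval("chrI", cds_start + 15 - 27 + 3 * k,
                                         cds_start + 15 + 1 + 3 * k, "+")])
            for k in range(1, 10) for _ in range(5)
        ]
        table, report = calibrate_offsets(reads, [m], min_support=10)
        assert table[28] == 15
        assert report.table.loc[28, "frame0"] == pytest.approx(1.0)
        assert abs(report.table.loc[28].filter(like="frame").sum() - 1.0) < 1e-9

    def test_tie_break_prefers_smaller_distance_and_records_it(self):
        m = self._model()
        cds_start = m.cds.start
        reads = []
        for dist in (12, 15):
            for _ in range(50):
                reads.append(AlignedRead([GenomicInterval(
                    "chrI", cds_start + dist - 27, cds_start + dist + 1, "+")]))
        table, _ = calibrate_offsets(reads, [m], min_support=10)
        assert table[28] == 12
        assert table.ties[28] == [12, 15]

    def test_insufficient_support_raises_with_diagnostics(self):
        m = self._model()
        reads = [AlignedRead([GenomicInterval("chrI", 1130, 1158, "+")])] * 5
        with pytest.raises(CalibrationError, match="min_support"):
            calibrate_offsets(reads, [m], min_support=100)

    def test_round_trip_with_planted_offsets(self):
        """Synthetic footprints with planted per-length offsets calibrate back
        to the planted table with >= 90% frame-0 reads."""
        m = self._model()
        dist = {L: 1 / 14 for L in range(21, 35)}
        reads = simulate_footprints(m, ScanParams(), 5000, length_dist=dist, seed=7)
        table, report = calibrate_offsets(reads, [m], min_support=20)
        from riboflux.simulate import DEFAULT_OFFSETS
        assert table.offsets == {L: DEFAULT_OFFSETS[L] for L in range(21, 35)}
        assert report.frame0_fraction() >= 0.9


class TestAssignFeatureCounts:
    def _model(self):
        # utr5 [0,100), cds [100,400), utr3 [400,500)
        return simple_model("g1", "chrI", 0, utr5_len=100, cds_len=300, utr3_len=100)

    def test_fractional_overlap_rule(self):
        m = self._model()
        r_low = AlignedRead([GenomicInterval("chrI", 95, 123, "+")])   # 5/28 on utr5
        r_mid = AlignedRead([GenomicInterval("chrI", 90, 118, "+")])   # 10/28 utr5, 18/28 cds
        counts = assign_feature_counts([r_low, r_mid], [m])
        get = lambda f: counts.set_index(["gene_id", "feature"]).loc[("g1", f), "count"]
        assert get("utr5") == 0
        assert get("cds") == 2  # both reads put >= 50% of their length on the CDS

    def test_even_split_counts_to_both_features(self):
        m = self._model()
        r = AlignedRead([GenomicInterval("chrI", 86, 114, "+")])  # 14/28 on each side
        counts = assign_feature_counts([r], [m])
        idx = counts.set_index(["gene_id", "feature"])
        assert idx.loc[("g1", "utr5"), "count"] == 1
        assert idx.loc[("g1", "cds"), "count"] == 1

    def test_antisense_read_never_assigned(self):
        m = self._model()
        r = AlignedRead([GenomicInterval("chrI", 150, 178, "-")])
        counts = assign_feature_counts([r], [m])
        assert counts["count"].sum() == 0
        assert counts.attrs["n_unassigned"] == 1


class TestFeatureDensities:
    def test_cds_relative_density_arithmetic(self):
        m = simple_model("g1", "chrI", 0, utr5_len=100, cds_len=300, utr3_len=100)
        utr5_reads = [AlignedRead([GenomicInterval("chrI", 10 + i, 38 + i, "+")])
                      for i in (0, 30)]
        cds_reads = [AlignedRead([GenomicInterval("chrI", 110 + 6 * i, 138 + 6 * i, "+")])
                     for i in range(30)]
        counts = assign_feature_counts(utr5_reads + cds_reads, [m])
        dens = feature_densities(counts, [m]).set_index("feature")
        # (2/100) / (30/300) = 0.2
        assert dens.loc["utr5", "density"] == pytest.approx(0.2)
        assert dens.loc["utr3", "density"] == 0.0

    def test_zero_cds_marks_undefined(self):
        m = simple_model("g1", "chrI", 0)
        counts = assign_feature_counts([], [m])
        dens = feature_densities(counts, [m])
        assert dens["undefined"].all()
        assert dens["density"].isna().all()

    def test_extreme_density_flagged_not_dropped(self):
        models = [simple_model(f"g{i}", "chrI", 2000 * i) for i in range(12)]
        reads = []
        for i, m in enumerate(models):
            for k in range(20):  # uniform CDS coverage everywhere
                reads.append(AlignedRead([GenomicInterval(
                    "chrI", m.cds.start + 10 + 6 * k, m.cds.start + 38 + 6 * k, "+")]))
            n_utr5 = 60 if i == 0 else 1 + (i % 5)  # one gene with a wildly hot leader
            for k in range(n_utr5):
                reads.append(AlignedRead([GenomicInterval(
                    "chrI", m.utr5.start + 10 + k, m.utr5.start + 38 + k, "+")]))
        dens = feature_densities(assign_feature_counts(reads, models), models)
        flagged = dens[dens["outlier"]]
        assert set(flagged["gene_id"]) == {"g0"}
        assert len(dens[dens["feature"] == "utr5"]) == 12  # flag, never drop


class TestMetagene:
    def _uniform_rpf_reads(self, lo, hi):
        reads = []
        for p in range(lo, hi):
            s = p - 14  # 29-mer whose midpoint is exactly p
            reads.append(AlignedRead([GenomicInterval("chrI", s, s + 29, "+")]))
        return reads

    def test_uniform_coverage_gives_unit_bins(self):
        m = simple_model("g1", "chrI", 100, utr5_len=100, cds_len=300, utr3_len=100)
        prof = metagene(self._uniform_rpf_reads(100, 600), [m], mode="rpf")
        assert prof.bins.shape == (300,)
        assert np.allclose(prof.bins, 1.0, atol=1e-9)
        assert prof.n_genes == 1

    def test_cds_only_coverage_worked_example(self):
        # coverage 2 on the CDS, 0 on UTRs: gene mean 1.2, CDS bins 2/1.2
        m = simple_model("g1", "chrI", 100, utr5_len=100, cds_len=300, utr3_len=100)
        reads = self._uniform_rpf_reads(200, 500) * 2
        prof = metagene(reads, [m], mode="rpf")
        assert np.allclose(prof.feature_bins("cds"), 2 / 1.2, atol=1e-9)
        assert np.allclose(prof.feature_bins("utr5"), 0.0)
        assert np.allclose(prof.feature_bins("utr3"), 0.0)

    def test_normalization_conservation_single_gene(self):
        """Bin means weighted by bin occupancy average to 1 for any profile."""
        m = simple_model("g1", "chrI", 100, utr5_len=100, cds_len=300, utr3_len=100)
        rng = np.random.default_rng(5)
        reads = []
        for p in range(100, 600):
            for _ in range(int(rng.integers(1, 6))):
                reads.append(AlignedRead([GenomicInterval("chrI", p - 14, p + 15, "+")]))
        prof = metagene(reads, [m], mode="rpf")
        weights = np.concatenate([np.full(100, 1.0), np.full(100, 3.0), np.full(100, 1.0)])
        assert np.average(prof.bins, weights=weights) == pytest.approx(1.0, abs=1e-6)

    def test_short_utr_gene_excluded(self):
        short = simple_model("g1", "chrI", 100, utr5_len=90, cds_len=300, utr3_len=100)
        with pytest.raises(EmptyProfileError):
            metagene(self._uniform_rpf_reads(100, 600), [short], mode="rpf")

    def test_rna_mode_uses_full_span_coverage(self):
        m = simple_model("g1", "chrI", 100, utr5_len=100, cds_len=300, utr3_len=100)
        # one 500-nt-tiling set of 25-mers every nt -> near-uniform full-span coverage
        reads = [AlignedRead([GenomicInterval("chrI", s, s + 25, "+")])
                 for s in range(100, 576)]
        prof = metagene(reads, [m], mode="rna", min_cds_reads=100)
        interior = prof.bins[30:270]
        assert interior.std() / interior.mean() < 0.05

    def test_overlapping_genes_dropped_when_unique(self):
        a = simple_model("gA", "chrI", 100)
        b = simple_model("gB", "chrI", 500)  # spans overlap with gA
        kept = drop_overlapping_genes([a, b])
        assert kept == []
        c = simple_model("gC", "chrI", 5000)
        assert [m.gene_id for m in drop_overlapping_genes([a, b, c])] == ["gC"]
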