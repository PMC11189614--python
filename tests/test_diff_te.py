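"""Interaction contrasts, TE, regulon scoring, feature correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riboflux import (
    SimDesign,
    simulate_counts,
    size_factors,
    fit_interaction,
    translational_efficiency,
    regulon_score,
    feature_correlation,
)
from riboflux.diffte import bh_adjust


def _sheet(assay="RNA", n_rep=3):
    rows = []
    for strain in ("WT", "MUT"):
        for temp in (25, 37):
            for r in range(1, n_rep + 1):
                rows.append({"sample_id": f"{assay}_{strain}_{temp}_r{r}",
                             "assay": assay, "strain": strain,
                             "temperature": temp, "replicate": r})
    return pd.DataFrame(rows)


def _matrix_from_cell_means(means, sheet, n_background=50):
    """Noiseless counts: gene g0 follows the per-cell means, a block of flat
    background genes anchors the size factors at 1."""
    cols = {}
    for _, row in sheet.iterrows():
        mu = means[(row["strain"], row["temperature"])]
        cols[row["sample_id"]] = np.concatenate(
            [[mu], np.full(n_background, 5000)]).astype(np.int64)
    idx = ["g0"] + [f"bg{i}" for i in range(n_background)]
    return pd.DataFrame(cols, index=idx)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_doubled_sample_median_of_ratios(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(m)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_single_sample_gets_factor_one(self):
        m = pd.DataFrame({"a": [5, 0, 7]})
        assert size_factors(m).tolist() == [1.0]

    def test_no_common_nonzero_gene_is_an_error(self):
        m = pd.DataFrame({"a": [5, 0], "b": [0, 3]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(m)


class TestFitInteraction:
    def test_noiseless_fixture_recovers_closed_form_lfc(self):
        """Cell means (100, 200, 100, 800) x100 imply an interaction of
        log2((800/100)/(200/100)) = 2."""
        sheet = _sheet()
        means = {("WT", 25): 10_000, ("WT", 37): 20_000,
                 ("MUT", 25): 10_000, ("MUT", 37): 80_000}
        res = fit_interaction(_matrix_from_cell_means(means, sheet), sheet, "RNA")
        assert res.loc["g0", "lfc_interaction"] == pytest.approx(2.0, abs=0.05)

    def test_equal_temperature_effect_cancels(self):
        sheet = _sheet()
        means = {("WT", 25): 10_000, ("WT", 37): 40_000,
                 ("MUT", 25): 10_000, ("MUT", 37): 40_000}
        res = fit_interaction(_matrix_from_cell_means(means, sheet), sheet, "RNA")
        assert res.loc["g0", "lfc_interaction"] == pytest.approx(0.0, abs=0.05)

    def test_all_zero_gene_excluded_and_recorded(self):
        sheet = _sheet()
        means = {k: 1000 for k in [("WT", 25), ("WT", 37), ("MUT", 25), ("MUT", 37)]}
        m = _matrix_from_cell_means(means, sheet)
        m.loc["bg0"] = 0
        res = fit_interaction(m, sheet, "RNA")
        assert "bg0" not in res.index
        assert res.attrs["excluded"] == ["bg0"]

    def test_missing_design_cell_is_error(self):
        sheet = _sheet()
        sheet = sheet[~((sheet["strain"] == "MUT") & (sheet["temperature"] == 37))]
        means = {("WT", 25): 100, ("WT", 37): 100, ("MUT", 25): 100, ("MUT", 37): 100}
        with pytest.raises(ValueError, match="missing design cells"):
            fit_interaction(_matrix_from_cell_means(means, _sheet()), sheet, "RNA")

    def test_null_false_positive_rate_at_q05(self):
        """With zero interaction everywhere, BH discoveries at q<=0.05 are
        rare (seed-averaged over 5 simulated studies)."""
        rates = []
        for seed in range(5):
            design = SimDesign(seed=seed, n_genes=120, regulon_gene_count=0,
                               heatshock_gene_count=20, focal_interaction_fold=1.0)
            exp = simulate_counts(design)
            res = fit_interaction(exp.counts, exp.sheet, "RNA")
            rates.append((res["q_value"] <= 0.05).mean())
        assert np.mean(rates) <= 0.06

    def test_interaction_bias_shrinks_with_depth(self):
        """The planted regulon contrast is recovered more accurately as
        sequencing depth grows."""
        disp = {c: {"RNA": 1e-6, "RPF": 1e-6}
                for c in ("background", "regulon", "heatshock", "focal")}
        mae = []
        for depth, reps in ((2e4, 2), (2e5, 3), (2e6, 4)):
            design = SimDesign(seed=11, n_genes=60, regulon_gene_count=15,
                               heatshock_gene_count=0, mean_depth=depth,
                               dispersion=disp,
                               replicates={"RPF": 2, "RNA": reps})
            exp = simulate_counts(design)
            res = fit_interaction(exp.counts, exp.sheet, "RNA")
            reg = exp.gene_classes[exp.gene_classes == "regulon"].index
            err = res.loc[reg, "lfc_interaction"] - design.regulon_interaction_lfc
            mae.append(err.abs().mean())
        assert mae[2] < mae[0]
        assert mae[2] < 0.2


class TestTranslationalEfficiency:
    def _fake(self, lfcs, ses=None):
        idx = [f"g{i}" for i in range(len(lfcs))]
        ses = ses or [0.1] * len(lfcs)
        return pd.DataFrame({
            "lfc_interaction": lfcs, "standard_error": ses,
            "wald_statistic": np.nan, "p_value": 0.5, "q_value": 0.5,
        }, index=idx)

    def test_te_is_rpf_minus_rna_identity(self):
        te = translational_efficiency(self._fake([3.0]), self._fake([0.0]))
        assert te.loc["g0", "lfc_te"] == 3.0
        assert te.loc["g0", "standard_error"] == pytest.approx(np.sqrt(0.02))

    def test_buffered_gene_has_zero_te_change(self):
        te = translational_efficiency(self._fake([1.7]), self._fake([1.7]))
        assert te.loc["g0", "lfc_te"] == 0.0

    def test_empty_intersection_is_error(self):
        a, b = self._fake([1.0]), self._fake([1.0])
        b.index = ["other"]
        with pytest.raises(ValueError, match="shared"):
            translational_efficiency(a, b)

    def test_focal_te_recovered_from_default_design(self, default_fits):
        """The GCN4-like gene's planted RPF-only interaction (8-fold, i.e.
        3 log2) is recovered within 0.3 log2 at default design depth."""
        te = translational_efficiency(default_fits["RPF"], default_fits["RNA"])
        assert te.loc["g000", "lfc_te"] == pytest.approx(3.0, abs=0.3)
        assert te.loc["g000", "q_value"] < 0.05


class TestRegulonScore:
    def test_planted_regulon_recovered(self, default_experiment, default_fits):
        exp = default_experiment
        regulon = list(exp.gene_classes[exp.gene_classes == "regulon"].index)
        score = regulon_score(default_fits["RNA"], regulon, n_perm=999, seed=1)
        assert score.score == pytest.approx(1.5, abs=0.2)
        assert score.p_value <= 0.01

    def test_all_gene_set_is_degenerate(self, default_fits):
        # every same-size random set IS the full universe, so each
        # permutation ties the observed score and p is exactly 1
        res = default_fits["RNA"]
        score = regulon_score(res, list(res.index), n_perm=199, seed=4)
        assert score.score == pytest.approx(
            res["lfc_interaction"].dropna().mean(), abs=1e-9)
        assert score.p_value == 1.0

    def test_zero_permutations_rejected(self, default_fits):
        with pytest.raises(ValueError, match="n_perm"):
            regulon_score(default_fits["RNA"], ["g001"], n_perm=0)

    def test_empty_set_rejected(self, default_fits):
        with pytest.raises(ValueError, match="empty"):
            regulon_score(default_fits["RNA"], [], n_perm=10)


class TestFeatureCorrelation:
    def _te(self, values):
        idx = [f"g{i}" for i in range(len(values))]
        return pd.DataFrame({"lfc_te": values}, index=idx)

    def test_identical_column_has_unit_correlation(self):
        vals = np.linspace(-1, 2, 50)
        te = self._te(vals)
        feats = pd.DataFrame({"utr5_len": vals}, index=te.index)
        corr = feature_correlation(te, feats)
        assert corr.loc["utr5_len", "Change_TE"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_independent_feature_uncorrelated(self):
        rng = np.random.default_rng(2)
        te = self._te(rng.normal(size=500))
        feats = pd.DataFrame({"gc": rng.normal(size=500)}, index=te.index)
        corr = feature_correlation(te, feats)
        assert abs(corr.loc["gc", "Change_TE"]) < 0.1

    def test_constant_column_marked_undefined(self):
        te = self._te(np.linspace(0, 1, 20))
        feats = pd.DataFrame({"n_uorfs": np.zeros(20)}, index=te.index)
        corr = feature_correlation(te, feats)
        assert np.isnan(corr.loc["n_uorfs", "Change_TE"])
        assert np.isnan(corr.loc["n_uorfs", "n_uorfs"])


class TestBenjaminiHochberg:
    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
    def test_q_dominates_p_and_is_monotone(self, pvals):
        p = pd.Series(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        ordered = q[p.sort_values().index].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()
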