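"""Interaction-contrast differential expression and translational efficiency.

The strain x temperature interaction coefficient of a per-gene
negative-binomial log-linear model is the quantity of interest throughout:
it is the mutant/wild-type ratio at 37C normalized by the same ratio at
25C, and so isolates the eIF4E-depletion effect from the shared heat-shock
response.  Translational efficiency contrasts are the difference of the
RPF and RNA interaction coefficients.

Normalization is median-of-ratios; dispersion is per-gene method of
moments (floored); the interaction is tested with a Wald statistic and
Benjamini-Hochberg correction across genes.  No fold-change shrinkage is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)

DISPERSION_FLOOR = 1e-4
DISPERSION_CEIL = 10.0


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample normalization factors.

    For genes with nonzero counts in all samples, each sample's factor is
    the median of count / geometric-mean-across-samples.  RPF and RNA
    sample sets should be normalized separately (pass one assay at a time).
    """
    if matrix.shape[1] == 1:
        return pd.Series([1.0], index=matrix.columns)
    nonzero = matrix[(matrix > 0).all(axis=1)]
    if nonzero.empty:
        raise ValueError(
            "no gene has nonzero counts in all samples; median-of-ratios "
            "normalization is undefined (consider a pseudo-reference fallback)"
        )
    loggeo = np.log(nonzero).mean(axis=1)
    ratios = np.log(nonzero).sub(loggeo, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def _dispersion_mom(norm_counts: np.ndarray, cells: np.ndarray) -> float:
    """Pooled within-cell method-of-moments NB dispersion on normalized counts."""
    num = 0.0
    den = 0.0
    for c in np.unique(cells):
        y = norm_counts[cells == c]
        if y.size < 2:
            continue
        m = y.mean()
        if m <= 0:
            continue
        v = y.var(ddof=1)
        num += (y.size - 1) * max(0.0, (v - m)) / (m * m)
        den += y.size - 1
    if den == 0:
        return DISPERSION_FLOOR
    return float(np.clip(num / den, DISPERSION_FLOOR, DISPERSION_CEIL))


def _design_matrix(sub: pd.DataFrame) -> np.ndarray:
    strain = (sub["strain"] == "MUT").astype(float).to_numpy()
    temp = (sub["temperature"].astype(int) == 37).astype(float).to_numpy()
    return np.column_stack([np.ones(len(sub)), strain, temp, strain * temp])


def fit_interaction(matrix: pd.DataFrame, sheet: pd.DataFrame, assay: str) -> pd.DataFrame:
    """Per-gene NB Wald test on the strain:temperature interaction.

    Fits ``count ~ strain + temperature + strain:temperature`` with
    log(size factor) offsets for the samples of one assay, and reports the
    interaction coefficient in log2 with its Wald p-value and BH q-value.
    Genes with all-zero counts are excluded (listed in
    ``result.attrs['excluded']``).
    """
    sub = sheet[sheet["assay"] == assay].copy()
    if sub.empty:
        raise ValueError(f"no samples with assay {assay!r}")
    cells = {(s, int(t)) for s, t in zip(sub["strain"], sub["temperature"])}
    want = {(s, t) for s in ("WT", "MUT") for t in (25, 37)}
    if cells != want:
        raise ValueError(f"assay {assay}: missing design cells {sorted(want - cells)}")

    counts = matrix[sub["sample_id"]]
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    X = _design_matrix(sub)
    cell_codes = (sub["strain"] + sub["temperature"].astype(str)).to_numpy()

    excluded: list[str] = []
    rows = []
    for gene, y in counts.iterrows():
        y = y.to_numpy(dtype=float)
        if y.sum() == 0:
            excluded.append(gene)
            continue
        alpha = _dispersion_mom(y / sf.to_numpy(), cell_codes)
        try:
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
            coef, bse = fit.params[3], fit.bse[3]
        except Exception:
            coef, bse = np.nan, np.nan
        if not np.isfinite(coef) or not np.isfinite(bse) or bse == 0:
            rows.append({"gene_id": gene, "lfc_interaction": np.nan,
                         "standard_error": np.nan, "wald_statistic": np.nan,
                         "p_value": np.nan, "dispersion": alpha})
            continue
        z = coef / bse
        rows.append({
            "gene_id": gene,
            "lfc_interaction": coef / LN2,
            "standard_error": bse / LN2,
            "wald_statistic": z,
            "p_value": 2.0 * stats.norm.sf(abs(z)),
            "dispersion": alpha,
        })

    out = pd.DataFrame(rows).set_index("gene_id")
    out["q_value"] = bh_adjust(out["p_value"])
    out.attrs["excluded"] = excluded
    out.attrs["size_factors"] = sf
    return out


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (NaN-safe)."""
    q = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        q.loc[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return q


def translational_efficiency(rpf_results: pd.DataFrame,
                             rna_results: pd.DataFrame) -> pd.DataFrame:
    """TE contrast: interaction LFC difference (RPF - RNA) per gene.

    Standard errors combine in quadrature; the Wald p-value comes from the
    combined z and is BH-corrected across genes.  The gene universe is the
    intersection (differences recorded in ``attrs['only_in_one']``).
    """
    common = rpf_results.index.intersection(rna_results.index)
    if common.empty:
        raise ValueError("no genes shared between RPF and RNA results")
    rpf, rna = rpf_results.loc[common], rna_results.loc[common]
    lfc = rpf["lfc_interaction"] - rna["lfc_interaction"]
    se = np.sqrt(rpf["standard_error"] ** 2 + rna["standard_error"] ** 2)
    z = lfc / se
    out = pd.DataFrame({
        "lfc_te": lfc,
        "lfc_rpf": rpf["lfc_interaction"],
        "lfc_rna": rna["lfc_interaction"],
        "standard_error": se,
        "wald_statistic": z,
        "p_value": 2.0 * stats.norm.sf(np.abs(z)),
    }, index=common)
    out["q_value"] = bh_adjust(out["p_value"])
    out.attrs["only_in_one"] = sorted(
        set(rpf_results.index).symmetric_difference(rna_results.index)
    )
    return out


@dataclass
class RegulonScore:
    """Mean LFC of a gene set with a same-size-random-set permutation p."""

    gene_set_id: str
    score: float
    p_value: float
    n_perm: int
    member_lfc: pd.Series
    missing: list[str]


def regulon_score(results: pd.DataFrame, gene_set, n_perm: int = 999,
                  seed: int = 0, gene_set_id: str = "regulon",
                  lfc_column: str | None = None) -> RegulonScore:
    """Score a gene set by its mean LFC against random same-size sets."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if lfc_column is None:
        lfc_column = "lfc_te" if "lfc_te" in results.columns else "lfc_interaction"
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in results.index]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError("no gene of the set is in the result universe")
    lfcs = results[lfc_column].dropna()
    member = lfcs.reindex(present).dropna()
    score = float(member.mean())
    rng = np.random.default_rng(seed)
    vals = lfcs.to_numpy()
    k = len(member)
    hits = 0
    for _ in range(n_perm):
        perm = rng.choice(vals, size=k, replace=False)
        # small tolerance so exact ties (e.g. the degenerate full-universe
        # set) are counted as hits despite summation-order float jitter
        if perm.mean() >= score - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return RegulonScore(gene_set_id=gene_set_id, score=score, p_value=p,
                        n_perm=n_perm, member_lfc=member, missing=missing)


def feature_correlation(te_results: pd.DataFrame,
                        feature_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of transcript features and the TE change.

    Rows with any missing value are dropped; zero-variance columns yield
    NaN ("undefined") correlations.  The TE change enters as ``Change_TE``.
    """
    df = feature_table.copy()
    df["Change_TE"] = te_results["lfc_te"]
    df = df.dropna()
    if df.empty:
        raise ValueError("no gene with complete feature rows")
    cols = list(df.columns)
    n = len(cols)
    mat = np.full((n, n), np.nan)
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    for i in range(n):
        for j in range(i, n):
            if sd[i] > 0 and sd[j] > 0:
                r = np.corrcoef(arr[:, i], arr[:, j])[0, 1]
                mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=cols, columns=cols)
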