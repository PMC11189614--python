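"""Deterministic quantification formulas for the wet-lab validation assays.

Beta-galactosidase Miller units, RT-qPCR ddCt fold changes, dual-luciferase
ratios, and loading-control-normalized band intensities with replicate
statistics.  All inputs are plain numbers or small records; nothing here
touches sequencing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BetaGalReading:
    """One beta-galactosidase plate reading (ONPG assay)."""

    abs420: float
    abs550: float
    time_min: float
    volume_ml: float
    od600: float

    def __post_init__(self) -> None:
        if self.time_min <= 0 or self.volume_ml <= 0 or self.od600 <= 0:
            raise ValueError("time_min, volume_ml and od600 must be positive")
        if self.abs420 < 0 or self.abs550 < 0:
            raise ValueError("absorbances must be non-negative")


def miller_units(r: BetaGalReading) -> float:
    """Activity in Miller units: 1000 * (A420 - 1.75*A550) / (T * V * OD600).

    The published formula's denominator reads "T 3 V x OD600"; the "3" is a
    typeset multiplication sign, so T * V * OD600 is used, consistent with
    the stated units (change in A420 per min per mL of cells per OD600).
    Turbid blanks can make the numerator negative; the value is returned
    as-is (callers may flag it) rather than clamped.
    """
    return 1000.0 * (r.abs420 - 1.75 * r.abs550) / (r.time_min * r.volume_ml * r.od600)


@dataclass(frozen=True)
class QpcrRecord:
    """Target and reference-gene (TAF10 by default) Ct at one condition."""

    gene: str
    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(treated: QpcrRecord, baseline: QpcrRecord) -> float:
    """Relative expression by the ddCt method: 2^-((dCt_treated) - (dCt_baseline)).

    Expression in the treated condition (e.g. 37C) is normalized to the
    reference gene, then compared with the same quantity at baseline (25C).
    """
    if treated.gene != baseline.gene:
        raise ValueError(f"mismatched genes: {treated.gene} vs {baseline.gene}")
    return 2.0 ** (-(treated.delta_ct - baseline.delta_ct))


def dual_luciferase_ratio(firefly: float, renilla: float,
                          reference_ratio: float | None = None) -> float:
    """Firefly/renilla luminescence ratio, optionally as % of a reference ratio."""
    if renilla <= 0:
        raise ValueError("renilla luminescence must be positive")
    ratio = firefly / renilla
    if reference_ratio is None:
        return ratio
    if reference_ratio <= 0:
        raise ValueError("reference_ratio must be positive")
    return 100.0 * ratio / reference_ratio


@dataclass(frozen=True)
class BandRecord:
    """One blot lane: target band and loading-control band intensities."""

    condition: str
    intensity_target: float
    intensity_control: float

    def __post_init__(self) -> None:
        if self.intensity_target < 0 or self.intensity_control < 0:
            raise ValueError("band intensities must be non-negative")


@dataclass
class BandFoldChange:
    condition: str
    fold: float
    mean_ratio: float
    sd_ratio: float
    n: int
    p_value: float  # Welch t-test vs the reference condition's replicate ratios


def band_fold_change(records: list[BandRecord], reference: str) -> dict[str, BandFoldChange]:
    """Loading-control-normalized fold changes per condition vs a reference.

    Each lane's target intensity is divided by its control band; replicate
    ratios are averaged per condition and expressed relative to the
    reference condition's mean ratio.  p-values are two-sided Welch t-tests
    between replicate ratio vectors (unequal variances; requires >=2
    replicates in both conditions, else NaN).  Lanes with a zero control
    band are excluded with a warning tally in the result.
    """
    ratios: dict[str, list[float]] = {}
    n_excluded = 0
    for rec in records:
        if rec.intensity_control == 0:
            n_excluded += 1
            continue
        ratios.setdefault(rec.condition, []).append(
            rec.intensity_target / rec.intensity_control
        )
    if reference not in ratios:
        raise ValueError(f"no valid replicate for reference condition {reference!r}")
    ref = np.asarray(ratios[reference])
    out: dict[str, BandFoldChange] = {}
    for cond, vals in ratios.items():
        v = np.asarray(vals)
        if cond != reference and len(v) >= 2 and len(ref) >= 2:
            p = float(stats.ttest_ind(v, ref, equal_var=False).pvalue)
        else:
            p = float("nan")
        out[cond] = BandFoldChange(
            condition=cond,
            fold=float(v.mean() / ref.mean()),
            mean_ratio=float(v.mean()),
            sd_ratio=float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            n=len(v),
            p_value=p,
        )
        out[cond].n_excluded = n_excluded  # type: ignore[attr-defined]
    return out
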