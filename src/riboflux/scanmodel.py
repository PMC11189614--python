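"""Scanning/reinitiation model of a GCN4-like 5' leader.

A 40S subunit that terminates at uORF1 resumes scanning with probability
``p_resume``.  While scanning it re-acquires ternary complex (TC)
memorylessly at rate ``lambda_tc / speed_factor`` per nucleotide, so the
probability of covering a distance d without acquisition is
exp(-lambda_tc * d / speed_factor).  A subunit that re-acquires TC before
reaching uORF4 (start-to-start distance ``d1``) reinitiates there and is
lost unless it resumes again with probability ``p_reinit4``; a subunit
that bypasses uORF4 (or resumes after it) initiates on the main ORF iff it
acquires TC within the remaining ``d2`` nucleotides.

``speed_factor`` is the eIF4A proxy (faster scanning divides the per-nt
acquisition rate); ``load_rate`` is the eIF4E proxy (relative ribosome
loading at the cap) and scales occupancy, not the scanning kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

# Baseline bypass of ~3% at d1 = 350 nt fixes the default acquisition rate.
DEFAULT_D1 = 350
DEFAULT_D2 = 150
DEFAULT_LAMBDA_TC = -math.log(0.03) / DEFAULT_D1


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the uORF1 -> uORF4 -> main ORF reinitiation race."""

    p_resume: float = 0.5
    p_reinit4: float = 0.01
    lambda_tc: float = DEFAULT_LAMBDA_TC
    d1: float = DEFAULT_D1
    d2: float = DEFAULT_D2
    load_rate: float = 1.0
    speed_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_resume <= 1.0 and 0.0 <= self.p_reinit4 <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.lambda_tc < 0 or self.d1 < 0 or self.d2 < 0:
            raise ValueError("lambda_tc, d1, d2 must be non-negative")
        if self.load_rate <= 0 or self.speed_factor <= 0:
            raise ValueError("load_rate and speed_factor must be positive")

    @property
    def rate(self) -> float:
        """Effective per-nt TC acquisition rate while scanning."""
        return self.lambda_tc / self.speed_factor


def bypass_probability(params: ScanParams) -> float:
    """P(resumed subunit reaches the uORF4 start without re-acquiring TC)."""
    return math.exp(-params.rate * params.d1)


def _acquire_within(params: ScanParams, d: float) -> float:
    return -math.expm1(-params.rate * d)


def main_orf_initiation_probability(params: ScanParams) -> float:
    """P(a subunit terminating at uORF1 initiates on the main ORF).

    Closed form of the race described in the module docstring:
    ``p_resume * (B * A2 + (1 - B) * p_reinit4 * A2)`` with
    ``B = bypass_probability`` and ``A2`` the probability of acquiring TC
    within ``d2`` nt.  The Monte-Carlo walker
    :func:`monte_carlo_main_orf` shares the same per-ribosome rules.
    """
    b = bypass_probability(params)
    a2 = _acquire_within(params, params.d2)
    return params.p_resume * (b * a2 + (1.0 - b) * params.p_reinit4 * a2)


@dataclass(frozen=True)
class WalkerResult:
    """Monte-Carlo outcome fractions with binomial standard errors.

    ``p_bypass`` is conditional on resumption, so its standard error is
    computed over ``n_resumed`` trials; ``p_main`` and ``p_uorf4`` are per
    initial subunit (``n`` trials).
    """

    n: int
    n_resumed: int
    p_bypass: float
    p_main: float
    p_uorf4: float

    def se_bypass(self, p: float) -> float:
        return math.sqrt(max(p * (1.0 - p), 1e-12) / max(self.n_resumed, 1))

    def se_main(self, p: float) -> float:
        return math.sqrt(max(p * (1.0 - p), 1e-12) / self.n)


def monte_carlo_main_orf(params: ScanParams, n: int, rng: np.random.Generator) -> WalkerResult:
    """Simulate n post-uORF1 subunits one event at a time.

    Independent oracle for the closed forms: resumption is a Bernoulli
    draw, TC re-acquisition distance an exponential draw, repeated after a
    uORF4 reinitiation event.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    resumed = rng.random(n) < params.p_resume
    n_res = int(resumed.sum())
    if params.rate > 0:
        dist1 = rng.exponential(1.0 / params.rate, size=n_res)
    else:
        dist1 = np.full(n_res, np.inf)
    bypassed = dist1 > params.d1
    # bypassers race for the main AUG over d2
    n_by = int(bypassed.sum())
    if params.rate > 0:
        main_from_bypass = rng.exponential(1.0 / params.rate, size=n_by) <= params.d2
    else:
        main_from_bypass = np.zeros(n_by, dtype=bool)
    # captured subunits translate uORF4; a few resume once more
    n_cap = n_res - n_by
    resumed4 = rng.random(n_cap) < params.p_reinit4
    n_res4 = int(resumed4.sum())
    if params.rate > 0:
        main_from_reinit = rng.exponential(1.0 / params.rate, size=n_res4) <= params.d2
    else:
        main_from_reinit = np.zeros(n_res4, dtype=bool)
    n_main = int(main_from_bypass.sum()) + int(main_from_reinit.sum())
    return WalkerResult(
        n=n,
        n_resumed=n_res,
        p_bypass=n_by / max(n_res, 1),
        p_main=n_main / n,
        p_uorf4=n_cap / n,
    )


def occupancy(params: ScanParams) -> float:
    """Relative main-ORF ribosome occupancy: initiation probability x loading."""
    return main_orf_initiation_probability(params) * params.load_rate


def solve_load_rate_for_fold(base: ScanParams, perturbed: ScanParams, fold: float) -> ScanParams:
    """Return ``perturbed`` with load_rate set so occupancy(perturbed)/occupancy(base) == fold."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    p_base = occupancy(base)
    p_pert = main_orf_initiation_probability(perturbed)
    if p_pert == 0:
        raise ValueError("perturbed condition has zero initiation probability")
    return replace(perturbed, load_rate=fold * p_base / p_pert)


def solve_speed_factor_for_fold(base: ScanParams, fold: float,
                                lo: float = 1.0, hi: float = 64.0) -> ScanParams:
    """Solve for the speed_factor whose occupancy fold over ``base`` equals ``fold``.

    Only folds up to the model's speed-only maximum are reachable (faster
    scanning also suppresses TC acquisition before the main AUG); raises if
    the requested fold exceeds it.
    """
    p0 = occupancy(base)

    def f(s: float) -> float:
        return occupancy(replace(base, speed_factor=s)) / p0 - fold

    grid = np.geomspace(lo, hi, 256)
    vals = [f(s) for s in grid]
    for a, b, fa, fb in zip(grid, grid[1:], vals, vals[1:]):
        if fa == 0:
            return replace(base, speed_factor=float(a))
        if fa * fb < 0:
            s = brentq(f, a, b)
            return replace(base, speed_factor=float(s))
    raise ValueError(f"fold {fold} not reachable by speed_factor alone in [{lo}, {hi}]")
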