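"""Median-based mutation/rearrangement rate estimation from fluctuation assays.

A fluctuation assay grows many parallel cultures from small inocula and
counts mutant colonies in each. Because a mutation arising early in a
culture founds a large mutant clone, the counts follow the heavy-tailed
Luria–Delbrück distribution, and the *median* count r̃ is the robust summary.
The Lea–Coulson method of the median inverts

    r̃ / m − ln(m) = 1.24

for m, the expected number of mutational events per culture; the left side
is strictly decreasing in m (d/dm = −r̃/m² − 1/m < 0), so the root is unique
for any r̃ > 0. The per-cell rate is then μ̂ = m / N̄_t with N̄_t the mean
number of viable cells per culture. When the median is zero the p0 method
(m = −ln P₀, with P₀ the fraction of cultures without mutants) takes over.

Confidence intervals are nonparametric: the 95% CI of the median of the
counts is read off order statistics via the Binomial(n, 1/2) distribution,
and each bound is pushed through the same m(·)/N̄_t map as the point
estimate, so the interval lives on the rate scale. The estimator and CI
method used are recorded in every :class:`RateEstimate`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .quant_io import FluctuationAssay

__all__ = [
    "RateEstimate",
    "lea_coulson_m",
    "p0_m",
    "median_ci_ranks",
    "estimate_rate",
    "estimate_rates",
    "fold_change",
]

LEA_COULSON_CONSTANT = 1.24


class ZeroMedianError(ValueError):
    """Median mutant count is zero; the median estimator does not apply."""


class P0NotApplicableError(ValueError):
    """No culture has zero mutants, so m = -ln(P0) is undefined."""


@dataclass
class RateEstimate:
    """A median-based rate estimate with its 95% CI and provenance.

    rate, ci_low, ci_high are per cell (per plated cell, plating efficiency
    1); m_hat is the expected number of mutational events per culture;
    method records which estimator produced m_hat.
    """

    strain: str
    m_hat: float
    rate: float
    ci_low: float
    ci_high: float
    n_cultures: int
    median_count: float
    mean_viable_cells: float
    method: str
    ci_achieved_coverage: float
    fold_vs_reference: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError(
                f"{self.strain}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket the estimate {self.rate}"
            )


def lea_coulson_m(median_r: float) -> float:
    """Solve r̃/m − ln(m) = 1.24 for the expected mutations per culture m.

    Strictly increasing in the median; residual of the returned root is
    below 1e-9. A zero median raises :class:`ZeroMedianError` so the caller
    can fall back to the p0 method.
    """
    if median_r < 0:
        raise ValueError("median mutant count cannot be negative")
    if median_r == 0:
        raise ZeroMedianError("median is zero; use the p0 method")

    def f(m: float) -> float:
        return median_r / m - math.log(m) - LEA_COULSON_CONSTANT

    lo, hi = 1e-12, 1.0
    while f(hi) > 0:
        hi *= 2.0
    root = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
    assert abs(f(root)) < 1e-9
    return float(root)


def p0_m(assay: FluctuationAssay) -> float:
    """p0 estimator: m = −ln(fraction of cultures with zero mutants)."""
    counts = assay.counts
    p0 = float(np.mean(counts == 0))
    if p0 == 0:
        raise P0NotApplicableError(
            f"{assay.strain}: no culture has zero mutants; p0 method not applicable"
        )
    return float(-math.log(p0))


def median_ci_ranks(n: int, conf: float = 0.95) -> tuple[int, int]:
    """Symmetric 1-based order-statistic ranks (a, n+1−a) for a CI of the median.

    Chooses the narrowest symmetric pair whose exact Binomial(n, 1/2)
    coverage, P(X_(a) ≤ median ≤ X_(b)) = 1 − 2·F(a−1; n, 1/2), is at least
    ``conf``. If even the widest pair (1, n) undershoots, it is returned with
    an achieved-coverage warning.
    """
    if n < 2:
        raise ValueError("need at least 2 cultures for a CI")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    best = None
    for a in range(n // 2, 0, -1):
        coverage = 1.0 - 2.0 * binom.cdf(a - 1, n, 0.5)
        if coverage >= conf:
            best = a
            break
    if best is None:
        best = 1
        coverage = 1.0 - 2.0 * binom.cdf(0, n, 0.5)
        warnings.warn(
            f"n={n} too small for {conf:.0%} coverage of the median; widest "
            f"symmetric interval achieves {coverage:.3f}",
            stacklevel=2,
        )
    return best, n + 1 - best


def _achieved_coverage(n: int, a: int) -> float:
    return float(1.0 - 2.0 * binom.cdf(a - 1, n, 0.5))


def _m_of_count(count: float) -> float:
    # CI bounds go through the same map as the point estimate; a zero-count
    # bound pins the corresponding rate bound at 0 (the p0 method needs a
    # whole assay, not a single order statistic).
    return 0.0 if count == 0 else lea_coulson_m(count)


def estimate_rate(assay: FluctuationAssay, conf: float = 0.95) -> RateEstimate:
    """Estimate a strain's per-cell rate with a 95% CI of the median.

    Median count → m via Lea–Coulson (p0 fallback at median 0) → rate
    m/N̄_t; the order-statistic CI bounds of the median are transformed
    through the same map. Cultures whose viable-cell counts span more than
    10× trigger a heterogeneity warning.
    """
    n = len(assay.cultures)
    if n < 2:
        raise ValueError(f"{assay.strain}: need at least 2 cultures, got {n}")
    counts = assay.counts
    n_t = assay.viable_cells
    if n_t.max() / n_t.min() > 10:
        warnings.warn(
            f"{assay.strain}: viable-cell counts span more than 10-fold "
            f"({n_t.min():.3g}..{n_t.max():.3g}); mean N_t may be a poor summary",
            stacklevel=2,
        )
    mean_nt = float(n_t.mean())
    median_r = float(np.median(counts))

    try:
        m_hat = lea_coulson_m(median_r)
        method = "lea_coulson_median"
    except ZeroMedianError:
        m_hat = p0_m(assay)
        method = "p0_fallback"

    a, b = median_ci_ranks(n, conf)
    ordered = np.sort(counts)
    r_low, r_high = float(ordered[a - 1]), float(ordered[b - 1])
    ci_low = _m_of_count(r_low) / mean_nt
    ci_high = _m_of_count(r_high) / mean_nt
    rate = m_hat / mean_nt
    # the p0 fallback can sit below a zero-count lower bound's image (0 maps to 0)
    ci_low = min(ci_low, rate)
    ci_high = max(ci_high, rate)
    return RateEstimate(
        strain=assay.strain,
        m_hat=m_hat,
        rate=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cultures=n,
        median_count=median_r,
        mean_viable_cells=mean_nt,
        method=method,
        ci_achieved_coverage=_achieved_coverage(n, a),
    )


def fold_change(estimate: RateEstimate, reference: RateEstimate) -> float:
    """Point-estimate rate ratio vs a reference strain (reference rate > 0).

    With a zero reference rate the ratio is undefined; the error message
    carries the ">x" lower bound implied by the reference CI's upper limit.
    """
    if reference.rate == 0:
        if reference.ci_high > 0:
            bound = estimate.rate / reference.ci_high
            raise ZeroDivisionError(
                f"reference strain {reference.strain} has rate 0; fold change "
                f"undefined (> {bound:.3g} using the reference CI upper limit)"
            )
        raise ZeroDivisionError(
            f"reference strain {reference.strain} has rate 0 and a degenerate CI"
        )
    return estimate.rate / reference.rate


def estimate_rates(
    assays: list[FluctuationAssay],
    reference: str | None = None,
    conf: float = 0.95,
) -> list[RateEstimate]:
    """Estimate every strain's rate; attach fold changes vs a reference strain."""
    estimates = [estimate_rate(a, conf) for a in assays]
    if reference is not None:
        by_strain = {e.strain: e for e in estimates}
        if reference not in by_strain:
            raise KeyError(
                f"reference strain {reference!r} not found; available: "
                f"{', '.join(sorted(by_strain))}"
            )
        ref = by_strain[reference]
        for est in estimates:
            est.fold_vs_reference = fold_change(est, ref)
    return estimates
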