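"""Fluctuation-test mutation-rate estimation by the null-class (p0) method.

In a fluctuation test many small parallel cultures are grown from a few
cells each and then plated whole under selection.  Under the classical
birth-and-mutation model the number of mutational *events* per culture is
Poisson with mean m = mu * d, where mu is the mutation rate per cell
division and d the number of divisions in one culture (final minus initial
cells).  The fraction of cultures with no mutant therefore estimates
exp(-m), giving the null-class estimator

    mu_hat = -ln(n_negative / n_total) / d .

Confidence intervals are obtained by putting an exact Clopper-Pearson
interval on the null-class proportion p0 and mapping both ends through
-ln(.)/d (a monotone decreasing transform, so the p0 limits swap roles).

Two division-count conventions exist in the literature: ``per_culture``
divides by the divisions of a single culture (the default; -ln p0 counts
mutation events per culture), while ``summed`` divides additionally by the
number of cultures.  Outputs record which convention produced them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import beta

__all__ = [
    "FluctuationExperiment",
    "RateEstimate",
    "total_divisions",
    "p0_estimate",
    "fold_ratio",
    "clopper_pearson",
]


@dataclass(frozen=True)
class FluctuationExperiment:
    """Observed outcome counts of a fluctuation test.

    ``n_negative`` is the number of cultures with no mutant colony,
    ``n_total`` the number of selectively plated cultures, and
    ``divisions_per_culture`` the estimated cell divisions d in one culture.
    """

    n_negative: int
    n_total: int
    divisions_per_culture: int
    titer_final_counts: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_negative <= self.n_total):
            raise ValueError("require 0 <= n_negative <= n_total")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.divisions_per_culture < 1:
            raise ValueError("divisions_per_culture must be >= 1")

    @property
    def p0(self) -> float:
        return self.n_negative / self.n_total


@dataclass(frozen=True)
class RateEstimate:
    """Mutation rate per division with a confidence interval.

    ``point`` is ``inf`` when no culture was negative (the rate is only
    bounded from below) and 0 when every culture was negative (bounded from
    above); the corresponding CI end is one-sided at ``ci_level``.
    """

    point: float
    ci_low: float
    ci_high: float
    ci_level: float
    convention: str = "per_culture"

    def __post_init__(self) -> None:
        if math.isfinite(self.point) and not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("require ci_low <= point <= ci_high")


def total_divisions(titer_final_counts: Sequence[int], initial_cells: int) -> int:
    """Divisions per culture from titer-well final counts: mean(Nt) - N0.

    The titer wells estimate the common final population size; with one
    division per cell added, d = Nt - N0 (rounded to the nearest integer).
    """
    counts = list(titer_final_counts)
    if not counts:
        raise ValueError("titer_final_counts must be non-empty")
    if any(c < initial_cells for c in counts):
        raise ValueError("every final count must be >= initial_cells")
    return round(sum(counts) / len(counts) - initial_cells)


def clopper_pearson(k: int, n: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided CI for a binomial proportion k/n."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("require 0 <= k <= n, n >= 1")
    if not (0 < ci_level < 1):
        raise ValueError("ci_level must lie in (0, 1)")
    alpha = 1.0 - ci_level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def p0_estimate(
    experiment: FluctuationExperiment,
    ci_level: float = 0.95,
    convention: str = "per_culture",
) -> RateEstimate:
    """Null-class mutation-rate estimate with an exact transformed CI.

    Boundary handling: with zero negative cultures the point estimate is
    infinite and only a finite *lower* rate bound is reported, from a
    one-sided Clopper-Pearson upper limit on p0 at ``ci_level``; with all
    cultures negative the point estimate is 0 and a one-sided upper rate
    bound comes from the p0 lower limit.
    """
    if convention not in ("per_culture", "summed"):
        raise ValueError("convention must be 'per_culture' or 'summed'")
    k, n, d = experiment.n_negative, experiment.n_total, experiment.divisions_per_culture
    scale = 1.0 / d if convention == "per_culture" else 1.0 / (d * n)
    alpha = 1.0 - ci_level

    if k == 0:
        # one-sided upper bound on p0 -> lower bound on the rate
        p0_high = 1.0 - alpha ** (1.0 / n)
        return RateEstimate(
            point=math.inf,
            ci_low=-math.log(p0_high) * scale,
            ci_high=math.inf,
            ci_level=ci_level,
            convention=convention,
        )
    if k == n:
        p0_low = alpha ** (1.0 / n)
        return RateEstimate(
            point=0.0,
            ci_low=0.0,
            ci_high=-math.log(p0_low) * scale,
            ci_level=ci_level,
            convention=convention,
        )

    p0_low, p0_high = clopper_pearson(k, n, ci_level)
    return RateEstimate(
        point=-math.log(k / n) * scale,
        ci_low=-math.log(p0_high) * scale,
        ci_high=-math.log(p0_low) * scale,
        ci_level=ci_level,
        convention=convention,
    )


def fold_ratio(a: float, b: float) -> float:
    """Ratio a/b of two rates or frequencies (fold difference)."""
    if b <= 0:
        raise ValueError("denominator must be > 0")
    return a / b
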