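"""Selection-stringency frequencies from colony counts.

Stringency of a selection marker is measured operationally as the fraction
of viable cells that still form colonies under restrictive conditions
(lower = more stringent).  The workflow is:

1. quantify the culture by serial-dilution plating on non-restrictive
   plates (:func:`cfu_from_dilution_counts`),
2. spread a large known number of cells (typically 1e10) on restrictive
   plates and count breakthrough colonies,
3. divide (:func:`stringency_frequency`); when no colony appears the
   result is a 95% upper bound by the rule of three (3 / cells plated),
4. aggregate biological replicates geometrically
   (:func:`aggregate_replicates`), since stringencies live on a log scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "PlatingRecord",
    "PlatingExperiment",
    "CfuEstimate",
    "StringencyResult",
    "AggregateStringency",
    "COUNTABLE_RANGE",
    "cfu_from_dilution_counts",
    "stringency_frequency",
    "stringency_from_experiment",
    "aggregate_replicates",
]

#: Inclusive colony-count range considered reliable on a single plate.
COUNTABLE_RANGE = (3, 300)


@dataclass(frozen=True)
class PlatingRecord:
    """One plate: counts at a known dilution of the original suspension."""

    plate_id: str
    condition: str  # "restrictive" | "nonrestrictive"
    dilution_factor: float
    volume_ml: float
    colonies: int

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.condition not in ("restrictive", "nonrestrictive"):
            raise ValueError("condition must be 'restrictive' or 'nonrestrictive'")


@dataclass(frozen=True)
class PlatingExperiment:
    """All plates of one stringency assay plus the cells spread restrictively."""

    records: Sequence[PlatingRecord]
    plated_total: int | None = None  # cells spread on restrictive plates

    def by_condition(self, condition: str) -> list[PlatingRecord]:
        return [r for r in self.records if r.condition == condition]


@dataclass(frozen=True)
class CfuEstimate:
    """CFU/ml with provenance: how many plates were countable."""

    cfu_per_ml: float
    n_countable: int
    low_confidence: bool


@dataclass(frozen=True)
class StringencyResult:
    """Breakthrough frequency (or its upper bound at zero colonies)."""

    frequency: float
    is_upper_bound: bool
    restrictive_cfu: int
    plated_total: int
    reference_cfu_per_ml: float | None = None


def cfu_from_dilution_counts(records: Iterable[PlatingRecord]) -> CfuEstimate:
    """Pooled CFU/ml over the countable plates of a serial-dilution series.

    The pooled ratio estimator sums colonies over plates with counts in the
    countable range (3-300 inclusive) and divides by the summed effective
    plated volume (volume/dilution).  If no plate is countable, the
    least-diluted plates are used and the estimate flagged low-confidence
    (0 CFU/ml if every plate is empty).
    """
    recs = list(records)
    if not recs:
        raise ValueError("no plating records supplied")
    lo, hi = COUNTABLE_RANGE
    countable = [r for r in recs if lo <= r.colonies <= hi]
    if countable:
        used, low_confidence = countable, False
    else:
        min_dilution = min(r.dilution_factor for r in recs)
        used = [r for r in recs if r.dilution_factor == min_dilution]
        low_confidence = True
    total_colonies = sum(r.colonies for r in used)
    effective_volume = sum(r.volume_ml / r.dilution_factor for r in used)
    return CfuEstimate(
        cfu_per_ml=total_colonies / effective_volume,
        n_countable=len(countable),
        low_confidence=low_confidence,
    )


def stringency_frequency(restrictive_colonies: int, plated_total: int) -> StringencyResult:
    """Breakthrough colonies divided by cells plated on restrictive medium.

    With zero colonies returns the 95% upper bound 3/plated_total
    (rule of three) and marks the result as a bound.
    """
    if plated_total < 1:
        raise ValueError("plated_total must be >= 1")
    if restrictive_colonies < 0:
        raise ValueError("restrictive_colonies must be >= 0")
    if restrictive_colonies == 0:
        return StringencyResult(
            frequency=3.0 / plated_total,
            is_upper_bound=True,
            restrictive_cfu=0,
            plated_total=plated_total,
        )
    return StringencyResult(
        frequency=restrictive_colonies / plated_total,
        is_upper_bound=False,
        restrictive_cfu=restrictive_colonies,
        plated_total=plated_total,
    )


def stringency_from_experiment(experiment: PlatingExperiment) -> StringencyResult:
    """Full assay: reference CFU from non-restrictive plates, then the ratio.

    ``plated_total`` is taken from the experiment when recorded; otherwise
    it is reconstructed from the reference density and the total volume
    spread on restrictive plates (undiluted equivalents).
    """
    reference = cfu_from_dilution_counts(experiment.by_condition("nonrestrictive"))
    restrictive = experiment.by_condition("restrictive")
    if not restrictive:
        raise ValueError("no restrictive plates in experiment")
    colonies = sum(r.colonies for r in restrictive)
    if experiment.plated_total is not None:
        plated_total = experiment.plated_total
    else:
        spread_ml = sum(r.volume_ml / r.dilution_factor for r in restrictive)
        plated_total = round(reference.cfu_per_ml * spread_ml)
        if plated_total < 1:
            raise ValueError("cannot reconstruct plated_total: reference density is 0")
    result = stringency_frequency(colonies, plated_total)
    return StringencyResult(
        frequency=result.frequency,
        is_upper_bound=result.is_upper_bound,
        restrictive_cfu=result.restrictive_cfu,
        plated_total=result.plated_total,
        reference_cfu_per_ml=reference.cfu_per_ml,
    )


@dataclass(frozen=True)
class AggregateStringency:
    """Geometric mean of replicate frequencies with log10 dispersion."""

    geometric_mean: float
    log10_sd: float
    n: int


def aggregate_replicates(frequencies: Sequence[float]) -> AggregateStringency:
    """Geometric mean and sample SD of log10 frequencies across replicates.

    All frequencies must be > 0: zero-colony upper bounds are not averages
    and must be reported separately.  A single replicate has SD 0.
    """
    if not frequencies:
        raise ValueError("need at least one frequency")
    if any(f <= 0 for f in frequencies):
        raise ValueError("frequencies must be > 0 (aggregate upper bounds separately)")
    logs = [math.log10(f) for f in frequencies]
    n = len(logs)
    mean_log = sum(logs) / n
    if n > 1:
        var = sum((x - mean_log) ** 2 for x in logs) / (n - 1)
        sd = math.sqrt(var)
    else:
        sd = 0.0
    return AggregateStringency(geometric_mean=10.0**mean_log, log10_sd=sd, n=n)
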