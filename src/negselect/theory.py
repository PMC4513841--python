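"""Theoretical maximum stringency of a chromosomal negative-selection cassette.

A counterselection cassette (inducible toxin plus promoter) integrated in
single copy can only be escaped by a mutation that inactivates the toxin or
its expression.  The best stringency such a cassette can reach is therefore
bounded by the rate at which inactivating mutations arise.  This module
propagates a published genomic mutation-rate interval through a chain of
scalings:

    per genome  →  per nucleotide  →  per cassette  →  inactivating subset
                →  plus spontaneous large deletions  =  total escape rate

Each stage maps a :class:`RateInterval` (a lower/upper bracket, per
generation) to the next.  Published chains of this kind round intermediates
to two significant figures, so rounding is applied at each stage by default
(``sig_figs=2``); pass a large ``sig_figs`` for an unrounded chain.

Defaults correspond to an E. coli MG1655 host carrying an 811 bp
rhamnose-inducible tse2 cassette:

* genomic rate 1e-3 .. 3.3e-3 mutations/genome/generation,
* genome length 4,641,652 bp (the MG1655 chromosome),
* inactivating fraction 5% (nonsense) .. 40% (dominant-negative bound),
* spontaneous large-deletion rate 1.79e-9 .. 2.5e-7 per generation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RateInterval",
    "MutabilityInputs",
    "round_sig",
    "per_nucleotide_rate",
    "per_cassette_rate",
    "inactivation_rate",
    "total_escape_rate",
    "classify_observed",
    "theory_chain",
    "MG1655_GENOME_BP",
    "TSE2_CASSETTE_BP",
    "DEFAULT_INPUTS",
]

#: E. coli K-12 MG1655 chromosome length in bp.
MG1655_GENOME_BP = 4_641_652
#: Length of the rhamnose-promoter + tse2 toxin cassette in bp.
TSE2_CASSETTE_BP = 811


def round_sig(x: float, sig_figs: int) -> float:
    """Round ``x`` to ``sig_figs`` significant figures (0 maps to 0)."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0:
        return 0.0
    return float(f"{x:.{sig_figs - 1}e}")


@dataclass(frozen=True)
class RateInterval:
    """A lower/upper bracket on a rate (per generation)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high):
            raise ValueError(f"require 0 <= low <= high, got [{self.low}, {self.high}]")

    def rounded(self, sig_figs: int) -> "RateInterval":
        return RateInterval(round_sig(self.low, sig_figs), round_sig(self.high, sig_figs))

    def scale(self, factor: float) -> "RateInterval":
        return RateInterval(self.low * factor, self.high * factor)


@dataclass(frozen=True)
class MutabilityInputs:
    """Parameter set for the escape-rate chain.

    ``inactivating_fraction`` brackets the fraction of cassette mutations
    expected to abolish toxicity: the low end is the expected share of
    nonsense mutations, the high end the share of dominant (loss of
    function when heterozygous) mutations observed for a well-studied
    repressor.
    """

    genomic_rate: RateInterval = field(
        default_factory=lambda: RateInterval(1e-3, 3.3e-3)
    )
    genome_length: int = MG1655_GENOME_BP
    cassette_length: int = TSE2_CASSETTE_BP
    inactivating_fraction: tuple[float, float] = (0.05, 0.40)
    deletion_rate: RateInterval = field(
        default_factory=lambda: RateInterval(1.79e-9, 2.5e-7)
    )
    sig_figs: int = 2

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.cassette_length < 1:
            raise ValueError("lengths must be >= 1 bp")
        lo, hi = self.inactivating_fraction
        if not (0 <= lo <= hi <= 1):
            raise ValueError("inactivating_fraction must satisfy 0 <= low <= high <= 1")
        if self.sig_figs < 1:
            raise ValueError("sig_figs must be >= 1")


DEFAULT_INPUTS = MutabilityInputs()


def per_nucleotide_rate(
    genomic_rate: RateInterval, genome_length: int, sig_figs: int = 2
) -> RateInterval:
    """Genomic rate divided by genome length (mutations/nt/generation)."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    return genomic_rate.scale(1.0 / genome_length).rounded(sig_figs)


def per_cassette_rate(
    per_nt: RateInterval, cassette_length: int, sig_figs: int = 2
) -> RateInterval:
    """Per-nucleotide rate scaled to the cassette (mutations/cassette/generation)."""
    if cassette_length < 0:
        raise ValueError("cassette_length must be >= 0")
    return per_nt.scale(cassette_length).rounded(sig_figs)


def inactivation_rate(
    per_cassette: RateInterval,
    inactivating_fraction: tuple[float, float],
    sig_figs: int = 2,
) -> RateInterval:
    """Subset of cassette mutations expected to inactivate the toxin.

    Endpointwise product: the optimistic bound pairs the low rate with the
    low fraction, the pessimistic bound the high rate with the high fraction.
    """
    lo, hi = inactivating_fraction
    if not (0 <= lo <= hi <= 1):
        raise ValueError("fractions must satisfy 0 <= low <= high <= 1")
    return RateInterval(
        round_sig(per_cassette.low * lo, sig_figs),
        round_sig(per_cassette.high * hi, sig_figs),
    )


def total_escape_rate(
    inactivation: RateInterval,
    deletion_rate: RateInterval,
    sig_figs: int | None = None,
) -> RateInterval:
    """Point-mutation inactivation plus spontaneous large deletions (endpoint sums)."""
    out = RateInterval(
        inactivation.low + deletion_rate.low,
        inactivation.high + deletion_rate.high,
    )
    return out if sig_figs is None else out.rounded(sig_figs)


def classify_observed(observed: float, interval: RateInterval) -> str:
    """Place an observed rate relative to an interval (boundaries inclusive).

    Returns one of ``"below"``, ``"within"``, ``"above"``.
    """
    if observed < 0:
        raise ValueError("observed rate must be >= 0")
    if observed < interval.low:
        return "below"
    if observed > interval.high:
        return "above"
    return "within"


def theory_chain(inputs: MutabilityInputs = DEFAULT_INPUTS) -> dict[str, RateInterval]:
    """Run the full chain; returns every stage keyed by name.

    Keys: ``per_nucleotide``, ``per_cassette``, ``inactivation``,
    ``total_escape``.  Intermediates are rounded to ``inputs.sig_figs``
    significant figures before entering the next stage, matching how such
    chains are conventionally reported.
    """
    nt = per_nucleotide_rate(inputs.genomic_rate, inputs.genome_length, inputs.sig_figs)
    cassette = per_cassette_rate(nt, inputs.cassette_length, inputs.sig_figs)
    inact = inactivation_rate(cassette, inputs.inactivating_fraction, inputs.sig_figs)
    total = total_escape_rate(inact, inputs.deletion_rate, inputs.sig_figs)
    return {
        "per_nucleotide": nt,
        "per_cassette": cassette,
        "inactivation": inact,
        "total_escape": total,
    }
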