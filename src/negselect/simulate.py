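"""Stochastic generators for every input the analysis modules consume.

The central piece is a discrete birth-and-mutation culture model in the
Lea-Coulson tradition: a culture grows from N0 to Nt cells by synchronous
deterministic doubling over G = ceil(log2(Nt/N0)) generations, mutations
arise during divisions at rate mu per division, and a mutation in
generation g founds a clone that doubles until plating, reaching size
2**(G-g).  The number of mutational events is Poisson with mean
mu*(Nt-N0), so the probability that a culture contains no mutant is
exactly exp(-mu*(Nt-N0)) — the identity the null-class estimator inverts.
Heavy-tailed ("jackpot") mutant counts emerge from early mutations.

Also provided: Poisson dilution-series plating, rare-escape stringency
assays (colonies ~ Poisson(frequency * cells plated)), and synthetic
BLAST-tabular hit tables with controlled query coverage for the screening
module.

All randomness flows from one integer seed through numpy's splittable
SeedSequence, one stream per well, so fixtures are reproducible and
individual wells are independent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fluctuation import FluctuationExperiment, total_divisions
from .screen import AlignmentHit

__all__ = [
    "CultureModel",
    "FluctuationDesign",
    "CultureOutcome",
    "FluctuationRun",
    "PanelSpec",
    "simulate_culture",
    "simulate_fluctuation_experiment",
    "simulate_dilution_plating",
    "simulate_stringency_assay",
    "simulate_hit_table",
]

SeedLike = "int | np.random.SeedSequence"


@dataclass(frozen=True)
class CultureModel:
    """Grow-then-select culture: N0 cells double deterministically to Nt.

    ``mutation_rate`` is the probability of a (counter)selectable mutation
    per cell division.
    """

    initial_cells: int
    final_cells: int
    mutation_rate: float

    def __post_init__(self) -> None:
        if self.initial_cells < 1:
            raise ValueError("initial_cells must be >= 1")
        if self.final_cells < self.initial_cells:
            raise ValueError("final_cells must be >= initial_cells")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in [0, 1]")

    @property
    def divisions(self) -> int:
        """Cell divisions per culture, d = Nt - N0."""
        return self.final_cells - self.initial_cells

    @property
    def generations(self) -> int:
        """G = ceil(log2(Nt / N0)); 0 when no growth occurs."""
        if self.final_cells == self.initial_cells:
            return 0
        ratio = self.final_cells / self.initial_cells
        return max(1, math.ceil(math.log2(ratio) - 1e-12))


@dataclass(frozen=True)
class CultureOutcome:
    """Mutant and total cells of one plated culture."""

    mutant_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.mutant_count <= self.total_count):
            raise ValueError("require 0 <= mutant_count <= total_count")

    @property
    def is_positive(self) -> bool:
        return self.mutant_count > 0


@dataclass(frozen=True)
class FluctuationDesign:
    """Plate layout of a fluctuation test.

    Default counts mirror a two-plate 96-well design: 50 selectively plated
    wells per plate (100 total) and 10 titer wells per plate (20 total).
    ``poisson_titer`` perturbs titer-well final counts as Poisson(Nt)
    instead of reporting Nt exactly.
    """

    culture_model: CultureModel
    n_selective_cultures: int = 100
    n_titer_cultures: int = 20
    seed: int = 0
    poisson_titer: bool = False

    def __post_init__(self) -> None:
        if self.n_selective_cultures < 1:
            raise ValueError("n_selective_cultures must be >= 1")
        if self.n_titer_cultures < 0:
            raise ValueError("n_titer_cultures must be >= 0")


@dataclass(frozen=True)
class FluctuationRun:
    """Simulated fluctuation test: per-well outcomes plus titer counts."""

    design: FluctuationDesign
    outcomes: Sequence[CultureOutcome]
    titer_final_counts: Sequence[int]

    @property
    def n_negative(self) -> int:
        return sum(1 for o in self.outcomes if not o.is_positive)

    @property
    def n_total(self) -> int:
        return len(self.outcomes)

    def to_experiment(self) -> FluctuationExperiment:
        """Package counts for the null-class estimator.

        Divisions per culture come from the titer wells when present,
        otherwise from the design's culture model.
        """
        if self.titer_final_counts:
            d = total_divisions(
                self.titer_final_counts, self.design.culture_model.initial_cells
            )
        else:
            d = self.design.culture_model.divisions
        return FluctuationExperiment(
            n_negative=self.n_negative,
            n_total=self.n_total,
            divisions_per_culture=d,
            titer_final_counts=tuple(self.titer_final_counts) or None,
        )


def simulate_culture(model: CultureModel, seed) -> CultureOutcome:
    """Realise one culture of the birth-and-mutation process.

    Mutational events ~ Poisson(mu * d); each event falls in generation g
    with probability proportional to the divisions in that generation
    (N0 * 2**(g-1)) and founds a clone of 2**(G-g) cells at plating.  The
    summed clone size is capped at Nt.
    """
    rng = np.random.default_rng(seed)
    d = model.divisions
    m = model.mutation_rate * d
    if m == 0:
        return CultureOutcome(0, model.final_cells)
    n_events = int(rng.poisson(m))
    if n_events == 0:
        return CultureOutcome(0, model.final_cells)
    G = model.generations
    # divisions per generation, geometric in g
    weights = np.power(2.0, np.arange(G))
    weights /= weights.sum()
    gens = rng.choice(G, size=n_events, p=weights) + 1  # 1-based generation
    clone_sizes = np.power(2.0, G - gens)
    mutants = int(min(float(clone_sizes.sum()), model.final_cells))
    return CultureOutcome(mutants, model.final_cells)


def simulate_fluctuation_experiment(design: FluctuationDesign) -> FluctuationRun:
    """Simulate all wells of a fluctuation test, one RNG stream per well."""
    root = np.random.SeedSequence(design.seed)
    n_sel, n_tit = design.n_selective_cultures, design.n_titer_cultures
    children = root.spawn(n_sel + n_tit)
    outcomes = [
        simulate_culture(design.culture_model, child) for child in children[:n_sel]
    ]
    nt = design.culture_model.final_cells
    if design.poisson_titer:
        titers = [
            int(np.random.default_rng(child).poisson(nt))
            for child in children[n_sel:]
        ]
    else:
        titers = [nt] * n_tit
    return FluctuationRun(design=design, outcomes=outcomes, titer_final_counts=titers)


def simulate_dilution_plating(
    true_cfu_per_ml: float,
    dilutions: Sequence[float],
    plated_volume_ml: float,
    seed,
) -> list[int]:
    """Colony counts of a dilution series: Poisson(density * volume / dilution)."""
    if true_cfu_per_ml < 0:
        raise ValueError("true_cfu_per_ml must be >= 0")
    if plated_volume_ml <= 0:
        raise ValueError("plated_volume_ml must be > 0")
    if any(f <= 0 for f in dilutions):
        raise ValueError("dilution factors must be > 0")
    rng = np.random.default_rng(seed)
    means = [true_cfu_per_ml * plated_volume_ml / f for f in dilutions]
    return [int(rng.poisson(mu)) for mu in means]


def simulate_stringency_assay(escape_frequency: float, n_plated: int, seed) -> int:
    """Breakthrough colonies when n_plated cells are spread: Poisson(f * n)."""
    if not (0 <= escape_frequency <= 1):
        raise ValueError("escape_frequency must lie in [0, 1]")
    if n_plated < 0:
        raise ValueError("n_plated must be >= 0")
    rng = np.random.default_rng(seed)
    return int(rng.poisson(escape_frequency * n_plated))


@dataclass(frozen=True)
class PanelSpec:
    """Blueprint of a gene-by-genome alignment panel.

    ``presence`` maps (gene, genome) to the intended fraction of the gene
    length covered by alignment; pairs absent from the map (or with
    coverage 0) emit no hits.  ``fragmentation`` caps how many HSPs a
    present gene may be split into.
    """

    genomes: Sequence[str]
    genes: Sequence[tuple[str, int]]  # (name, length bp)
    presence: Mapping[tuple[str, str], float]
    identity: float = 95.0
    fragmentation: int = 1

    def __post_init__(self) -> None:
        if any(length < 1 for _, length in self.genes):
            raise ValueError("gene lengths must be >= 1")
        if any(not (0 <= c <= 1) for c in self.presence.values()):
            raise ValueError("coverage fractions must lie in [0, 1]")
        if self.fragmentation < 1:
            raise ValueError("fragmentation must be >= 1")

    @property
    def gene_lengths(self) -> dict[str, int]:
        return dict(self.genes)


def _place_intervals(rng, gene_length: int, target: int, k: int) -> list[tuple[int, int]]:
    """k disjoint non-adjacent intervals in [1, L] totalling `target` bases."""
    # gaps of >= 1 between pieces require target + (k - 1) <= L
    k = max(1, min(k, target, gene_length - target + 1))
    if k == 1:
        pieces = [target]
    else:
        cuts = np.sort(rng.choice(np.arange(1, target), size=k - 1, replace=False))
        bounds = np.concatenate(([0], cuts, [target]))
        pieces = list(np.diff(bounds))
    slack = gene_length - target - (k - 1)
    extra = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1)) if slack > 0 else [0] * (k + 1)
    pos = 1 + int(extra[0])
    intervals = []
    for i, piece in enumerate(pieces):
        intervals.append((pos, pos + int(piece) - 1))
        pos += int(piece) + 1 + int(extra[i + 1])
    return intervals


def simulate_hit_table(panel: PanelSpec, seed) -> list[AlignmentHit]:
    """Emit BLAST-tabular-style hits realising the panel's intended coverage.

    For each (gene, genome) with intended coverage c > 0 the merged query
    intervals total round(c * L) bases (within +-1 bp); intervals are
    separated so they do not merge.  Absent pairs emit nothing.
    """
    root = np.random.SeedSequence(seed)
    pairs = [
        (gene, length, genome)
        for gene, length in panel.genes
        for genome in panel.genomes
        if panel.presence.get((gene, genome), 0.0) > 0
    ]
    hits: list[AlignmentHit] = []
    for child, (gene, length, genome) in zip(root.spawn(len(pairs)), pairs):
        rng = np.random.default_rng(child)
        coverage = panel.presence[(gene, genome)]
        target = max(1, round(coverage * length))
        k = int(rng.integers(1, panel.fragmentation + 1))
        for qstart, qend in _place_intervals(rng, length, target, k):
            aln_len = qend - qstart + 1
            pident = float(np.clip(panel.identity + rng.normal(0, 1.0), 0, 100))
            mismatches = round(aln_len * (1 - pident / 100))
            sstart = int(rng.integers(1, 5_000_000))
            hits.append(
                AlignmentHit(
                    gene=gene,
                    genome=genome,
                    percent_identity=round(pident, 2),
                    alignment_length=aln_len,
                    mismatches=mismatches,
                    gap_opens=0,
                    query_start=qstart,
                    query_end=qend,
                    subject_start=sstart,
                    subject_end=sstart + aln_len - 1,
                    evalue=1e-50,
                    bitscore=round(2.0 * aln_len, 1),
                )
            )
    return hits
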