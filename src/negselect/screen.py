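"""Presence/absence screening of toxin genes across a genome panel.

Works from tabular nucleotide-alignment hits (BLAST outfmt 6/7 dialect):
for each (gene, genome) pair the query intervals of all hits are merged and
the fraction of the gene length covered is compared with a cutoff (0.80 by
default) to call the gene present or absent.  Candidate negative-selection
toxins for a target strain are the genes absent from that strain, ranked by
how often they are absent across a reference panel.

Coordinates follow the BLAST tabular convention: 1-based, inclusive, with
reverse-orientation hits reported as qstart > qend (normalised on parsing).
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "AlignmentHit",
    "PresenceMatrix",
    "BLAST_TAB_COLUMNS",
    "DEFAULT_COVERAGE_THRESHOLD",
    "parse_hit_table",
    "write_hit_table",
    "merge_intervals",
    "gene_coverage",
    "presence_matrix",
    "candidate_toxins",
]

#: blastn -outfmt 6 column order.
BLAST_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

DEFAULT_COVERAGE_THRESHOLD = 0.80


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP of a toxin gene (query) against a genome (subject)."""

    gene: str
    genome: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if min(self.query_start, self.query_end) < 1:
            raise ValueError("query coordinates are 1-based; must be >= 1")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity must lie in [0, 100]")

    @property
    def query_interval(self) -> tuple[int, int]:
        """Orientation-independent (start, end), start <= end."""
        return (
            min(self.query_start, self.query_end),
            max(self.query_start, self.query_end),
        )


def parse_hit_table(source: str | Path | TextIO | Iterable[str]) -> list[AlignmentHit]:
    """Read a 12-column BLAST tabular file into :class:`AlignmentHit` records.

    Accepts a path, an open text stream, or an iterable of lines.  Lines
    beginning with ``#`` (outfmt 7 comments) and blank lines are skipped;
    reverse-orientation hits (qstart > qend) are normalised by swapping.
    Raises :class:`ValueError` with the offending line number on malformed
    rows.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            return parse_hit_table(handle)

    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            qstart, qend = int(fields[6]), int(fields[7])
            hit = AlignmentHit(
                gene=fields[0],
                genome=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                query_start=min(qstart, qend),
                query_end=max(qstart, qend),
                subject_start=int(fields[8]),
                subject_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValueError as err:
            raise ValueError(f"line {lineno}: {err}") from err
        hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], dest: str | Path | TextIO) -> None:
    """Write hits as 12-column BLAST tabular TSV (lossless round trip)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as handle:
            write_hit_table(hits, handle)
        return
    for h in hits:
        row = (
            h.gene,
            h.genome,
            f"{h.percent_identity:g}",
            h.alignment_length,
            h.mismatches,
            h.gap_opens,
            h.query_start,
            h.query_end,
            h.subject_start,
            h.subject_end,
            f"{h.evalue:g}",
            f"{h.bitscore:g}",
        )
        dest.write("\t".join(str(x) for x in row) + "\n")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent 1-based inclusive intervals.

    [a, b] and [b+1, c] are considered adjacent and merged.
    """
    ivals = sorted((min(a, b), max(a, b)) for a, b in intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivals:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def gene_coverage(hits: Iterable[AlignmentHit], gene_length: int) -> float:
    """Fraction of the gene covered by the union of hit query intervals.

    Intervals are clipped to [1, gene_length] before merging.
    """
    if gene_length < 1:
        raise ValueError("gene_length must be >= 1")
    clipped = []
    for h in hits:
        start, end = h.query_interval
        start, end = max(start, 1), min(end, gene_length)
        if start <= end:
            clipped.append((start, end))
    covered = sum(end - start + 1 for start, end in merge_intervals(clipped))
    return covered / gene_length


@dataclass(frozen=True)
class PresenceMatrix:
    """Gene-by-genome presence calls and the underlying coverage fractions.

    ``presence.loc[g, s]`` is True iff ``coverage.loc[g, s] >= threshold``.
    """

    presence: pd.DataFrame
    coverage: pd.DataFrame
    threshold: float
    gene_lengths: Mapping[str, int]


def presence_matrix(
    hits: Iterable[AlignmentHit],
    gene_lengths: Mapping[str, int],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    genomes: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Call each gene present/absent in each genome at a coverage cutoff.

    ``genomes`` may list panel genomes with no hits at all (all-absent
    columns); genomes seen in ``hits`` are always included.  A hit whose gene
    is not in ``gene_lengths`` raises :class:`KeyError`.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    grouped: dict[tuple[str, str], list[AlignmentHit]] = {}
    genome_names: list[str] = list(genomes) if genomes is not None else []
    for h in hits:
        if h.gene not in gene_lengths:
            raise KeyError(f"hit references unknown gene {h.gene!r}")
        if h.genome not in genome_names:
            genome_names.append(h.genome)
        grouped.setdefault((h.gene, h.genome), []).append(h)

    genes = list(gene_lengths)
    coverage = pd.DataFrame(0.0, index=genes, columns=genome_names)
    for (gene, genome), ghits in grouped.items():
        coverage.loc[gene, genome] = gene_coverage(ghits, gene_lengths[gene])
    presence = coverage >= threshold
    return PresenceMatrix(
        presence=presence,
        coverage=coverage,
        threshold=threshold,
        gene_lengths=dict(gene_lengths),
    )


def candidate_toxins(
    matrix: PresenceMatrix, target_genome: str, panel: Sequence[str]
) -> pd.DataFrame:
    """Rank toxin genes as negative-selection candidates for a target strain.

    Step 1 keeps genes absent from ``target_genome`` (the cassette toxin must
    not already be neutralisable by a resident antitoxin or homolog).  Step 2
    computes each surviving gene's absence fraction across ``panel`` genomes
    and flags genes absent in strictly more than half of them (broadly usable
    candidates).  The result is sorted by absence fraction descending, ties
    broken by gene length ascending then name ascending.

    Returns a DataFrame with columns ``gene``, ``absence_fraction``,
    ``majority_absent``.
    """
    for name in [target_genome, *panel]:
        if name not in matrix.presence.columns:
            raise KeyError(f"unknown genome {name!r}")
    rows = []
    for gene in matrix.presence.index:
        if matrix.presence.loc[gene, target_genome]:
            continue
        absent = sum(not matrix.presence.loc[gene, g] for g in panel)
        frac = absent / len(panel) if panel else 0.0
        rows.append(
            {
                "gene": gene,
                "absence_fraction": frac,
                "majority_absent": frac > 0.5,
                "_length": matrix.gene_lengths.get(gene, 0),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "absence_fraction", "majority_absent", "_length"])
    if len(out):
        out = out.sort_values(
            ["absence_fraction", "_length", "gene"],
            ascending=[False, True, True],
            kind="mergesort",
        )
    return out.drop(columns="_length").reset_index(drop=True)
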