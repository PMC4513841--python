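"""Readers and writers for the tabular dialects shared by all stages.

Dialects:

* well CSV — one row per well of a fluctuation test
  (``well_id, arm, outcome, final_cfu``; arm is ``selective`` or ``titer``,
  outcome is ``positive``/``negative`` for selective wells and ``NA`` for
  titer wells),
* plating CSV — one row per plate of a stringency/dilution assay
  (``plate_id, condition, dilution_factor, volume_ml, colonies``),
* BLAST tabular TSV — see :mod:`negselect.screen`,
* gene lengths — FASTA (lengths of the records) or two-column TSV
  ``gene<TAB>length``,
* JSON reports — every numeric value carries a units annotation so rates
  (per division/generation) and frequencies (per cell plated) are never
  conflated.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .fluctuation import FluctuationExperiment, total_divisions
from .simulate import FluctuationRun
from .stringency import PlatingRecord

__all__ = [
    "write_well_csv",
    "read_well_csv",
    "experiment_from_well_table",
    "write_plating_csv",
    "read_plating_csv",
    "read_gene_lengths",
    "write_json_report",
    "quantity",
]

WELL_COLUMNS = ["well_id", "arm", "outcome", "final_cfu"]
PLATING_COLUMNS = ["plate_id", "condition", "dilution_factor", "volume_ml", "colonies"]


def write_well_csv(run: FluctuationRun, path: str | Path) -> None:
    """Serialise a simulated fluctuation run to the well-CSV dialect."""
    rows = []
    for i, outcome in enumerate(run.outcomes):
        rows.append(
            {
                "well_id": f"S{i + 1:03d}",
                "arm": "selective",
                "outcome": "positive" if outcome.is_positive else "negative",
                "final_cfu": outcome.total_count,
            }
        )
    for i, count in enumerate(run.titer_final_counts):
        rows.append(
            {"well_id": f"T{i + 1:03d}", "arm": "titer", "outcome": "NA", "final_cfu": count}
        )
    pd.DataFrame(rows, columns=WELL_COLUMNS).to_csv(path, index=False)


def read_well_csv(path: str | Path) -> pd.DataFrame:
    """Read the well-CSV dialect, validating the schema."""
    df = pd.read_csv(path, dtype={"well_id": str, "arm": str, "outcome": str})
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"well CSV missing columns: {sorted(missing)}")
    bad_arm = set(df["arm"]) - {"selective", "titer"}
    if bad_arm:
        raise ValueError(f"unknown arm values: {sorted(bad_arm)}")
    return df


def experiment_from_well_table(
    wells: pd.DataFrame, initial_cells: int
) -> FluctuationExperiment:
    """Collapse a well table into null-class estimator inputs.

    Divisions per culture are computed from the titer wells' final CFU and
    the known inoculum.
    """
    selective = wells[wells["arm"] == "selective"]
    titer = wells[wells["arm"] == "titer"]
    if selective.empty:
        raise ValueError("no selective wells in table")
    if titer.empty:
        raise ValueError("no titer wells in table (divisions cannot be derived)")
    n_total = len(selective)
    n_negative = int((selective["outcome"] == "negative").sum())
    titers = [int(x) for x in titer["final_cfu"]]
    return FluctuationExperiment(
        n_negative=n_negative,
        n_total=n_total,
        divisions_per_culture=total_divisions(titers, initial_cells),
        titer_final_counts=tuple(titers),
    )


def write_plating_csv(records: Iterable[PlatingRecord], path: str | Path) -> None:
    rows = [
        {
            "plate_id": r.plate_id,
            "condition": r.condition,
            "dilution_factor": r.dilution_factor,
            "volume_ml": r.volume_ml,
            "colonies": r.colonies,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PLATING_COLUMNS).to_csv(path, index=False)


def read_plating_csv(path: str | Path) -> list[PlatingRecord]:
    df = pd.read_csv(path, dtype={"plate_id": str, "condition": str})
    missing = set(PLATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plating CSV missing columns: {sorted(missing)}")
    return [
        PlatingRecord(
            plate_id=str(row.plate_id),
            condition=str(row.condition),
            dilution_factor=float(row.dilution_factor),
            volume_ml=float(row.volume_ml),
            colonies=int(row.colonies),
        )
        for row in df.itertuples()
    ]


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Gene lengths from a FASTA of gene sequences or a two-column TSV."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as handle:
        first = handle.readline()
    if first.startswith(">"):
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'gene<TAB>length'")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError as err:
                raise ValueError(f"line {lineno}: {err}") from err
    return lengths


def quantity(value: float, per: str, scale: str) -> dict[str, Any]:
    """Annotated numeric value for JSON reports.

    ``per`` is the denominator ("division", "generation", "cell plated" ...);
    ``scale`` distinguishes a "rate" from a "frequency" (or "ratio").
    """
    return {"value": value, "per": per, "scale": scale}


def write_json_report(payload: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
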