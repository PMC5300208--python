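"""Ingestion of per-residue binding-energy decompositions.

Endpoint free-energy estimates (MM/PB(GB)SA totals and their single-residue
decomposition) are computed by external MD tooling; this module only parses
their tabulated output (CSV: ``residue,mean,sd`` with a ``TOTAL`` row, units
kcal/mol) and ranks residues by contribution.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DuplicateEntryError, GagmimicError, MissingTotalError


@dataclass
class EnergyDecomposition:
    """Per-residue mean ± SD contributions plus the total ΔG interval."""

    table: pd.DataFrame  # columns: residue, mean, sd (kcal/mol)
    total_dg_mean: float
    total_dg_sd: float
    label: str = ""

    def __post_init__(self):
        if (self.table["sd"] < 0).any():
            raise GagmimicError("standard deviations must be non-negative")
        if self.table["residue"].duplicated().any():
            dup = self.table[self.table["residue"].duplicated()]["residue"].iloc[0]
            raise DuplicateEntryError(f"residue {dup!r} listed more than once")
        if self.total_dg_sd < 0:
            raise GagmimicError("total ΔG sd must be non-negative")

    @property
    def total_interval(self) -> tuple[float, float]:
        """(mean - sd, mean + sd) interval of the total ΔG in kcal/mol."""
        return (
            self.total_dg_mean - self.total_dg_sd,
            self.total_dg_mean + self.total_dg_sd,
        )


def read_energy_table(path: str | Path, label: str = "") -> EnergyDecomposition:
    """Parse a per-residue energy decomposition CSV.

    Expected columns ``residue, mean, sd`` (kcal/mol) and exactly one row
    whose residue field is ``TOTAL`` carrying the total ΔG mean ± sd.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise GagmimicError(f"{path}: empty energy table") from exc
    required = {"residue", "mean", "sd"}
    if not required.issubset(df.columns):
        raise GagmimicError(
            f"{path}: energy table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    df["residue"] = df["residue"].astype(str).str.strip()
    is_total = df["residue"].str.upper() == "TOTAL"
    if not is_total.any():
        raise MissingTotalError(f"{path}: no TOTAL row in energy table")
    total = df[is_total].iloc[0]
    residues = df[~is_total].reset_index(drop=True)
    return EnergyDecomposition(
        table=residues[["residue", "mean", "sd"]].copy(),
        total_dg_mean=float(total["mean"]),
        total_dg_sd=float(total["sd"]),
        label=label or path.stem,
    )


def dominant_residues(table: EnergyDecomposition, k: int = 3) -> list[str]:
    """The k residues with the most-negative mean contributions.

    Sorted by ascending mean energy (most favorable first); ties broken by
    residue identifier so the ranking is deterministic.  ``k`` larger than
    the table returns every residue.
    """
    if k < 1:
        raise GagmimicError(f"k must be >= 1, got {k}")
    ordered = table.table.sort_values(
        ["mean", "residue"], ascending=[True, True]
    )
    return list(ordered["residue"].head(k))
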