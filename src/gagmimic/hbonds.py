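"""Geometric hydrogen-bond detection and residue-level occupancy.

A hydrogen bond is scored between a donor (N/O/S with a covalently bonded
hydrogen) and an acceptor (any N/O/S) on opposite sides of a ligand/receptor
partition, using a donor–acceptor distance cutoff of 3.5 Å and an angle
cutoff of 60°.  Occupancy is the percentage of analysis-window frames in
which a receptor residue forms at least one intermolecular hydrogen bond —
the bound-state comparable of the mimicry algorithm.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble, FrameWindow
from .errors import (
    GagmimicError,
    MissingBondsError,
    MissingHydrogensError,
    SelectionOverlapError,
)
from .topology import Topology


class AngleConvention(str, Enum):
    """Which angle the 60° cutoff applies to.

    ``deviation_from_linearity_DHA`` (default): the deviation of the
    donor–hydrogen–acceptor angle from 180° must be <= cutoff, i.e.
    ∠DHA >= 120° at the default 60°.  ``theta_DH_DA``: the angle between
    the D→H and D→A directions must be <= cutoff.
    """

    DEVIATION_FROM_LINEARITY_DHA = "deviation_from_linearity_DHA"
    THETA_DH_DA = "theta_DH_DA"


@dataclass(frozen=True)
class HBondCriteria:
    donor_acceptor_cutoff: float = 3.5
    angle_cutoff: float = 60.0
    angle_convention: AngleConvention = AngleConvention.DEVIATION_FROM_LINEARITY_DHA

    def __post_init__(self):
        if self.donor_acceptor_cutoff <= 0:
            raise GagmimicError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise GagmimicError("angle cutoff must be in (0, 180] degrees")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    frame: int
    distance: float
    angle: float


_POLAR = {"N", "O", "S"}


def assign_donors_acceptors(
    topology: Topology,
) -> tuple[list[tuple[int, list[int]]], list[int]]:
    """Donors (polar atoms with bonded hydrogens) and acceptors (all polar).

    Returns ``(donors, acceptors)`` where donors is a list of
    ``(heavy_atom_index, [hydrogen indices])`` and acceptors a list of atom
    indices.  N, O and S qualify on both sides, so sulfate and phenolate
    oxygens are acceptors; an atom may be both donor and acceptor.
    """
    if not topology.bonds:
        raise MissingBondsError(
            "topology has no bonds; read CONECT records or call infer_bonds "
            "before hydrogen-bond analysis"
        )
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    for a in topology.atoms:
        if a.element.upper() not in _POLAR:
            continue
        acceptors.append(a.atom_index)
        hydrogens = [
            j
            for j in topology.bonded_to(a.atom_index)
            if topology.atoms[j].element.upper() == "H"
        ]
        if hydrogens:
            donors.append((a.atom_index, hydrogens))
    return donors, acceptors


def _angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    cos = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def detect_hbonds_frame(
    frame: np.ndarray,
    topology: Topology,
    ligand: set[int] | list[int],
    receptor: set[int] | list[int],
    criteria: HBondCriteria | None = None,
    frame_index: int = 0,
) -> list[HBond]:
    """Intermolecular hydrogen bonds in one frame.

    Donor and acceptor must lie on opposite sides of the ligand/receptor
    partition.  Each (donor, hydrogen, acceptor) triple is reported at most
    once.  Structures whose polar atoms carry no hydrogens at all are
    refused — the geometric criterion needs explicit hydrogen positions.
    """
    criteria = criteria or HBondCriteria()
    ligand = set(ligand)
    receptor = set(receptor)
    overlap = ligand & receptor
    if overlap:
        raise SelectionOverlapError(
            f"ligand and receptor selections share atoms {sorted(overlap)[:5]}"
        )
    donors, acceptors = assign_donors_acceptors(topology)
    if not any(
        topology.atoms[i].element.upper() == "H" for i in range(topology.n_atoms)
    ):
        raise MissingHydrogensError(
            "structure has no hydrogen atoms; the donor-H-acceptor criterion "
            "cannot be evaluated (no distance-only fallback is provided)"
        )
    frame = np.asarray(frame, dtype=float)
    out: list[HBond] = []
    seen: set[tuple[int, int, int]] = set()
    for d_idx, hydrogens in donors:
        if d_idx in ligand:
            other = receptor
        elif d_idx in receptor:
            other = ligand
        else:
            continue
        targets = [a for a in acceptors if a in other and a != d_idx]
        if not targets:
            continue
        d_pos = frame[d_idx]
        acc_pos = frame[targets]
        da = np.linalg.norm(acc_pos - d_pos, axis=1)
        for h_idx in hydrogens:
            h_pos = frame[h_idx]
            for a_i, a_idx in enumerate(targets):
                if da[a_i] > criteria.donor_acceptor_cutoff:
                    continue
                key = (d_idx, h_idx, a_idx)
                if key in seen:
                    continue
                if criteria.angle_convention is AngleConvention.THETA_DH_DA:
                    ang = float(
                        _angles_deg(h_pos - d_pos, acc_pos[a_i] - d_pos)
                    )
                    ok = ang <= criteria.angle_cutoff
                else:
                    dha = float(
                        _angles_deg(d_pos - h_pos, acc_pos[a_i] - h_pos)
                    )
                    ang = dha
                    ok = (180.0 - dha) <= criteria.angle_cutoff
                if ok:
                    seen.add(key)
                    out.append(
                        HBond(
                            donor=d_idx,
                            hydrogen=h_idx,
                            acceptor=a_idx,
                            frame=frame_index,
                            distance=float(da[a_i]),
                            angle=ang,
                        )
                    )
    return out


@dataclass
class OccupancyTable:
    """Residue-level hydrogen-bond occupancy over an analysis window.

    ``table`` has one row per receptor residue that formed at least one
    intermolecular bond: residue label, occupancy percent in [0, 100], the
    number of incident frames, and the window frame count.
    """

    table: pd.DataFrame
    window_frames: int
    criteria: HBondCriteria

    def occupancy_of(self, residue_label: str) -> float:
        row = self.table[self.table["residue"] == residue_label]
        return float(row["occupancy_percent"].iloc[0]) if len(row) else 0.0

    @property
    def mean_occupancy(self) -> float:
        """Mean occupancy (%) over residues present in the table."""
        if len(self.table) == 0:
            return 0.0
        return float(self.table["occupancy_percent"].mean())

    def residues_above(self, threshold: float) -> set[str]:
        mask = self.table["occupancy_percent"] >= threshold
        return set(self.table.loc[mask, "residue"])


def occupancy_table(
    ensemble: ConformerEnsemble,
    ligand: set[int] | list[int],
    receptor: set[int] | list[int],
    criteria: HBondCriteria | None = None,
    window: FrameWindow | None = None,
) -> tuple[pd.DataFrame, OccupancyTable]:
    """Per-frame residue incidence matrix and aggregated occupancy table.

    A receptor residue is *incident* in a frame iff at least one
    intermolecular hydrogen bond involves any of its atoms; its occupancy is
    ``100 x incident frames / window frames``.  The default window is the
    final 50% of frames (the equilibrated half of a production run).
    Residues that never bond are absent from the table, not listed as zero.
    """
    criteria = criteria or HBondCriteria()
    if window is None:
        # final half of the trajectory
        t = ensemble.times
        span = t[-1] - t[0]
        start = t[0] + span / 2.0
        sub = ensemble.select_frames(
            FrameWindow(start, t[-1], ensemble.frame_spacing if ensemble.n_frames > 1 else 1.0)
        )
    else:
        sub = ensemble.select_frames(window)

    receptor = set(receptor)
    atom_to_res = {
        a.atom_index: a.residue_label
        for a in sub.topology.atoms
        if a.atom_index in receptor
    }
    residues = sorted(set(atom_to_res.values()))
    incidence = pd.DataFrame(
        False, index=np.arange(sub.n_frames), columns=residues, dtype=bool
    )
    for f in range(sub.n_frames):
        bonds = detect_hbonds_frame(
            sub.coordinates[f], sub.topology, ligand, receptor, criteria, f
        )
        hit: set[str] = set()
        for b in bonds:
            for idx in (b.donor, b.acceptor):
                if idx in atom_to_res:
                    hit.add(atom_to_res[idx])
        if hit:
            incidence.loc[f, sorted(hit)] = True

    counts = incidence.sum(axis=0)
    rows = [
        {
            "residue": res,
            "occupancy_percent": 100.0 * counts[res] / sub.n_frames,
            "n_frames_observed": int(counts[res]),
            "window_frames": sub.n_frames,
        }
        for res in residues
        if counts[res] > 0
    ]
    table = pd.DataFrame(
        rows, columns=["residue", "occupancy_percent", "n_frames_observed", "window_frames"]
    )
    return incidence, OccupancyTable(table=table, window_frames=sub.n_frames, criteria=criteria)
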