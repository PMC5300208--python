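"""Seeded synthetic fixtures with recorded ground truth.

Every generator is a pure function of its parameters and seed and returns a
``FixtureTruth`` alongside its output, so downstream analyses can be tested
for *recovery of planted parameters* rather than against re-derived values.
The models are deliberately minimal: freely jointed chains for flexible-
molecule end-to-end-distance distributions, Gaussian-jittered template
mixtures for conformer basins, and Bernoulli-planted donor–H–acceptor
geometries for hydrogen-bond occupancy.  No force-field realism is
attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble
from .energetics import EnergyDecomposition
from .errors import GagmimicError, InfeasibleParametersError
from .topology import AtomRecord, Topology

LINK_LENGTH = 1.5  # Å, fixed bond length of the freely jointed chain


@dataclass
class FixtureTruth:
    """What a generator planted: its name, seed, and planted parameters."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)


def _chain_topology(n_atoms: int, element: str = "C", chain_id: str = "A") -> Topology:
    atoms = [
        AtomRecord(
            atom_index=i,
            atom_name=f"{element}{i + 1}",
            element=element,
            residue_name="CHN",
            residue_id=1,
            chain_id=chain_id,
        )
        for i in range(n_atoms)
    ]
    bonds = {frozenset((i, i + 1)) for i in range(n_atoms - 1)}
    return Topology(atoms=atoms, bonds=bonds)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_chain_ensemble(
    n_atoms: int,
    n_frames: int,
    target_eed_mean: float,
    target_eed_sd: float,
    seed: int,
) -> tuple[ConformerEnsemble, FixtureTruth]:
    """Flexible-chain ensemble with a planted end-to-end-distance law.

    Each frame is a freely jointed chain of ``n_atoms - 1`` links of 1.5 Å,
    then uniformly rescaled about its first atom so its terminal-atom
    distance equals a draw from Normal(mean, sd) truncated to
    (0, contour length).  The drawn distances are recorded in the truth.
    """
    if n_atoms < 4:
        raise GagmimicError(f"need n_atoms >= 4, got {n_atoms}")
    if n_frames < 1:
        raise GagmimicError(f"need n_frames >= 1, got {n_frames}")
    if target_eed_sd < 0:
        raise GagmimicError("target_eed_sd must be >= 0")
    contour = (n_atoms - 1) * LINK_LENGTH
    if target_eed_mean >= contour:
        raise InfeasibleParametersError(
            f"target EED mean {target_eed_mean} Å is not below the contour "
            f"length {contour} Å of a {n_atoms}-atom chain"
        )
    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, n_atoms, 3))
    drawn = np.empty(n_frames)
    for f in range(n_frames):
        # truncated-normal draw by rejection; falls back to clipping for
        # pathological parameter choices
        for _ in range(1000):
            e = rng.normal(target_eed_mean, target_eed_sd)
            if 0.0 < e < contour:
                break
        else:
            e = float(np.clip(target_eed_mean, 1e-6, contour * 0.999))
        while True:
            steps = _random_unit_vectors(rng, n_atoms - 1) * LINK_LENGTH
            pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            e0 = np.linalg.norm(pts[-1])
            if e0 > 1e-9:
                break
        coords[f] = pts * (e / e0)
        drawn[f] = e
    ensemble = ConformerEnsemble(
        topology=_chain_topology(n_atoms), coordinates=coords
    )
    truth = FixtureTruth(
        generator="chain_ensemble",
        seed=seed,
        parameters={
            "n_atoms": n_atoms,
            "n_frames": n_frames,
            "target_eed_mean": target_eed_mean,
            "target_eed_sd": target_eed_sd,
            "contour_length": contour,
            "drawn_eed": drawn.tolist(),
        },
    )
    return ensemble, truth


def generate_conformer_mixture(
    templates: list[np.ndarray],
    weights: list[float],
    jitter_sd: float,
    n_frames: int,
    seed: int,
    topology: Topology | None = None,
) -> tuple[ConformerEnsemble, FixtureTruth]:
    """Mixture of discrete conformer templates with Gaussian jitter.

    Frames pick a template multinomially by the normalized weights, then add
    i.i.d. Normal(0, jitter_sd) noise per coordinate.  The frame→template
    labels are recorded in the truth.
    """
    templates = [np.asarray(t, dtype=float) for t in templates]
    if not templates:
        raise GagmimicError("need at least one template")
    shape = templates[0].shape
    if any(t.shape != shape for t in templates):
        raise GagmimicError(
            f"templates must share one topology; shapes "
            f"{[t.shape for t in templates]}"
        )
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(templates),) or np.any(w < 0) or w.sum() <= 0:
        raise GagmimicError(
            "weights must be non-negative, one per template, not all zero"
        )
    if n_frames < 1:
        raise GagmimicError(f"need n_frames >= 1, got {n_frames}")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(templates), size=n_frames, p=w)
    coords = np.stack([templates[lab] for lab in labels])
    if jitter_sd > 0:
        coords = coords + rng.normal(scale=jitter_sd, size=coords.shape)
    topo = topology or _chain_topology(shape[0])
    ensemble = ConformerEnsemble(topology=topo, coordinates=coords)
    truth = FixtureTruth(
        generator="conformer_mixture",
        seed=seed,
        parameters={
            "n_templates": len(templates),
            "weights": w.tolist(),
            "jitter_sd": jitter_sd,
            "labels": labels.tolist(),
        },
    )
    return ensemble, truth


def generate_complex_with_hbonds(
    receptor_residues: int,
    bond_probabilities: list[float],
    n_frames: int,
    seed: int,
) -> tuple[ConformerEnsemble, FixtureTruth]:
    """Receptor–ligand ensemble with planted per-residue H-bond occupancy.

    The receptor (chain A) has one N–H donor per residue; the ligand (chain
    L) one acceptor oxygen per residue.  In each frame a residue's acceptor
    sits either in ideal bonding geometry (donor–acceptor 2.9 Å, linear
    D–H–A) with its planted Bernoulli probability, or displaced to 5 Å.
    Residues are spaced 10 Å apart so bonds never cross residues.  The
    realized frame × residue incidence matrix is recorded in the truth.
    """
    probs = np.asarray(bond_probabilities, dtype=float)
    if probs.shape != (receptor_residues,):
        raise GagmimicError(
            f"need one probability per residue ({receptor_residues}), "
            f"got {probs.shape}"
        )
    if np.any((probs < 0) | (probs > 1)):
        raise GagmimicError("bond probabilities must lie in [0, 1]")
    if n_frames < 1:
        raise GagmimicError(f"need n_frames >= 1, got {n_frames}")

    atoms: list[AtomRecord] = []
    bonds: set[frozenset[int]] = set()
    for r in range(receptor_residues):
        n_idx, h_idx = 2 * r, 2 * r + 1
        atoms.append(
            AtomRecord(n_idx, "N", "N", "RES", r + 1, chain_id="A")
        )
        atoms.append(
            AtomRecord(h_idx, "H", "H", "RES", r + 1, chain_id="A")
        )
        bonds.add(frozenset((n_idx, h_idx)))
    lig_offset = 2 * receptor_residues
    for r in range(receptor_residues):
        atoms.append(
            AtomRecord(lig_offset + r, f"O{r + 1}", "O", "LIG", 1, chain_id="L")
        )
    topology = Topology(atoms=atoms, bonds=bonds)

    rng = np.random.default_rng(seed)
    incidence = rng.random((n_frames, receptor_residues)) < probs
    coords = np.zeros((n_frames, len(atoms), 3))
    for r in range(receptor_residues):
        x = 10.0 * r
        coords[:, 2 * r] = (x, 0.0, 0.0)        # donor N
        coords[:, 2 * r + 1] = (x, 0.0, 1.0)    # its hydrogen
        az = np.where(incidence[:, r], 2.9, 5.0)
        coords[:, lig_offset + r, 0] = x
        coords[:, lig_offset + r, 2] = az
    ensemble = ConformerEnsemble(topology=topology, coordinates=coords)
    truth = FixtureTruth(
        generator="complex_with_hbonds",
        seed=seed,
        parameters={
            "receptor_residues": receptor_residues,
            "bond_probabilities": probs.tolist(),
            "incidence": incidence.tolist(),
            "residue_labels": [f"A:RES{r + 1}" for r in range(receptor_residues)],
        },
    )
    return ensemble, truth


def generate_energy_table(
    residues: list[str],
    dominant_residue: str,
    gap: float,
    seed: int,
    noise_sd: float = 0.0,
    path: str | Path | None = None,
) -> tuple[EnergyDecomposition, FixtureTruth]:
    """Per-residue energy decomposition with a planted dominant residue.

    The dominant residue's planted mean is more negative than every other
    residue's by at least ``gap`` kcal/mol.  ``noise_sd`` (default 0) adds
    Gaussian noise to the *written* means, so small gaps can be swamped —
    useful for recovery-rate studies.  The total row is the sum of the
    written residue means.  With a given seed the CSV written to ``path``
    is byte-identical across runs.
    """
    if dominant_residue not in residues:
        raise GagmimicError(
            f"dominant residue {dominant_residue!r} not in residue list"
        )
    if gap <= 0:
        raise GagmimicError(f"gap must be positive, got {gap}")
    rng = np.random.default_rng(seed)
    base = {}
    for res in residues:
        if res != dominant_residue:
            base[res] = float(rng.uniform(-6.0, -3.0))
    floor = min(base.values()) if base else -5.0
    base[dominant_residue] = floor - gap
    means = {
        res: base[res] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        for res in residues
    }
    sds = {res: float(abs(rng.normal(1.0, 0.3))) for res in residues}
    table = pd.DataFrame(
        {
            "residue": residues,
            "mean": [means[r] for r in residues],
            "sd": [sds[r] for r in residues],
        }
    )
    total_mean = float(table["mean"].sum())
    total_sd = float(np.sqrt(np.sum(table["sd"] ** 2)))
    decomp = EnergyDecomposition(
        table=table,
        total_dg_mean=total_mean,
        total_dg_sd=total_sd,
        label=f"synthetic-seed{seed}",
    )
    if path is not None:
        lines = ["residue,mean,sd"]
        for _, row in table.iterrows():
            lines.append(f"{row['residue']},{row['mean']:.6f},{row['sd']:.6f}")
        lines.append(f"TOTAL,{total_mean:.6f},{total_sd:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")
    truth = FixtureTruth(
        generator="energy_table",
        seed=seed,
        parameters={
            "residues": list(residues),
            "dominant_residue": dominant_residue,
            "gap": gap,
            "noise_sd": noise_sd,
            "planted_means": base,
        },
    )
    return decomp, truth
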