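"""Reading and writing conformational ensembles.

Two plain-text formats are supported: multi-model PDB (MODEL/ENDMDL blocks,
ATOM/HETATM records, CONECT honored when present) and a dense coordinate
table (CSV with columns ``frame,atom_index,x,y,z``).
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble
from .errors import (
    DuplicateEntryError,
    IncompleteTableError,
    MalformedEnsembleError,
    PDBParseError,
)
from .topology import COVALENT_RADII, AtomRecord, Topology

_TWO_LETTER = {s for s in COVALENT_RADII if len(s) == 2}


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from a PDB atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in _TWO_LETTER:
        return two.capitalize()
    return stripped[0].upper()


def read_multimodel_pdb(path: str | Path, times=None) -> ConformerEnsemble:
    """Read a (multi-model) PDB file into a :class:`ConformerEnsemble`.

    One frame per MODEL/ENDMDL block; a file without MODEL records yields a
    single frame.  Atom order must be identical across models.  Only the
    first alternate location of an atom is kept (with a warning).  CONECT
    records populate the bond set.  Frame times default to 0, 1, 2, … ps
    unless ``times`` overrides them.

    Raises
    ------
    MalformedEnsembleError
        If a model's atom count or atom names differ from the first model;
        the message names the offending model.
    PDBParseError
        If a coordinate field is unreadable; the message carries the line
        number.
    """
    path = Path(path)
    models: list[list[tuple]] = []  # per model: list of (key, element, xyz)
    current: list[tuple] | None = None
    serial_map: dict[int, int] = {}  # PDB serial -> atom index (first model)
    conect_pairs: set[tuple[int, int]] = set()
    seen_altloc: set[tuple] = set()
    dropped_altloc = 0
    in_model = False
    model_id = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                model_id += 1
                current = []
                models.append(current)
            elif rec == "ENDMDL":
                in_model = False
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if in_model:
                        raise PDBParseError("ATOM outside model block", lineno)
                    # file without MODEL records: implicit single model
                    model_id = 1
                    current = []
                    models.append(current)
                try:
                    serial = int(line[6:11])
                except ValueError:
                    serial = len(current) + 1
                name = line[12:16].strip()
                altloc = line[16:17].strip()
                resname = line[17:20].strip()
                chain = line[21:22].strip() or "A"
                try:
                    resid = int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(
                        f"unreadable residue number {line[22:26]!r}", lineno
                    ) from exc
                icode = line[26:27].strip()
                try:
                    xyz = (
                        float(line[30:38]),
                        float(line[38:46]),
                        float(line[46:54]),
                    )
                except ValueError as exc:
                    raise PDBParseError(
                        f"unreadable coordinates {line[30:54]!r}", lineno
                    ) from exc
                elem = line[76:78].strip().capitalize() if len(line) >= 78 else ""
                if not elem:
                    elem = _element_from_name(name)
                atom_key = (chain, resid, icode, name)
                if altloc:
                    loc_key = (model_id,) + atom_key
                    if loc_key in seen_altloc:
                        dropped_altloc += 1
                        continue
                    seen_altloc.add(loc_key)
                if model_id == 1:
                    serial_map[serial] = len(current)
                current.append((atom_key, resname, elem, xyz))
            elif rec == "CONECT":
                fields = [line[i : i + 5] for i in range(6, len(line.rstrip()), 5)]
                serials = []
                for f in fields:
                    f = f.strip()
                    if f:
                        serials.append(int(f))
                if serials:
                    base = serials[0]
                    for other in serials[1:]:
                        conect_pairs.add((min(base, other), max(base, other)))

    if dropped_altloc:
        warnings.warn(
            f"{path.name}: dropped {dropped_altloc} alternate-location records "
            "(first altloc kept)",
            stacklevel=2,
        )
    if not models or not models[0]:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    ref = models[0]
    ref_keys = [m[0] for m in ref]
    for i, model in enumerate(models[1:], start=2):
        if len(model) != len(ref):
            raise MalformedEnsembleError(
                f"model {i} has {len(model)} atoms but model 1 has {len(ref)}"
            )
        keys = [m[0] for m in model]
        if keys != ref_keys:
            first_bad = next(
                j for j, (a, b) in enumerate(zip(keys, ref_keys)) if a != b
            )
            raise MalformedEnsembleError(
                f"model {i} atom {first_bad} is {keys[first_bad]} but model 1 "
                f"has {ref_keys[first_bad]}"
            )

    atoms = [
        AtomRecord(
            atom_index=i,
            atom_name=key[3],
            element=elem,
            residue_name=resname,
            residue_id=key[1],
            chain_id=key[0],
            insertion_code=key[2],
        )
        for i, (key, resname, elem, _) in enumerate(ref)
    ]
    bonds = set()
    for s1, s2 in conect_pairs:
        if s1 in serial_map and s2 in serial_map and s1 != s2:
            bonds.add(frozenset((serial_map[s1], serial_map[s2])))
    topology = Topology(atoms=atoms, bonds=bonds)
    coords = np.array(
        [[xyz for (_, _, _, xyz) in model] for model in models], dtype=float
    )
    return ConformerEnsemble(topology=topology, coordinates=coords, times=times)


def write_multimodel_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL block per frame)."""
    path = Path(path)
    top = ensemble.topology
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            for a in top.atoms:
                x, y, z = ensemble.coordinates[f, a.atom_index]
                name = a.atom_name
                # 4-char names start in col 13; shorter ones in col 14
                name_field = name if len(name) >= 4 else f" {name:<3s}"
                fh.write(
                    f"ATOM  {a.atom_index + 1:>5d} {name_field:<4s}"
                    f"{a.residue_name:>4s} {a.chain_id:1s}"
                    f"{a.residue_id:>4d}{a.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{a.element.upper():>2s}\n"
                )
            fh.write("ENDMDL\n")
        for bond in sorted(top.bonds, key=lambda b: tuple(sorted(b))):
            i, j = sorted(bond)
            fh.write(f"CONECT{i + 1:>5d}{j + 1:>5d}\n")
        fh.write("END\n")


def read_coord_table(path: str | Path, topology: Topology) -> ConformerEnsemble:
    """Read a dense CSV coordinate table into an ensemble.

    The table must have columns ``frame, atom_index, x, y, z`` with every
    (frame, atom) pair present exactly once.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "atom_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise PDBParseError(
            f"{path}: coordinate table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df.duplicated(subset=["frame", "atom_index"]).any():
        dup = df[df.duplicated(subset=["frame", "atom_index"])].iloc[0]
        raise DuplicateEntryError(
            f"duplicate entry for frame {int(dup.frame)}, "
            f"atom {int(dup.atom_index)}"
        )
    frames = np.sort(df["frame"].unique())
    n_atoms = topology.n_atoms
    expected = set(range(n_atoms))
    coords = np.empty((frames.size, n_atoms, 3), dtype=float)
    for fi, f in enumerate(frames):
        block = df[df["frame"] == f]
        atoms_present = set(block["atom_index"].astype(int))
        missing = expected - atoms_present
        extra = atoms_present - expected
        if missing or extra:
            raise IncompleteTableError(
                f"frame {int(f)}: missing atoms {sorted(missing)}, "
                f"unexpected atoms {sorted(extra)}"
            )
        block = block.sort_values("atom_index")
        coords[fi] = block[["x", "y", "z"]].to_numpy()
    return ConformerEnsemble(topology=topology, coordinates=coords)


def write_coord_table(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a dense CSV coordinate table (full precision)."""
    n_f, n_a = ensemble.n_frames, ensemble.n_atoms
    frame_col = np.repeat(np.arange(n_f), n_a)
    atom_col = np.tile(np.arange(n_a), n_f)
    flat = ensemble.coordinates.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame": frame_col,
            "atom_index": atom_col,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
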