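"""Atom records, topologies, bond inference, and atom selections.

A :class:`Topology` is the static half of a conformational ensemble: the
ordered atom list plus an (optional) covalent bond set.  Bonds matter only
for hydrogen-bond donor assignment, so they may be read from CONECT records
or inferred geometrically with :func:`infer_bonds`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptySelectionError, GagmimicError, UnknownElementError

# Covalent radii (Å), Cordero et al. consensus values for the elements that
# occur in proteins, GAGs and sulfated small molecules.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "MG": 1.41, "CA": 1.76, "ZN": 1.22, "FE": 1.32, "MN": 1.39, "SE": 1.20,
    "B": 0.84, "SI": 1.11,
}

#: extra slack over the covalent-radii sum when inferring bonds (Å)
BOND_TOLERANCE = 0.4


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``(chain_id, residue_id, insertion_code, atom_name)`` is unique within a
    topology; ``element`` is a periodic-table symbol (upper-case).
    """

    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str = "A"
    insertion_code: str = ""

    def __post_init__(self):
        if self.atom_index < 0:
            raise GagmimicError(f"negative atom_index {self.atom_index}")
        if not self.element:
            raise GagmimicError(
                f"atom {self.atom_name!r} has an empty element symbol"
            )

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Identity of the residue this atom belongs to."""
        return (self.chain_id, self.residue_id, self.insertion_code)

    @property
    def residue_label(self) -> str:
        """Human-readable residue identifier, e.g. ``A:LYS126``."""
        return f"{self.chain_id}:{self.residue_name}{self.residue_id}{self.insertion_code}"


@dataclass
class Topology:
    """Ordered atoms plus an unordered covalent bond set."""

    atoms: list[AtomRecord]
    bonds: set[frozenset[int]] = field(default_factory=set)

    def __post_init__(self):
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_id, a.insertion_code, a.atom_name)
            if key in seen:
                raise GagmimicError(f"duplicate atom {key} in topology")
            seen.add(key)
        n = len(self.atoms)
        for bond in self.bonds:
            pair = tuple(bond)
            if len(pair) != 2:
                raise GagmimicError(f"self-bond or malformed bond {pair}")
            if any(i < 0 or i >= n for i in pair):
                raise GagmimicError(f"bond {pair} references atom out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def bonded_to(self, index: int) -> list[int]:
        """Indices of atoms covalently bonded to ``index``."""
        out = []
        for bond in self.bonds:
            if index in bond:
                (other,) = bond - {index}
                out.append(other)
        return sorted(out)

    def subset(self, indices: Sequence[int]) -> "Topology":
        """Topology restricted to ``indices`` (original order), re-indexed.

        Bonds with both endpoints inside the subset are kept and re-indexed.
        """
        indices = list(indices)
        remap = {old: new for new, old in enumerate(indices)}
        atoms = [
            replace(self.atoms[old], atom_index=new)
            for new, old in enumerate(indices)
        ]
        bonds = {
            frozenset(remap[i] for i in bond)
            for bond in self.bonds
            if all(i in remap for i in bond)
        }
        return Topology(atoms=atoms, bonds=bonds)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique residue keys in order of first appearance."""
        seen: list[tuple[str, int, str]] = []
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.append(a.residue_key)
        return seen


def infer_bonds(topology: Topology, frame: np.ndarray) -> Topology:
    """Add geometric covalent bonds from a single frame of coordinates.

    Two atoms are bonded when their distance is at most the sum of their
    covalent radii plus 0.4 Å.  A hydrogen is bonded to at most one heavy
    atom — the nearest candidate wins.

    Parameters
    ----------
    topology:
        Topology whose elements are all known.
    frame:
        ``(n_atoms, 3)`` coordinates in Å.

    Returns
    -------
    Topology
        A new topology with the inferred bond set (existing bonds are kept).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise GagmimicError(
            f"frame shape {frame.shape} does not match {topology.n_atoms} atoms"
        )
    radii = []
    for a in topology.atoms:
        sym = a.element.upper()
        if sym not in COVALENT_RADII:
            raise UnknownElementError(
                f"unknown element symbol {a.element!r} for atom "
                f"{a.atom_name!r}; no covalent radius available"
            )
        radii.append(COVALENT_RADII[sym])
    radii = np.array(radii)
    dists = cdist(frame, frame)
    cutoff = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    is_h = np.array([a.element.upper() == "H" for a in topology.atoms])

    bonds = set(topology.bonds)
    candidate = (dists <= cutoff) & ~np.eye(topology.n_atoms, dtype=bool)
    # H–H pairs are never covalent partners here
    candidate[np.ix_(is_h, is_h)] = False
    # hydrogens: keep only the nearest heavy-atom partner
    for i in np.flatnonzero(is_h):
        partners = np.flatnonzero(candidate[i])
        if partners.size > 1:
            keep = partners[np.argmin(dists[i, partners])]
            candidate[i, :] = False
            candidate[:, i] = False
            candidate[i, keep] = candidate[keep, i] = True
    ii, jj = np.nonzero(candidate)
    for i, j in zip(ii, jj):
        if i < j:
            bonds.add(frozenset((int(i), int(j))))
    return Topology(atoms=list(topology.atoms), bonds=bonds)


# --- selections -----------------------------------------------------------

SelectionLike = Callable[[AtomRecord], bool] | str


def _match_token(token: str) -> Callable[[AtomRecord], bool]:
    parts = token.split()
    kw = parts[0].lower()
    args = parts[1:]
    values = {v for arg in args for v in arg.split(",") if v}
    if kw == "all":
        return lambda a: True
    if kw == "heavy":
        return lambda a: a.element.upper() != "H"
    if kw == "hydrogen":
        return lambda a: a.element.upper() == "H"
    if kw == "element":
        vals = {v.upper() for v in values}
        return lambda a: a.element.upper() in vals
    if kw == "chain":
        return lambda a: a.chain_id in values
    if kw == "resname":
        vals = {v.upper() for v in values}
        return lambda a: a.residue_name.upper() in vals
    if kw == "name":
        vals = {v.upper() for v in values}
        return lambda a: a.atom_name.upper() in vals
    if kw == "resid":
        ids: set[int] = set()
        for v in values:
            if ":" in v:
                lo, hi = v.split(":")
                ids.update(range(int(lo), int(hi) + 1))
            else:
                ids.add(int(v))
        return lambda a: a.residue_id in ids
    raise GagmimicError(
        f"unknown selection keyword {kw!r}; expected one of "
        "all/heavy/hydrogen/element/chain/resname/name/resid"
    )


def compile_selection(expr: SelectionLike) -> Callable[[AtomRecord], bool]:
    """Compile a selection expression into a predicate on atoms.

    Strings use a small keyword language: ``all``, ``heavy``, ``hydrogen``,
    ``element O,S``, ``chain A``, ``resname LYS``, ``name CA``,
    ``resid 1:6``; clauses combine with ``and`` / ``or`` (``and`` binds
    tighter) and negate with a leading ``not``.  Callables pass through.
    """
    if callable(expr):
        return expr

    def compile_clause(clause: str) -> Callable[[AtomRecord], bool]:
        clause = clause.strip()
        if clause.lower().startswith("not "):
            inner = _match_token(clause[4:].strip())
            return lambda a: not inner(a)
        return _match_token(clause)

    or_terms = []
    for disjunct in expr.split(" or "):
        preds = [compile_clause(c) for c in disjunct.split(" and ")]
        or_terms.append(preds)

    def predicate(a: AtomRecord) -> bool:
        return any(all(p(a) for p in preds) for preds in or_terms)

    return predicate


def select_atom_indices(topology: Topology, expr: SelectionLike) -> list[int]:
    """Indices of atoms matching ``expr``, in topology order.

    Raises
    ------
    EmptySelectionError
        If the selection matches no atoms (explicit, never silent).
    """
    pred = compile_selection(expr)
    indices = [a.atom_index for a in topology.atoms if pred(a)]
    if not indices:
        raise EmptySelectionError(f"selection {expr!r} matched no atoms")
    return indices
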