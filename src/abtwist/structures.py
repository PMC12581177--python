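"""Core structure model: atoms, residues, monomers and the dimer Structure.

The Structure is the carrier shared by all analyses: a peptide dimer (or
single monomer) with covalent topology inferred from geometry and every
atom classified as mainchain or sidechain.  Coordinates live on the
individual Atom objects; ``coords()`` / ``with_coords()`` convert to and
from a flat ``(n, 3)`` array in a stable atom order (monomer, then
residue N->C, then atom input order), which is the order used by the
energy model, the torsion engine and the NEB path object.

Classification convention: the mainchain set is {N, amide H, CA, HA, C,
O} plus terminal backbone atoms (OXT and its hydrogen, extra N-terminal
amide hydrogens).  Glycine has two alpha hydrogens; the first (by serial
order) is classed mainchain and the second is treated as the glycine
"sidechain", so that every residue's sidechain is the substituent on CA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .elements import bond_cutoff


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the named dialect."""


class TopologyError(ValueError):
    """Raised when a structure violates peptide topology expectations."""


MAINCHAIN_HEAVY = {"N", "CA", "C", "O", "OXT"}
BACKBONE_REQUIRED = ("N", "CA", "C", "O")


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    mainchain: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.isfinite(self.coords).all():
            raise ValueError(f"atom {self.serial} ({self.name}): coords must be a finite 3-vector")

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.element, self.coords.copy(), self.mainchain)


@dataclass
class Residue:
    position: int
    code: str
    atoms: list[Atom]

    @property
    def mainchain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.mainchain]

    @property
    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.mainchain]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.code}{self.position} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Monomer:
    residues: list[Residue]
    layer_label: str | None = None

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def residue(self, position: int) -> Residue:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(f"no residue at position {position}")

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)


@dataclass
class SegmentLabel:
    """The i - i+1 segment: the C-C, CO-NH, N-CA bond triplet between residues i and i+1."""

    i: int

    def __str__(self) -> str:
        return f"{self.i}-{self.i + 1}"


@dataclass
class Structure:
    monomers: list[Monomer]
    provenance: str = ""
    _bonds: list[tuple[int, int]] | None = field(default=None, repr=False, compare=False)

    # ---- flat views -------------------------------------------------

    @property
    def atoms(self) -> list[Atom]:
        return [a for m in self.monomers for r in m.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for m in self.monomers for r in m.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def atom_meta(self) -> list[tuple[int, int, str]]:
        """(monomer_index, residue_position, atom_name) per flat atom index."""
        out = []
        for mi, m in enumerate(self.monomers):
            for r in m.residues:
                for a in r.atoms:
                    out.append((mi, r.position, a.name))
        return out

    def monomer_of(self) -> np.ndarray:
        """Monomer index per flat atom index."""
        out = []
        for mi, m in enumerate(self.monomers):
            out.extend([mi] * sum(len(r.atoms) for r in m.residues))
        return np.array(out, dtype=int)

    def residue_key_of(self) -> list[tuple[int, int]]:
        """(monomer_index, residue_position) per flat atom index."""
        out = []
        for mi, m in enumerate(self.monomers):
            for r in m.residues:
                out.extend([(mi, r.position)] * len(r.atoms))
        return out

    def mainchain_mask(self) -> np.ndarray:
        return np.array([a.mainchain for a in self.atoms], dtype=bool)

    def with_coords(self, X: np.ndarray) -> "Structure":
        """New Structure with the same topology and the given flat coordinates."""
        X = np.asarray(X, dtype=float)
        if X.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3), got {X.shape}")
        new = Structure(
            [
                Monomer([Residue(r.position, r.code, [a.copy() for a in r.atoms]) for r in m.residues], m.layer_label)
                for m in self.monomers
            ],
            self.provenance,
        )
        for a, x in zip(new.atoms, X):
            a.coords = np.array(x, dtype=float)
        new._bonds = self._bonds
        return new

    def copy(self) -> "Structure":
        return self.with_coords(self.coords())

    # ---- topology ---------------------------------------------------

    @property
    def bonds(self) -> list[tuple[int, int]]:
        """Covalent bonds as sorted flat-index pairs (distance criterion)."""
        if self._bonds is None:
            self._bonds = infer_bonds(self)
        return self._bonds

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    @property
    def upper(self) -> Monomer:
        return self._layer("upper")

    @property
    def lower(self) -> Monomer:
        return self._layer("lower")

    def _layer(self, label: str) -> Monomer:
        hits = [m for m in self.monomers if m.layer_label == label]
        if len(hits) != 1:
            raise TopologyError(f"structure does not have exactly one {label!r} monomer")
        return hits[0]

    def upper_index(self) -> int:
        for i, m in enumerate(self.monomers):
            if m.layer_label == "upper":
                return i
        raise TopologyError("no monomer labeled upper")


def infer_bonds(s: Structure) -> list[tuple[int, int]]:
    X = s.coords()
    elements = s.elements()
    if len(X) == 0:
        return []
    tree = cKDTree(X)
    max_cut = bond_cutoff("S", "S")
    pairs = tree.query_pairs(max_cut)
    bonds = []
    for i, j in pairs:
        d = float(np.linalg.norm(X[i] - X[j]))
        if d < 0.4:  # overlapping atoms are not a bond
            continue
        if d <= bond_cutoff(elements[i], elements[j]):
            if elements[i] == "H" and elements[j] == "H":
                continue
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def infer_topology(s: Structure) -> Structure:
    """Validate backbone completeness and classify mainchain/sidechain atoms in place.

    Idempotent.  Raises TopologyError naming the offending residue when a
    backbone heavy atom (N, CA, C, O) is missing, and when consecutive
    residues are not peptide-bonded (C(i)-N(i+1) < 2.0 A).
    """
    if s.n_atoms == 0:
        raise FormatError("structure has no atoms")
    adj = s.adjacency()
    atoms = s.atoms
    # flat index of each atom object
    index_of = {id(a): i for i, a in enumerate(atoms)}

    for m in s.monomers:
        positions = m.positions
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise TopologyError("residue positions must be strictly increasing within a monomer")
        for r in m.residues:
            for name in BACKBONE_REQUIRED:
                if not r.has_atom(name):
                    raise TopologyError(f"residue {r.code}{r.position} is missing backbone atom {name}")
        for ra, rb in zip(m.residues, m.residues[1:]):
            d = float(np.linalg.norm(ra.atom("C").coords - rb.atom("N").coords))
            if d >= 2.0:
                raise TopologyError(
                    f"residues {ra.code}{ra.position} and {rb.code}{rb.position} are not peptide-bonded (C-N = {d:.2f} A)"
                )

    for m in s.monomers:
        for r in m.residues:
            gly_ca_h_seen = 0
            for a in sorted(r.atoms, key=lambda a: a.serial):
                if a.element != "H":
                    a.mainchain = a.name in MAINCHAIN_HEAVY
                    continue
                # hydrogens classified by the heavy atom they ride on
                i = index_of[id(a)]
                heavy = [atoms[j] for j in adj[i] if atoms[j].element != "H"]
                if not heavy:
                    a.mainchain = False
                    continue
                parent = heavy[0]
                if parent.name in {"N", "C", "OXT"}:
                    a.mainchain = True
                elif parent.name == "CA":
                    if r.code == "G":
                        gly_ca_h_seen += 1
                        a.mainchain = gly_ca_h_seen == 1
                    else:
                        a.mainchain = True
                else:
                    a.mainchain = False
    return s
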