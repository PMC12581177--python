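"""Synthetic inputs: ideal beta strands, parallel in-register double layers,
and controlled hydrogen-bond fixtures.

The builder stands in for crystal-derived coordinates: it produces a
15-residue amyloid-beta fragment (positions 20-34, sequence
FAEDVGSNKGAIIGL) as an ideal extended beta strand and stacks two exact
translated copies ~4.8 A apart along the sheet's hydrogen-bonding axis,
which yields a parallel in-register ladder with one mainchain
intermolecular hydrogen bond per i-(i+1) segment.

Strand geometry comes from RDKit (sequence -> 3D embed with standard
bond lengths/angles), after which every backbone dihedral is set exactly:
omega = 180 deg, (phi, psi) as requested, sidechains in a single extended
rotamer (chi = 180 deg along the main arm).  The default (phi, psi) =
(-120, +120) deg lies in the parallel-beta region of the Ramachandran map
and aligns consecutive carbonyls with the stacking axis so the ladder
actually forms under the 3.6 A / 120 deg hydrogen-bond criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms
from rdkit import RDLogger

from .elements import AA1TO3
from .structures import Atom, Monomer, Residue, Structure, TopologyError, infer_topology
from .structure_io import assign_layers

RDLogger.DisableLog("rdApp.*")

ABETA_20_34 = "FAEDVGSNKGAIIGL"
ABETA_START = 20


@dataclass
class BuilderParams:
    """Geometry of the synthetic double layer.

    layer_separation defaults to 4.8 A, the inter-strand spacing of
    parallel in-register beta sheets (the experimental amyloid value is
    ~4.78 A).  registry_shift slides the upper copy along the strand by
    whole residues (0 = in register).  jitter_sigma adds seeded Gaussian
    coordinate noise for test ensembles.
    """

    sequence: str = ABETA_20_34
    phi: float = -120.0
    psi: float = 120.0
    layer_separation: float = 4.8
    registry_shift: int = 0
    seed: int = 7
    jitter_sigma: float = 0.0
    start_position: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.layer_separation <= 0:
            raise ValueError("layer_separation must be > 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        bad = [c for c in self.sequence if c not in AA1TO3]
        if bad:
            raise ValueError(f"unknown residue code(s): {bad}")

    @property
    def first_position(self) -> int:
        if self.start_position is not None:
            return self.start_position
        return ABETA_START if self.sequence == ABETA_20_34 else 1


# ---------------------------------------------------------------------------
# strand construction


def _backbone_indices(mol: "Chem.Mol") -> dict[int, dict[str, int]]:
    bb: dict[int, dict[str, int]] = {}
    for a in mol.GetAtoms():
        mi = a.GetMonomerInfo()
        if mi is None:
            continue
        name = mi.GetName().strip()
        if name in {"N", "CA", "C", "O", "OXT"}:
            bb.setdefault(mi.GetResidueNumber(), {})[name] = a.GetIdx()
    return bb


def _set_backbone_dihedrals(mol: "Chem.Mol", phi: float, psi: float) -> None:
    conf = mol.GetConformer()
    bb = _backbone_indices(mol)
    nres = max(bb)
    for i in range(1, nres + 1):
        b = bb[i]
        if i > 1:
            rdMolTransforms.SetDihedralDeg(conf, bb[i - 1]["C"], b["N"], b["CA"], b["C"], phi)
        if i < nres:
            rdMolTransforms.SetDihedralDeg(conf, b["N"], b["CA"], b["C"], bb[i + 1]["N"], psi)
            rdMolTransforms.SetDihedralDeg(conf, b["CA"], b["C"], bb[i + 1]["N"], bb[i + 1]["CA"], 180.0)


def _extend_sidechains(mol: "Chem.Mol") -> None:
    """Walk each sidechain's main arm from CA and set every rotatable torsion to 180 deg."""
    conf = mol.GetConformer()
    bb = _backbone_indices(mol)
    for i, b in bb.items():
        prev, cur = b["N"], b["CA"]
        visited = {b["N"], b["C"]}
        while True:
            nxt = sorted(
                n.GetIdx()
                for n in mol.GetAtomWithIdx(cur).GetNeighbors()
                if n.GetAtomicNum() > 1
                and n.GetIdx() not in visited
                and n.GetIdx() != prev
                and not mol.GetBondBetweenAtoms(cur, n.GetIdx()).IsInRing()
            )
            if not nxt:
                break
            nb = nxt[0]
            beyond = sorted(
                n.GetIdx()
                for n in mol.GetAtomWithIdx(nb).GetNeighbors()
                if n.GetAtomicNum() > 1 and n.GetIdx() != cur
            )
            if beyond:
                try:
                    rdMolTransforms.SetDihedralDeg(conf, prev, cur, nb, beyond[0], 180.0)
                except (ValueError, RuntimeError):
                    pass  # torsion in a ring or otherwise unsettable
            visited.add(cur)
            prev, cur = cur, nb


_H_NAME_BY_PARENT = {"N": "H", "CA": "HA", "OXT": "HXT"}


def _mol_to_monomer(mol: "Chem.Mol", first_position: int, codes: str) -> Monomer:
    """Convert an RDKit peptide (with PDB residue info on heavy atoms) to a Monomer."""
    conf = mol.GetConformer()
    X = conf.GetPositions()
    res_atoms: dict[int, list[tuple[int, str, str]]] = {}
    parent_of_h: dict[int, int] = {}
    heavy_name: dict[int, tuple[int, str]] = {}
    for a in mol.GetAtoms():
        mi = a.GetMonomerInfo()
        if mi is not None:
            heavy_name[a.GetIdx()] = (mi.GetResidueNumber(), mi.GetName().strip())
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 1:
            parent = a.GetNeighbors()[0].GetIdx()
            parent_of_h[a.GetIdx()] = parent

    for idx, (rn, name) in sorted(heavy_name.items()):
        res_atoms.setdefault(rn, []).append((idx, name, Chem.Atom(mol.GetAtomWithIdx(idx).GetAtomicNum()).GetSymbol()))
    # attach hydrogens after their parent residues, named from the parent atom
    h_counter: dict[tuple[int, str], int] = {}
    for h_idx, p_idx in sorted(parent_of_h.items()):
        rn, pname = heavy_name[p_idx]
        base = _H_NAME_BY_PARENT.get(pname, "H" + pname[1:])
        h_counter[(rn, base)] = h_counter.get((rn, base), 0) + 1
        k = h_counter[(rn, base)]
        res_atoms[rn].append((h_idx, base if k == 1 else f"{base}{k}", "H"))

    residues = []
    serial = 0
    for rn in sorted(res_atoms):
        atoms = []
        for idx, name, el in res_atoms[rn]:
            serial += 1
            atoms.append(Atom(serial, name, el, X[idx].copy()))
        residues.append(Residue(first_position + rn - 1, codes[rn - 1], atoms))
    return Monomer(residues)


def _orient_strand(m: Monomer) -> None:
    """Rotate/translate in place: strand axis -> x, carbonyl (H-bond) axis -> z, centroid -> origin."""
    ca = np.array([r.atom("CA").coords for r in m.residues])
    atoms = [a for r in m.residues for a in r.atoms]
    X = np.array([a.coords for a in atoms])
    center = ca.mean(axis=0)
    X = X - center
    ca = ca - center
    if len(m.residues) >= 2:
        _, _, vt = np.linalg.svd(ca - ca.mean(axis=0))
        ax = vt[0] / np.linalg.norm(vt[0])
        if np.dot(ca[-1] - ca[0], ax) < 0:
            ax = -ax
    else:
        ax = np.array([1.0, 0.0, 0.0])
    vs = []
    for k, r in enumerate(m.residues):
        if r.has_atom("O"):
            v = r.atom("O").coords - r.atom("C").coords
            v = v / np.linalg.norm(v)
            vs.append(v * (1.0 if k % 2 == 0 else -1.0))
    if vs:
        z = np.mean(vs, axis=0)
        z = z - np.dot(z, ax) * ax
        nz = np.linalg.norm(z)
        z = z / nz if nz > 1e-8 else _any_perpendicular(ax)
    else:
        z = _any_perpendicular(ax)
    y = np.cross(z, ax)
    R = np.array([ax, y, z])
    X = X @ R.T
    for a, x in zip(atoms, X):
        a.coords = x


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, w)
    return p / np.linalg.norm(p)


def build_strand(p: BuilderParams) -> Monomer:
    """Ideal extended beta strand for p.sequence with every hydrogen placed.

    Every non-terminal residue's (phi, psi) equals the requested values
    exactly (set as torsions, not refined).  The strand is oriented with
    its axis along x and its carbonyl ladder along z.
    """
    cached = _build_strand_cached(p.sequence, p.phi, p.psi, p.first_position)
    return Monomer(
        [Residue(r.position, r.code, [a.copy() for a in r.atoms]) for r in cached.residues]
    )


@lru_cache(maxsize=16)
def _build_strand_cached(sequence: str, phi: float, psi: float, first_position: int) -> Monomer:
    p = BuilderParams(sequence=sequence, phi=phi, psi=psi, start_position=first_position)
    mol = Chem.MolFromSequence(p.sequence)
    if mol is None:
        raise ValueError(f"cannot build sequence {p.sequence!r}")
    etkdg = AllChem.ETKDGv3()
    # fixed embedding seed: the strand geometry is a deterministic definition
    # (every dihedral is forced afterwards); BuilderParams.seed drives jitter
    etkdg.randomSeed = 7
    etkdg.useRandomCoords = True
    if AllChem.EmbedMolecule(mol, etkdg) != 0:
        raise RuntimeError(f"embedding failed for sequence {p.sequence!r}")
    mol = Chem.AddHs(mol, addCoords=True)
    if len(p.sequence) > 1:
        _set_backbone_dihedrals(mol, p.phi, p.psi)
        _extend_sidechains(mol)
    monomer = _mol_to_monomer(mol, p.first_position, p.sequence)
    _orient_strand(monomer)
    return monomer


# ---------------------------------------------------------------------------
# double layer


def _strand_rise(m: Monomer) -> float:
    ca = np.array([r.atom("CA").coords for r in m.residues])
    if len(ca) < 2:
        return 3.4
    return float(np.mean(np.diff(ca[:, 0])))


def build_parallel_dimer(p: BuilderParams) -> Structure:
    """Two in-register translated copies of the ideal strand, layer_separation apart.

    The upper copy is an exact translate of the lower along the stacking
    (hydrogen-bond) axis; with default geometry this produces one
    intermolecular mainchain hydrogen bond per i-(i+1) segment.  Raises
    TopologyError when the separation causes covalent-scale clashes
    (heavy-atom contact < 1.5 A between layers).
    """
    lower = build_strand(p)
    shift = np.array([0.0, 0.0, p.layer_separation])
    if p.registry_shift:
        shift = shift + np.array([p.registry_shift * _strand_rise(lower), 0.0, 0.0])
    upper = Monomer(
        [
            Residue(r.position, r.code, [Atom(a.serial, a.name, a.element, a.coords + shift) for a in r.atoms])
            for r in lower.residues
        ]
    )
    # renumber serials over the whole dimer
    serial = 0
    for m in (lower, upper):
        for r in m.residues:
            for a in r.atoms:
                serial += 1
                a.serial = serial
    s = Structure([lower, upper], provenance=f"synthetic parallel dimer {p.sequence}")
    if p.jitter_sigma > 0:
        rng = np.random.default_rng(p.seed)
        s = s.with_coords(s.coords() + rng.normal(0.0, p.jitter_sigma, (s.n_atoms, 3)))

    lo = np.array([a.coords for r in s.monomers[0].residues for a in r.atoms if a.element != "H"])
    hi = np.array([a.coords for r in s.monomers[1].residues for a in r.atoms if a.element != "H"])
    dmin = float(np.min(np.linalg.norm(lo[:, None, :] - hi[None, :, :], axis=-1)))
    if dmin < 1.5:
        raise TopologyError(f"layer separation {p.layer_separation} A causes covalent clash (min contact {dmin:.2f} A)")
    infer_topology(s)
    assign_layers(s)
    return s


# ---------------------------------------------------------------------------
# controlled hydrogen-bond fixture


def _rotate_about(point: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    v = point - origin
    return origin + v * np.cos(th) + np.cross(u, v) * np.sin(th) + u * np.dot(u, v) * (1 - np.cos(th))


def make_hb_fixture(n_bonds: int, seed: int = 7, criteria=None) -> Structure:
    """Dimer with exactly ``n_bonds`` detectable intermolecular hydrogen bonds.

    Starts from a poly-glycine double layer (a clean ladder) and swings
    acceptor carbonyls / donor hydrogens of the surplus rungs out of the
    geometric criteria, one bond at a time, until exactly ``n_bonds``
    donor-H...acceptor triples remain.  Deterministic given ``seed``.
    """
    from .hbonds import HBCriteria, detect_hbonds  # local import; hbonds does not import synthetic

    if n_bonds < 0:
        raise ValueError("n_bonds must be >= 0")
    if n_bonds > 21:
        raise ValueError("fixture supports at most 21 bonds (a 24-residue ladder)")
    criteria = criteria or HBCriteria()
    length = max(15, n_bonds + 3)
    s = build_parallel_dimer(BuilderParams(sequence="G" * length, seed=seed, start_position=1))
    adj = s.adjacency()

    def inter_bonds():
        hbs = [hb for hb in detect_hbonds(s, criteria) if hb.scope == "intermolecular"]
        return sorted(hbs, key=lambda hb: (hb.donor_index, hb.acceptor_index, hb.hydrogen_index))

    initial = inter_bonds()
    if n_bonds > len(initial):
        raise ValueError(f"fixture supports at most {len(initial)} bonds, requested {n_bonds}")
    keep = {(hb.donor_index, hb.acceptor_index) for hb in initial[:n_bonds]}

    X = s.coords()
    for _ in range(12):
        current = inter_bonds()
        surplus = [hb for hb in current if (hb.donor_index, hb.acceptor_index) not in keep]
        if not surplus and len(current) == n_bonds:
            break
        for hb in surplus:
            # swing the acceptor (if terminal, e.g. carbonyl O) or else the donor H
            a_idx = hb.acceptor_index
            heavy_nb = [j for j in adj[a_idx] if s.atoms[j].element != "H"]
            if len(heavy_nb) == 1 and len(adj[a_idx]) == 1:
                parent = heavy_nb[0]
                ref = [j for j in adj[parent] if j != a_idx and s.atoms[j].element != "H"]
                X[a_idx] = _rotate_about(X[a_idx], X[parent], X[ref[0]] - X[parent], 137.0)
            else:
                h_idx = hb.hydrogen_index
                parent = hb.donor_index
                ref = [j for j in adj[parent] if j != h_idx and s.atoms[j].element != "H"]
                axis = X[ref[0]] - X[parent] if ref else np.array([1.0, 0.0, 0.0])
                X[h_idx] = _rotate_about(X[h_idx], X[parent], axis, 137.0)
            s = s.with_coords(X)
    else:
        raise RuntimeError(f"could not converge to exactly {n_bonds} hydrogen bonds")

    s.provenance = f"synthetic HB fixture n={n_bonds}"
    infer_topology(s)
    assign_layers(s)
    return s
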