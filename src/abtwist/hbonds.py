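"""Geometric hydrogen-bond detection and the structural observables built on it.

A hydrogen bond is a donor-H...acceptor triple satisfying two criteria:
donor-acceptor distance <= 3.6 A and D-H...A angle >= 120 deg (boundary
values inclusive).  Donors are N or O atoms covalently bearing at least
one hydrogen; acceptors are any O atom, plus N atoms carrying no
hydrogen.  Triples with donor and acceptor in the same residue are
excluded.  A bond is classed mainchain only when both heavy partners are
mainchain atoms.

On top of the detector sit the dimer observables: the broken/formed
ledger between two conformations (delta_n_hb counts intermolecular
mainchain breaks), the interlayer distance (mean of in-register CA-CA
distances), the per-segment carbonyl O-O distance, and the near-axis
contact table for barrier-top / local-minimum images of a pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import SegmentLabel, Structure, TopologyError


@dataclass
class HBCriteria:
    max_donor_acceptor_distance: float = 3.6
    min_dha_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance criterion must be > 0")
        if not 0 <= self.min_dha_angle <= 180:
            raise ValueError("angle criterion must be in [0, 180]")


@dataclass
class HydrogenBond:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_desc: tuple[int, int, str]      # (monomer, residue position, atom name)
    hydrogen_desc: tuple[int, int, str]
    acceptor_desc: tuple[int, int, str]
    da_distance: float
    dha_angle: float
    scope: str                            # intermolecular | intramolecular
    donor_class: str                      # mainchain | sidechain
    acceptor_class: str

    @property
    def is_mainchain(self) -> bool:
        return self.donor_class == "mainchain" and self.acceptor_class == "mainchain"

    @property
    def key(self) -> tuple:
        """Identity of the bond, ignoring which hydrogen carries it."""
        return (self.donor_desc, self.acceptor_desc)


@dataclass
class HBChangeReport:
    delta_n_hb: int
    broken: list[HydrogenBond] = field(default_factory=list)
    formed: list[HydrogenBond] = field(default_factory=list)


@dataclass
class ContactReport:
    axis_label: str
    pairs: list[tuple[str, float, float]]  # (atom-pair description, d at barrier top, d at local minimum)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def donor_acceptor_atoms(s: Structure) -> tuple[list[tuple[int, int]], list[int]]:
    """Donor (heavy, hydrogen) index pairs and acceptor indices.

    Donors: N/O bearing >= 1 H.  Acceptors: any O; N with no bonded H.
    """
    atoms = s.atoms
    adj = s.adjacency()
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i, a in enumerate(atoms):
        if a.element not in {"N", "O"}:
            continue
        hs = sorted(j for j in adj[i] if atoms[j].element == "H")
        for h in hs:
            donors.append((i, h))
        if a.element == "O" or not hs:
            acceptors.append(i)
    return donors, acceptors


def detect_hbonds(s: Structure, criteria: HBCriteria | None = None) -> list[HydrogenBond]:
    """All donor-H...acceptor triples satisfying the geometric criteria, once each."""
    criteria = criteria or HBCriteria()
    atoms = s.atoms
    if not any(a.element == "H" for a in atoms):
        raise TopologyError("structure has no hydrogens; cannot detect hydrogen bonds")
    X = s.coords()
    meta = s.atom_meta()
    reskey = s.residue_key_of()
    donors, acceptors = donor_acceptor_atoms(s)
    out: list[HydrogenBond] = []
    for d, h in donors:
        for a in acceptors:
            if a == d or a == h:
                continue
            if reskey[a] == reskey[d]:
                continue
            dist = float(np.linalg.norm(X[d] - X[a]))
            if dist > criteria.max_donor_acceptor_distance:
                continue
            ang = _angle_deg(X[d] - X[h], X[a] - X[h])
            if ang < criteria.min_dha_angle:
                continue
            out.append(
                HydrogenBond(
                    donor_index=d,
                    hydrogen_index=h,
                    acceptor_index=a,
                    donor_desc=meta[d],
                    hydrogen_desc=meta[h],
                    acceptor_desc=meta[a],
                    da_distance=dist,
                    dha_angle=ang,
                    scope="intermolecular" if meta[d][0] != meta[a][0] else "intramolecular",
                    donor_class="mainchain" if atoms[d].mainchain else "sidechain",
                    acceptor_class="mainchain" if atoms[a].mainchain else "sidechain",
                )
            )
    out.sort(key=lambda hb: (hb.donor_index, hb.acceptor_index, hb.hydrogen_index))
    return out


def count_hbonds(
    s: Structure,
    scope: str | None = None,
    class_filter: str | None = None,
    criteria: HBCriteria | None = None,
) -> int:
    """Number of hydrogen bonds after scope/class filtering.

    class_filter='mainchain' keeps bonds whose both heavy partners are
    mainchain; 'sidechain' keeps bonds involving at least one sidechain
    heavy partner.
    """
    if scope == "intermolecular" and len(s.monomers) < 2:
        raise TopologyError("intermolecular scope requires a dimer")
    hbs = detect_hbonds(s, criteria)
    n = 0
    for hb in hbs:
        if scope and hb.scope != scope:
            continue
        if class_filter == "mainchain" and not hb.is_mainchain:
            continue
        if class_filter == "sidechain" and hb.is_mainchain:
            continue
        n += 1
    return n


def delta_hb(
    reference: Structure,
    comparison: Structure,
    criteria: HBCriteria | None = None,
) -> HBChangeReport:
    """Broken/formed hydrogen-bond ledger between two conformations.

    Bonds are keyed by (donor, acceptor) identity, so a bond that merely
    switches hydrogens is unchanged.  delta_n_hb counts intermolecular
    mainchain bonds present in the reference and absent in the comparison.
    """
    if [a.name for a in reference.atoms] != [a.name for a in comparison.atoms] or \
            reference.atom_meta() != comparison.atom_meta():
        raise TopologyError("reference and comparison structures have different topologies")
    ref = {hb.key: hb for hb in detect_hbonds(reference, criteria)}
    cmp_ = {hb.key: hb for hb in detect_hbonds(comparison, criteria)}
    broken = [ref[k] for k in ref if k not in cmp_]
    formed = [cmp_[k] for k in cmp_ if k not in ref]
    n = sum(1 for hb in broken if hb.scope == "intermolecular" and hb.is_mainchain)
    return HBChangeReport(delta_n_hb=n, broken=broken, formed=formed)


def interlayer_distance(s: Structure) -> float:
    """Mean over residue positions of the corresponding upper/lower CA-CA distance."""
    upper, lower = s.upper, s.lower
    if upper.positions != lower.positions:
        raise TopologyError("interlayer distance requires matching residue positions in both layers")
    d = [
        float(np.linalg.norm(ru.atom("CA").coords - rl.atom("CA").coords))
        for ru, rl in zip(upper.residues, lower.residues)
    ]
    return float(np.mean(d))


def segment_oo_distance(s: Structure, seg: SegmentLabel | int) -> float:
    """Distance between upper and lower mainchain carbonyl O of the i-(i+1) segment.

    The segment's carbonyl is the C=O of residue i.
    """
    i = seg.i if isinstance(seg, SegmentLabel) else int(seg)
    upper, lower = s.upper, s.lower
    for m in (upper, lower):
        if i not in m.positions or (i + 1) not in m.positions:
            raise TopologyError(f"segment {i}-{i + 1} not present in both monomers")
    return float(np.linalg.norm(upper.residue(i).atom("O").coords - lower.residue(i).atom("O").coords))


def _near_axis_residue_position(axis) -> int:
    """Residue whose sidechain sits at the torsional axis: i for psi(i), i-1 for phi(i)."""
    return axis.residue_position if axis.kind == "psi" else axis.residue_position - 1


def contact_table(images: list[Structure], axis, barrier_index: int, minimum_index: int) -> ContactReport:
    """Near-axis steric contact distances at the barrier-top and local-minimum images.

    For an aspartate near the axis: minimum distance from each sidechain
    carboxyl O (upper) to the lower mainchain carbonyl O of the segment
    N-terminal of it.  Otherwise: minimum distance from each sidechain
    hydrogen of the near-axis residue (both alpha hydrogens for glycine)
    to any hydrogen of the lower monomer.
    """
    if not images:
        raise ValueError("empty pathway")
    for idx in (barrier_index, minimum_index):
        if not 0 <= idx < len(images):
            raise IndexError(f"image index {idx} out of range (0..{len(images) - 1})")
    pos = _near_axis_residue_position(axis)
    top, mini = images[barrier_index], images[minimum_index]
    res = top.upper.residue(pos)
    label = getattr(axis, "label", f"{res.code}{pos}")

    def lower_targets(s: Structure, mode: str) -> np.ndarray:
        if mode == "OO":
            return np.array([s.lower.residue(pos - 1).atom("O").coords])
        coords = [a.coords for r in s.lower.residues for a in r.atoms if a.element == "H"]
        if not coords:
            raise TopologyError("lower monomer has no hydrogens")
        return np.array(coords)

    if res.code == "D":
        mode = "OO"
        probe_names = [a.name for a in res.sidechain_atoms if a.element == "O"]
    else:
        mode = "HH"
        probe_names = [a.name for a in res.atoms if a.element == "H" and not a.mainchain]
        if res.code == "G":
            probe_names = [a.name for a in res.atoms if a.element == "H" and a.name.startswith("HA")]
    if not probe_names:
        raise TopologyError(f"near-axis residue {res.code}{pos} lacks the probed atom class")

    pairs = []
    for name in probe_names:
        d_top = float(np.min(np.linalg.norm(lower_targets(top, mode) - top.upper.residue(pos).atom(name).coords, axis=1)))
        d_min = float(np.min(np.linalg.norm(lower_targets(mini, mode) - mini.upper.residue(pos).atom(name).coords, axis=1)))
        kind = "O-O" if mode == "OO" else "H-H"
        pairs.append((f"{res.code}{pos}:{name} {kind}", d_top, d_min))
    return ContactReport(axis_label=str(label), pairs=pairs)
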