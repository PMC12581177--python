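"""Backbone torsion kinematics: axis enumeration, rigid twisting, clash screening.

A torsional axis is a backbone single bond of the upper monomer: the
CA(i)-C(i) bond for psi(i) or the N(i)-CA(i) bond for phi(i).  Twisting
rotates, as a rigid body, the connected component on the N-terminal side
of that bond (found by deleting the bond from the covalent graph), which
lifts the chain N-terminal of the axis off the lower layer while leaving
the C-terminal beta-ladder untouched.  The applied delta is defined so
that the measured Ramachandran dihedral changes by exactly +delta
(mod 360 deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Structure, TopologyError
from .structure_io import stacking_axis


@dataclass(frozen=True)
class TorsionAxis:
    residue_position: int
    kind: str  # 'psi' | 'phi'
    monomer: str = "upper"

    def __post_init__(self) -> None:
        if self.kind not in {"psi", "phi"}:
            raise ValueError(f"axis kind must be psi or phi, got {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.residue_position}:{self.kind}"

    def label_with_code(self, s: Structure) -> str:
        code = s.upper.residue(self.residue_position).code
        return f"{code}{self.residue_position}:{self.kind}"


@dataclass
class TwistResult:
    structure: Structure
    axis: TorsionAxis
    applied_angle: float
    relaxed: bool = False
    clash_count: int = 0


def parse_axis(spec: str) -> TorsionAxis:
    """Parse an axis spec like 'G25:psi' or '25:phi'."""
    try:
        resid, kind = spec.split(":")
    except ValueError as exc:
        raise ValueError(f"axis spec {spec!r} is not of the form RES<POS>:<psi|phi>") from exc
    digits = "".join(c for c in resid if c.isdigit())
    if not digits:
        raise ValueError(f"axis spec {spec!r} has no residue position")
    return TorsionAxis(int(digits), kind.strip().lower())


# ---------------------------------------------------------------------------
# geometry helpers


def measure_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    # sign: atan2((n1 x n2).b2_hat, n1.n2), the IUPAC convention
    return float(np.degrees(np.arctan2(-np.dot(m, n2), np.dot(n1, n2))))


def _wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def dihedral_atom_indices(s: Structure, axis: TorsionAxis) -> tuple[int, int, int, int]:
    """Flat indices of the four atoms defining the axis' Ramachandran dihedral."""
    meta = s.atom_meta()
    mi = s.upper_index()
    lookup = {(pos, name): k for k, (m, pos, name) in enumerate(meta) if m == mi}
    i = axis.residue_position
    try:
        if axis.kind == "psi":
            return (lookup[(i, "N")], lookup[(i, "CA")], lookup[(i, "C")], lookup[(i + 1, "N")])
        return (lookup[(i - 1, "C")], lookup[(i, "N")], lookup[(i, "CA")], lookup[(i, "C")])
    except KeyError as exc:
        raise TopologyError(f"dihedral {axis.label} is not defined in this structure") from exc


def axis_atom_indices(s: Structure, axis: TorsionAxis) -> tuple[int, int]:
    """Flat indices of the rotation bond: (CA(i), C(i)) for psi, (N(i), CA(i)) for phi."""
    _, b, c, _ = dihedral_atom_indices(s, axis)
    return b, c


def moving_set(s: Structure, axis: TorsionAxis) -> np.ndarray:
    """Flat indices rotated by the torsion: the component on the N-terminal
    side of the axis bond after deleting it from the covalent graph."""
    b, c = axis_atom_indices(s, axis)
    adj = s.adjacency()
    seen = {b}
    stack = [b]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if u == b and v == c:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if c in seen:
        raise TopologyError(f"axis bond {axis.label} lies on a cycle; cannot split the molecule")
    # b itself lies on the axis line, so its rotation is the identity; it is
    # kept in the moving set (the pivot CA/N belongs to the lifted side).
    return np.array(sorted(seen), dtype=int)


def _rotation_matrix(axis_vec: np.ndarray, angle_deg: float) -> np.ndarray:
    u = axis_vec / np.linalg.norm(axis_vec)
    th = np.radians(angle_deg)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) * np.cos(th) + np.sin(th) * K + (1 - np.cos(th)) * np.outer(u, u)


def apply_torsion(s: Structure, axis: TorsionAxis, delta: float) -> TwistResult:
    """Rigidly rotate the N-terminal moving set about the axis bond by delta degrees.

    The measured dihedral changes by exactly +delta (mod 360).  All
    pairwise distances within the moving set and within its complement
    are preserved (rigid-body rotation).
    """
    b, c = axis_atom_indices(s, axis)
    X = s.coords()
    axis_vec = X[c] - X[b]
    if np.linalg.norm(axis_vec) < 1e-8:
        raise TopologyError(f"axis atoms of {axis.label} are coincident")
    mv = moving_set(s, axis)
    # Rotating the N-terminal side by -delta (right-hand rule about the
    # b->c axis vector) advances the IUPAC dihedral by exactly +delta.
    R = _rotation_matrix(axis_vec, -delta)
    Xn = X.copy()
    Xn[mv] = (X[mv] - X[b]) @ R.T + X[b]
    out = s.with_coords(Xn)
    return TwistResult(structure=out, axis=axis, applied_angle=_wrap_angle(delta), relaxed=False,
                       clash_count=clash_count(out, 1.8, heavy_only=True))


def enumerate_axes(s: Structure, residue_range) -> list[TorsionAxis]:
    """Torsional axes of the upper monomer for each residue in the range.

    Order is deterministic: N->C, phi before psi within a residue.  phi is
    undefined at the N-terminal residue (no chain to lift) and psi at the
    C-terminal residue.
    """
    positions = sorted(residue_range)
    if not positions:
        raise ValueError("empty residue range")
    upper = s.upper
    known = upper.positions
    first, last = known[0], known[-1]
    axes = []
    for i in positions:
        if i not in known:
            raise TopologyError(f"residue position {i} not in upper monomer")
        if i > first:
            axes.append(TorsionAxis(i, "phi"))
        if i < last:
            axes.append(TorsionAxis(i, "psi"))
    return axes


def clash_count(s: Structure, cutoff: float, heavy_only: bool = False) -> int:
    """Non-bonded atom pairs (1-2 and 1-3 exclusions applied) closer than cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    X = s.coords()
    n = len(X)
    adj = s.adjacency()
    excluded = set()
    for i in range(n):
        for j in adj[i]:
            excluded.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
    from scipy.spatial import cKDTree

    heavy = np.array([a.element != "H" for a in s.atoms])
    tree = cKDTree(X)
    count = 0
    for i, j in tree.query_pairs(cutoff):
        a, b = min(i, j), max(i, j)
        if (a, b) in excluded:
            continue
        if heavy_only and not (heavy[a] and heavy[b]):
            continue
        count += 1
    return count


def _min_nonbonded_heavy(s: Structure) -> float:
    """Smallest non-bonded (beyond 1-3) heavy-atom distance in the structure."""
    from scipy.spatial import cKDTree

    X = s.coords()
    adj = s.adjacency()
    heavy = np.array([a.element != "H" for a in s.atoms])
    excluded = set()
    for i in range(len(X)):
        for j in adj[i]:
            excluded.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
    best = np.inf
    for i, j in cKDTree(X).query_pairs(2.0):
        a, b = min(i, j), max(i, j)
        if (a, b) in excluded or not (heavy[a] and heavy[b]):
            continue
        best = min(best, float(np.linalg.norm(X[a] - X[b])))
    return best


def _segment_backbone_dihedrals(s: Structure, axis: TorsionAxis) -> list[tuple[int, int, int, int]]:
    """Flat-index quadruples of every backbone torsion (phi, psi, omega) of the
    upper monomer from the N-terminus through the axis residue."""
    meta = s.atom_meta()
    mi = s.upper_index()
    lookup = {(pos, name): k for k, (m, pos, name) in enumerate(meta) if m == mi}
    positions = s.upper.positions
    quads = []
    for i in positions:
        if i > axis.residue_position:
            break
        if (i - 1, "C") in lookup:  # phi(i)
            quads.append((lookup[(i - 1, "C")], lookup[(i, "N")], lookup[(i, "CA")], lookup[(i, "C")]))
        if (i + 1, "N") in lookup:  # psi(i) and omega(i, i+1)
            quads.append((lookup[(i, "N")], lookup[(i, "CA")], lookup[(i, "C")], lookup[(i + 1, "N")]))
            if (i + 1, "CA") in lookup:
                quads.append((lookup[(i, "CA")], lookup[(i, "C")], lookup[(i + 1, "N")], lookup[(i + 1, "CA")]))
    return quads


def relax_twist_endpoint(
    s: Structure,
    axis: TorsionAxis,
    delta: float,
    energy_params=None,
    max_iter: int = 800,
    tether_k: float = 25.0,
) -> TwistResult:
    """Apply a fixed torsion and relax with the lifted backbone tethered.

    The moving segment's mainchain atoms are held at their rigid-rotation
    positions (the detached region keeps its strand geometry) while
    sidechains, the ladder and covalent geometry relax.  This is the
    endpoint-preparation step of generate_twisted exposed for controlled,
    matched-pair constructions.
    """
    from .energy import minimize

    cand = apply_torsion(s, axis, delta)
    mv = moving_set(s, axis)
    mainchain = s.mainchain_mask()
    Xc = cand.structure.coords()
    tethers = [(int(i), Xc[int(i)], tether_k) for i in mv if mainchain[int(i)]]
    res = minimize(cand.structure, energy_params, max_iter=max_iter, position_restraints=tethers)
    return TwistResult(
        structure=res.structure,
        axis=axis,
        applied_angle=_wrap_angle(delta),
        relaxed=res.converged,
        clash_count=clash_count(res.structure, 1.8, heavy_only=True),
    )


def generate_twisted(
    s: Structure,
    axis: TorsionAxis,
    angle_grid: np.ndarray | None = None,
    energy_params=None,
    relax: bool = True,
    minimize_max_iter: int = 800,
) -> TwistResult:
    """Scan the angle grid for a lifted, viable twisted conformation and relax it.

    Both torsion directions are scanned over the grid; angles that drive
    heavy atoms inside the covalent core (non-bonded contact < 0.5 A,
    which the surrogate cannot relax apart) are rejected.  Among the
    viable angles, candidates breaking the most intermolecular mainchain
    hydrogen bonds are preferred (the twist is meant to detach the
    N-terminal chain), with segment lift as the tie-break; the winner is
    relaxed to a nearby torsion-pinned optimum.
    """
    from .energy import EnergyParams, minimize
    from .hbonds import delta_hb, detect_hbonds

    if angle_grid is None:
        angle_grid = np.arange(10.0, 181.0, 10.0)
    # Both torsion directions are scanned; the direction that drives the
    # near-axis sidechain through a layer is eliminated by the clash screen
    # (the steric limitation on direction and axis choice).
    mv = moving_set(s, axis)
    try:
        up = stacking_axis(s)
        if s.monomers[0].layer_label == "upper":
            up = -up  # stacking_axis points monomer0 -> monomer1
    except TopologyError:
        up = np.array([0.0, 0.0, 1.0])

    params = energy_params or EnergyParams()
    flat_lift = float(np.mean(s.coords()[mv] @ up))
    # the ladder rungs the twist is supposed to break: every flat
    # intermolecular mainchain HB carried by an atom of the moving set
    mvset = set(int(i) for i in mv)
    target_keys = {
        hb.key
        for hb in detect_hbonds(s)
        if hb.scope == "intermolecular"
        and hb.is_mainchain
        and ({hb.donor_index, hb.hydrogen_index, hb.acceptor_index} & mvset)
    }

    candidates = []
    for a in angle_grid:
        for sign in (+1.0, -1.0):
            delta = sign * float(a)
            if delta == -180.0:
                continue
            t = apply_torsion(s, axis, delta)
            # a rigid rotation of an in-register stack always grazes something;
            # overlaps deep inside the covalent core cannot be relaxed apart
            # even adiabatically, so those angles are disqualified outright
            if _min_nonbonded_heavy(t.structure) < 0.3:
                continue
            n_broken = delta_hb(s, t.structure).delta_n_hb
            lift = float(np.mean(t.structure.coords()[mv] @ up)) - flat_lift
            candidates.append((n_broken, lift, delta))
    if not candidates:
        raise TopologyError(f"no viable twist found for axis {axis.label}: every grid angle clashes")
    # prefer candidates detaching the whole N-terminal ladder; among those,
    # the most lifted segment, which survives relaxation without re-docking
    candidates.sort(key=lambda c: (c[0], c[1]), reverse=True)
    if not relax:
        return apply_torsion(s, axis, candidates[0][2])

    # The twisted endpoint is prepared as a constrained optimum: a twisted
    # state need not be a free minimum of the surrogate (torsions are
    # unrestrained and the detached chain is floppy), so the lifted
    # segment's backbone atoms are tethered to their rigid-rotation
    # positions — the detached region keeps its strand geometry — while
    # sidechain rotamers, the ladder and covalent geometry relax freely.
    best = None  # (delta_n_hb, TwistResult)
    for n_broken, _, delta in candidates[:8]:
        result = relax_twist_endpoint(s, axis, delta, params, max_iter=minimize_max_iter)
        change = delta_hb(s, result.structure)
        broken_keys = {
            hb.key for hb in change.broken if hb.scope == "intermolecular" and hb.is_mainchain
        }
        if target_keys <= broken_keys and change.delta_n_hb == len(target_keys):
            return result  # exactly the N-terminal ladder is detached
        if best is None or change.delta_n_hb > best[0]:
            best = (change.delta_n_hb, result)
    return best[1]
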