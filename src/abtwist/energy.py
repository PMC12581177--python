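"""Coarse surrogate energy for peptide dimers, with analytic gradients.

The functional form captures the qualitative drivers of beta-ladder
stability — steric repulsion / van der Waals attraction and the
intermolecular hydrogen-bond ladder — without any pretence of
first-principles accuracy (energies are in arbitrary "surrogate units",
not eV):

* 12-6 Lennard-Jones over all non-bonded pairs (1-2 and 1-3 exclusions),
  per-atom-class parameters with Lorentz-Berthelot combining.  Polar
  hydrogens (on N/O) get a near-zero radius so the hydrogen-bond well can
  express itself.  Below 0.8 A the 12-6 term is evaluated at 0.8 A and a
  quadratic core penalty takes over, so overlapping atoms give a large
  but finite energy.
* a smooth hydrogen-bond well, minus ``hb_well_depth`` at ideal geometry:
  Gaussian in donor-acceptor distance times an angular alignment factor
  ((cos(180 - theta) - cos60) / (1 - cos60))^p that vanishes smoothly at
  the 120 deg criterion boundary.
* harmonic restraints tying bonded (1-2) and geminal (1-3) distances to
  the reference topology, standing in for fixed covalent geometry while
  leaving torsions free.

All terms depend only on interatomic distances and angles, so the energy
is exactly invariant under rigid rotation and translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .structures import Structure

_DEF_EPS = {"HP": 0.005, "H": 0.015, "C": 0.060, "N": 0.050, "O": 0.050, "S": 0.060}
_DEF_SIG = {"HP": 1.00, "H": 2.40, "C": 3.20, "N": 3.00, "O": 2.90, "S": 3.50}


@dataclass
class EnergyParams:
    lj_epsilon: dict = field(default_factory=lambda: dict(_DEF_EPS))
    lj_sigma: dict = field(default_factory=lambda: dict(_DEF_SIG))
    hb_well_depth: float = 1.0
    hb_ideal_distance: float = 2.9
    hb_distance_width: float = 0.35
    hb_angle_power: int = 2
    restraint_k_bond: float = 100.0
    restraint_k_angle: float = 20.0
    lj_cutoff: float = 10.0
    hb_cutoff: float = 6.0
    core_radius: float = 0.8
    core_k: float = 50.0

    def __post_init__(self) -> None:
        for name in ("hb_well_depth", "hb_ideal_distance", "hb_distance_width",
                     "restraint_k_bond", "restraint_k_angle", "lj_cutoff", "hb_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MinimizeResult:
    structure: Structure
    converged: bool
    energy: float
    n_iter: int


class EnergyModel:
    """Surrogate energy bound to one topology (pair lists precomputed once).

    ``dihedral_restraints`` is an optional list of
    ``(i, j, k, l, target_degrees, force_constant)`` tuples adding
    ``k * dtau^2`` (dtau in radians, wrapped to the shortest arc) — used to
    pin a torsion while the rest of the structure relaxes, e.g. when
    preparing a twisted endpoint that is not a free local minimum.
    """

    def __init__(
        self,
        s: Structure,
        params: EnergyParams | None = None,
        dihedral_restraints: list[tuple[int, int, int, int, float, float]] | None = None,
        position_restraints: list[tuple[int, np.ndarray, float]] | None = None,
    ):
        self.params = params or EnergyParams()
        self.dihedral_restraints = list(dihedral_restraints or [])
        self.position_restraints = [
            (int(i), np.asarray(x0, dtype=float), float(k)) for i, x0, k in (position_restraints or [])
        ]
        self.n = s.n_atoms
        X0 = s.coords()
        atoms = s.atoms
        adj = s.adjacency()
        reskey = s.residue_key_of()

        # atom classes: polar hydrogens ride on N/O
        classes = []
        for i, a in enumerate(atoms):
            if a.element == "H":
                parents = [atoms[j].element for j in adj[i]]
                classes.append("HP" if any(p in {"N", "O"} for p in parents) else "H")
            else:
                classes.append(a.element if a.element in _DEF_EPS else "C")
        eps = np.array([self.params.lj_epsilon.get(c, 0.05) for c in classes])
        sig = np.array([self.params.lj_sigma.get(c, 3.0) for c in classes])

        # exclude pairs within 3 bonds (1-2, 1-3, 1-4): covalent geometry is
        # held by the harmonic restraints and torsions are deliberately free
        excluded: set[tuple[int, int]] = set()
        for i in range(self.n):
            frontier = {i}
            seen = {i}
            for _ in range(3):
                frontier = {k for j in frontier for k in adj[j]} - seen
                seen |= frontier
            for j in seen - {i}:
                excluded.add((min(i, j), max(i, j)))
        iu, ju = np.triu_indices(self.n, 1)
        keep = np.array([(a, b) not in excluded for a, b in zip(iu, ju)], dtype=bool)
        self.pair_i = iu[keep]
        self.pair_j = ju[keep]
        self.pair_eps = np.sqrt(eps[self.pair_i] * eps[self.pair_j])
        self.pair_sig = 0.5 * (sig[self.pair_i] + sig[self.pair_j])

        self.bond_i = np.array([i for i, _ in s.bonds], dtype=int)
        self.bond_j = np.array([j for _, j in s.bonds], dtype=int)
        self.bond_r0 = (
            np.linalg.norm(X0[self.bond_i] - X0[self.bond_j], axis=1)
            if len(self.bond_i)
            else np.zeros(0)
        )
        bond_set = {(int(a), int(b)) for a, b in zip(self.bond_i, self.bond_j)}
        ang_pairs = sorted(
            {(min(i, k), max(i, k)) for j in range(self.n) for i in adj[j] for k in adj[j] if i != k}
            - bond_set
        )
        self.ang_i = np.array([i for i, _ in ang_pairs], dtype=int)
        self.ang_j = np.array([j for _, j in ang_pairs], dtype=int)
        self.ang_r0 = (
            np.linalg.norm(X0[self.ang_i] - X0[self.ang_j], axis=1)
            if len(self.ang_i)
            else np.zeros(0)
        )

        # hydrogen-bond candidate triples (donor heavy, hydrogen, acceptor)
        from .hbonds import donor_acceptor_atoms

        donors, acceptors = donor_acceptor_atoms(s)
        trip = []
        for d, h in donors:
            for a in acceptors:
                if a in (d, h) or reskey[a] == reskey[d]:
                    continue
                if (min(d, a), max(d, a)) in excluded:
                    continue
                trip.append((d, h, a))
        self.hb_d = np.array([t[0] for t in trip], dtype=int)
        self.hb_h = np.array([t[1] for t in trip], dtype=int)
        self.hb_a = np.array([t[2] for t in trip], dtype=int)

    # ------------------------------------------------------------------

    def energy(self, X: np.ndarray) -> float:
        return self.energy_and_gradient(X)[0]

    def energy_and_gradient(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        X = np.asarray(X, dtype=float).reshape(self.n, 3)
        p = self.params
        E = 0.0
        G = np.zeros_like(X)

        # Lennard-Jones + finite core
        if len(self.pair_i):
            d = X[self.pair_i] - X[self.pair_j]
            r = np.linalg.norm(d, axis=1)
            sel = r < p.lj_cutoff
            if sel.any():
                i, j = self.pair_i[sel], self.pair_j[sel]
                rr = r[sel]
                dd = d[sel]
                e4 = 4.0 * self.pair_eps[sel]
                rs = np.maximum(rr, p.core_radius)
                sr6 = (self.pair_sig[sel] / rs) ** 6
                E += float(np.sum(e4 * (sr6 * sr6 - sr6)))
                dEdr = np.where(rr > p.core_radius, e4 * (-12.0 * sr6 * sr6 + 6.0 * sr6) / rs, 0.0)
                core = rr < p.core_radius
                if core.any():
                    E += float(np.sum(p.core_k * (p.core_radius - rr[core]) ** 2))
                    dEdr = dEdr - np.where(core, 2.0 * p.core_k * (p.core_radius - rr), 0.0)
                gvec = (dEdr / np.maximum(rr, 1e-12))[:, None] * dd
                np.add.at(G, i, gvec)
                np.add.at(G, j, -gvec)

        # harmonic restraints (1-2 and 1-3 distances to reference)
        for idx_i, idx_j, r0, k in (
            (self.bond_i, self.bond_j, self.bond_r0, p.restraint_k_bond),
            (self.ang_i, self.ang_j, self.ang_r0, p.restraint_k_angle),
        ):
            if len(idx_i) == 0:
                continue
            d = X[idx_i] - X[idx_j]
            r = np.linalg.norm(d, axis=1)
            dr = r - r0
            E += float(np.sum(k * dr**2))
            gvec = (2.0 * k * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(G, idx_i, gvec)
            np.add.at(G, idx_j, -gvec)

        # hydrogen-bond wells
        if len(self.hb_d):
            dvec = X[self.hb_d] - X[self.hb_a]
            dda = np.linalg.norm(dvec, axis=1)
            sel = dda < p.hb_cutoff
            if sel.any():
                D, H, A = self.hb_d[sel], self.hb_h[sel], self.hb_a[sel]
                dda = dda[sel]
                dvec = dvec[sel]
                u = X[D] - X[H]
                v = X[A] - X[H]
                nu = np.linalg.norm(u, axis=1)
                nv = np.linalg.norm(v, axis=1)
                c = np.einsum("ij,ij->i", u, v) / (nu * nv)
                q = -c  # alignment: 1 at theta = 180 deg
                q0 = 0.5  # -cos(120 deg): well vanishes at the criterion boundary
                act = q > q0
                if act.any():
                    D, H, A = D[act], H[act], A[act]
                    dda, dvec = dda[act], dvec[act]
                    u, v, nu, nv, c, q = u[act], v[act], nu[act], nv[act], c[act], q[act]
                    g = np.exp(-((dda - p.hb_ideal_distance) ** 2) / (2.0 * p.hb_distance_width**2))
                    t = (q - q0) / (1.0 - q0)
                    s_ang = t**p.hb_angle_power
                    E += float(np.sum(-p.hb_well_depth * g * s_ang))
                    # distance part
                    dgdd = g * (-(dda - p.hb_ideal_distance) / p.hb_distance_width**2)
                    coeff_d = -p.hb_well_depth * dgdd * s_ang / np.maximum(dda, 1e-12)
                    np.add.at(G, D, coeff_d[:, None] * dvec)
                    np.add.at(G, A, -coeff_d[:, None] * dvec)
                    # angle part: dE/dq = -depth * g * p * t^(p-1) / (1-q0); q = -c
                    dEdc = p.hb_well_depth * g * p.hb_angle_power * t ** (p.hb_angle_power - 1) / (1.0 - q0)
                    dcdu = v / (nu * nv)[:, None] - (c / nu**2)[:, None] * u
                    dcdv = u / (nu * nv)[:, None] - (c / nv**2)[:, None] * v
                    np.add.at(G, D, dEdc[:, None] * dcdu)
                    np.add.at(G, A, dEdc[:, None] * dcdv)
                    np.add.at(G, H, -dEdc[:, None] * (dcdu + dcdv))

        # position tethers (endpoint pinning)
        for (i, x0, kf) in self.position_restraints:
            d = X[i] - x0
            E += float(kf * np.dot(d, d))
            G[i] += 2.0 * kf * d

        # dihedral restraints (endpoint pinning)
        for (i, j, k, l, target_deg, kf) in self.dihedral_restraints:
            tau, grads = _dihedral_and_gradient(X[i], X[j], X[k], X[l])
            dtau = tau - np.radians(target_deg)
            dtau = (dtau + np.pi) % (2 * np.pi) - np.pi
            E += float(kf * dtau**2)
            coeff = 2.0 * kf * dtau
            for idx, gr in zip((i, j, k, l), grads):
                G[idx] += coeff * gr

        return E, G


def _dihedral(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(-np.dot(m, n2), np.dot(n1, n2)))


def _dihedral_and_gradient(p0, p1, p2, p3, h: float = 1e-6):
    """Dihedral (radians, IUPAC sign) and its gradient w.r.t. the four points.

    The gradient is a central difference on the four atoms (24 cheap
    evaluations); the restraint is applied to a single torsion, so this
    costs nothing against the pairwise terms.
    """
    P = np.array([p0, p1, p2, p3], dtype=float)
    tau = _dihedral(*P)
    grads = np.zeros((4, 3))
    for a in range(4):
        for c in range(3):
            Pp = P.copy()
            Pp[a, c] += h
            Pm = P.copy()
            Pm[a, c] -= h
            d = _dihedral(*Pp) - _dihedral(*Pm)
            grads[a, c] = ((d + np.pi) % (2 * np.pi) - np.pi) / (2 * h)
    return tau, grads


def energy(s: Structure, params: EnergyParams | None = None) -> float:
    """Surrogate energy of a structure (arbitrary units)."""
    return EnergyModel(s, params).energy(s.coords())


def gradient(s: Structure, params: EnergyParams | None = None) -> np.ndarray:
    return EnergyModel(s, params).energy_and_gradient(s.coords())[1]


def minimize(
    s: Structure,
    params: EnergyParams | None = None,
    tol: float = 1e-3,
    max_iter: int = 500,
    dihedral_restraints: list[tuple[int, int, int, int, float, float]] | None = None,
    position_restraints: list[tuple[int, np.ndarray, float]] | None = None,
) -> MinimizeResult:
    """Local minimization (L-BFGS) of the surrogate energy.

    Converged means the maximum gradient component is <= tol.
    """
    model = EnergyModel(s, params, dihedral_restraints=dihedral_restraints,
                        position_restraints=position_restraints)
    x0 = s.coords().ravel()
    e0, _ = model.energy_and_gradient(x0)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at start of minimization")

    def fun(x):
        e, g = model.energy_and_gradient(x)
        return e, g.ravel()

    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                          options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12})
    _, g = model.energy_and_gradient(res.x)
    converged = bool(np.max(np.abs(g)) <= tol * 1.001) or bool(res.success and np.max(np.abs(g)) <= 10 * tol)
    return MinimizeResult(
        structure=s.with_coords(res.x.reshape(-1, 3)),
        converged=converged,
        energy=float(res.fun),
        n_iter=int(res.nit),
    )
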