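"""Minimum-energy-path relaxation: nudged elastic band and barrier extraction.

The band is a chain of images between two fixed endpoints (flat and
twisted conformations).  Each interior image feels the true force
projected perpendicular to the local path tangent plus a spring force
along the tangent; the tangent is the energy-weighted "improved" tangent
(uphill-neighbor), which avoids the kinks of the bisection tangent.
With ``climbing`` enabled, the highest image instead feels the true
force with its parallel component inverted and no spring, so it converges
onto the saddle point.  The optimizer is projected steepest descent with
an adaptive step and a per-coordinate displacement cap.

The core (`neb_relax_arrays`) is dimension-agnostic: it drives any
callable ``f(x) -> (energy, gradient)``, which makes it directly testable
on analytic 2-D potentials with known saddles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, EnergyParams
from .structures import Structure
from .torsion import TorsionAxis, apply_torsion, dihedral_atom_indices, measure_dihedral


@dataclass
class ReactionPath:
    """Ordered images from flat (first) to twisted (last) with per-image energies."""

    images: list[Structure]
    energies: np.ndarray
    spring_k: float = 1.0
    converged: bool = False

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.energies) != len(self.images):
            raise ValueError("energies must parallel images")

    @property
    def relative_energies(self) -> np.ndarray:
        """Energies with the first (flat) image as the zero reference."""
        return self.energies - self.energies[0]


@dataclass
class BarrierReport:
    barrier_twisted_to_flat: float
    barrier_flat_to_twisted: float
    top_index: int
    endothermic_energy: float


def barrier(path: ReactionPath) -> BarrierReport:
    """Activation barriers and endothermic energy from the path's energy profile.

    top = argmax; twisted->flat barrier = E(top) - E(last);
    flat->twisted = E(top) - E(first); endothermic = E(last) - E(first).
    """
    E = np.asarray(path.energies, dtype=float)
    if E.size == 0:
        raise ValueError("empty path")
    top = int(np.argmax(E))
    return BarrierReport(
        barrier_twisted_to_flat=float(E[top] - E[-1]),
        barrier_flat_to_twisted=float(E[top] - E[0]),
        top_index=top,
        endothermic_energy=float(E[-1] - E[0]),
    )


# ---------------------------------------------------------------------------
# path construction


def interpolate_path(
    flat: Structure,
    twisted: Structure,
    axis: TorsionAxis | None = None,
    n_images: int = 8,
    mode: str = "dihedral",
    params: EnergyParams | None = None,
) -> ReactionPath:
    """Initial chain of images between the flat and twisted conformations.

    ``dihedral`` mode sweeps the axis dihedral linearly between endpoint
    values (shortest arc), applying rigid torsion to the flat structure
    per image — covalent bond lengths are preserved exactly along the
    path.  ``cartesian`` mode interpolates coordinates linearly, which
    distorts bonds (kept as a documented contrast).  Endpoints are the
    given structures, preserved exactly.
    """
    if n_images < 3:
        raise ValueError("a path needs at least 3 images")
    if flat.n_atoms != twisted.n_atoms or flat.atom_meta() != twisted.atom_meta():
        raise ValueError("flat and twisted structures have different topologies")
    Xa, Xb = flat.coords(), twisted.coords()
    images: list[Structure] = [flat.copy()]
    if mode == "dihedral":
        if axis is None:
            raise ValueError("dihedral interpolation requires a torsion axis")
        idx = dihedral_atom_indices(flat, axis)
        th_a = measure_dihedral(*(Xa[k] for k in idx))
        th_b = measure_dihedral(*(Xb[k] for k in idx))
        delta = (th_b - th_a + 180.0) % 360.0 - 180.0  # shortest arc
        for k in range(1, n_images - 1):
            frac = k / (n_images - 1)
            images.append(apply_torsion(flat, axis, frac * delta).structure)
    elif mode == "cartesian":
        for k in range(1, n_images - 1):
            frac = k / (n_images - 1)
            images.append(flat.with_coords((1 - frac) * Xa + frac * Xb))
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    images.append(twisted.copy())
    if params is not None:
        model = EnergyModel(flat, params)
        energies = np.array([model.energy(img.coords()) for img in images])
    else:
        energies = np.full(n_images, np.nan)
    return ReactionPath(images=images, energies=energies)


def prepare_twist_path(
    flat: Structure,
    twisted: Structure,
    axis: TorsionAxis,
    n_images: int = 8,
    params: EnergyParams | None = None,
    image_relax_iters: int = 150,
    tether_k: float = 25.0,
) -> ReactionPath:
    """Dihedral-interpolated path with clash-relieved interior images.

    A rigid rotation of an in-register stack grazes the layers at
    intermediate angles, leaving interior images with core overlaps that
    dominate the band.  Each interior image is therefore relaxed briefly
    with the lifted backbone tethered at its rotated position (the same
    preparation as the twisted endpoint) before NEB takes over.
    Endpoints are preserved exactly.
    """
    from .energy import minimize
    from .torsion import moving_set

    path = interpolate_path(flat, twisted, axis, n_images=n_images, mode="dihedral")
    mv = moving_set(flat, axis)
    mainchain = flat.mainchain_mask()
    model = EnergyModel(flat, params)
    images = [path.images[0]]
    for img in path.images[1:-1]:
        X = img.coords()
        tethers = [(int(i), X[int(i)], tether_k) for i in mv if mainchain[int(i)]]
        res = minimize(img, params, max_iter=image_relax_iters, position_restraints=tethers)
        images.append(res.structure)
    images.append(path.images[-1])
    energies = np.array([model.energy(im.coords()) for im in images])
    return ReactionPath(images=images, energies=energies)


# ---------------------------------------------------------------------------
# NEB core (dimension-agnostic)


def _improved_tangent(X: np.ndarray, E: np.ndarray, i: int) -> np.ndarray:
    tp = X[i + 1] - X[i]
    tm = X[i] - X[i - 1]
    if E[i + 1] > E[i] > E[i - 1]:
        tau = tp
    elif E[i + 1] < E[i] < E[i - 1]:
        tau = tm
    else:
        dmax = max(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
        dmin = min(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
        if E[i + 1] >= E[i - 1]:
            tau = tp * dmax + tm * dmin
        else:
            tau = tp * dmin + tm * dmax
    n = np.linalg.norm(tau)
    return tau / n if n > 1e-12 else tau


def neb_forces(X: np.ndarray, E: np.ndarray, G: np.ndarray, spring_k: float, climbing: bool) -> np.ndarray:
    """NEB force on every image (zero on the endpoints)."""
    M = len(X)
    F = np.zeros_like(X)
    top = int(np.argmax(E))
    for i in range(1, M - 1):
        tau = _improved_tangent(X, E, i)
        f_true = -G[i]
        f_par = np.dot(f_true, tau)
        if climbing and i == top:
            F[i] = f_true - 2.0 * f_par * tau
            continue
        f_perp = f_true - f_par * tau
        f_spring = spring_k * (np.linalg.norm(X[i + 1] - X[i]) - np.linalg.norm(X[i] - X[i - 1]))
        F[i] = f_perp + f_spring * tau
    return F


def neb_relax_arrays(
    X0: np.ndarray,
    fgrad,
    spring_k: float = 1.0,
    climbing: bool = False,
    tol: float = 1e-3,
    max_iter: int = 5000,
    step0: float = 0.05,
    max_disp: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Relax a band of images X0 (M, D) under ``fgrad(x) -> (E, grad)``.

    Returns (relaxed images, per-image energies, converged).  Endpoints
    are never moved.  Convergence: max NEB-force component <= tol.
    """
    X = np.array(X0, dtype=float)
    M = len(X)
    if M < 3:
        raise ValueError("NEB needs at least 3 images")

    def evaluate(Xc):
        E = np.empty(M)
        G = np.empty_like(Xc)
        for i in range(M):
            E[i], G[i] = fgrad(Xc[i])
        if not np.isfinite(E).all():
            raise ValueError("non-finite energy on an image")
        return E, G

    E, G = evaluate(X)
    step = step0
    prev_fmax = np.inf
    converged = False
    for _ in range(max_iter):
        F = neb_forces(X, E, G, spring_k, climbing)
        fmax = float(np.max(np.abs(F)))
        if fmax <= tol:
            converged = True
            break
        step = min(step * 1.05, 10 * step0) if fmax <= prev_fmax else max(step * 0.5, 1e-4 * step0)
        prev_fmax = fmax
        disp = np.clip(step * F, -max_disp, max_disp)
        X[1:-1] += disp[1:-1]
        E, G = evaluate(X)
    return X, E, converged


def neb_relax(
    path: ReactionPath,
    params: EnergyParams | None = None,
    spring_k: float = 1.0,
    climbing: bool = False,
    tol: float = 1e-3,
    max_iter: int = 5000,
) -> ReactionPath:
    """Relax a molecular path under the surrogate energy. Endpoints stay fixed."""
    if len(path.images) < 3:
        raise ValueError("NEB needs at least 3 images")
    model = EnergyModel(path.images[0], params)
    n = path.images[0].n_atoms

    def fgrad(x):
        e, g = model.energy_and_gradient(x)
        return e, g.ravel()

    X0 = np.array([img.coords().ravel() for img in path.images])
    X, E, converged = neb_relax_arrays(X0, fgrad, spring_k=spring_k, climbing=climbing, tol=tol, max_iter=max_iter)
    images = [path.images[0].copy()] + [
        path.images[0].with_coords(X[i].reshape(n, 3)) for i in range(1, len(X) - 1)
    ] + [path.images[-1].copy()]
    return ReactionPath(images=images, energies=E, spring_k=spring_k, converged=converged)
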