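"""Nudged elastic band: analytic saddles, endpoint immobility, barrier arithmetic."""

import numpy as np
import pytest

import abtwist as ab
from abtwist.neb import ReactionPath, neb_relax_arrays


def double_well(x):
    """V(x, y) = (x^2 - 1)^2 + 5 y^2: minima at (+-1, 0), saddle V(0,0) = 1."""
    e = (x[0] ** 2 - 1) ** 2 + 5 * x[1] ** 2
    return e, np.array([4 * x[0] * (x[0] ** 2 - 1), 10 * x[1]])


def initial_band(n_images, seed=1):
    X = np.linspace([-1.0, 0.0], [1.0, 0.0], n_images)
    rng = np.random.default_rng(seed)
    X[1:-1] += rng.normal(0, 0.05, (n_images - 2, 2))
    return X


def test_double_well_barrier_recovered():
    X, E, conv = neb_relax_arrays(initial_band(11), double_well, tol=1e-4)
    assert conv
    assert E.max() == pytest.approx(1.0, abs=0.01)
    assert E[0] == pytest.approx(0.0, abs=1e-12) and E[-1] == pytest.approx(0.0, abs=1e-12)


def test_double_well_barrier_stable_under_refinement():
    _, E11, _ = neb_relax_arrays(initial_band(11), double_well, tol=1e-4)
    _, E21, _ = neb_relax_arrays(initial_band(21, seed=2), double_well, tol=1e-4)
    assert abs(E11.max() - E21.max()) < 0.01


def test_climbing_image_lands_on_the_saddle():
    X, E, conv = neb_relax_arrays(initial_band(11), double_well, climbing=True, tol=1e-4)
    top = int(np.argmax(E))
    assert np.linalg.norm(X[top] - np.array([0.0, 0.0])) < 1e-2
    assert E[top] == pytest.approx(1.0, abs=1e-3)


def test_endpoints_never_move():
    X0 = initial_band(9)
    X, _, _ = neb_relax_arrays(X0, double_well, tol=1e-4, max_iter=500)
    assert np.array_equal(X[0], X0[0])
    assert np.array_equal(X[-1], X0[-1])


def test_flat_potential_converges_immediately():
    flat = lambda x: (0.0, np.zeros_like(x))
    X0 = np.linspace([0.0, 0.0], [1.0, 0.0], 5)
    X, E, conv = neb_relax_arrays(X0, flat, tol=1e-4)
    assert conv
    assert np.allclose(E, 0.0)


def test_neb_needs_three_images():
    with pytest.raises(ValueError):
        neb_relax_arrays(np.zeros((2, 2)), double_well)


@pytest.mark.parametrize(
    "energies,expected",
    [
        ([0.0, 0.5, 0.3], (0.2, 0.5, 1, 0.3)),
        ([0.0, 0.1, 0.2], (0.0, 0.2, 2, 0.2)),
        ([0.0, 0.0, 0.0], (0.0, 0.0, 0, 0.0)),
    ],
)
def test_barrier_arithmetic(energies, expected, abeta_dimer):
    images = [abeta_dimer] * len(energies)
    rep = ab.barrier(ReactionPath(images=images, energies=np.array(energies)))
    assert rep.barrier_twisted_to_flat == pytest.approx(expected[0])
    assert rep.barrier_flat_to_twisted == pytest.approx(expected[1])
    assert rep.top_index == expected[2]
    assert rep.endothermic_energy == pytest.approx(expected[3])


def test_barrier_identity_holds_exactly():
    rng = np.random.default_rng(0)
    for _ in range(50):
        E = rng.normal(0, 3, rng.integers(2, 12))
        rep = ab.barrier(ReactionPath(images=[None] * len(E), energies=E))
        assert rep.barrier_flat_to_twisted - rep.barrier_twisted_to_flat == pytest.approx(
            rep.endothermic_energy, abs=1e-12
        )


def test_dihedral_interpolation_preserves_bonds_cartesian_does_not(flat_relaxed):
    axis = ab.TorsionAxis(25, "psi")
    twisted = ab.apply_torsion(flat_relaxed, axis, 110.0).structure
    bonds = flat_relaxed.bonds

    def bond_lengths(s):
        X = s.coords()
        return np.array([np.linalg.norm(X[i] - X[j]) for i, j in bonds])

    ref = bond_lengths(flat_relaxed)
    dih = ab.interpolate_path(flat_relaxed, twisted, axis, n_images=5, mode="dihedral")
    cart = ab.interpolate_path(flat_relaxed, twisted, axis, n_images=5, mode="cartesian")
    for img in dih.images:
        assert np.abs(bond_lengths(img) - ref).max() < 1e-6
    mid_dev = np.abs(bond_lengths(cart.images[2]) - ref).max()
    assert mid_dev > 0.1  # linear interpolation shears covalent bonds


def test_dihedral_interpolation_midpoint_is_the_mean(flat_relaxed):
    from abtwist.torsion import dihedral_atom_indices

    axis = ab.TorsionAxis(23, "psi")
    twisted = ab.apply_torsion(flat_relaxed, axis, 80.0).structure
    path = ab.interpolate_path(flat_relaxed, twisted, axis, n_images=3, mode="dihedral")
    idx = dihedral_atom_indices(flat_relaxed, axis)

    def dih(s):
        X = s.coords()
        return ab.measure_dihedral(*(X[k] for k in idx))

    mean = dih(flat_relaxed) + 40.0
    assert abs((dih(path.images[1]) - mean + 180) % 360 - 180) < 1e-6


def test_identical_endpoints_give_identical_images(flat_relaxed):
    path = ab.interpolate_path(flat_relaxed, flat_relaxed.copy(), ab.TorsionAxis(25, "psi"), n_images=4)
    for img in path.images:
        assert np.abs(img.coords() - flat_relaxed.coords()).max() < 1e-9


def test_molecular_neb_keeps_endpoints_and_computes_profile(flat_relaxed):
    axis = ab.TorsionAxis(22, "psi")
    twisted = ab.relax_twist_endpoint(flat_relaxed, axis, -50.0, max_iter=150)
    params = ab.EnergyParams()
    p0 = ab.interpolate_path(flat_relaxed, twisted.structure, axis, n_images=5, params=params)
    rp = ab.neb_relax(p0, params, max_iter=40)
    assert np.array_equal(rp.images[0].coords(), flat_relaxed.coords())
    assert np.array_equal(rp.images[-1].coords(), twisted.structure.coords())
    assert np.isfinite(rp.energies).all()
    assert rp.relative_energies[0] == 0.0
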