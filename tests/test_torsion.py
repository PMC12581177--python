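"""Torsion engine: axis enumeration, rigid-rotation kinematics, clash counting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import abtwist as ab
from abtwist.structures import Atom, Monomer, Residue, Structure, TopologyError
from abtwist.torsion import dihedral_atom_indices, moving_set


def pairwise(X, ids):
    sub = X[ids]
    return np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)


def test_enumerate_axes_contains_the_six_studied(abeta_dimer):
    axes = ab.enumerate_axes(abeta_dimer, range(22, 27))
    labels = [a.label for a in axes]
    for want in ["22:psi", "23:phi", "23:psi", "24:phi", "25:psi", "26:phi"]:
        assert want in labels
    # deterministic order: N->C, phi before psi
    assert labels.index("23:phi") < labels.index("23:psi") < labels.index("24:phi")


def test_enumerate_axes_boundaries(abeta_dimer):
    assert [a.kind for a in ab.enumerate_axes(abeta_dimer, [20])] == ["psi"]
    assert len(ab.enumerate_axes(abeta_dimer, [25])) == 2
    with pytest.raises(ValueError):
        ab.enumerate_axes(abeta_dimer, [])


def test_moving_set_matches_bond_connectivity(abeta_dimer):
    meta = abeta_dimer.atom_meta()
    ui = abeta_dimer.upper_index()
    mv_psi = {meta[i] for i in moving_set(abeta_dimer, ab.TorsionAxis(25, "psi"))}
    # psi at 25: residues < 25 entirely, plus N/H/CA/both HA of 25 (G sidechain H included)
    assert (ui, 24, "C") in mv_psi and (ui, 20, "N") in mv_psi
    assert (ui, 25, "N") in mv_psi and (ui, 25, "CA") in mv_psi
    assert (ui, 25, "C") not in mv_psi and (ui, 25, "O") not in mv_psi
    assert (ui, 26, "N") not in mv_psi
    mv_phi = {meta[i] for i in moving_set(abeta_dimer, ab.TorsionAxis(26, "phi"))}
    assert (ui, 26, "N") in mv_phi and (ui, 26, "H") in mv_phi
    assert (ui, 26, "CA") not in mv_phi
    # phi does not carry the pivot's sidechain; psi carries its own
    assert not any(pos == 26 and name.startswith(("CB", "OG")) for _, pos, name in mv_phi)


@pytest.mark.parametrize("kind,pos", [("psi", 25), ("phi", 23)])
def test_torsion_changes_dihedral_by_exactly_delta(abeta_dimer, kind, pos):
    axis = ab.TorsionAxis(pos, kind)
    idx = dihedral_atom_indices(abeta_dimer, axis)
    X0 = abeta_dimer.coords()
    before = ab.measure_dihedral(*(X0[k] for k in idx))
    for delta in (90.0, -47.3, 181.0):
        X1 = ab.apply_torsion(abeta_dimer, axis, delta).structure.coords()
        after = ab.measure_dihedral(*(X1[k] for k in idx))
        assert abs((after - before - delta + 180) % 360 - 180) < 1e-6


def test_torsion_is_rigid_on_both_sides(abeta_dimer):
    axis = ab.TorsionAxis(23, "psi")
    mv = moving_set(abeta_dimer, axis)
    fixed = np.setdiff1d(np.arange(abeta_dimer.n_atoms), mv)
    X0 = abeta_dimer.coords()
    X1 = ab.apply_torsion(abeta_dimer, axis, 73.0).structure.coords()
    assert np.abs(pairwise(X0, mv) - pairwise(X1, mv)).max() < 1e-9
    assert np.abs(pairwise(X0, fixed) - pairwise(X1, fixed)).max() < 1e-9


def test_torsion_identity_and_full_turn(abeta_dimer):
    axis = ab.TorsionAxis(24, "phi")
    X0 = abeta_dimer.coords()
    assert np.abs(ab.apply_torsion(abeta_dimer, axis, 0.0).structure.coords() - X0).max() < 1e-12
    assert np.abs(ab.apply_torsion(abeta_dimer, axis, 360.0).structure.coords() - X0).max() < 1e-6


@given(d1=st.floats(-170, 170), d2=st.floats(-170, 170))
def test_torsion_composition_and_inverse(gg_dimer, d1, d2):
    axis = ab.TorsionAxis(2, "psi")
    one = ab.apply_torsion(ab.apply_torsion(gg_dimer, axis, d1).structure, axis, d2).structure
    both = ab.apply_torsion(gg_dimer, axis, d1 + d2).structure
    assert np.abs(one.coords() - both.coords()).max() < 1e-6
    back = ab.apply_torsion(ab.apply_torsion(gg_dimer, axis, d1).structure, axis, -d1).structure
    assert np.abs(back.coords() - gg_dimer.coords()).max() < 1e-6


def test_small_torsion_leaves_cterminal_hbonds(abeta_dimer):
    axis = ab.TorsionAxis(25, "psi")
    before = {
        hb.key for hb in ab.detect_hbonds(abeta_dimer)
        if hb.scope == "intermolecular" and hb.is_mainchain
        and min(hb.donor_desc[1], hb.acceptor_desc[1]) >= 25
    }
    tw = ab.apply_torsion(abeta_dimer, axis, 4.0).structure
    after = {
        hb.key for hb in ab.detect_hbonds(tw)
        if hb.scope == "intermolecular" and hb.is_mainchain
        and min(hb.donor_desc[1], hb.acceptor_desc[1]) >= 25
    }
    assert before <= after


def test_clash_count_bonded_exclusion_and_bruteforce():
    rng = np.random.default_rng(5)
    # small random blob with known bonds
    atoms = [Atom(i + 1, "C", "C", rng.uniform(0, 6, 3)) for i in range(40)]
    s = Structure([Monomer([Residue(1, "G", atoms)])])
    got = ab.clash_count(s, 1.8)
    X = s.coords()
    adj = s.adjacency()
    excl = set()
    for i in range(40):
        for j in adj[i]:
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
    brute = sum(
        1
        for i in range(40)
        for j in range(i + 1, 40)
        if (i, j) not in excl and np.linalg.norm(X[i] - X[j]) < 1.8
    )
    assert got == brute


def test_clash_count_simple_cases():
    # two covalently bonded atoms at 1.0 A: excluded, no clash
    a = Atom(1, "C", "C", [0.0, 0.0, 0.0])
    b = Atom(2, "C", "C", [1.0, 0.0, 0.0])
    s = Structure([Monomer([Residue(1, "G", [a, b])])])
    assert ab.clash_count(s, 1.8) == 0
    # two non-bonded atoms at 1.0 A (H-H pairs are never covalent): one clash
    h1 = Atom(1, "H", "H", [0.0, 0.0, 0.0])
    h2 = Atom(2, "H", "H", [1.0, 0.0, 0.0])
    s2 = Structure([Monomer([Residue(1, "G", [h1, h2])])])
    assert ab.clash_count(s2, 1.8) == 1
    with pytest.raises(ValueError):
        ab.clash_count(s2, -1.0)


def test_generate_twisted_detaches_nterminal_ladder(flat_relaxed):
    axis = ab.TorsionAxis(25, "psi")
    tw = ab.generate_twisted(flat_relaxed, axis)
    flat_rungs = {
        hb.key: min(hb.donor_desc[1], hb.acceptor_desc[1])
        for hb in ab.detect_hbonds(flat_relaxed)
        if hb.scope == "intermolecular" and hb.is_mainchain
    }
    tw_keys = {
        hb.key for hb in ab.detect_hbonds(tw.structure)
        if hb.scope == "intermolecular" and hb.is_mainchain
    }
    broken = {k for k in flat_rungs if k not in tw_keys}
    kept = {k for k in flat_rungs if k in tw_keys}
    assert all(flat_rungs[k] < 25 for k in broken)  # only N-terminal rungs break
    assert all(flat_rungs[k] >= 25 for k in flat_rungs if flat_rungs[k] >= 25 and k in kept)
    assert {k for k in flat_rungs if flat_rungs[k] < 25} == broken  # all of them break


def test_generate_twisted_is_deterministic(flat_relaxed):
    axis = ab.TorsionAxis(22, "psi")
    a = ab.generate_twisted(flat_relaxed, axis)
    b = ab.generate_twisted(flat_relaxed, axis)
    assert a.applied_angle == b.applied_angle
    assert np.array_equal(a.structure.coords(), b.structure.coords())


def test_zero_length_axis_raises(abeta_dimer):
    broken = abeta_dimer.copy()
    axis = ab.TorsionAxis(25, "psi")
    i, j = ab.torsion.axis_atom_indices(broken, axis)
    X = broken.coords()
    X[j] = X[i]
    broken2 = abeta_dimer.with_coords(X)
    with pytest.raises(TopologyError, match="coincident"):
        ab.apply_torsion(broken2, axis, 30.0)


def test_parse_axis():
    ax = ab.parse_axis("G25:psi")
    assert (ax.residue_position, ax.kind) == (25, "psi")
    assert ab.parse_axis("23:phi").kind == "phi"
    with pytest.raises(ValueError):
        ab.parse_axis("nonsense")
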