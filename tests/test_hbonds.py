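"""Hydrogen-bond detection, ledgers, and the dimer's structural observables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import abtwist as ab
from abtwist.structures import Atom, Monomer, Residue, SegmentLabel, Structure, TopologyError
from conftest import brute_force_hbonds, random_hb_soup


def two_unit_structure(d_no: float, angle_deg: float) -> Structure:
    """One N-H donor (residue 1, monomer 0) and one C=O acceptor (monomer 1)
    arranged with the given N...O distance and D-H...A angle."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    # place O so that the angle at H is angle_deg and |N-O| = d_no
    th = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(th), np.sin(th), 0.0])
    lo = 0.0
    hi = 10.0
    for _ in range(60):  # bisect along the H->direction ray for the exact N-O distance
        mid = 0.5 * (lo + hi)
        o = h + mid * direction
        if np.linalg.norm(o - n) < d_no:
            lo = mid
        else:
            hi = mid
    o = h + 0.5 * (lo + hi) * direction
    c = o + np.array([0.0, 0.0, 1.23])
    m0 = Monomer([Residue(1, "G", [Atom(1, "N", "N", n), Atom(2, "H", "H", h)])])
    m1 = Monomer([Residue(1, "G", [Atom(3, "C", "C", c), Atom(4, "O", "O", o)])])
    return Structure([m0, m1])


@pytest.mark.parametrize(
    "d,angle,expected",
    [
        (3.6, 180.0, 1),   # boundary distance inclusive
        (3.7, 180.0, 0),   # beyond distance cutoff
        (2.9, 120.0, 1),   # boundary angle inclusive
        (2.9, 119.0, 0),   # below angle cutoff
        (2.9, 175.0, 1),
    ],
)
def test_criteria_boundaries_are_inclusive(d, angle, expected):
    s = two_unit_structure(d, angle)
    hbs = ab.detect_hbonds(s)
    assert len(hbs) == expected
    if expected:
        assert hbs[0].scope == "intermolecular"
        assert hbs[0].da_distance == pytest.approx(d, abs=1e-6)
        assert hbs[0].dha_angle == pytest.approx(angle, abs=0.5)


def test_detector_requires_hydrogens():
    m = Monomer([Residue(1, "G", [Atom(1, "C", "C", [0, 0, 0]), Atom(2, "O", "O", [1.2, 0, 0])])])
    with pytest.raises(TopologyError, match="hydrogen"):
        ab.detect_hbonds(Structure([m]))


def test_detector_matches_brute_force_on_random_fixtures():
    for seed in range(30):
        s = random_hb_soup(np.random.default_rng(seed))
        got = {(h.donor_index, h.hydrogen_index, h.acceptor_index) for h in ab.detect_hbonds(s)}
        assert got == brute_force_hbonds(s), f"mismatch at seed {seed}"


def test_detector_invariant_under_rigid_motion():
    s = random_hb_soup(np.random.default_rng(1))
    ref = {(h.donor_index, h.hydrogen_index, h.acceptor_index) for h in ab.detect_hbonds(s)}
    th = 1.1
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    moved = s.with_coords(s.coords() @ R.T + np.array([5.0, -3.0, 2.0]))
    got = {(h.donor_index, h.hydrogen_index, h.acceptor_index) for h in ab.detect_hbonds(moved)}
    assert got == ref


@given(dist=st.floats(2.0, 3.6), ang=st.floats(120.0, 180.0))
def test_tightening_criteria_never_adds_bonds(dist, ang):
    s = random_hb_soup(np.random.default_rng(7), n_units=16)
    base = len(ab.detect_hbonds(s))
    tightened = len(ab.detect_hbonds(s, ab.HBCriteria(dist, ang)))
    assert tightened <= base


def test_counts_by_scope_and_class(abeta_dimer):
    total = ab.count_hbonds(abeta_dimer, scope="intermolecular")
    mc = ab.count_hbonds(abeta_dimer, scope="intermolecular", class_filter="mainchain")
    sc = ab.count_hbonds(abeta_dimer, scope="intermolecular", class_filter="sidechain")
    assert total == mc + sc
    single = Structure([abeta_dimer.copy().monomers[0]])
    with pytest.raises(TopologyError):
        ab.count_hbonds(single, scope="intermolecular")


def test_delta_hb_identity_and_antisymmetry(abeta_dimer):
    same = ab.delta_hb(abeta_dimer, abeta_dimer)
    assert same.delta_n_hb == 0 and not same.broken and not same.formed
    tw = ab.apply_torsion(abeta_dimer, ab.TorsionAxis(25, "psi"), 90.0).structure
    fwd = ab.delta_hb(abeta_dimer, tw)
    rev = ab.delta_hb(tw, abeta_dimer)
    assert {h.key for h in fwd.broken} == {h.key for h in rev.formed}
    assert {h.key for h in fwd.formed} == {h.key for h in rev.broken}


def test_delta_hb_rejects_mismatched_topology(abeta_dimer, gg_dimer):
    with pytest.raises(TopologyError):
        ab.delta_hb(abeta_dimer, gg_dimer)


def test_interlayer_distance_equals_bruteforce_mean():
    s = ab.build_parallel_dimer(ab.BuilderParams(jitter_sigma=0.1, seed=2))
    got = ab.interlayer_distance(s)
    d = [
        np.linalg.norm(s.upper.residue(p).atom("CA").coords - s.lower.residue(p).atom("CA").coords)
        for p in range(20, 35)
    ]
    assert got == pytest.approx(float(np.mean(d)), abs=1e-12)


def test_segment_oo_distance_on_ideal_dimer(abeta_dimer):
    for i in (22, 25):
        d = ab.segment_oo_distance(abeta_dimer, SegmentLabel(i))
        assert d == pytest.approx(4.8, abs=0.2)
    with pytest.raises(TopologyError):
        ab.segment_oo_distance(abeta_dimer, 34)  # no residue 35


def test_contact_table_matches_bruteforce_minimum(abeta_dimer):
    axis = ab.TorsionAxis(25, "psi")
    tw = ab.apply_torsion(abeta_dimer, axis, 90.0).structure
    images = [abeta_dimer, tw]
    rep = ab.contact_table(images, axis, barrier_index=0, minimum_index=1)
    assert rep.pairs
    lower_h = np.array(
        [a.coords for r in abeta_dimer.lower.residues for a in r.atoms if a.element == "H"]
    )
    for desc, d_top, d_min in rep.pairs:
        name = desc.split()[0].split(":")[1]
        probe = abeta_dimer.upper.residue(25).atom(name).coords
        assert d_top == pytest.approx(float(np.min(np.linalg.norm(lower_h - probe, axis=1))), abs=1e-9)
        assert d_min > 0


def test_contact_table_far_segment_reports_large_distances(flat_relaxed):
    axis = ab.TorsionAxis(25, "psi")
    # translate the whole moving segment far above the lower layer
    from abtwist.torsion import moving_set

    mv = moving_set(flat_relaxed, axis)
    X = flat_relaxed.coords()
    X[mv] += np.array([0.0, 0.0, 30.0])
    lifted = flat_relaxed.with_coords(X)
    rep = ab.contact_table([lifted, lifted], axis, 0, 1)
    assert all(d > 10.0 for _, d, _ in rep.pairs)


def test_contact_table_aspartate_uses_carboxyl_oxygens(abeta_dimer):
    axis = ab.TorsionAxis(23, "psi")  # near-axis residue D23
    rep = ab.contact_table([abeta_dimer, abeta_dimer], axis, 0, 1)
    assert all("O-O" in desc for desc, _, _ in rep.pairs)
    assert len(rep.pairs) == 2  # both carboxyl oxygens
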