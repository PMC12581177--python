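"""Shared fixtures and independent oracles for the test suite.

The expensive objects (the amyloid-beta dimer, its surrogate-relaxed flat
reference) are session-scoped; tests must not mutate them in place (use
``.copy()`` / ``with_coords`` when a modified structure is needed).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import abtwist as ab
from abtwist.structures import Atom, Monomer, Residue, Structure

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def abeta_dimer() -> Structure:
    """Default synthetic amyloid-beta(20-34) parallel double layer."""
    return ab.build_parallel_dimer(ab.BuilderParams())


@pytest.fixture(scope="session")
def flat_relaxed(abeta_dimer) -> Structure:
    """The flat reference after surrogate-energy relaxation."""
    return ab.minimize(abeta_dimer, max_iter=2000).structure


@pytest.fixture(scope="session")
def gg_dimer() -> Structure:
    return ab.build_parallel_dimer(ab.BuilderParams(sequence="GAG", start_position=1))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_hbonds(s: Structure, max_dist: float = 3.6, min_angle: float = 120.0):
    """O(n^3)-style enumeration over every donor-H-acceptor triple.

    Re-derives hydrogen attachment and donor/acceptor chemistry from raw
    distances, independent of the package's adjacency machinery: an H
    belongs to every N/O within covalent-bond range (1.2 x radius sum);
    donors are N/O with >= 1 H, acceptors are O atoms plus N atoms with
    no H.
    """
    atoms = s.atoms
    X = s.coords()
    reskey = s.residue_key_of()
    n = len(atoms)
    bond_range = {"N": 1.2 * (0.31 + 0.71), "O": 1.2 * (0.31 + 0.66)}
    attached: dict[int, list[int]] = {}
    for h in range(n):
        if atoms[h].element != "H":
            continue
        for i in range(n):
            el = atoms[i].element
            if el in bond_range and 0.4 <= np.linalg.norm(X[h] - X[i]) <= bond_range[el]:
                attached.setdefault(i, []).append(h)
    triples = set()
    for d in range(n):
        if atoms[d].element not in {"N", "O"} or d not in attached:
            continue
        for a in range(n):
            if atoms[a].element == "O" or (atoms[a].element == "N" and a not in attached):
                if a == d or reskey[a] == reskey[d]:
                    continue
                dist = float(np.linalg.norm(X[d] - X[a]))
                if dist > max_dist:
                    continue
                for h in attached[d]:
                    if a == h:
                        continue
                    u = X[d] - X[h]
                    v = X[a] - X[h]
                    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                    if ang >= min_angle:
                        triples.add((d, h, a))
    return triples


def random_hb_soup(rng: np.random.Generator, n_units: int = 12) -> Structure:
    """Random structure of N-H and C=O units split over two 'monomers'.

    Not a valid peptide — just a geometric fixture for detector oracles.
    """
    monomers = []
    serial = 0
    for m in range(2):
        residues = []
        for r in range(n_units // 2):
            atoms = []
            center = rng.uniform(-6, 6, 3) + np.array([0, 0, 7.0 * m])
            # one N-H donor unit
            npos = center + rng.uniform(-1.5, 1.5, 3)
            hdir = rng.normal(size=3)
            hdir /= np.linalg.norm(hdir)
            serial += 1
            atoms.append(Atom(serial, "N", "N", npos))
            serial += 1
            atoms.append(Atom(serial, "H", "H", npos + 1.0 * hdir))
            # one C=O acceptor unit
            cpos = center + rng.uniform(-1.5, 1.5, 3)
            odir = rng.normal(size=3)
            odir /= np.linalg.norm(odir)
            serial += 1
            atoms.append(Atom(serial, "C", "C", cpos))
            serial += 1
            atoms.append(Atom(serial, "O", "O", cpos + 1.23 * odir))
            residues.append(Residue(r + 1, "G", atoms))
        monomers.append(Monomer(residues, layer_label="lower" if m == 0 else "upper"))
    return Structure(monomers, provenance="random HB soup")
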