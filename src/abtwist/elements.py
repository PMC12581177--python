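"""Element tables: covalent radii for bond inference, Lennard-Jones classes.

Covalent radii are the Cordero (2008) single-bond values in Angstrom.
Bond inference uses a 1.2 x (r_i + r_j) distance cutoff, which cleanly
separates covalent bonds from hydrogen-bond contacts (shortest H...O
contacts in tight beta-ladders are ~1.6 A, well above 1.2 x 0.97).
"""

from __future__ import annotations

COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
}

BOND_TOLERANCE = 1.2

#: amino-acid one-letter -> PDB three-letter codes (20 standard residues)
AA1TO3: dict[str, str] = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1: dict[str, str] = {v: k for k, v in AA1TO3.items()}


def bond_cutoff(el1: str, el2: str) -> float:
    """Maximum distance (A) at which two atoms are considered covalently bonded."""
    r1 = COVALENT_RADII.get(el1, 0.77)
    r2 = COVALENT_RADII.get(el2, 0.77)
    return BOND_TOLERANCE * (r1 + r2)
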