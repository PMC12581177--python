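"""Reading and writing peptide structures and pathway ensembles.

PDB files are handled through gemmi (ATOM/TER/MODEL/ENDMDL records;
coordinates in Angstrom, 10^-3 A precision).  XYZ files (``element x y
z`` with concatenated frames) carry no residue or chain information, so
the XYZ readers require a ``template`` Structure supplying the topology;
coordinates are taken from the file in template atom order.

Layer labels (upper/lower) are always re-derived geometrically on read,
never trusted from chain identifiers: the stacking axis is the normal of
the least-squares plane through the first monomer's CA atoms, and the
monomer whose centroid projects higher along that axis is labeled upper.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .elements import AA1TO3, AA3TO1
from .structures import (
    Atom,
    FormatError,
    Monomer,
    Residue,
    Structure,
    TopologyError,
    infer_topology,
)


def _format_from_path(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise FormatError(f"cannot infer format from suffix {suffix!r}; pass format='pdb' or 'xyz'")


# ---------------------------------------------------------------------------
# reading


def _structure_from_gemmi_model(model: "gemmi.Model", provenance: str) -> Structure:
    monomers = []
    serial = 0
    for chain in model:
        residues = []
        for res in chain:
            code = AA3TO1.get(res.name.upper())
            if code is None:
                raise FormatError(f"unknown residue name {res.name!r}")
            atoms = []
            for at in res:
                serial += 1
                el = at.element.name if at.element else ""
                atoms.append(Atom(serial, at.name, el, np.array([at.pos.x, at.pos.y, at.pos.z])))
            residues.append(Residue(res.seqid.num, code, atoms))
        if residues:
            monomers.append(Monomer(residues))
    if not monomers or all(len(m.residues) == 0 for m in monomers):
        raise FormatError(f"no atoms found in {provenance}")
    return Structure(monomers, provenance=provenance)


def _read_gemmi(path: str | Path) -> "gemmi.Structure":
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    return st


def _read_xyz_frames(path: str | Path) -> list[np.ndarray]:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame at line {i + 1}")
        coords = []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed XYZ line {ln!r}")
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(np.array(coords))
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames


def read_structure(
    path: str | Path,
    format: str | None = None,
    template: Structure | None = None,
    assign: bool = True,
) -> Structure:
    """Read a single structure; infer topology; for dimers assign layer labels.

    XYZ input requires ``template`` (XYZ carries no residue topology).
    """
    fmt = _format_from_path(path, format)
    if fmt == "pdb":
        st = _read_gemmi(path)
        s = _structure_from_gemmi_model(st[0], provenance=str(path))
    elif fmt == "xyz":
        if template is None:
            raise FormatError("XYZ carries no topology; pass template=<Structure>")
        frames = _read_xyz_frames(path)
        if frames[0].shape[0] != template.n_atoms:
            raise FormatError(
                f"XYZ frame has {frames[0].shape[0]} atoms, template has {template.n_atoms}"
            )
        s = template.with_coords(frames[0])
        s.provenance = str(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    infer_topology(s)
    if assign and len(s.monomers) == 2:
        assign_layers(s)
    return s


def read_path(
    path: str | Path,
    format: str | None = None,
    template: Structure | None = None,
) -> list[Structure]:
    """Read an ordered pathway ensemble (multi-model PDB or XYZ trajectory).

    All images share topology (taken from the first image) and atom order.
    Requires at least two images.
    """
    fmt = _format_from_path(path, format)
    if fmt == "pdb":
        st = _read_gemmi(path)
        if len(st) < 2:
            raise FormatError(f"{path}: a pathway needs >= 2 models, found {len(st)}")
        first = _structure_from_gemmi_model(st[0], provenance=f"{path}#1")
        infer_topology(first)
        if len(first.monomers) == 2:
            assign_layers(first)
        images = [first]
        for k in range(1, len(st)):
            s_k = _structure_from_gemmi_model(st[k], provenance=f"{path}#{k + 1}")
            if s_k.n_atoms != first.n_atoms:
                raise FormatError(
                    f"{path}: model {k + 1} has {s_k.n_atoms} atoms, model 1 has {first.n_atoms}"
                )
            img = first.with_coords(s_k.coords())
            img.provenance = s_k.provenance
            images.append(img)
        return images
    if fmt == "xyz":
        if template is None:
            raise FormatError("XYZ carries no topology; pass template=<Structure>")
        frames = _read_xyz_frames(path)
        if len(frames) < 2:
            raise FormatError(f"{path}: a pathway needs >= 2 frames, found {len(frames)}")
        for k, fr in enumerate(frames):
            if fr.shape[0] != template.n_atoms:
                raise FormatError(
                    f"{path}: frame {k + 1} has {fr.shape[0]} atoms, template has {template.n_atoms}"
                )
        return [template.with_coords(fr) for fr in frames]
    raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(structures: list[Structure]) -> "gemmi.Structure":
    st = gemmi.Structure()
    st.name = "abtwist"
    chain_ids = "ABCDEFGH"
    for k, s in enumerate(structures):
        model = gemmi.Model(k + 1)
        # upper monomer written first as chain A when labels exist
        monomers = list(s.monomers)
        if len(monomers) == 2 and all(m.layer_label for m in monomers):
            monomers.sort(key=lambda m: 0 if m.layer_label == "upper" else 1)
        for ci, m in enumerate(monomers):
            chain = gemmi.Chain(chain_ids[ci])
            for r in m.residues:
                res = gemmi.Residue()
                res.name = AA1TO3[r.code]
                res.seqid = gemmi.SeqId(r.position, " ")
                for a in r.atoms:
                    at = gemmi.Atom()
                    at.name = a.name
                    at.element = gemmi.Element(a.element)
                    at.pos = gemmi.Position(*a.coords)
                    at.occ = 1.0
                    at.serial = a.serial
                    res.add_atom(at)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, format: str | None = None) -> None:
    fmt = _format_from_path(path, format)
    if fmt == "pdb":
        _to_gemmi([s]).write_pdb(str(path))
    elif fmt == "xyz":
        _write_xyz([s], path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def write_path(images: list[Structure], path: str | Path, format: str | None = None) -> None:
    fmt = _format_from_path(path, format)
    if fmt == "pdb":
        _to_gemmi(images).write_pdb(str(path))
    elif fmt == "xyz":
        _write_xyz(images, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def _write_xyz(images: list[Structure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, s in enumerate(images):
            fh.write(f"{s.n_atoms}\nframe {k + 1}\n")
            for a in s.atoms:
                x, y, z = a.coords
                fh.write(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------------------
# layers


def stacking_axis(s: Structure) -> np.ndarray:
    """Unit normal of the least-squares plane through the first monomer's CA atoms,
    oriented from the first monomer toward the second."""
    if len(s.monomers) != 2:
        raise TopologyError("stacking axis is defined for dimers only")
    ca = np.array([r.atom("CA").coords for r in s.monomers[0].residues])
    if len(ca) < 3:
        raise TopologyError("need >= 3 CA atoms to fit a stacking plane")
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[-1] / np.linalg.norm(vt[-1])
    c0 = np.mean([a.coords for r in s.monomers[0].residues for a in r.atoms], axis=0)
    c1 = np.mean([a.coords for r in s.monomers[1].residues for a in r.atoms], axis=0)
    sign = float(np.dot(c1 - c0, n))
    if abs(sign) < 0.1:
        raise TopologyError("monomer centroids coincide along the stacking axis; cannot assign layers")
    return n if sign > 0 else -n


def assign_layers(s: Structure) -> Structure:
    """Label the dimer's monomers upper/lower by projection on the stacking axis.

    Deterministic and invariant under monomer input order.  Raises on
    monomer input and on degenerate (coincident-centroid) geometry.
    """
    if len(s.monomers) != 2:
        raise TopologyError("assign_layers requires a dimer")
    n = stacking_axis(s)
    # canonicalize the axis sign independently of monomer input order:
    # the largest-magnitude component points positive
    if n[int(np.argmax(np.abs(n)))] < 0:
        n = -n
    proj = []
    for m in s.monomers:
        c = np.mean([a.coords for r in m.residues for a in r.atoms], axis=0)
        proj.append(float(np.dot(c, n)))
    hi = int(np.argmax(proj))
    s.monomers[hi].layer_label = "upper"
    s.monomers[1 - hi].layer_label = "lower"
    return s
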