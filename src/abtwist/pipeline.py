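"""End-to-end orchestration: build/load -> twist -> HB ledger -> NEB -> report.

A run is described by a PipelineConfig (constructable from YAML).  For
each requested torsional axis the pipeline generates the twisted
conformation, accounts for broken/formed hydrogen bonds, relaxes a
flat->twisted band under the surrogate energy, and extracts barriers and
near-axis contact distances.  Outputs are machine-readable: one JSON
report plus tidy CSVs (hbonds.csv, ledger.csv, profile_<axis>.csv,
contacts.csv) and per-axis multi-model PDB paths.  Runs are deterministic
given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .energy import EnergyModel, EnergyParams, minimize
from .hbonds import HBCriteria, contact_table, delta_hb, detect_hbonds, interlayer_distance
from .neb import barrier, neb_relax, prepare_twist_path
from .structure_io import read_path, read_structure, write_path, write_structure
from .structures import Structure
from .synthetic import BuilderParams, build_parallel_dimer
from .torsion import TorsionAxis, generate_twisted, parse_axis

logger = logging.getLogger("abtwist")


@dataclass
class NEBSettings:
    n_images: int = 8
    spring_k: float = 1.0
    climbing: bool = False
    tol: float = 1e-3
    max_iter: int = 300


@dataclass
class PipelineConfig:
    input_path: str | None = None
    builder: BuilderParams | None = None
    axes: list[str] = field(default_factory=lambda: ["G25:psi"])
    criteria: HBCriteria = field(default_factory=HBCriteria)
    energy: EnergyParams = field(default_factory=EnergyParams)
    neb: NEBSettings = field(default_factory=NEBSettings)
    out_dir: str = "abtwist_run"
    seed: int = 7
    log_level: str = "INFO"
    relax_flat: bool = True
    relax_max_iter: int = 2000

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.builder is None):
            raise ValueError("config needs exactly one input source: input_path or builder")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "builder" in kw and kw["builder"] is not None:
            kw["builder"] = BuilderParams(**kw["builder"])
        if "criteria" in kw and kw["criteria"] is not None:
            kw["criteria"] = HBCriteria(**kw["criteria"])
        if "energy" in kw and kw["energy"] is not None:
            kw["energy"] = EnergyParams(**kw["energy"])
        if "neb" in kw and kw["neb"] is not None:
            kw["neb"] = NEBSettings(**kw["neb"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    return x


def _hb_rows(structure: Structure, criteria: HBCriteria) -> list[dict]:
    rows = []
    for hb in detect_hbonds(structure, criteria):
        rows.append(
            {
                "donor": f"{hb.donor_desc[0]}/{hb.donor_desc[1]}/{hb.donor_desc[2]}",
                "hydrogen": f"{hb.hydrogen_desc[0]}/{hb.hydrogen_desc[1]}/{hb.hydrogen_desc[2]}",
                "acceptor": f"{hb.acceptor_desc[0]}/{hb.acceptor_desc[1]}/{hb.acceptor_desc[2]}",
                "distance": round(hb.da_distance, 4),
                "angle": round(hb.dha_angle, 2),
                "scope": hb.scope,
                "class": "mainchain" if hb.is_mainchain else "sidechain",
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load-input"
    try:
        if config.builder is not None:
            flat = build_parallel_dimer(config.builder)
        else:
            flat = read_structure(config.input_path)
        stage = "relax-flat"
        if config.relax_flat:
            logger.info("relaxing flat reference (max %d iterations)", config.relax_max_iter)
            flat = minimize(flat, config.energy, max_iter=config.relax_max_iter).structure
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    model = EnergyModel(flat, config.energy)
    e_flat = model.energy(flat.coords())

    stage = "flat-census"
    hb_rows = _hb_rows(flat, config.criteria)
    pd.DataFrame(hb_rows).to_csv(out / "hbonds.csv", index=False)
    inter = [r for r in hb_rows if r["scope"] == "intermolecular"]
    flat_summary = {
        "n_hb_intermolecular": len(inter),
        "n_hb_intermolecular_mainchain": sum(1 for r in inter if r["class"] == "mainchain"),
        "interlayer_distance": interlayer_distance(flat),
    }
    write_structure(flat, out / "flat.pdb")

    records = []
    ledger_rows = []
    contact_rows = []
    for axis_spec in config.axes:
        axis = parse_axis(axis_spec) if isinstance(axis_spec, str) else axis_spec
        label = axis.label_with_code(flat)
        try:
            stage = "twist"
            logger.info("axis %s: generating twisted conformation", label)
            tw = generate_twisted(flat, axis, energy_params=config.energy)
            stage = "hb-ledger"
            change = delta_hb(flat, tw.structure, config.criteria)
            for kind, bonds in (("broken", change.broken), ("formed", change.formed)):
                for hb in bonds:
                    ledger_rows.append(
                        {
                            "axis": label,
                            "event": kind,
                            "donor": "/".join(map(str, hb.donor_desc)),
                            "acceptor": "/".join(map(str, hb.acceptor_desc)),
                            "scope": hb.scope,
                            "class": "mainchain" if hb.is_mainchain else "sidechain",
                        }
                    )
            stage = "path-relax"
            logger.info("axis %s: NEB relaxation (%d images)", label, config.neb.n_images)
            path0 = prepare_twist_path(flat, tw.structure, axis, n_images=config.neb.n_images, params=config.energy)
            path = neb_relax(
                path0,
                config.energy,
                spring_k=config.neb.spring_k,
                climbing=config.neb.climbing,
                tol=config.neb.tol,
                max_iter=config.neb.max_iter,
            )
            stage = "barrier"
            rep = barrier(path)
            stage = "contacts"
            contacts = contact_table(path.images, axis, rep.top_index, len(path.images) - 1)
            for desc, d_top, d_min in contacts.pairs:
                contact_rows.append(
                    {"axis": label, "pair": desc, "d_barrier_top": round(d_top, 4), "d_local_minimum": round(d_min, 4)}
                )
            stage = "write-outputs"
            safe = label.replace(":", "_")
            write_path(path.images, out / f"path_{safe}.pdb")
            prof = pd.DataFrame(
                {"image": np.arange(len(path.images)), "relative_energy": np.round(path.relative_energies, 6)}
            )
            prof.to_csv(out / f"profile_{safe}.csv", index=False)
            records.append(
                {
                    "axis": label,
                    "applied_angle": tw.applied_angle,
                    "relaxed": tw.relaxed,
                    "delta_n_hb": change.delta_n_hb,
                    "n_broken_total": len(change.broken),
                    "n_formed_total": len(change.formed),
                    "endothermic_energy": float(model.energy(tw.structure.coords()) - e_flat),
                    "barrier_twisted_to_flat": rep.barrier_twisted_to_flat,
                    "barrier_flat_to_twisted": rep.barrier_flat_to_twisted,
                    "top_index": rep.top_index,
                    "neb_converged": path.converged,
                    "contacts": [
                        {"pair": d, "d_barrier_top": t, "d_local_minimum": m} for d, t, m in contacts.pairs
                    ],
                }
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for axis {label}: {exc}") from exc

    pd.DataFrame(ledger_rows).to_csv(out / "ledger.csv", index=False)
    pd.DataFrame(contact_rows).to_csv(out / "contacts.csv", index=False)

    report = {
        "flat": _round(flat_summary),
        "axes": _round(records),
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package": "abtwist",
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def analyze_deposited_path(
    path_files: list[str | Path],
    axis: TorsionAxis | str,
    criteria: HBCriteria | None = None,
    template: Structure | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image hydrogen-bond counts and near-axis contacts for a pathway ensemble.

    Accepts one or more multi-model PDB / XYZ-trajectory files (images are
    concatenated in order).  Returns (hb_counts, contacts) DataFrames: one
    row per image with intermolecular total/mainchain counts and
    upper-monomer intramolecular counts; and per-image near-axis contact
    distances for the given axis.
    """
    criteria = criteria or HBCriteria()
    if isinstance(axis, str):
        axis = parse_axis(axis)
    images: list[Structure] = []
    for f in path_files:
        images.extend(read_path(f, template=template))
    if not images:
        raise ValueError("no images found")
    meta0 = images[0].atom_meta()
    for k, img in enumerate(images[1:], start=2):
        if img.atom_meta() != meta0:
            raise ValueError(f"image {k} topology differs from image 1")

    hb_rows = []
    contact_rows = []
    upper_idx = images[0].upper_index()
    for k, img in enumerate(images):
        hbs = detect_hbonds(img, criteria)
        inter = [h for h in hbs if h.scope == "intermolecular"]
        hb_rows.append(
            {
                "image": k,
                "inter_total": len(inter),
                "inter_mainchain": sum(1 for h in inter if h.is_mainchain),
                "intra_upper": sum(
                    1 for h in hbs if h.scope == "intramolecular" and h.donor_desc[0] == upper_idx
                ),
            }
        )
        contacts = contact_table(images, axis, k, k)
        for desc, d, _ in contacts.pairs:
            contact_rows.append({"image": k, "pair": desc, "distance": round(d, 4)})
    return pd.DataFrame(hb_rows), pd.DataFrame(contact_rows)
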