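"""End-to-end pipeline: build → simulate → analyze, with a manifest.

A single structured config drives every stage; all randomness funnels
through per-stage seeds derived from one global seed, so identical
config+seed reproduce every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .electrostatics_pb import GridSpec, SlabDielectricSpec, compute_mctrdz, mm_pb_total
from .io_core import (
    select,
    write_charges_csv,
    write_pdb,
    write_profile_csv,
    write_series_csv,
    write_xyz,
)
from .permeation_analysis import (
    contact_number,
    delta_z,
    detect_crossings,
    ion_displacement,
    lipid_residue_groups,
    segment_stages,
    target_residue_groups,
)
from .structure_geometry import helix_rotation, pore_profile
from .synthetic_system import (
    BathSpec,
    ChannelSpec,
    LigandSpec,
    LipidSpec,
    build_log,
    build_pentamer,
    place_ions_and_slab,
    place_ligand,
    place_lipids,
)
from .toy_dynamics import (
    DynamicsConfig,
    ExternalField,
    ForceField,
    run_dynamics,
)

__all__ = ["default_demo_config", "validate_config", "run_pipeline",
           "build_system"]

HELIX_SELECTIONS = {
    "S1": "resnum 3:12 and name CA",
    "TM1": "resnum 15:43 and name CA",
    "TM2": "resnum 77:106 and name CA",
    "CH": "resnum 115:130 and name CA",
}


def default_demo_config() -> dict:
    """The packaged demo: an open channel, a 0.2 V/Å field on the ligand."""
    return {
        "seed": 1,
        "build": {
            "pore_constriction_radius": 6.0,
            "ligand_position": [0.0, 0.0, 10.0],
            "n_cations": 95,
            "n_anions": 95,
            "n_lipids": 40,
        },
        "simulate": {
            "field_V_per_A": 0.2,
            "timestep_ps": 0.01,
            "temperature_K": 300.0,
            "friction_per_ps": 5.0,
            "n_steps": 4000,
            "save_interval_ps": 0.5,
            "coulomb_dielectric": 80.0,
            "ligand_mass_amu": 194.0,
        },
        "analysis": {
            "ligand": "resname LIG",
            "ring": "resnum 106 and name CA",
            "z_upper": 10.0,
            "z_lower": -5.0,
            "bands": [20.0, 0.0],
            "min_dwell_ps": 2.0,
            "contact_resnum": 103,
        },
        "pore": {"zmin": -40.0, "zmax": 5.0, "step": 1.0, "r_max": 15.0},
        "energy": {"spacing": 2.0, "buffer": 8.0, "n_frames": 3},
    }


def validate_config(config: dict) -> dict:
    """Schema/sanity validation before any computation."""
    cfg = default_demo_config()
    for section, values in (config or {}).items():
        if section == "seed":
            cfg["seed"] = int(values)
            continue
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for k, v in values.items():
            if k not in cfg[section]:
                raise ValueError(f"unknown key {k!r} in section {section!r}")
            cfg[section][k] = v
    ana = cfg["analysis"]
    if ana["z_upper"] <= ana["z_lower"]:
        raise ValueError("z_upper must exceed z_lower")
    if cfg["pore"]["zmin"] >= cfg["pore"]["zmax"]:
        raise ValueError("pore zmin must be below zmax")
    if cfg["simulate"]["n_steps"] <= 0:
        raise ValueError("n_steps must be positive")
    return cfg


def build_system(cfg: dict, seed: int):
    b = cfg["build"]
    st = build_pentamer(ChannelSpec(
        pore_constriction_radius=float(b["pore_constriction_radius"])))
    st = place_ligand(st, LigandSpec(),
                      initial_position=b["ligand_position"])
    st = place_ions_and_slab(st, BathSpec(
        n_cations=int(b["n_cations"]), n_anions=int(b["n_anions"]),
        rng_seed=seed))
    if int(b["n_lipids"]) > 0:
        st = place_lipids(st, LipidSpec(n_lipids=int(b["n_lipids"]),
                                        rng_seed=seed + 1))
    return st


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run every stage and write the artifact set plus a manifest.

    On failure the manifest is still written with a FAILED marker and the
    exception re-raised (partial artifacts are retained).
    """
    cfg = validate_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "artifacts": [],
        "status": "RUNNING",
    }

    def save_manifest():
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")

    try:
        # ---- build
        system = build_system(cfg, seed)
        write_pdb(system, outdir / "system.pdb")
        write_charges_csv(system, outdir / "charges.csv")
        manifest["artifacts"] += ["system.pdb", "charges.csv"]
        manifest["build_log"] = build_log(system)

        # ---- simulate
        sim = cfg["simulate"]
        lig = select(system, cfg["analysis"]["ligand"])
        ff = ForceField(
            coulomb_dielectric=float(sim["coulomb_dielectric"]),
            eef=ExternalField(field=(0.0, 0.0, -float(sim["field_V_per_A"])),
                              mask=lig.indices),
        )
        masses = np.full(system.n_atoms, 100.0)
        masses[lig.indices] = float(sim["ligand_mass_amu"])
        dyn = DynamicsConfig(
            timestep=float(sim["timestep_ps"]),
            temperature=float(sim["temperature_K"]),
            friction=float(sim["friction_per_ps"]),
            n_steps=int(sim["n_steps"]),
            save_interval=float(sim["save_interval_ps"]),
            rng_seed=seed,
            mobile=lig.indices,
            masses=masses,
            rigid_groups=[lig.indices],
        )
        traj = run_dynamics(system, ff, dyn)
        write_xyz(traj, outdir / "traj.xyz")
        manifest["artifacts"].append("traj.xyz")

        # ---- permeation analysis
        ana = cfg["analysis"]
        series = delta_z(traj, ana["ligand"], ana["ring"])
        write_series_csv(series, outdir / "deltaz.csv")
        events = detect_crossings(series, z_upper=float(ana["z_upper"]),
                                  z_lower=float(ana["z_lower"]))
        stages = segment_stages(series, bands=ana["bands"],
                                min_dwell=float(ana["min_dwell_ps"]))
        ions = select(system, "name K")
        disp = ion_displacement(traj, ions)
        lipids = lipid_residue_groups(system)
        contacts = None
        if lipids:
            targets = target_residue_groups(system, int(ana["contact_resnum"]))
            cs = contact_number(traj, targets, lipids)
            contacts = {k: float(v) for k, v in cs.averages.items()}
        down = [e for e in events if e["direction"] == "down"]
        report = {
            "crossings": events,
            "n_downward_passages": len(down),
            "first_passage_ps": down[0]["t_end"] if down else None,
            "stages": stages,
            "ion_mean_shift_A": disp["mean"],
            "contact_averages": contacts,
            "net_charge_e": manifest["build_log"]["net_charge_e"],
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        manifest["artifacts"] += ["deltaz.csv", "report.json"]

        # ---- MM-PB energy series (subsampled frames)
        en = cfg["energy"]
        nf = min(int(en["n_frames"]), traj.n_frames)
        frame_ids = np.linspace(0, traj.n_frames - 1, nf).astype(int)
        mct = compute_mctrdz(system, "resname MKU or resname MKL")
        spec = SlabDielectricSpec(z_offset=mct)
        gspec = GridSpec(spacing=float(en["spacing"]),
                         buffer=float(en["buffer"]))
        ff_mm = ForceField(coulomb_dielectric=float(sim["coulomb_dielectric"]))
        rows = []
        for fi in frame_ids:
            st_f = traj.frame_structure(int(fi))
            res = mm_pb_total(st_f, ff_mm, spec, gspec)
            rows.append((traj.times[fi], res["E_MM"], res["E_PB"],
                         res["total"]))
        import pandas as pd
        edf = pd.DataFrame(rows, columns=["time_ps", "E_MM_kcal_mol",
                                          "E_PB_kcal_mol", "total_kcal_mol"])
        write_series_csv(edf, outdir / "energies.csv")
        manifest["artifacts"].append("energies.csv")

        # ---- pore profile (last frame, protein only)
        pore = cfg["pore"]
        last = traj.frame_structure(traj.n_frames - 1)
        prof = pore_profile(last, (float(pore["zmin"]), float(pore["zmax"])),
                            step=float(pore["step"]),
                            r_max=float(pore["r_max"]),
                            selection=select(last, "not resname LIG and not "
                                             "name K and not name CL"))
        write_profile_csv(prof, outdir / "profile.csv")
        manifest["artifacts"].append("profile.csv")

        # ---- helix rotations (last frame vs built reference)
        rots = helix_rotation(last, system, HELIX_SELECTIONS)
        rdf = pd.DataFrame(
            [{"helix": k, "angle_deg": v["angle_deg"],
              "axis_x": v["axis"][0], "axis_y": v["axis"][1],
              "axis_z": v["axis"][2],
              "clockwise_from_periplasm": v["clockwise_from_periplasm"]}
             for k, v in rots.items()])
        rdf.to_csv(outdir / "rotations.csv", index=False,
                   float_format="%.6g")
        manifest["artifacts"].append("rotations.csv")

        manifest["status"] = "OK"
        manifest["report"] = {"n_downward_passages": len(down)}
        save_manifest()
        return {"manifest": manifest, "report": report, "outdir": str(outdir)}
    except Exception:
        manifest["status"] = "FAILED"
        save_manifest()
        raise
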