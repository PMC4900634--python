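"""Coarse-grained Langevin dynamics with an external-electric-field term.

The force field has four terms:

* plain Coulomb (no cutoff), optionally screened by a uniform relative
  dielectric (default 1, i.e. bare charges);
* WCA repulsion (purely repulsive Lennard-Jones truncated and shifted at
  its minimum) with per-atom contact radii, ``σ_ij = r_i + r_j``;
* harmonic positional restraints with the ``E = k·d²`` convention (no ½) —
  the force-constant convention under which restraint strengths such as
  20, 15, 10, 5, 2, 1 kcal/mol/Å² are meaningful;
* the external electric field (EEF): for every atom *i* in a selection
  mask, ``f_i = c_i · E`` componentwise, converted at 23.0609
  kcal/(mol·Å) per e·(V/Å); atoms outside the mask feel exactly zero.

Integration is BAOAB-split Langevin with a friction (collision frequency)
default of 5 ps⁻¹; snapshots are saved every 4 ps by default.  Scaffold
atoms are static unless selected as mobile; the ligand can be kept rigid
by constraint projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ACCEL_CONV, COULOMB_KCAL, EEF_TO_FORCE, KB_KCAL
from .io_core import Selection, Structure, Trajectory, select

__all__ = [
    "Restraint",
    "ExternalField",
    "ForceField",
    "DynamicsConfig",
    "eef_forces",
    "potential_energy",
    "forces",
    "run_dynamics",
    "run_permeation_protocol",
]


@dataclass
class Restraint:
    indices: np.ndarray
    reference: np.ndarray
    k: float  # kcal/(mol·Å²), energy = k·d² per atom

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.reference = np.asarray(self.reference, dtype=np.float64).reshape(-1, 3)
        if self.reference.shape[0] != self.indices.size:
            raise ValueError("restraint reference count mismatch")


@dataclass
class ExternalField:
    field: np.ndarray  # V/Å
    mask: np.ndarray   # atom indices the field acts on

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.field)):
            raise ValueError("field must be finite")
        self.mask = np.asarray(self.mask, dtype=np.int64)


@dataclass
class ForceField:
    coulomb_constant: float = COULOMB_KCAL
    coulomb_dielectric: float = 1.0
    wca_epsilon: float = 0.2
    wca_enabled: bool = True
    coulomb_enabled: bool = True
    restraints: list[Restraint] = field(default_factory=list)
    eef: ExternalField | None = None


@dataclass
class DynamicsConfig:
    timestep: float = 0.01          # ps
    temperature: float = 300.0      # K
    friction: float = 5.0           # ps⁻¹
    n_steps: int = 1000
    save_interval: float = 4.0      # ps
    rng_seed: int = 0
    mobile: Selection | np.ndarray | None = None  # scaffold static by default
    masses: float | np.ndarray = 100.0            # amu
    rigid_groups: list[np.ndarray] = field(default_factory=list)
    energy_abort_threshold: float = 1e8           # kcal/mol

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        ratio = self.save_interval / self.timestep
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("save_interval must be a multiple of timestep")


def eef_forces(charges, field_v_per_A, mask, n_atoms=None) -> np.ndarray:
    """Per-atom EEF forces, kcal/(mol·Å): ``f_i = c_i · E`` inside the mask.

    ``mask`` is a :class:`Selection` or an index array; atoms outside it
    get exactly zero force.
    """
    charges = np.asarray(charges, dtype=np.float64)
    n = n_atoms if n_atoms is not None else charges.size
    fvec = np.asarray(field_v_per_A, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(fvec)):
        raise ValueError("field must be finite")
    idx = mask.indices if isinstance(mask, Selection) else np.asarray(mask, dtype=np.int64)
    out = np.zeros((n, 3))
    out[idx] = EEF_TO_FORCE * charges[idx, None] * fvec[None, :]
    return out


# ---------------------------------------------------------------------------
# pairwise terms
# ---------------------------------------------------------------------------

def _exclusion_mask(structure: Structure) -> np.ndarray:
    """Pairs excluded from nonbonded terms: same residue, or backbone
    neighbors (|Δresidue| ≤ 2 within one monomer) — the coarse analog of
    1-2/1-3 exclusions."""
    mono = structure.monomer_index
    resnum = structure.residue_number
    same_mono = mono[:, None] == mono[None, :]
    close_res = np.abs(resnum[:, None] - resnum[None, :]) <= 2
    same_chain = same_mono & (mono[:, None] >= 0) & close_res
    same_residue = (resnum[:, None] == resnum[None, :]) & same_mono
    excl = same_chain | same_residue
    np.fill_diagonal(excl, True)
    return excl


def _pair_distances(coords):
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    return diff, r


def potential_energy(structure: Structure, ff: ForceField, coords=None):
    """Total potential energy (kcal/mol) with a per-term breakdown.

    Returns ``(total, breakdown)`` where breakdown has keys ``coulomb``,
    ``wca``, ``restraints``, ``eef``.  Coincident charged atoms error
    (infinite Coulomb).
    """
    x = structure.coords if coords is None else np.asarray(coords, float)
    excl = _exclusion_mask(structure)
    diff, r = _pair_distances(x)
    iu = np.triu_indices(structure.n_atoms, k=1)
    pair_ok = ~excl[iu]
    rij = r[iu]

    e_coul = 0.0
    if ff.coulomb_enabled:
        q = structure.charge
        qq = (q[:, None] * q[None, :])[iu]
        charged = pair_ok & (qq != 0)
        if np.any(charged & (rij < 1e-9)):
            raise ValueError("coincident charged atoms: Coulomb energy diverges")
        e_coul = float(np.sum(
            ff.coulomb_constant / ff.coulomb_dielectric
            * qq[charged] / rij[charged]))

    e_wca = 0.0
    if ff.wca_enabled:
        sig = (structure.vdw_radius[:, None] + structure.vdw_radius[None, :])[iu]
        cutoff = 2.0 ** (1.0 / 6.0) * sig
        act = pair_ok & (rij < cutoff) & (sig > 0)
        if np.any(act):
            sr6 = (sig[act] / np.maximum(rij[act], 1e-12)) ** 6
            e_wca = float(np.sum(4.0 * ff.wca_epsilon * (sr6 ** 2 - sr6)
                                 + ff.wca_epsilon))

    e_rest = 0.0
    for rs in ff.restraints:
        d2 = np.sum((x[rs.indices] - rs.reference) ** 2, axis=1)
        e_rest += float(rs.k * np.sum(d2))

    e_eef = 0.0
    if ff.eef is not None:
        f = eef_forces(structure.charge, ff.eef.field, ff.eef.mask,
                       structure.n_atoms)
        e_eef = float(-np.sum(f * x))

    breakdown = {"coulomb": e_coul, "wca": e_wca, "restraints": e_rest,
                 "eef": e_eef}
    return sum(breakdown.values()), breakdown


def _mobile_energy(structure: Structure, ff: ForceField, x, rows, excl):
    """Energy of the mobile subsystem (its internal terms plus interaction
    with the static scaffold) — the only part that can diverge during
    dynamics.  O(m·n); pair terms internal to ``rows`` are halved."""
    diff = x[rows, None, :] - x[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    valid = ~excl[rows]
    np.putmask(r, r < 1e-12, np.inf)
    in_rows = np.zeros(structure.n_atoms, dtype=bool)
    in_rows[rows] = True
    weight = np.where(in_rows[None, :], 0.5, 1.0) * valid
    e = 0.0
    if ff.coulomb_enabled:
        qq = structure.charge[rows, None] * structure.charge[None, :]
        e += float(np.sum(weight * ff.coulomb_constant
                          / ff.coulomb_dielectric * qq / r))
    if ff.wca_enabled:
        sig = structure.vdw_radius[rows, None] + structure.vdw_radius[None, :]
        act = (r < 2.0 ** (1.0 / 6.0) * sig) & (sig > 0)
        sr6 = np.where(act, (sig / r) ** 6, 0.0)
        e += float(np.sum(weight * act
                          * (4.0 * ff.wca_epsilon * (sr6 ** 2 - sr6)
                             + ff.wca_epsilon * act)))
    for rs in ff.restraints:
        sel = np.flatnonzero(np.isin(rs.indices, rows))
        idx = rs.indices[sel]
        e += float(rs.k * np.sum((x[idx] - rs.reference[sel]) ** 2))
    if ff.eef is not None:
        f = eef_forces(structure.charge, ff.eef.field, ff.eef.mask,
                       structure.n_atoms)
        e += float(-np.sum(f[rows] * x[rows]))
    return e


def forces(structure: Structure, ff: ForceField, coords=None,
           mobile=None, _excl=None) -> np.ndarray:
    """Analytic forces, kcal/(mol·Å); exact negative gradients of
    :func:`potential_energy`.  If ``mobile`` indices are given, only those
    rows are computed (the rest are zero)."""
    x = structure.coords if coords is None else np.asarray(coords, float)
    n = structure.n_atoms
    excl = _exclusion_mask(structure) if _excl is None else _excl
    rows = np.arange(n) if mobile is None else np.asarray(mobile, dtype=np.int64)
    diff = x[rows, None, :] - x[None, :, :]        # (m, n, 3)
    r = np.linalg.norm(diff, axis=-1)
    valid = ~excl[rows]
    np.putmask(r, r < 1e-12, np.inf)
    f = np.zeros((n, 3))

    if ff.coulomb_enabled:
        qq = structure.charge[rows, None] * structure.charge[None, :]
        coef = ff.coulomb_constant / ff.coulomb_dielectric * qq / r ** 3
        coef[~valid] = 0.0
        f[rows] += np.einsum("mn,mnd->md", coef, diff)

    if ff.wca_enabled:
        sig = structure.vdw_radius[rows, None] + structure.vdw_radius[None, :]
        cutoff = 2.0 ** (1.0 / 6.0) * sig
        act = valid & (r < cutoff) & (sig > 0)
        if np.any(act):
            sr6 = np.where(act, (sig / r) ** 6, 0.0)
            # dE/dr = 4ε(−12 σ^12/r^13 + 6 σ^6/r^7); force = −dE/dr · r̂
            mag = np.where(act,
                           4.0 * ff.wca_epsilon * (12.0 * sr6 ** 2 - 6.0 * sr6) / r ** 2,
                           0.0)
            f[rows] += np.einsum("mn,mnd->md", mag, diff)

    for rs in ff.restraints:
        if mobile is None:
            sel = np.arange(rs.indices.size)
        else:
            sel = np.flatnonzero(np.isin(rs.indices, rows))
        idx = rs.indices[sel]
        f[idx] += -2.0 * rs.k * (x[idx] - rs.reference[sel])

    if ff.eef is not None:
        f += eef_forces(structure.charge, ff.eef.field, ff.eef.mask, n)

    if mobile is not None:
        keep = np.zeros(n, dtype=bool)
        keep[rows] = True
        f[~keep] = 0.0
    return f


# ---------------------------------------------------------------------------
# rigid-body projection (constraint handling for the ligand)
# ---------------------------------------------------------------------------

def _kabsch_rotation(mobile, reference):
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, cr


def _project_rigid_positions(x, group, reference_geometry):
    """Snap group coordinates onto the rigid reference geometry."""
    cur = x[group]
    ref = np.asarray(reference_geometry)
    rot, _, c_cur = _kabsch_rotation(ref, cur)
    x[group] = (rot @ ref.T).T + c_cur


def _project_rigid_velocities(x, v, group, masses):
    """Project group velocities onto the rigid-body subspace (COM + rotation)."""
    pts = x[group]
    vel = v[group]
    m = masses[group][:, None]
    com = np.sum(m * pts, axis=0) / np.sum(m)
    vcom = np.sum(m * vel, axis=0) / np.sum(m)
    rel = pts - com
    L = np.sum(np.cross(rel, m * (vel - vcom)), axis=0)
    inertia = np.zeros((3, 3))
    for ri, mi in zip(rel, m[:, 0]):
        inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    # pseudo-inverse guards collinear/planar bead clusters
    omega = np.linalg.pinv(inertia, rcond=1e-10) @ L
    v[group] = vcom + np.cross(np.broadcast_to(omega, rel.shape), rel)


def run_dynamics(structure: Structure, ff: ForceField,
                 config: DynamicsConfig) -> Trajectory:
    """BAOAB-discretized Langevin dynamics; deterministic given the seed.

    Only atoms in ``config.mobile`` move; frames (full coordinate sets) are
    saved every ``save_interval`` ps starting at t = 0.  Diverging energy
    aborts with a diagnostic.
    """
    if config.mobile is None:
        raise ValueError("mobile selection is empty; nothing to integrate")
    mobile = (config.mobile.indices if isinstance(config.mobile, Selection)
              else np.asarray(config.mobile, dtype=np.int64))
    if mobile.size == 0:
        raise ValueError("mobile selection is empty; nothing to integrate")

    n = structure.n_atoms
    masses = np.broadcast_to(
        np.asarray(config.masses, dtype=np.float64), (n,)).copy() \
        if np.ndim(config.masses) else np.full(n, float(config.masses))
    x = structure.coords.copy()
    rng = np.random.default_rng(config.rng_seed)
    kT = KB_KCAL * config.temperature
    if config.temperature > 0:
        v = rng.normal(size=(n, 3)) * np.sqrt(ACCEL_CONV * kT / masses)[:, None]
    else:
        v = np.zeros((n, 3))
    static = np.ones(n, dtype=bool)
    static[mobile] = False
    v[static] = 0.0

    h = config.timestep
    gamma = config.friction
    c1 = np.exp(-gamma * h)
    c2 = np.sqrt(max(0.0, (1.0 - c1 ** 2)) * ACCEL_CONV * kT / masses)[:, None]
    excl = _exclusion_mask(structure)
    rigid = [np.asarray(g, dtype=np.int64) for g in config.rigid_groups]
    rigid_ref = [x[g] - x[g].mean(axis=0) for g in rigid]

    def apply_constraints():
        for g, ref in zip(rigid, rigid_ref):
            _project_rigid_positions(x, g, ref)
            _project_rigid_velocities(x, v, g, masses)

    apply_constraints()
    save_every = int(round(config.save_interval / h))
    frames = [x.copy()]
    times = [0.0]
    e0 = _mobile_energy(structure, ff, x, mobile, excl)
    fvec = forces(structure, ff, x, mobile=mobile, _excl=excl)
    inv_m = (ACCEL_CONV / masses)[:, None]
    for step in range(1, config.n_steps + 1):
        v[mobile] += 0.5 * h * fvec[mobile] * inv_m[mobile]
        x[mobile] += 0.5 * h * v[mobile]
        if config.temperature > 0:
            v[mobile] = c1 * v[mobile] + c2[mobile] * rng.normal(
                size=(mobile.size, 3))
        else:
            v[mobile] = c1 * v[mobile]
        x[mobile] += 0.5 * h * v[mobile]
        for g, ref in zip(rigid, rigid_ref):
            _project_rigid_positions(x, g, ref)
            _project_rigid_velocities(x, v, g, masses)
        fvec = forces(structure, ff, x, mobile=mobile, _excl=excl)
        v[mobile] += 0.5 * h * fvec[mobile] * inv_m[mobile]
        if step % save_every == 0:
            if not np.all(np.isfinite(x[mobile])):
                raise RuntimeError(
                    f"dynamics diverged at step {step}: non-finite coordinates")
            e = _mobile_energy(structure, ff, x, mobile, excl)
            # drift relative to the starting energy, so a constant clash in
            # the static scaffold cannot mask or mimic a divergence
            if not np.isfinite(e) or abs(e - e0) > config.energy_abort_threshold:
                raise RuntimeError(
                    f"dynamics diverged at step {step}: "
                    f"|E - E0| = {abs(e - e0):.3g} kcal/mol")
            frames.append(x.copy())
            times.append(step * h)
    return Trajectory(structure=structure, frames=np.array(frames),
                      times=np.array(times))


def run_permeation_protocol(
    system: Structure,
    field_strengths,
    seeds,
    *,
    ligand_expr: str = "resname LIG",
    ring_expr: str = "resnum 106 and name CA",
    z_upper: float = 10.0,
    z_lower: float = -5.0,
    base_config: DynamicsConfig | None = None,
    ligand_mass: float = 194.0,
    rigid_ligand: bool = True,
    coulomb_dielectric: float = 80.0,
):
    """Run one trajectory per (field, seed) and tabulate first-passage times.

    The field (V/Å) points along −Z (periplasm→cytoplasm for a positive
    ligand) and acts only on the ligand selection.  Returns
    ``(records, summary)`` where records are (trajectory, field, seed)
    tuples and summary is a DataFrame with the first downward passage time
    per run (``inf`` if none).
    """
    from .permeation_analysis import delta_z, detect_crossings

    lig = select(system, ligand_expr)
    if len(lig) == 0:
        raise ValueError("ligand selection is empty")
    cfg0 = base_config or DynamicsConfig(n_steps=15000, save_interval=0.5)
    records = []
    rows = []
    for f in field_strengths:
        for s in seeds:
            ff = ForceField(
                coulomb_dielectric=coulomb_dielectric,
                eef=ExternalField(field=(0.0, 0.0, -float(f)), mask=lig.indices),
            )
            masses = np.full(system.n_atoms, 100.0)
            masses[lig.indices] = ligand_mass
            cfg = DynamicsConfig(
                timestep=cfg0.timestep, temperature=cfg0.temperature,
                friction=cfg0.friction, n_steps=cfg0.n_steps,
                save_interval=cfg0.save_interval, rng_seed=int(s),
                mobile=lig.indices, masses=masses,
                rigid_groups=[lig.indices] if rigid_ligand and len(lig) > 1 else [],
            )
            traj = run_dynamics(system, ff, cfg)
            series = delta_z(traj, ligand_expr, ring_expr)
            events = detect_crossings(series, z_upper=z_upper, z_lower=z_lower)
            down = [e for e in events if e["direction"] == "down"]
            fpt = down[0]["t_end"] if down else np.inf
            records.append((traj, float(f), int(s)))
            rows.append({"field_V_per_A": float(f), "seed": int(s),
                         "first_passage_ps": float(fpt),
                         "n_down": len(down)})
    summary = pd.DataFrame(rows)
    return records, summary
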