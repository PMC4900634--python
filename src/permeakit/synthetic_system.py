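"""Synthetic channel/ligand/bath builder.

Generates an idealized pentameric two-helix-per-subunit channel — exact
n-fold symmetry about Z, ideal α-helix geometry (1.5 Å rise and 100° twist
per residue), one Cα plus one side-chain pseudo-atom per residue — together
with a rigid +3-charged ligand surrogate (~10 Å across), K⁺/Cl⁻ ion baths,
a membrane slab with face marker atoms, and three-residue lipid surrogates
(one polar PC plus hydrophobic PA/OL residues) for contact statistics.

Orientation convention: the membrane normal is +Z and the periplasmic side
is +Z; the cytoplasmic lysine ring (residue 106 per monomer, numbered with
the concatenated +136 offset) sits below the slab.  The builder enforces
the requested minimum pore radius by placing a ring of side-chain beads of
the constriction residue at exactly that clearance from the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import Structure, concat_structures

__all__ = [
    "HelixSpec",
    "ChannelSpec",
    "LigandSpec",
    "BathSpec",
    "LipidSpec",
    "GeometryError",
    "build_pentamer",
    "place_ligand",
    "place_ions_and_slab",
    "place_lipids",
    "build_log",
]

CA_RADIUS = 1.9
CB_RADIUS = 2.0
HELIX_RADIUS = 2.3   # Å, Cα distance from the helix axis
RISE = 1.5           # Å per residue along the axis
TWIST = 100.0        # degrees per residue
SIDE_OFFSET = 1.8    # Å, side-chain bead beyond the Cα, radially from the axis

_RESNAME_MAP = {19: "LEU", 25: "ILE", 103: "ASN", 106: "LYS"}


class GeometryError(ValueError):
    """Raised for infeasible builder geometry."""


@dataclass
class HelixSpec:
    """A straight ideal helix: residue range plus axis origin/direction."""

    res_start: int
    res_end: int
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    phase_deg: float = 0.0


def _default_helices() -> dict[str, HelixSpec]:
    return {
        "S1": HelixSpec(3, 12, (11.0, 0.0, -28.0), (1.0, 0.0, 0.05)),
        "TM1": HelixSpec(15, 43, (13.0, 0.0, -16.0), (0.18, 0.0, 1.0)),
        "TM2": HelixSpec(77, 106, (17.0, 0.0, 24.0), (0.12, 0.0, -1.0)),
        "CH": HelixSpec(115, 130, (12.0, 0.0, -30.0), (0.05, 0.0, -1.0)),
    }


@dataclass
class ChannelSpec:
    n_monomers: int = 5
    residues_per_monomer: int = 136
    helices: dict[str, HelixSpec] = field(default_factory=_default_helices)
    pore_constriction_radius: float = 6.0
    constriction_z: float = -13.0
    lysine_ring_resnum: int = 106
    numbering_offset: int = 136
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_monomers < 3:
            raise GeometryError("n_monomers must be >= 3")
        if self.pore_constriction_radius <= 0:
            raise GeometryError(
                "infeasible geometry: pore constriction radius must be positive"
            )
        ranges = sorted((h.res_start, h.res_end) for h in self.helices.values())
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if a1 >= b0:
                raise GeometryError("helix residue ranges overlap")
            if a0 > a1:
                raise GeometryError("helix residue range reversed")
        if ranges and (ranges[0][0] < 1 or ranges[-1][1] > self.residues_per_monomer):
            raise GeometryError("helix residues outside the monomer")


@dataclass
class LigandSpec:
    n_beads: int = 3
    total_charge: float = 3.0
    diameter: float = 10.0
    bead_vdw_radius: float = 2.0

    def __post_init__(self):
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.diameter <= 2 * self.bead_vdw_radius and self.n_beads > 1:
            raise ValueError("diameter too small for the bead radius")


@dataclass
class BathSpec:
    n_cations: int = 95
    n_anions: int = 95
    box: tuple = ((-30.0, 30.0), (-30.0, 30.0), (-45.0, 35.0))
    slab_z: tuple[float, float] = (-9.0, 9.0)
    min_separation: float = 3.0
    exclusion_cylinder_radius: float = 15.0
    n_headgroup_markers: int = 16
    marker_ring_radius: float = 28.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cations < 0 or self.n_anions < 0:
            raise ValueError("ion counts must be >= 0")
        if self.slab_z[0] >= self.slab_z[1]:
            raise ValueError("slab z-bounds must be ordered")


@dataclass
class LipidSpec:
    n_lipids: int = 40
    ring_radius_range: tuple[float, float] = (26.0, 34.0)
    rng_seed: int = 0


def _helix_frame(direction):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return d, u, v


def _helix_positions(spec: HelixSpec):
    """Cα and side-bead positions for one ideal helix."""
    n = spec.res_end - spec.res_start + 1
    d, u, v = _helix_frame(spec.direction)
    o = np.asarray(spec.origin, dtype=float)
    i = np.arange(n)
    theta = np.deg2rad(spec.phase_deg + TWIST * i)
    axis_pts = o + np.outer(RISE * i, d)
    radial = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
    ca = axis_pts + HELIX_RADIUS * radial
    cb = ca + SIDE_OFFSET * radial
    return ca, cb


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def axial_pore_radius(structure: Structure, z: float, indices=None) -> float:
    """Clearance radius at the on-axis point (0, 0, z): min_i(|c−x_i| − r_i)."""
    x = structure.coords if indices is None else structure.coords[indices]
    r = structure.vdw_radius if indices is None else structure.vdw_radius[indices]
    c = np.array([0.0, 0.0, z])
    d = np.linalg.norm(x - c, axis=1) - r
    return float(d.min())


def build_pentamer(spec: ChannelSpec | None = None) -> Structure:
    """Build the symmetric channel scaffold.

    Monomer 0 is generated residue by residue (helix residues on ideal
    helices, linker residues linearly interpolated between flanking helix
    ends), then replicated by exact 360/n rotations about Z with the
    residue-number offset applied.  The side-chain bead of the constriction
    residue (the TM1 residue whose Cα is nearest ``constriction_z``) is
    pinned at exactly ``pore_constriction_radius + bead radius`` from the
    axis so the minimum pore radius equals the requested value.
    """
    spec = spec or ChannelSpec()
    R = spec.residues_per_monomer
    ca = np.full((R, 3), np.nan)
    cb = np.full((R, 3), np.nan)
    in_helix = np.zeros(R, dtype=bool)
    for h in spec.helices.values():
        hca, hcb = _helix_positions(h)
        sl = slice(h.res_start - 1, h.res_end)
        ca[sl] = hca
        cb[sl] = hcb
        in_helix[sl] = True
    # linkers: interpolate between flanking anchors; termini stack along -Z
    anchor_idx = np.flatnonzero(in_helix)
    if anchor_idx.size == 0:
        raise GeometryError("at least one helix is required")
    first, last = anchor_idx[0], anchor_idx[-1]
    for i in range(R):
        if in_helix[i]:
            continue
        if i < first:
            ca[i] = ca[first] + np.array([0.0, 0.0, -RISE * (first - i)])
        elif i > last:
            ca[i] = ca[last] + np.array([0.0, 0.0, -RISE * (i - last)])
        else:
            prev = anchor_idx[anchor_idx < i][-1]
            nxt = anchor_idx[anchor_idx > i][0]
            f = (i - prev) / (nxt - prev)
            ca[i] = (1 - f) * ca[prev] + f * ca[nxt]
        cb[i] = ca[i] + np.array([1.0, 0.0, 0.0])

    # pin the constriction ring bead
    tm1 = spec.helices["TM1"]
    tm1_res = np.arange(tm1.res_start - 1, tm1.res_end)
    ring_res = int(tm1_res[np.argmin(np.abs(ca[tm1_res, 2] - spec.constriction_z))])
    theta = np.arctan2(ca[ring_res, 1], ca[ring_res, 0])
    ring_rho = spec.pore_constriction_radius + CB_RADIUS
    cb[ring_res] = [ring_rho * np.cos(theta), ring_rho * np.sin(theta),
                    spec.constriction_z]

    # assemble monomer 0 atom table
    n_res = R
    names = np.empty(2 * n_res, dtype="U6")
    resnames = np.empty(2 * n_res, dtype="U6")
    resnums = np.empty(2 * n_res, dtype=np.int64)
    coords = np.empty((2 * n_res, 3))
    radii = np.empty(2 * n_res)
    for i in range(n_res):
        names[2 * i], names[2 * i + 1] = "CA", "CB"
        rn = _RESNAME_MAP.get(i + 1, "ALA")
        resnames[2 * i] = resnames[2 * i + 1] = rn
        resnums[2 * i] = resnums[2 * i + 1] = i + 1
        coords[2 * i], coords[2 * i + 1] = ca[i], cb[i]
        radii[2 * i], radii[2 * i + 1] = CA_RADIUS, CB_RADIUS

    # replicate with exact symmetry
    all_coords, all_resnums, all_monomer = [], [], []
    for m in range(spec.n_monomers):
        Rm = _rot_z(360.0 * m / spec.n_monomers)
        all_coords.append(coords @ Rm.T)
        all_resnums.append(resnums + spec.numbering_offset * m)
        all_monomer.append(np.full(2 * n_res, m, dtype=np.int64))
    nm = spec.n_monomers
    st = Structure(
        atom_name=np.tile(names, nm),
        residue_name=np.tile(resnames, nm),
        residue_number=np.concatenate(all_resnums),
        monomer_index=np.concatenate(all_monomer),
        element=np.full(2 * n_res * nm, "C", dtype="U4"),
        coords=np.vstack(all_coords),
        charge=np.zeros(2 * n_res * nm),
        vdw_radius=np.tile(radii, nm),
        numbering_offset=spec.numbering_offset,
        metadata={
            "constriction_residue": ring_res + 1,
            "constriction_z": spec.constriction_z,
            "pore_constriction_radius": spec.pore_constriction_radius,
            "n_monomers": spec.n_monomers,
        },
    )
    # verify no other atom intrudes past the requested constriction radius
    # in a window around the ring
    zs = spec.constriction_z + np.linspace(-6.0, 6.0, 25)
    min_clear = min(axial_pore_radius(st, z) for z in zs)
    if min_clear < spec.pore_constriction_radius - 1e-6:
        raise GeometryError(
            f"infeasible geometry: pore clearance {min_clear:.2f} Å < requested "
            f"constriction radius {spec.pore_constriction_radius:.2f} Å"
        )
    return st


def place_ligand(
    structure: Structure,
    spec: LigandSpec | None = None,
    initial_position=(0.0, 0.0, 10.0),
) -> Structure:
    """Append the rigid ligand surrogate centered at ``initial_position``.

    Beads sit on a ring in the XY plane whose extent (max pairwise center
    distance plus two bead radii) equals the requested diameter; the total
    charge is split uniformly over the beads.
    """
    spec = spec or LigandSpec()
    p0 = np.asarray(initial_position, dtype=float)
    n = spec.n_beads
    if n == 1:
        pts = np.zeros((1, 3))
    else:
        ang = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
        # scale so that max pairwise center distance + 2 r = diameter
        unit_max = np.max(
            np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1))
        target = spec.diameter - 2 * spec.bead_vdw_radius
        pts = pts * (target / unit_max)
        pts -= pts.mean(axis=0)
    coords = pts + p0
    lig = Structure(
        atom_name=np.array([f"L{i+1}" for i in range(n)], dtype="U6"),
        residue_name=np.full(n, "LIG", dtype="U6"),
        residue_number=np.full(n, 1, dtype=np.int64),
        monomer_index=np.full(n, -1, dtype=np.int64),
        element=np.full(n, "C", dtype="U4"),
        coords=coords,
        charge=np.full(n, spec.total_charge / n),
        vdw_radius=np.full(n, spec.bead_vdw_radius),
        numbering_offset=structure.numbering_offset,
    )
    out = concat_structures(structure, lig)
    out.metadata["ligand_indices"] = list(
        range(structure.n_atoms, structure.n_atoms + n))
    out.metadata["ligand_reference_geometry"] = pts.tolist()
    return out


def place_ions_and_slab(structure: Structure, spec: BathSpec | None = None) -> Structure:
    """Append K⁺/Cl⁻ ions by rejection sampling plus slab metadata/markers.

    Ions keep a minimum separation from each other and from existing atoms,
    and stay out of a cylinder around the pore axis (the permeation path,
    standing in for the channel interior the explicit system keeps
    water-filled).  Deterministic under ``rng_seed``.
    """
    spec = spec or BathSpec()
    rng = np.random.default_rng(spec.rng_seed)
    (x0, x1), (y0, y1), (z0, z1) = spec.box
    existing = structure.coords
    placed: list[np.ndarray] = []
    total = spec.n_cations + spec.n_anions
    max_attempts = 20000 * max(total, 1)
    attempts = 0
    while len(placed) < total:
        attempts += 1
        if attempts > max_attempts:
            raise GeometryError(
                "ion placement failed; use a larger box or fewer ions"
            )
        p = rng.uniform([x0, y0, z0], [x1, y1, z1])
        if np.hypot(p[0], p[1]) < spec.exclusion_cylinder_radius:
            continue
        if existing.size and np.min(
                np.linalg.norm(existing - p, axis=1)) < spec.min_separation:
            continue
        if placed and np.min(
                np.linalg.norm(np.array(placed) - p, axis=1)) < spec.min_separation:
            continue
        placed.append(p)
    ion_coords = np.array(placed).reshape(total, 3)
    names = np.array(["K"] * spec.n_cations + ["CL"] * spec.n_anions, dtype="U6")
    charges = np.array([1.0] * spec.n_cations + [-1.0] * spec.n_anions)
    radii = np.array([1.76] * spec.n_cations + [1.81] * spec.n_anions)
    ions = Structure(
        atom_name=names,
        residue_name=names.copy(),
        residue_number=np.arange(1, total + 1, dtype=np.int64),
        monomer_index=np.full(total, -1, dtype=np.int64),
        element=names.copy(),
        coords=ion_coords,
        charge=charges,
        vdw_radius=radii,
        numbering_offset=structure.numbering_offset,
    )
    out = concat_structures(structure, ions)
    out.metadata["ion_indices"] = list(
        range(structure.n_atoms, structure.n_atoms + total))
    out.metadata["slab_z"] = list(spec.slab_z)
    out.metadata["bath_seed"] = spec.rng_seed
    # headgroup marker atoms on deterministic rings at both slab faces
    if spec.n_headgroup_markers > 0:
        ang = 2 * np.pi * np.arange(spec.n_headgroup_markers) / spec.n_headgroup_markers
        ring = spec.marker_ring_radius * np.column_stack(
            [np.cos(ang), np.sin(ang), np.zeros_like(ang)])
        upper = ring + [0.0, 0.0, spec.slab_z[1]]
        lower = ring + [0.0, 0.0, spec.slab_z[0]]
        nm = 2 * spec.n_headgroup_markers
        markers = Structure(
            atom_name=np.full(nm, "MK", dtype="U6"),
            residue_name=np.array(
                ["MKU"] * spec.n_headgroup_markers + ["MKL"] * spec.n_headgroup_markers,
                dtype="U6"),
            residue_number=np.arange(1, nm + 1, dtype=np.int64),
            monomer_index=np.full(nm, -1, dtype=np.int64),
            element=np.full(nm, "P", dtype="U4"),
            coords=np.vstack([upper, lower]),
            charge=np.zeros(nm),
            vdw_radius=np.full(nm, 1.8),
            numbering_offset=structure.numbering_offset,
        )
        out = concat_structures(out, markers)
    return out


def place_lipids(structure: Structure, spec: LipidSpec | None = None) -> Structure:
    """Append three-residue lipid surrogates (PC polar, PA/OL hydrophobic).

    Each lipid has one PC residue near a slab face and PA/OL residues
    reaching toward the slab midplane, two beads per residue, scattered on
    an annulus outside the protein.  Used by the lipid contact statistics.
    """
    spec = spec or LipidSpec()
    rng = np.random.default_rng(spec.rng_seed)
    slab = structure.metadata.get("slab_z", [-9.0, 9.0])
    rows = {k: [] for k in
            ("atom_name", "residue_name", "residue_number", "coords")}
    resnum = 0
    existing = structure.coords
    placed_beads: list = []
    attempts = 0
    n_done = 0
    while n_done < spec.n_lipids:
        attempts += 1
        if attempts > 20000 * max(spec.n_lipids, 1):
            raise GeometryError("lipid placement failed; widen the annulus")
        rho = rng.uniform(*spec.ring_radius_range)
        phi = rng.uniform(0, 2 * np.pi)
        leaflet = 1 if rng.random() < 0.5 else -1
        z_face = slab[1] if leaflet > 0 else slab[0]
        x, y = rho * np.cos(phi), rho * np.sin(phi)
        # PC at the face, PA and OL stacked toward the midplane
        beads = []
        for rname, dz in (("PC", 0.0), ("PA", -3.0 * leaflet), ("OL", -6.0 * leaflet)):
            for j, dxy in enumerate(((0.0, 0.0), (1.2, 0.6))):
                beads.append((rname, j,
                              [x + dxy[0], y + dxy[1],
                               z_face + dz + 0.5 * j * leaflet]))
        pts = np.array([b[2] for b in beads])
        if existing.size and np.min(
                np.linalg.norm(existing[:, None, :] - pts[None, :, :],
                               axis=-1)) < 3.0:
            continue
        if placed_beads and np.min(np.linalg.norm(
                np.asarray(placed_beads)[:, None, :] - pts[None, :, :],
                axis=-1)) < 3.0:
            continue
        n_done += 1
        placed_beads.extend(pts.tolist())
        last_rname = None
        for rname, j, p in beads:
            if rname != last_rname:
                resnum += 1
                last_rname = rname
            rows["atom_name"].append(f"C{j+1}")
            rows["residue_name"].append(rname)
            rows["residue_number"].append(resnum)
            rows["coords"].append(p)
    n = len(rows["atom_name"])
    lip = Structure(
        atom_name=np.array(rows["atom_name"], dtype="U6"),
        residue_name=np.array(rows["residue_name"], dtype="U6"),
        residue_number=np.array(rows["residue_number"], dtype=np.int64),
        monomer_index=np.full(n, -1, dtype=np.int64),
        element=np.full(n, "C", dtype="U4"),
        coords=np.array(rows["coords"]),
        charge=np.zeros(n),
        vdw_radius=np.full(n, 2.0),
        numbering_offset=structure.numbering_offset,
    )
    out = concat_structures(structure, lip)
    out.metadata["lipid_seed"] = spec.rng_seed
    return out


def build_log(structure: Structure) -> dict:
    """Summary of a built system: counts, seeds, net charge."""
    return {
        "n_atoms": structure.n_atoms,
        "n_protein_atoms": int(np.sum(structure.monomer_index >= 0)),
        "n_monomers": int(structure.metadata.get("n_monomers", 0)),
        "net_charge_e": float(structure.charge.sum()),
        "slab_z": structure.metadata.get("slab_z"),
        "bath_seed": structure.metadata.get("bath_seed"),
        "lipid_seed": structure.metadata.get("lipid_seed"),
        "constriction_residue": structure.metadata.get("constriction_residue"),
        "pore_constriction_radius": structure.metadata.get(
            "pore_constriction_radius"),
    }
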