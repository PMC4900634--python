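"""Structure/trajectory data model and PDB/XYZ/CSV input-output.

The :class:`Structure` is a flat atom table (names, residue labels,
monomer index, Cartesian coordinates in Å, partial charge in e, van der
Waals radius in Å).  Residue numbering across monomers follows the
concatenated convention: residue ``r`` of monomer ``m`` carries the number
``r + offset·m`` (offset 136 by default), so the lysine ring residue 106
appears as 106/242/378/514/650 in a pentamer.

PDB files are read and written through :mod:`biotite`; charges and radii,
which PDB cannot carry, come from a lookup table and/or a sidecar CSV.
Trajectories are multi-model PDB or plain XYZ (the XYZ comment line may
carry ``t=<ps>``).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from .selection import Selection, SelectionError, select  # noqa: F401  (re-export)

__all__ = [
    "Structure",
    "Trajectory",
    "Selection",
    "SelectionError",
    "StructureParseError",
    "select",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_xyz",
    "read_charges_csv",
    "write_charges_csv",
    "write_series_csv",
    "write_profile_csv",
    "concat_structures",
    "DEFAULT_ELEMENT_RADII",
]


class StructureParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


#: Fallback van der Waals radii by element (Å); a per-(resname, atom name)
#: lookup table and the sidecar CSV both override these.
DEFAULT_ELEMENT_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "K": 1.76,
    "CL": 1.81,
}
_FALLBACK_RADIUS = 1.70


@dataclass
class Structure:
    """Ordered, indexable atom table with coordinates, charges and radii."""

    atom_name: np.ndarray
    residue_name: np.ndarray
    residue_number: np.ndarray
    monomer_index: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    charge: np.ndarray
    vdw_radius: np.ndarray
    numbering_offset: int = 136
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atom_name)
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.residue_name = np.asarray(self.residue_name, dtype="U6")
        self.residue_number = np.asarray(self.residue_number, dtype=np.int64)
        self.monomer_index = np.asarray(self.monomer_index, dtype=np.int64)
        self.element = np.asarray(self.element, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(n, 3)
        self.charge = np.asarray(self.charge, dtype=np.float64)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=np.float64)
        for arr in (self.residue_name, self.residue_number, self.monomer_index,
                    self.element, self.charge, self.vdw_radius):
            if len(arr) != n:
                raise ValueError("atom table columns have inconsistent lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.vdw_radius < 0):
            raise ValueError("negative van der Waals radius")
        if np.any(self.monomer_index < -1):
            raise ValueError("monomer_index must be >= -1")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def copy(self) -> "Structure":
        return Structure(
            atom_name=self.atom_name.copy(),
            residue_name=self.residue_name.copy(),
            residue_number=self.residue_number.copy(),
            monomer_index=self.monomer_index.copy(),
            element=self.element.copy(),
            coords=self.coords.copy(),
            charge=self.charge.copy(),
            vdw_radius=self.vdw_radius.copy(),
            numbering_offset=self.numbering_offset,
            metadata=dict(self.metadata),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=np.float64).reshape(self.n_atoms, 3)
        return out

    def select(self, expression: str) -> Selection:
        return select(self, expression)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "atom_name": self.atom_name,
            "residue_name": self.residue_name,
            "residue_number": self.residue_number,
            "monomer_index": self.monomer_index,
            "element": self.element,
            "x_A": self.coords[:, 0],
            "y_A": self.coords[:, 1],
            "z_A": self.coords[:, 2],
            "charge_e": self.charge,
            "vdw_radius_A": self.vdw_radius,
        })


@dataclass
class Trajectory:
    """Coordinate frames over a fixed atom table.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``times`` are in ps
    and strictly increasing; ``box`` is an optional orthorhombic box.
    """

    structure: Structure
    frames: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.structure.n_atoms}"
            )
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.structure.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _validate_pdb_lines(lines: list[str]) -> None:
    """Pre-flight check of coordinate records; errors name the 1-based line."""
    serials: set[str] = set()
    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            serials.clear()  # serials restart per model
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise StructureParseError(
                f"line {ln}: truncated coordinate record"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi]
            try:
                float(fld)
            except ValueError:
                raise StructureParseError(
                    f"line {ln}: malformed {what} coordinate field {fld!r}"
                ) from None
        serial = line[6:11].strip()
        if serial:
            if serial in serials:
                warnings.warn(
                    f"duplicate atom serial {serial} at line {ln}; keeping both",
                    stacklevel=3,
                )
            serials.add(serial)


def _structure_from_atom_array(
    arr,
    lookup: dict | None,
    numbering_offset: int,
) -> Structure:
    chain_ids = arr.chain_id
    hetero = arr.hetero
    monomer = np.full(arr.array_length(), -1, dtype=np.int64)
    order: dict[str, int] = {}
    for i in range(arr.array_length()):
        if hetero[i]:
            continue
        cid = chain_ids[i]
        if cid not in order:
            order[cid] = len(order)
        monomer[i] = order[cid]
    element = np.char.upper(arr.element.astype(str))
    charge = np.zeros(arr.array_length())
    radius = np.empty(arr.array_length())
    lookup = lookup or {}
    for i in range(arr.array_length()):
        key = (str(arr.res_name[i]).strip(), str(arr.atom_name[i]).strip())
        if key in lookup:
            charge[i], radius[i] = lookup[key]
        elif key[1] in lookup:
            charge[i], radius[i] = lookup[key[1]]
        else:
            radius[i] = DEFAULT_ELEMENT_RADII.get(element[i], _FALLBACK_RADIUS)
    return Structure(
        atom_name=arr.atom_name.astype("U6"),
        residue_name=arr.res_name.astype("U6"),
        residue_number=arr.res_id.astype(np.int64),
        monomer_index=monomer,
        element=element,
        coords=np.asarray(arr.coord, dtype=np.float64),
        charge=charge,
        vdw_radius=radius,
        numbering_offset=numbering_offset,
    )


def read_pdb(
    path,
    lookup: dict | None = None,
    sidecar: str | Path | None = None,
    numbering_offset: int = 136,
) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`.

    Chain IDs map to ``monomer_index`` in order of first appearance
    (HETATM records get −1).  ``lookup`` maps ``(resname, atom_name)`` or
    ``atom_name`` to ``(charge, vdw_radius)``; ``sidecar`` is a CSV written
    by :func:`write_charges_csv` applied on top, by atom order.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    _validate_pdb_lines(lines)
    n_models = sum(1 for line in lines if line.startswith("MODEL"))
    if n_models > 1:
        raise StructureParseError(
            f"{n_models} MODEL records; use read_trajectory for multi-model files"
        )
    try:
        pdb = PDBFile.read(io.StringIO(text))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - caught by pre-flight normally
        raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc
    st = _structure_from_atom_array(arr, lookup, numbering_offset)
    if sidecar is not None:
        apply_charges_csv(st, sidecar)
    return st


def write_pdb(structure: Structure, path) -> None:
    """Write a :class:`Structure` as PDB (charges/radii go to a sidecar CSV)."""
    n = structure.n_atoms
    arr = AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.atom_name = structure.atom_name
    arr.res_name = structure.residue_name
    arr.res_id = structure.residue_number
    arr.element = structure.element
    chain = np.where(
        structure.monomer_index >= 0,
        np.array([chr(ord("A") + int(m) % 26) if m >= 0 else "X"
                  for m in structure.monomer_index]),
        "X",
    )
    arr.chain_id = chain.astype("U4")
    arr.hetero = structure.monomer_index < 0
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Trajectories (multi-model PDB, XYZ)
# ---------------------------------------------------------------------------

def _read_xyz_frames(path):
    frames, times, symbols = [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    k = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        k += 1
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise StructureParseError(
                f"frame {k}: bad atom count line {lines[pos]!r}"
            ) from None
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t = None
        for tok in comment.split():
            if tok.startswith("t="):
                try:
                    t = float(tok[2:])
                except ValueError:
                    pass
        block = lines[pos + 2: pos + 2 + count]
        if len(block) < count:
            raise StructureParseError(f"frame {k}: truncated (expected {count} atoms)")
        coords = np.empty((count, 3))
        syms = []
        for i, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise StructureParseError(f"frame {k}: malformed atom line {line!r}")
            syms.append(parts[0])
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        times.append(t)
        symbols = syms
        pos += 2 + count
    if not frames:
        raise StructureParseError("no frames found in XYZ file")
    if any(t is None for t in times):
        times = list(range(len(frames)))
    return frames, np.array(times, dtype=float), symbols


def read_trajectory(path, topology: Structure, fmt: str | None = None) -> Trajectory:
    """Read a trajectory (multi-model PDB or XYZ) over ``topology``.

    Every frame must have the topology's atom count; a mismatch errors
    naming the offending frame.  XYZ comment lines may carry ``t=<ps>``,
    otherwise times default to 0, 1, 2, ... ps.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "xyz":
        frames, times, _ = _read_xyz_frames(path)
        for k, fr in enumerate(frames, start=1):
            if fr.shape[0] != topology.n_atoms:
                raise StructureParseError(
                    f"frame {k}: atom count {fr.shape[0]} does not match "
                    f"topology ({topology.n_atoms})"
                )
        return Trajectory(structure=topology, frames=np.array(frames),
                          times=times)
    # multi-model PDB: count atoms per MODEL block manually so that errors
    # can name the frame, then let biotite parse the coordinates
    lines = path.read_text().splitlines()
    _validate_pdb_lines(lines)
    counts, current, in_model = [], 0, False
    for line in lines:
        if line.startswith("MODEL"):
            in_model = True
            current = 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line[:6].strip() in ("ATOM", "HETATM") and in_model:
            current += 1
    if not counts:  # single implicit model
        counts = [sum(1 for line in lines if line[:6].strip() in ("ATOM", "HETATM"))]
    for k, c in enumerate(counts, start=1):
        if c != topology.n_atoms:
            raise StructureParseError(
                f"frame {k}: atom count {c} does not match topology "
                f"({topology.n_atoms})"
            )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    coords = np.asarray(stack.coord, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(structure=topology, frames=coords, times=times)


def write_xyz(trajectory: Trajectory, path) -> None:
    """Write a trajectory as plain XYZ with ``t=<ps>`` comment lines."""
    st = trajectory.structure
    with open(path, "w") as fh:
        for fr, t in zip(trajectory.frames, trajectory.times):
            fh.write(f"{st.n_atoms}\n")
            fh.write(f"t={t:.6g} ps\n")
            for name, (x, y, z) in zip(st.element, fr):
                fh.write(f"{name or 'X'} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Sidecar charge/radius CSV
# ---------------------------------------------------------------------------

def write_charges_csv(structure: Structure, path) -> None:
    df = pd.DataFrame({
        "atom_index": np.arange(structure.n_atoms),
        "atom_name": structure.atom_name,
        "charge_e": structure.charge,
        "vdw_radius_A": structure.vdw_radius,
    })
    df.to_csv(path, index=False, float_format="%.6g")


def read_charges_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def apply_charges_csv(structure: Structure, path) -> Structure:
    """Apply a sidecar CSV (by atom order) onto ``structure`` in place."""
    df = read_charges_csv(path)
    if len(df) != structure.n_atoms:
        raise ValueError(
            f"sidecar has {len(df)} rows for {structure.n_atoms} atoms"
        )
    structure.charge[:] = df["charge_e"].to_numpy(dtype=float)
    structure.vdw_radius[:] = df["vdw_radius_A"].to_numpy(dtype=float)
    return structure


# ---------------------------------------------------------------------------
# CSV outputs for series and profiles
# ---------------------------------------------------------------------------

def _as_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if hasattr(obj, "to_frame"):
        return obj.to_frame()
    raise TypeError(f"cannot convert {type(obj).__name__} to a table")


def write_series_csv(series, path) -> None:
    """Write a time series (first column ``time_ps``) at 6 significant digits."""
    df = _as_frame(series)
    if len(df) == 0:
        raise ValueError("empty series")
    df.to_csv(path, index=False, float_format="%.6g")


def write_profile_csv(profile, path) -> None:
    """Write a (z, radius) profile at 6 significant digits."""
    df = _as_frame(profile)
    if len(df) == 0:
        raise ValueError("empty profile")
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Structure concatenation (builder plumbing)
# ---------------------------------------------------------------------------

def concat_structures(a: Structure, b: Structure) -> Structure:
    if a.numbering_offset != b.numbering_offset:
        raise ValueError("numbering offsets differ")
    meta = dict(a.metadata)
    meta.update(b.metadata)
    return Structure(
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        residue_name=np.concatenate([a.residue_name, b.residue_name]),
        residue_number=np.concatenate([a.residue_number, b.residue_number]),
        monomer_index=np.concatenate([a.monomer_index, b.monomer_index]),
        element=np.concatenate([a.element, b.element]),
        coords=np.vstack([a.coords, b.coords]),
        charge=np.concatenate([a.charge, b.charge]),
        vdw_radius=np.concatenate([a.vdw_radius, b.vdw_radius]),
        numbering_offset=a.numbering_offset,
        metadata=meta,
    )
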