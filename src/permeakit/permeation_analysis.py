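"""Trajectory statistics for channel permeation.

* ΔZ — the permeation coordinate: Z difference between the geometric
  centers of the ligand and of the reference lysine ring (one residue per
  monomer); ΔZ ≥ 0 when the ligand is on or above the ring plane.
* Crossing detection with hysteresis: a downward passage is recorded when
  the series, having most recently been at or above the upper threshold,
  first reaches the lower one; upward passages are symmetric.
* Stage segmentation: frames labeled by ΔZ band, short runs merged into
  the longer neighbor, per-stage dwell/mean-ΔZ/mean-energy reported.
* Ion displacement along Z (endpoint difference by default; negative means
  toward the cytoplasmic exit side, −Z).
* Lipid contact numbers: hydrophobic lipid residues whose geometric center
  lies within an inclusive distance threshold (6.5 Å default) of a target
  residue's geometric center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Selection, Structure, Trajectory, select

__all__ = [
    "DeltaZSeries",
    "ContactSeries",
    "geometric_center",
    "delta_z",
    "detect_crossings",
    "segment_stages",
    "ion_displacement",
    "contact_number",
    "lipid_residue_groups",
    "target_residue_groups",
]

HYDROPHOBIC_LIPID_RESNAMES = frozenset({"PA", "OL"})

_ONE_LETTER = {"ALA": "A", "ASN": "N", "LYS": "K", "LEU": "L", "ILE": "I",
               "GLY": "G", "ASP": "D", "GLU": "E", "VAL": "V", "PHE": "F"}


@dataclass
class DeltaZSeries:
    times: np.ndarray
    values: np.ndarray
    ligand_expression: str = ""
    reference_expression: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite ΔZ values")

    def __len__(self):
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "delta_z_A": self.values})


@dataclass
class ContactSeries:
    times: np.ndarray
    counts: pd.DataFrame      # one integer column per target
    averages: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "time_ps", self.times)
        return out


def geometric_center(coords) -> np.ndarray:
    """Unweighted componentwise mean of n ≥ 1 points."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.size == 0:
        raise ValueError("geometric center of zero points is undefined")
    return coords.reshape(-1, 3).mean(axis=0)


def _resolve(traj_or_structure, sel) -> np.ndarray:
    st = (traj_or_structure.structure
          if isinstance(traj_or_structure, Trajectory) else traj_or_structure)
    if isinstance(sel, Selection):
        return sel.indices
    if isinstance(sel, str):
        return select(st, sel).indices
    return np.asarray(sel, dtype=np.int64)


def delta_z(trajectory: Trajectory, ligand_sel, reference_sel) -> DeltaZSeries:
    """Per-frame ΔZ = z(gc(ligand)) − z(gc(reference ring))."""
    lig = _resolve(trajectory, ligand_sel)
    ref = _resolve(trajectory, reference_sel)
    if lig.size == 0:
        raise ValueError("empty ligand selection")
    if ref.size == 0:
        raise ValueError("empty reference selection")
    vals = (trajectory.frames[:, lig, 2].mean(axis=1)
            - trajectory.frames[:, ref, 2].mean(axis=1))
    return DeltaZSeries(
        times=trajectory.times, values=vals,
        ligand_expression=getattr(ligand_sel, "expression", str(ligand_sel)),
        reference_expression=getattr(reference_sel, "expression",
                                     str(reference_sel)),
    )


def detect_crossings(series: DeltaZSeries, z_upper: float, z_lower: float):
    """Hysteresis crossing events.

    Returns a time-ordered list of ``{"t_start", "t_end", "direction"}``
    dicts.  ``t_start`` is the last sample in the origin zone, ``t_end``
    the first sample in the destination zone.
    """
    if z_upper <= z_lower:
        raise ValueError("z_upper must exceed z_lower")
    if len(series) < 2:
        raise ValueError("series must have at least 2 samples")
    t, v = series.times, series.values
    events = []
    state = None          # 'upper' | 'lower'
    last_idx = -1         # last sample in the current zone
    for i in range(len(v)):
        if v[i] >= z_upper:
            if state == "lower":
                events.append({"t_start": float(t[last_idx]),
                               "t_end": float(t[i]), "direction": "up"})
            if state != "upper":
                state = "upper"
            last_idx = i
        elif v[i] <= z_lower:
            if state == "upper":
                events.append({"t_start": float(t[last_idx]),
                               "t_end": float(t[i]), "direction": "down"})
            if state != "lower":
                state = "lower"
            last_idx = i
        # in the dead band: state and last_idx unchanged
    return events


def _run_length_encode(labels: np.ndarray):
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([int(labels[start]), start, i - 1])  # label, i0, i1
            start = i
    return runs


def segment_stages(series: DeltaZSeries, energies=None, *,
                   bands, min_dwell: float = 0.0):
    """ΔZ-band dwell segmentation.

    ``bands`` are strictly decreasing ΔZ break values; frames at or above
    the first break get band 0, below the last break band ``len(bands)``.
    Contiguous runs shorter than ``min_dwell`` (ps) are merged into the
    longer neighbor (ties: the earlier one), deterministically.  Stages are
    half-open intervals [t_start, t_end) whose union covers the analyzed
    window; dwell = t_end − t_start.
    """
    bands = np.asarray(bands, dtype=float)
    if bands.size == 0:
        raise ValueError("empty band set")
    if bands.size > 1 and not np.all(np.diff(bands) < 0):
        raise ValueError("bands must be strictly decreasing")
    if min_dwell < 0:
        raise ValueError("min_dwell must be >= 0")
    t, v = series.times, series.values
    if len(v) == 0:
        raise ValueError("empty series")
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    labels = np.sum(v[:, None] < bands[None, :], axis=1)
    runs = _run_length_encode(labels)

    def dwell(run):
        return (run[2] - run[1] + 1) * dt

    while len(runs) > 1:
        short = [k for k, r in enumerate(runs) if dwell(r) < min_dwell]
        if not short:
            break
        k = min(short, key=lambda k: (dwell(runs[k]), k))
        if k == 0:
            nb = 1
        elif k == len(runs) - 1:
            nb = k - 1
        else:
            nb = k - 1 if dwell(runs[k - 1]) >= dwell(runs[k + 1]) else k + 1
        runs[k][0] = runs[nb][0]
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0] and merged[-1][2] + 1 == r[1]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged

    e = None if energies is None else np.asarray(energies, dtype=float)
    stages = []
    for label, i0, i1 in runs:
        stage = {
            "label": int(label),
            "t_start": float(t[i0]),
            "t_end": float(t[i1] + dt),
            "dwell_ps": float((i1 - i0 + 1) * dt),
            "mean_delta_z": float(v[i0:i1 + 1].mean()),
        }
        if e is not None:
            stage["mean_energy"] = float(e[i0:i1 + 1].mean())
        stages.append(stage)
    return stages


def ion_displacement(trajectory: Trajectory, ion_sel, window=None,
                     mode: str = "endpoint"):
    """Per-ion ΔZ over a frame window plus the mean over ions.

    ``mode='endpoint'`` (default): z(last) − z(first).  ``mode='mean'``:
    mean-over-window minus initial.  Negative values point toward −Z, the
    cytoplasmic exit side under the build convention.
    """
    ions = _resolve(trajectory, ion_sel)
    if ions.size == 0:
        raise ValueError("empty ion selection")
    i0, i1 = (0, trajectory.n_frames - 1) if window is None else window
    if not (0 <= i0 <= i1 < trajectory.n_frames):
        raise ValueError(f"window ({i0}, {i1}) outside trajectory")
    z = trajectory.frames[:, ions, 2]
    if mode == "endpoint":
        per_ion = z[i1] - z[i0]
    elif mode == "mean":
        per_ion = z[i0:i1 + 1].mean(axis=0) - z[i0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"per_ion": per_ion, "mean": float(per_ion.mean()), "mode": mode}


def lipid_residue_groups(structure: Structure):
    """(resname, atom indices) per lipid residue (PA/PC/OL surrogates)."""
    groups = []
    mask = (structure.monomer_index < 0) & np.isin(
        structure.residue_name, ["PA", "PC", "OL"])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return groups
    key = list(zip(structure.residue_name[idx], structure.residue_number[idx]))
    start = 0
    for i in range(1, len(idx) + 1):
        if i == len(idx) or key[i] != key[start]:
            groups.append((str(key[start][0]), idx[start:i]))
            start = i
    return groups


def target_residue_groups(structure: Structure, resnum: int):
    """Per-monomer atom groups for a monomer-local residue number.

    Labels carry the concatenated residue number ("N103", "N239", ...).
    """
    out = {}
    off = structure.numbering_offset
    for m in sorted(set(structure.monomer_index[structure.monomer_index >= 0])):
        glob = resnum + off * int(m)
        idx = np.flatnonzero((structure.monomer_index == m)
                             & (structure.residue_number == glob))
        if idx.size:
            rn3 = str(structure.residue_name[idx[0]])
            rn = _ONE_LETTER.get(rn3, rn3[:1])
            out[f"{rn}{glob}"] = idx
    return out


def contact_number(trajectory: Trajectory, targets: dict, lipid_residues,
                   threshold: float = 6.5,
                   hydrophobic=HYDROPHOBIC_LIPID_RESNAMES) -> ContactSeries:
    """Hydrophobic lipid residues within ``threshold`` (inclusive) of each
    target residue's geometric center, per frame, plus averages."""
    hydro = [(rn, idx) for rn, idx in lipid_residues if rn in hydrophobic]
    if not hydro:
        raise ValueError("no hydrophobic lipid residues flagged")
    if not targets:
        raise ValueError("no target residues")
    nf = trajectory.n_frames
    labels = list(targets)
    counts = np.zeros((nf, len(labels)), dtype=np.int64)
    lip_idx = [idx for _, idx in hydro]
    for f in range(nf):
        x = trajectory.frames[f]
        lip_centers = np.array([x[idx].mean(axis=0) for idx in lip_idx])
        for j, lab in enumerate(labels):
            c = x[targets[lab]].mean(axis=0)
            d = np.linalg.norm(lip_centers - c, axis=1)
            counts[f, j] = int(np.sum(d <= threshold))
    df = pd.DataFrame(counts, columns=labels)
    return ContactSeries(times=trajectory.times.copy(), counts=df,
                         averages=df.mean())
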