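"""Superposition, RMSD conventions, helix rotation, and pore profiling.

* :func:`kabsch_fit` — weighted least-squares rigid superposition with the
  reflection corrected to a proper rotation.
* :func:`rmsd_two_selection` — fit on one atom set, measure the RMSD of
  another without re-fitting (the protocol used to track how individual
  secondary-structure domains move once global rigid motion is removed).
* :func:`axis_angle` — rotation matrix → (axis, angle in [0°, 180°]) with
  stable branches near 0° and 180°; the axis sign is fixed by making its
  largest-magnitude component positive.
* :func:`helix_rotation` — per-helix direct fit against a reference
  conformation, reporting the corkscrew angle and its handedness as the
  sign of axis·ẑ (with +Z periplasmic, a negative sign is clockwise as
  seen from the periplasm).
* :func:`pore_profile` — largest-sphere pore radius along Z, HOLE-style
  but with the probe center confined to each slice plane; local minima
  are bottlenecks.
* :func:`membrane_thickness` — mean marker-plane separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io_core import Structure, Trajectory
from .permeation_analysis import _resolve

__all__ = [
    "RigidTransform",
    "AxisAngle",
    "PoreProfile",
    "kabsch_fit",
    "rmsd_two_selection",
    "axis_angle",
    "rotation_about_axis",
    "helix_rotation",
    "pore_profile",
    "membrane_thickness",
]


@dataclass
class RigidTransform:
    rotation: np.ndarray     # 3×3 proper orthogonal
    translation: np.ndarray  # Å

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.max(np.abs(self.rotation.T @ self.rotation - np.eye(3))) > 1e-8:
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class AxisAngle:
    axis: np.ndarray
    angle_deg: float

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.axis)
        if abs(norm - 1.0) > 1e-8:
            raise ValueError("axis must be a unit vector")
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("angle must lie in [0, 180] degrees")


@dataclass
class PoreProfile:
    z: np.ndarray
    radii: np.ndarray
    bottlenecks: list = field(default_factory=list)  # (z, radius) pairs
    capped: np.ndarray | None = None
    centers: np.ndarray | None = None  # probe XY center per slice

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z, "radius_A": self.radii})


def kabsch_fit(mobile, reference, weights=None) -> RigidTransform:
    """Least-squares rigid transform taking ``mobile`` onto ``reference``.

    Minimizes the weighted squared deviation; the reflection branch of the
    SVD solution is corrected so the rotation is always proper.  Requires
    n ≥ 3 non-collinear points.
    """
    mob = np.asarray(mobile, dtype=np.float64).reshape(-1, 3)
    ref = np.asarray(reference, dtype=np.float64).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise ValueError("mobile/reference point count mismatch")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("kabsch_fit needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("invalid weights")
    w = w / w.sum()
    cm = np.sum(w[:, None] * mob, axis=0)
    cr = np.sum(w[:, None] * ref, axis=0)
    a = mob - cm
    b = ref - cr
    h = (w[:, None] * a).T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=cr - rot @ cm)


def rmsd_two_selection(traj_or_coords, reference: Structure, fit_sel,
                       measure_sel):
    """Fit on ``fit_sel`` only, then RMSD over ``measure_sel`` without
    re-fitting.  Accepts a Trajectory (per-frame array returned), a
    Structure, or a bare coordinate array."""
    fit_idx = _resolve(reference, fit_sel)
    meas_idx = _resolve(reference, measure_sel)
    if fit_idx.size < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    if meas_idx.size == 0:
        raise ValueError("empty measure selection")

    def one(coords):
        if coords.shape[0] != reference.n_atoms:
            raise ValueError("frame/reference atom count mismatch")
        tf = kabsch_fit(coords[fit_idx], reference.coords[fit_idx])
        moved = tf.apply(coords[meas_idx])
        d2 = np.sum((moved - reference.coords[meas_idx]) ** 2, axis=1)
        return float(np.sqrt(d2.mean()))

    if isinstance(traj_or_coords, Trajectory):
        return np.array([one(fr) for fr in traj_or_coords.frames])
    if isinstance(traj_or_coords, Structure):
        return one(traj_or_coords.coords)
    return one(np.asarray(traj_or_coords, dtype=float))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    a = np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def axis_angle(rotation, tol: float = 1e-6) -> AxisAngle:
    """Axis-angle decomposition of a proper rotation matrix.

    Angle in [0°, 180°]; the axis comes from the antisymmetric part away
    from the branch points and from the symmetric part near 180°.  The
    axis sign convention makes the largest-magnitude component positive;
    the identity reports (0, 0, 1) by convention.
    """
    R = np.asarray(rotation, dtype=np.float64).reshape(3, 3)
    if np.max(np.abs(R.T @ R - np.eye(3))) > tol or abs(np.linalg.det(R) - 1) > tol:
        raise ValueError("input is not a proper orthogonal matrix")
    cos_t = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_t))
    if angle < 1e-9:
        return AxisAngle(axis=np.array([0.0, 0.0, 1.0]), angle_deg=float(angle))
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if angle < 179.0:
        axis = w / (2.0 * np.sin(np.deg2rad(angle)))
    else:
        # near 180° the antisymmetric part vanishes; the symmetrized matrix
        # (R + Rᵀ)/2 = cosθ·I + (1−cosθ)·nnᵀ yields the axis exactly
        S = (R + R.T) / 2.0
        N = (S - cos_t * np.eye(3)) / (1.0 - cos_t)
        axis = N[:, int(np.argmax(np.diag(N)))]
    axis = axis / np.linalg.norm(axis)
    imax = int(np.argmax(np.abs(axis)))
    if axis[imax] < 0:
        axis = -axis
    return AxisAngle(axis=axis, angle_deg=float(angle))


def helix_rotation(conformation: Structure, reference: Structure,
                   helix_selections: dict) -> dict:
    """Per-helix Kabsch fit of the conformation onto the reference and
    axis-angle of the fitted rotation.

    No global pre-alignment is performed (a ``global_prefit`` flag adds
    one).  Each result records the angle, axis, the sign of axis·ẑ, and
    whether the rotation is clockwise as seen from the periplasm (+Z).
    """
    out = {}
    for name, sel in helix_selections.items():
        ic = _resolve(conformation, sel)
        ir = _resolve(reference, sel)
        if ic.size != ir.size or ic.size < 3:
            raise ValueError(f"helix {name!r}: selection mismatch or too small")
        # the rotation carrying the reference helix onto the conformation:
        # "how far has this helix turned since the reference state"
        tf = kabsch_fit(reference.coords[ir], conformation.coords[ic])
        aa = axis_angle(tf.rotation)
        # handedness from the raw antisymmetric part (∝ sinθ·n_z), which the
        # canonical axis sign convention would otherwise erase
        wz = tf.rotation[1, 0] - tf.rotation[0, 1]
        significant = aa.angle_deg > 1e-9 and abs(wz) > 1e-12
        out[name] = {
            "axis_angle": aa,
            "angle_deg": aa.angle_deg,
            "axis": aa.axis,
            "axis_z_sign": float(np.sign(wz)) if significant else 0.0,
            "clockwise_from_periplasm": bool(significant and wz < 0),
        }
    return out


def helix_rotation_global_prefit(conformation, reference, helix_selections,
                                 fit_sel="name CA") -> dict:
    """Variant that removes global rigid motion (fit on ``fit_sel``) before
    the per-helix fits."""
    idx = _resolve(reference, fit_sel)
    tf = kabsch_fit(conformation.coords[idx], reference.coords[idx])
    conf2 = conformation.with_coords(tf.apply(conformation.coords))
    return helix_rotation(conf2, reference, helix_selections)


def _slice_objective(structure, indices):
    x = structure.coords[indices]
    r = structure.vdw_radius[indices]

    def f(cx, cy, z):
        d = np.sqrt((x[:, 0] - cx) ** 2 + (x[:, 1] - cy) ** 2
                    + (x[:, 2] - z) ** 2) - r
        return float(d.min())

    return f


def pore_profile(structure: Structure, z_range, step: float = 1.0,
                 r_max: float = 15.0, selection=None,
                 bottleneck_max_radius: float | None = None) -> PoreProfile:
    """Pore radius profile along Z.

    At each z sample the radius is the largest clearance
    ``min_i(‖c − x_i‖ − r_i)`` over probe centers c in the slice plane,
    found by local Nelder-Mead simplex ascent from a deterministic pair of
    seeds — the channel axis and the previous slice's optimal center — so
    the probe follows the pore instead of escaping through the open bulk
    (the channel-following behavior of pore-profiling tools); capped at
    ``r_max``.  Bottlenecks are strict local minima of the sampled profile
    (leftmost sample of a flat minimum) below ``bottleneck_max_radius``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    idx = (np.arange(structure.n_atoms) if selection is None
           else _resolve(structure, selection))
    z0, z1 = z_range
    zs = np.arange(z0, z1 + 0.5 * step, step)
    radii = np.empty_like(zs)
    capped = np.zeros(zs.size, dtype=bool)
    centers = np.zeros((zs.size, 2))
    if idx.size == 0:
        radii[:] = r_max
        capped[:] = True
        return PoreProfile(z=zs, radii=radii, bottlenecks=[], capped=capped)
    f = _slice_objective(structure, idx)

    prev_center = None
    for i, z in enumerate(zs):
        def neg(c, z=z):
            val = f(c[0], c[1], z)
            # soft wall keeps the probe in the channel when a slice is open
            excess = np.hypot(c[0], c[1]) - r_max
            if excess > 0:
                val -= 10.0 * excess
            return -val

        starts = [np.zeros(2)]
        if prev_center is not None:
            starts.append(prev_center)
        best, best_c = -np.inf, np.zeros(2)
        for s in starts:
            simplex = np.array([s, s + [0.3, 0.0], s + [0.0, 0.3]])
            res = minimize(neg, s, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxiter": 400,
                                    "initial_simplex": simplex})
            if -res.fun > best:
                best, best_c = -res.fun, res.x
        prev_center = best_c
        centers[i] = best_c
        if best >= r_max:
            radii[i] = r_max
            capped[i] = True
        else:
            radii[i] = max(best, 0.0)

    cutoff = r_max if bottleneck_max_radius is None else bottleneck_max_radius
    bottlenecks = []
    i = 1
    while i < zs.size - 1:
        if radii[i] == radii[i - 1]:
            i += 1
            continue
        # find plateau [i, j] of equal values
        j = i
        while j + 1 < zs.size and radii[j + 1] == radii[i]:
            j += 1
        if j >= zs.size - 1:
            break
        if radii[i] < radii[i - 1] and radii[i] < radii[j + 1] \
                and radii[i] <= cutoff and not capped[i]:
            bottlenecks.append((float(zs[i]), float(radii[i])))
        i = j + 1
    return PoreProfile(z=zs, radii=radii, bottlenecks=bottlenecks,
                       capped=capped, centers=centers)


def membrane_thickness(structure: Structure, upper_marker_sel,
                       lower_marker_sel) -> float:
    """Mean z of the upper markers minus mean z of the lower markers."""
    up = _resolve(structure, upper_marker_sel)
    lo = _resolve(structure, lower_marker_sel)
    if up.size == 0 or lo.size == 0:
        raise ValueError("empty marker selection")
    return float(structure.coords[up, 2].mean() - structure.coords[lo, 2].mean())
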