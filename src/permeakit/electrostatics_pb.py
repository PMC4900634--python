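"""Implicit-membrane finite-difference Poisson solver and MM-PB totals.

The solvation model is the three-dielectric slab geometry used for
membrane proteins: solute interior ε_in = 1, a membrane slab of ε_m = 4
and default thickness 18 Å, and ε_w = 80 water everywhere else.  Because
the solute's geometric center need not coincide with the membrane center,
a per-conformation Z offset (the ``mctrdz`` convention) shifts the slab to
the membrane midplane.

The solver is a 7-point finite-difference stencil with harmonic-mean edge
dielectrics, Dirichlet boundary from an analytic Coulomb sum, and
diagonally preconditioned conjugate-gradient iteration.  The polar
solvation energy uses the standard two-solve reaction-field definition

    E_PB = ½ Σ_i q_i (φ_env(r_i) − φ_ref(r_i))

where φ_env uses the slab dielectric map and φ_ref a uniform ε_in, so the
grid self-energy cancels in the difference.  Zero ionic strength (pure
Poisson) by default.  The total MM-PB energy is E_MM + E_PB with no
surface-area term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .constants import COULOMB_KCAL
from .io_core import Structure
from .permeation_analysis import _resolve, geometric_center

__all__ = [
    "SlabDielectricSpec",
    "GridSpec",
    "PBGrid",
    "compute_mctrdz",
    "build_dielectric_map",
    "solve_poisson",
    "pb_energy",
    "mm_pb_total",
]


@dataclass
class SlabDielectricSpec:
    eps_water: float = 80.0
    eps_membrane: float = 4.0
    eps_solute: float = 1.0
    thickness: float = 18.0
    z_offset: float = 0.0     # mctrdz: shifts the slab to the membrane center

    def __post_init__(self):
        if min(self.eps_water, self.eps_membrane, self.eps_solute) <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class GridSpec:
    spacing: float = 0.5
    buffer: float = 10.0

    def __post_init__(self):
        if self.spacing <= 0 or self.buffer <= 0:
            raise ValueError("spacing and buffer must be positive")


@dataclass
class PBGrid:
    origin: np.ndarray
    spacing: float
    shape: tuple
    eps: np.ndarray              # per-node dielectric
    charge: np.ndarray           # e, trilinearly spread
    positions: np.ndarray        # point charges used for the boundary sum
    charges: np.ndarray
    potential: np.ndarray | None = None

    def node_z(self):
        return self.origin[2] + self.spacing * np.arange(self.shape[2])


def compute_mctrdz(structure: Structure, membrane_marker_sel,
                   solute_sel=None) -> float:
    """Z offset from the solute's geometric center to the membrane center.

    Defined as z(gc(membrane markers)) − z(gc(solute)); shifting the slab
    by this amount centers it on the membrane for each conformation.
    """
    mk = _resolve(structure, membrane_marker_sel)
    if mk.size == 0:
        raise ValueError("empty membrane marker selection")
    if solute_sel is None:
        sol = np.flatnonzero((structure.monomer_index >= 0)
                             | (structure.residue_name == "LIG"))
        if sol.size == 0:
            sol = np.arange(structure.n_atoms)
    else:
        sol = _resolve(structure, solute_sel)
    return float(geometric_center(structure.coords[mk])[2]
                 - geometric_center(structure.coords[sol])[2])


def _grid_bounds(coords, radii, grid: GridSpec, center_on=None):
    lo = (coords - radii[:, None]).min(axis=0) - grid.buffer
    hi = (coords + radii[:, None]).max(axis=0) + grid.buffer
    h = grid.spacing
    center = coords.mean(axis=0) if center_on is None else np.asarray(center_on)
    # snap the origin so the chosen center falls on a node
    lo = center - np.ceil((center - lo) / h) * h
    dims = np.ceil((hi - lo) / h).astype(int) + 1
    return lo, tuple(int(d) for d in dims)


def build_dielectric_map(structure: Structure, spec: SlabDielectricSpec,
                         grid: GridSpec, atoms=None,
                         uniform: float | None = None) -> PBGrid:
    """Dielectric map on a grid enclosing the structure plus the buffer.

    Node assignment: inside any solute sphere → ε_in; otherwise inside the
    slab (|z − slab center| ≤ thickness/2) → ε_m; otherwise ε_w.  With
    ``uniform`` set, every node gets that value (the reference solve).
    """
    idx = np.arange(structure.n_atoms) if atoms is None else np.asarray(atoms)
    coords = structure.coords[idx]
    radii = structure.vdw_radius[idx]
    charges = structure.charge[idx]
    gc = geometric_center(coords)
    origin, shape = _grid_bounds(coords, radii, grid, center_on=gc)
    h = grid.spacing
    eps = np.full(shape, spec.eps_water if uniform is None else uniform)
    if uniform is None:
        zs = origin[2] + h * np.arange(shape[2])
        slab_center = gc[2] + spec.z_offset
        in_slab = np.abs(zs - slab_center) <= spec.thickness / 2.0
        eps[:, :, in_slab] = spec.eps_membrane
        # solute spheres override, via local subgrids per atom
        for p, r in zip(coords, radii):
            if r <= 0:
                continue
            i0 = np.maximum(np.floor((p - r - origin) / h).astype(int), 0)
            i1 = np.minimum(np.ceil((p + r - origin) / h).astype(int) + 1,
                            np.array(shape))
            if np.any(i0 >= i1):
                continue
            gx = origin[0] + h * np.arange(i0[0], i1[0])
            gy = origin[1] + h * np.arange(i0[1], i1[1])
            gz = origin[2] + h * np.arange(i0[2], i1[2])
            dx2 = (gx - p[0])[:, None, None] ** 2
            dy2 = (gy - p[1])[None, :, None] ** 2
            dz2 = (gz - p[2])[None, None, :] ** 2
            inside = dx2 + dy2 + dz2 <= r * r
            sub = eps[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
            sub[inside] = spec.eps_solute
    # trilinear charge spreading
    q = np.zeros(shape)
    for p, c in zip(coords, charges):
        if c == 0.0:
            continue
        g = (p - origin) / h
        i = np.floor(g).astype(int)
        if np.any(i < 0) or np.any(i + 1 >= np.array(shape)):
            raise ValueError("charge outside grid; enlarge the buffer")
        f = g - i
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = ((f[0] if dx else 1 - f[0])
                           * (f[1] if dy else 1 - f[1])
                           * (f[2] if dz else 1 - f[2]))
                    q[i[0] + dx, i[1] + dy, i[2] + dz] += c * wgt
    return PBGrid(origin=np.asarray(origin), spacing=h, shape=shape, eps=eps,
                  charge=q, positions=coords[charges != 0],
                  charges=charges[charges != 0])


def _boundary_potential(grid: PBGrid) -> np.ndarray:
    """Analytic Coulomb potential on all nodes of the boundary shell,
    screened by the local node dielectric."""
    nx, ny, nz = grid.shape
    phi = np.zeros(grid.shape)
    if grid.charges.size == 0:
        return phi
    h = grid.spacing
    xs = grid.origin[0] + h * np.arange(nx)
    ys = grid.origin[1] + h * np.arange(ny)
    zs = grid.origin[2] + h * np.arange(nz)
    shell = np.zeros(grid.shape, dtype=bool)
    shell[0, :, :] = shell[-1, :, :] = True
    shell[:, 0, :] = shell[:, -1, :] = True
    shell[:, :, 0] = shell[:, :, -1] = True
    ii, jj, kk = np.nonzero(shell)
    pts = np.column_stack([xs[ii], ys[jj], zs[kk]])
    acc = np.zeros(len(pts))
    for p, c in zip(grid.positions, grid.charges):
        r = np.linalg.norm(pts - p, axis=1)
        acc += COULOMB_KCAL * c / np.maximum(r, 1e-6)
    phi[ii, jj, kk] = acc / grid.eps[ii, jj, kk]
    return phi


def solve_poisson(grid: PBGrid, rtol: float = 1e-8,
                  maxiter: int = 20000) -> np.ndarray:
    """Solve −∇·(ε∇φ) = 4π k_C ρ on the grid; returns φ in kcal/(mol·e).

    7-point stencil, harmonic-mean edge dielectrics, Dirichlet boundary
    from the analytic Coulomb sum, diagonal-preconditioned CG to the
    requested relative residual.  Non-convergence raises with the residual.
    """
    nx, ny, nz = grid.shape
    if min(nx, ny, nz) < 3:
        raise ValueError("grid too small")
    h = grid.spacing
    eps = grid.eps
    hx = 2.0 * eps[:-1, :, :] * eps[1:, :, :] / (eps[:-1, :, :] + eps[1:, :, :])
    hy = 2.0 * eps[:, :-1, :] * eps[:, 1:, :] / (eps[:, :-1, :] + eps[:, 1:, :])
    hz = 2.0 * eps[:, :, :-1] * eps[:, :, 1:] / (eps[:, :, :-1] + eps[:, :, 1:])

    phi = _boundary_potential(grid)
    interior = np.zeros(grid.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    lin = -np.ones(grid.shape, dtype=np.int64)
    n_unknown = int(interior.sum())
    lin[interior] = np.arange(n_unknown)

    ii, jj, kk = np.nonzero(interior)
    rows_c = lin[ii, jj, kk]
    diag = np.zeros(n_unknown)
    rhs = 4.0 * np.pi * COULOMB_KCAL * grid.charge[ii, jj, kk] / h ** 3

    rows, cols, data = [], [], []
    neighbor_info = [
        (-1, 0, 0, hx[ii - 1, jj, kk]),
        (+1, 0, 0, hx[ii, jj, kk]),
        (0, -1, 0, hy[ii, jj - 1, kk]),
        (0, +1, 0, hy[ii, jj, kk]),
        (0, 0, -1, hz[ii, jj, kk - 1]),
        (0, 0, +1, hz[ii, jj, kk]),
    ]
    for di, dj, dk, he in neighbor_info:
        coef = he / h ** 2
        diag += coef
        ni, nj, nk = ii + di, jj + dj, kk + dk
        nlin = lin[ni, nj, nk]
        inside = nlin >= 0
        rows.append(rows_c[inside])
        cols.append(nlin[inside])
        data.append(-coef[inside])
        # boundary neighbors: known Dirichlet value moves to the RHS
        out = ~inside
        if np.any(out):
            np.add.at(rhs, rows_c[out], coef[out] * phi[ni[out], nj[out], nk[out]])

    A = sparse.csr_matrix(
        (np.concatenate(data + [diag]),
         (np.concatenate(rows + [rows_c]), np.concatenate(cols + [rows_c]))),
        shape=(n_unknown, n_unknown))
    Minv = LinearOperator((n_unknown, n_unknown),
                          matvec=lambda x: x / diag)
    x, info = cg(A, rhs, rtol=rtol, atol=0.0, maxiter=maxiter, M=Minv)
    if info != 0:
        res = np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
        raise RuntimeError(
            f"Poisson solver did not converge (info={info}, residual={res:.3e})")
    phi[ii, jj, kk] = x
    grid.potential = phi
    return phi


def _interp_potential(grid: PBGrid, points: np.ndarray) -> np.ndarray:
    phi = grid.potential
    h = grid.spacing
    out = np.empty(len(points))
    for n, p in enumerate(points):
        g = (p - grid.origin) / h
        i = np.floor(g).astype(int)
        f = g - i
        val = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = ((f[0] if dx else 1 - f[0])
                           * (f[1] if dy else 1 - f[1])
                           * (f[2] if dz else 1 - f[2]))
                    val += wgt * phi[i[0] + dx, i[1] + dy, i[2] + dz]
        out[n] = val
    return out


def pb_energy(structure: Structure, spec: SlabDielectricSpec,
              grid: GridSpec | None = None, atoms=None) -> float:
    """Polar solvation energy E_PB (kcal/mol), reaction-field definition."""
    grid = grid or GridSpec()
    if not np.any(structure.charge != 0):
        return 0.0
    env = build_dielectric_map(structure, spec, grid, atoms=atoms)
    solve_poisson(env)
    ref = build_dielectric_map(structure, spec, grid, atoms=atoms,
                               uniform=spec.eps_solute)
    solve_poisson(ref)
    phi_env = _interp_potential(env, env.positions)
    phi_ref = _interp_potential(ref, ref.positions)
    return float(0.5 * np.sum(env.charges * (phi_env - phi_ref)))


def mm_pb_total(structure: Structure, forcefield, spec: SlabDielectricSpec,
                grid: GridSpec | None = None) -> dict:
    """Total MM-PB energy: E_MM + E_PB (no surface-area term)."""
    from .toy_dynamics import potential_energy

    e_mm, breakdown = potential_energy(structure, forcefield)
    e_pb = pb_energy(structure, spec, grid)
    return {"E_MM": e_mm, "E_PB": e_pb, "total": e_mm + e_pb,
            "mm_breakdown": breakdown}
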