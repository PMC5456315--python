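"""Finite-difference linearized Poisson-Boltzmann electrostatics.

Solves div(eps grad phi) - eps_out * kappa^2 * lam(r) * phi = -4 pi C rho
on a regular grid with a 7-point stencil, where phi is in kT/e, lengths
in Angstrom and charges in elementary charges.  The dielectric boundary
is the union of atom spheres (eps_in inside, eps_out outside, sampled at
face centers); ion accessibility lam is zero within atom radius + 2 A.
Charges are spread trilinearly; the Dirichlet boundary is a sum of
Debye-Hueckel monopoles.  Red-black SOR iteration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import coulomb_kt, debye_kappa
from .structure_io import Structure

__all__ = [
    "GridSpec",
    "SolverParams",
    "PotentialGrid",
    "ConvergenceError",
    "solve_lpbe",
    "analytic_reference",
    "write_dx",
    "read_dx",
]

ION_EXCLUSION = 2.0  # Angstrom added to atom radii for the Stern layer


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin (A), isotropic spacing h (A), dims (nx,ny,nz)."""

    origin: tuple[float, float, float]
    h: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(n < 2 for n in self.dims):
            raise ValueError("grid must have >= 2 points per axis")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(n) for n in self.dims))

    @classmethod
    def from_structure(cls, s: Structure, h: float = 1.0,
                       pad: float = 15.0) -> "GridSpec":
        xyz = s.coords()
        lo = xyz.min(axis=0) - pad
        hi = xyz.max(axis=0) + pad
        dims = tuple(int(math.ceil((b - a) / h)) + 1 for a, b in zip(lo, hi))
        return cls(origin=tuple(lo), h=h, dims=dims)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o, h, n = self.origin, self.h, self.dims
        return tuple(o[i] + h * np.arange(n[i]) for i in range(3))

    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.h * (np.asarray(self.dims) - 1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = np.asarray(self.origin)
        return np.all((p >= lo) & (p <= self.upper()), axis=1)

    def point_coords(self) -> np.ndarray:
        """All node coordinates, shape (nx*ny*nz, 3), C order (z fastest)."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def same_grid(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (self.dims == other.dims
                and abs(self.h - other.h) <= tol
                and all(abs(a - b) <= tol
                        for a, b in zip(self.origin, other.origin)))


@dataclass
class SolverParams:
    eps_in: float = 4.0
    eps_out: float = 78.4
    ionic_strength: float = 0.150  # mol/L
    temperature: float = 298.15
    tol: float = 1e-6
    max_iter: int = 20000
    omega: float | None = None  # SOR relaxation; auto when None
    ion_exclusion: float = ION_EXCLUSION  # Stern layer width, Angstrom

    def __post_init__(self) -> None:
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("dielectric constants must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.eps_out,
                           self.temperature)


@dataclass
class PotentialGrid:
    """Scalar electrostatic potential field in kT/e on a GridSpec."""

    spec: GridSpec
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.dims:
            raise ValueError("values shape does not match grid dims")


def _inside_mask(spec: GridSpec, centers: np.ndarray, radii: np.ndarray,
                 offset: np.ndarray) -> np.ndarray:
    """Boolean mask of staggered-grid points inside any atom sphere.

    ``offset`` shifts the sampling lattice (e.g. h/2 along one axis for
    face centers); the lattice has spec.dims minus one along shifted axes.
    """
    h = spec.h
    dims = tuple(n - 1 if offset[i] != 0 else n
                 for i, n in enumerate(spec.dims))
    origin = np.asarray(spec.origin) + offset
    mask = np.zeros(dims, dtype=bool)
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        lo_idx = np.maximum(np.ceil((c - r - origin) / h).astype(int), 0)
        hi_idx = np.minimum(np.floor((c + r - origin) / h).astype(int),
                            np.asarray(dims) - 1)
        if np.any(lo_idx > hi_idx):
            continue
        ax = [origin[i] + h * np.arange(lo_idx[i], hi_idx[i] + 1)
              for i in range(3)]
        dx2 = (ax[0] - c[0]) ** 2
        dy2 = (ax[1] - c[1]) ** 2
        dz2 = (ax[2] - c[2]) ** 2
        local = (dx2[:, None, None] + dy2[None, :, None]
                 + dz2[None, None, :]) <= r * r
        mask[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1,
             lo_idx[2]:hi_idx[2] + 1] |= local
    return mask


def _trilinear_deposit(spec: GridSpec, centers: np.ndarray,
                       charges: np.ndarray) -> np.ndarray:
    """Spread point charges onto the 8 surrounding nodes."""
    q_grid = np.zeros(spec.dims)
    o = np.asarray(spec.origin)
    for c, q in zip(centers, charges):
        if q == 0:
            continue
        f = (c - o) / spec.h
        i0 = np.floor(f).astype(int)
        i0 = np.clip(i0, 0, np.asarray(spec.dims) - 2)
        t = f - i0
        for dx in (0, 1):
            wx = t[0] if dx else 1 - t[0]
            for dy in (0, 1):
                wy = t[1] if dy else 1 - t[1]
                for dz in (0, 1):
                    wz = t[2] if dz else 1 - t[2]
                    q_grid[i0[0] + dx, i0[1] + dy, i0[2] + dz] += q * wx * wy * wz
    return q_grid


def _dh_boundary(spec: GridSpec, centers: np.ndarray, charges: np.ndarray,
                 eps_out: float, kappa: float, coul: float) -> np.ndarray:
    """Dirichlet boundary: screened-Coulomb monopole sum on the box faces."""
    phi = np.zeros(spec.dims)
    sel = charges != 0
    centers, charges = centers[sel], charges[sel]
    if len(charges) == 0:
        return phi
    ax, ay, az = spec.axes()
    nx, ny, nz = spec.dims

    def fill(ix=None, iy=None, iz=None):
        xs = ax if ix is None else ax[[ix]]
        ys = ay if iy is None else ay[[iy]]
        zs = az if iz is None else az[[iz]]
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        d = np.maximum(d, 1e-6)
        vals = (coul / eps_out) * (charges[None, :] * np.exp(-kappa * d) / d)
        vals = vals.sum(axis=1).reshape(len(xs), len(ys), len(zs))
        sl = [slice(None)] * 3
        for axis, idx in zip(range(3), (ix, iy, iz)):
            if idx is not None:
                sl[axis] = slice(ix, ix + 1) if axis == 0 else (
                    slice(iy, iy + 1) if axis == 1 else slice(iz, iz + 1))
        phi[tuple(sl)] = vals

    for face in (0, nx - 1):
        fill(ix=face)
    for face in (0, ny - 1):
        fill(iy=face)
    for face in (0, nz - 1):
        fill(iz=face)
    return phi


def solve_lpbe(s: Structure, g: GridSpec | None = None,
               p: SolverParams | None = None, h: float = 1.0,
               pad: float = 15.0) -> PotentialGrid:
    """Solve the LPBE for a charged structure; returns potential in kT/e.

    When ``g`` is omitted a grid is built from the structure with spacing
    ``h`` and padding ``pad``.  Raises ConvergenceError when the relative
    residual does not reach ``p.tol`` within ``p.max_iter`` sweeps.
    """
    p = p or SolverParams()
    if g is None:
        g = GridSpec.from_structure(s, h=h, pad=pad)
    centers = s.coords()
    radii = s.radii()
    charges = s.charges()
    if len(centers) == 0:
        raise ValueError("structure has no atoms")
    if np.any(radii <= 0):
        raise ValueError("all atoms need positive radii; run assign_charges")
    if not np.all(g.contains(centers)):
        raise ValueError("structure extends outside the grid")
    lo_pad = (centers - np.asarray(g.origin)).min()
    hi_pad = (g.upper() - centers).min()
    if min(lo_pad, hi_pad) < 10.0 - 1e-9:
        import warnings
        warnings.warn(f"grid padding {min(lo_pad, hi_pad):.1f} A is below "
                      "the recommended 10 A", stacklevel=2)

    coul = coulomb_kt(p.temperature)
    kappa = p.kappa
    hh = g.h

    # face-centered dielectric maps, one per axis
    eps_face = []
    for axis in range(3):
        off = np.zeros(3)
        off[axis] = hh / 2
        inside = _inside_mask(g, centers, radii, off)
        eps_face.append(np.where(inside, p.eps_in, p.eps_out))
    # node-centered ion accessibility
    ion_excl = _inside_mask(g, centers, radii + p.ion_exclusion, np.zeros(3))
    k2 = np.where(ion_excl, 0.0, p.eps_out * kappa * kappa)

    src = 4.0 * math.pi * coul * _trilinear_deposit(g, centers, charges) / hh

    phi = _dh_boundary(g, centers, charges, p.eps_out, kappa, coul)
    if not np.any(charges):
        zero = PotentialGrid(g, np.zeros(g.dims))
        zero.metadata = _solver_metadata(p, g, 0, 0.0)
        return zero

    exl, eyl, ezl = eps_face  # faces along x, y, z
    C = slice(1, -1)
    # stencil coefficients on the interior
    ex_m, ex_p = exl[:-1, C, C], exl[1:, C, C]
    ey_m, ey_p = eyl[C, :-1, C], eyl[C, 1:, C]
    ez_m, ez_p = ezl[C, C, :-1], ezl[C, C, 1:]
    diag = ex_m + ex_p + ey_m + ey_p + ez_m + ez_p + k2[C, C, C] * hh * hh
    b = src[C, C, C]  # 4 pi C q / h per node (equation scaled by h^2)

    nx, ny, nz = g.dims
    ii, jj, kk = np.meshgrid(np.arange(1, nx - 1), np.arange(1, ny - 1),
                             np.arange(1, nz - 1), indexing="ij")
    red = ((ii + jj + kk) % 2 == 0)
    black = ~red
    omega = p.omega
    if omega is None:
        n_max = max(g.dims)
        omega = 2.0 / (1.0 + math.sin(math.pi / n_max))

    b_norm = np.linalg.norm(b)
    if b_norm == 0:
        b_norm = 1.0

    interior = phi[C, C, C]
    converged = False
    it = 0
    residual = np.inf
    for it in range(1, p.max_iter + 1):
        for mask in (red, black):
            nb = (ex_m * phi[:-2, C, C] + ex_p * phi[2:, C, C]
                  + ey_m * phi[C, :-2, C] + ey_p * phi[C, 2:, C]
                  + ez_m * phi[C, C, :-2] + ez_p * phi[C, C, 2:])
            new = (nb + b) / diag
            interior[mask] += omega * (new[mask] - interior[mask])
        if it % 10 == 0 or it == p.max_iter:
            nb = (ex_m * phi[:-2, C, C] + ex_p * phi[2:, C, C]
                  + ey_m * phi[C, :-2, C] + ey_p * phi[C, 2:, C]
                  + ez_m * phi[C, C, :-2] + ez_p * phi[C, C, 2:])
            res = b - (diag * interior - nb)
            residual = np.linalg.norm(res) / b_norm
            if residual < p.tol:
                converged = True
                break
    if not converged:
        raise ConvergenceError(
            f"LPBE solver did not converge in {p.max_iter} iterations "
            f"(relative residual {residual:.3e}, tol {p.tol:.1e})")
    return PotentialGrid(g, phi, metadata=_solver_metadata(p, g, it, residual))


def _solver_metadata(p: SolverParams, g: GridSpec, iterations: int,
                     residual: float) -> dict:
    return {
        "solver": "lpbe-fd-sor",
        "units": "kT/e",
        "eps_in": p.eps_in,
        "eps_out": p.eps_out,
        "ionic_strength_M": p.ionic_strength,
        "temperature_K": p.temperature,
        "kappa_inv_A": p.kappa,
        "h_A": g.h,
        "dims": list(g.dims),
        "iterations": iterations,
        "relative_residual": float(residual),
    }


def analytic_reference(charges: list[tuple], points, eps: float,
                       kappa: float = 0.0) -> np.ndarray:
    """Superposition of (screened) Coulomb monopoles, in kT/e.

    ``charges`` is a list of (position, q) with q in e; ``points`` an
    (n, 3) array.  Evaluation at a charge position is an error.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coul = coulomb_kt()
    phi = np.zeros(len(pts))
    for pos, q in charges:
        d = np.linalg.norm(pts - np.asarray(pos, dtype=float), axis=1)
        if np.any(d < 1e-9):
            raise ValueError("evaluation point coincides with a charge")
        phi += (coul / eps) * q * np.exp(-kappa * d) / d
    return phi


# ---------------------------------------------------------------------------
# OpenDX scalar-grid interchange (the APBS grid format)

def write_dx(grid: PotentialGrid, path) -> None:
    nx, ny, nz = grid.spec.dims
    o = grid.spec.origin
    h = grid.spec.h
    n = nx * ny * nz
    lines = [
        "# OpenDX scalar field written by episurf",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6e} {o[1]:.6e} {o[2]:.6e}",
        f"delta {h:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {h:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {h:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {n} data follows",
    ]
    flat = grid.values.ravel(order="C")
    for i in range(0, n, 3):
        chunk = flat[i:i + 3]
        lines.append(" ".join(f"{v:.6e}" for v in chunk))
    lines += [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path) -> PotentialGrid:
    dims = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    in_data = False
    for line in Path(path).read_text().splitlines():
        t = line.strip()
        if not t or t.startswith("#"):
            continue
        if t.startswith("object 1"):
            dims = tuple(int(v) for v in t.split()[-3:])
        elif t.startswith("origin"):
            origin = tuple(float(v) for v in t.split()[1:4])
        elif t.startswith("delta"):
            deltas.append([float(v) for v in t.split()[1:4]])
        elif "data follows" in t:
            n_items = int(t.split("items")[1].split()[0])
            in_data = True
        elif in_data:
            if t.startswith(("attribute", "object", "component")):
                in_data = False
                continue
            values.extend(float(v) for v in t.split())
    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular OpenDX scalar grid")
    h = deltas[0][0]
    if not (abs(deltas[1][1] - h) < 1e-9 and abs(deltas[2][2] - h) < 1e-9):
        raise ValueError("anisotropic grids are not supported")
    arr = np.asarray(values[:n_items]).reshape(dims, order="C")
    return PotentialGrid(GridSpec(origin=origin, h=h, dims=dims), arr)
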