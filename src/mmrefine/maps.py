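"""Real-space data targets: density maps, interpolation, CC_mask, profiles.

Maps are stored on a regular grid over the unit cell (x fastest in memory,
``values[ix, iy, iz]``).  Two synthesis routes are provided: inverse Fourier
synthesis from structure factors (crystallographic route, periodic) and
direct Gaussian-atom synthesis (cryo-EM-style fixtures, non-periodic box).
Interpolation is tricubic Catmull-Rom — continuous with continuous first
derivatives — with analytic gradients used by the real-space refinement
target T = −Σ occ·ρ(x_atom)/N_atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomicModel, UnitCell
from .scatter import (FORM_FACTORS, DataError, calc_structure_factors,
                      generate_hkl)


@dataclass
class DensityMap:
    """Grid of density values over a unit cell / box."""

    values: np.ndarray            # (nx, ny, nz)
    cell: UnitCell
    periodic: bool = True
    d_min: float | None = None    # resolution of Fourier synthesis, if any
    origin_frac: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise DataError("map values must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def grid_spacing(self) -> tuple[float, float, float]:
        n = self.shape
        return (self.cell.a / n[0], self.cell.b / n[1], self.cell.c / n[2])

    def grid_coords(self, point: np.ndarray) -> np.ndarray:
        """Cartesian point -> continuous grid index."""
        frac = (np.asarray(point, float)
                @ self.cell.fractionalization_matrix().T)
        frac = frac - np.array(self.origin_frac)
        return frac * np.array(self.shape)

    def sigma(self) -> float:
        return float(self.values.std())


# --------------------------------------------------------------------------
# Synthesis


def map_from_structure_factors(hkl: np.ndarray, f: np.ndarray,
                               cell: UnitCell, shape: tuple[int, int, int],
                               d_min: float | None = None) -> DensityMap:
    """Inverse Fourier synthesis: rho(x) = (1/V) sum_h F(h) e^{-2pi i h.x}.

    The input list covers a Friedel hemisphere; mates are added as complex
    conjugates.  F(000) is taken as zero (mean-subtracted density).
    """
    hkl = np.asarray(hkl, int).reshape(-1, 3)
    f = np.asarray(f, complex)
    grid = np.zeros(shape, complex)
    n = np.array(shape)
    for (h, k, l), fh in zip(hkl, f):
        if 2 * abs(h) >= shape[0] or 2 * abs(k) >= shape[1] \
                or 2 * abs(l) >= shape[2]:
            raise DataError("grid too coarse for reflection "
                            f"({h},{k},{l})")
        grid[h % n[0], k % n[1], l % n[2]] += fh
        grid[(-h) % n[0], (-k) % n[1], (-l) % n[2]] += np.conj(fh)
    rho = np.fft.fftn(grid).real / cell.volume
    return DensityMap(rho, cell, periodic=True, d_min=d_min)


def map_from_model_fourier(model: AtomicModel, d_min: float,
                           shape: tuple[int, int, int] | None = None
                           ) -> DensityMap:
    """Fourier synthesis of F_calc to ``d_min`` (grid spacing d_min/4)."""
    if model.unit_cell is None:
        raise DataError("Fourier map synthesis requires a unit cell")
    cell = model.unit_cell
    if shape is None:
        shape = grid_for_resolution(cell, d_min)
    hkl = generate_hkl(cell, d_min)
    f = calc_structure_factors(model, hkl)
    return map_from_structure_factors(hkl, f, cell, shape, d_min=d_min)


def grid_for_resolution(cell: UnitCell, d_min: float,
                        spacing_factor: float = 4.0) -> tuple[int, int, int]:
    """Grid dimensions giving spacing d_min / spacing_factor."""
    spacing = d_min / spacing_factor
    return tuple(int(np.ceil(edge / spacing))
                 for edge in (cell.a, cell.b, cell.c))


def map_from_atoms(model: AtomicModel,
                   shape: tuple[int, int, int] | None = None,
                   spacing: float = 0.5,
                   truncation: float = 4.0) -> DensityMap:
    """Direct Gaussian-atom synthesis (cryo-EM-style, non-periodic box).

    Each atom contributes the inverse transform of its 4-Gaussian form
    factor smeared by its isotropic B: a sum of real-space Gaussians
    a_i (4 pi / (b_i + B))^{3/2} exp(-4 pi^2 r^2 / (b_i + B)), truncated at
    ``truncation`` Angstrom.
    """
    if model.unit_cell is None:
        raise DataError("map synthesis requires a cell/box")
    cell = model.unit_cell
    if shape is None:
        shape = tuple(int(np.ceil(edge / spacing))
                      for edge in (cell.a, cell.b, cell.c))
    values = np.zeros(shape)
    steps = np.array([cell.a / shape[0], cell.b / shape[1],
                      cell.c / shape[2]])
    coords = model.get_coords()
    bfac = model.b_factors()
    occ = model.occupancies()
    elements = model.elements()
    for j, e in enumerate(elements):
        key = e.upper()
        if key not in FORM_FACTORS:
            raise DataError(f"no form factors for element {e!r}")
        a, b, _ = FORM_FACTORS[key]
        beff = np.array(b) + bfac[j]
        if np.any(beff < 1.0):
            raise DataError("B factor too small for stable Gaussian-atom "
                            "synthesis (need B + b_i >= 1)")
        pos = coords[j]
        lo = np.maximum(np.floor((pos - truncation) / steps).astype(int), 0)
        hi = np.minimum(np.ceil((pos + truncation) / steps).astype(int),
                        np.array(shape) - 1)
        gx = np.arange(lo[0], hi[0] + 1) * steps[0]
        gy = np.arange(lo[1], hi[1] + 1) * steps[1]
        gz = np.arange(lo[2], hi[2] + 1) * steps[2]
        r2 = ((gx - pos[0])[:, None, None] ** 2
              + (gy - pos[1])[None, :, None] ** 2
              + (gz - pos[2])[None, None, :] ** 2)
        dens = np.zeros_like(r2)
        for ai, bi in zip(a, beff):
            dens += ai * (4.0 * np.pi / bi) ** 1.5 \
                * np.exp(-4.0 * np.pi ** 2 * r2 / bi)
        values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += \
            occ[j] * dens
    return DensityMap(values, cell, periodic=False)


# --------------------------------------------------------------------------
# Tricubic Catmull-Rom interpolation


def _cr_weights(t: float):
    """Catmull-Rom weights for nodes at offsets (-1, 0, 1, 2) and d/dt."""
    t2, t3 = t * t, t * t * t
    w = np.array([0.5 * (-t3 + 2 * t2 - t),
                  0.5 * (3 * t3 - 5 * t2 + 2),
                  0.5 * (-3 * t3 + 4 * t2 + t),
                  0.5 * (t3 - t2)])
    dw = np.array([0.5 * (-3 * t2 + 4 * t - 1),
                   0.5 * (9 * t2 - 10 * t),
                   0.5 * (-9 * t2 + 8 * t + 1),
                   0.5 * (3 * t2 - 2 * t)])
    return w, dw


def interpolate(dmap: DensityMap, point: np.ndarray):
    """Tricubic Catmull-Rom value and Cartesian gradient at a point."""
    g = dmap.grid_coords(point)
    n = dmap.shape
    base = np.floor(g).astype(int)
    t = g - base
    idx = []
    for axis in range(3):
        rng = base[axis] + np.arange(-1, 3)
        if dmap.periodic:
            rng = rng % n[axis]
        elif rng[0] < 0 or rng[-1] >= n[axis]:
            raise DataError(
                f"point {np.asarray(point).round(3)} outside "
                "interpolation region of a non-periodic map")
        idx.append(rng)
    block = dmap.values[np.ix_(idx[0], idx[1], idx[2])]
    w, dw = zip(*(_cr_weights(tc) for tc in t))
    val = np.einsum("ijk,i,j,k->", block, w[0], w[1], w[2])
    grad_g = np.array([
        np.einsum("ijk,i,j,k->", block, dw[0], w[1], w[2]),
        np.einsum("ijk,i,j,k->", block, w[0], dw[1], w[2]),
        np.einsum("ijk,i,j,k->", block, w[0], w[1], dw[2]),
    ])
    # chain rule grid index -> Cartesian: g_i = N_i * (M_frac x)_i
    jac = np.array(n)[:, None] * dmap.cell.fractionalization_matrix()
    return float(val), jac.T @ grad_g


# --------------------------------------------------------------------------
# Real-space target


class RealSpaceTarget:
    """T = -sum(occ * rho(x_atom)) / n_atoms  (DataTarget contract)."""

    mode = "real"

    def __init__(self, model: AtomicModel, dmap: DensityMap):
        self.map = dmap
        self.occ = model.occupancies()
        self.labels = model.atom_labels()
        self.n = len(self.occ)

    def evaluate(self, coords: np.ndarray):
        x = np.asarray(coords, float).reshape(-1, 3)
        if x.shape[0] != self.n:
            raise ValueError("coordinate count mismatch")
        t = 0.0
        grad = np.zeros_like(x)
        outside = []
        for j in range(self.n):
            try:
                val, g = interpolate(self.map, x[j])
            except DataError:
                outside.append(self.labels[j])
                continue
            t -= self.occ[j] * val / self.n
            grad[j] = -self.occ[j] * g / self.n
        if outside:
            raise DataError("atoms outside map box: " + ", ".join(outside))
        return float(t), grad


def cc_mask(model: AtomicModel, dmap: DensityMap,
            mask_radius: float = 2.0) -> float:
    """Pearson correlation of map vs model map over a 2 A atom mask.

    The model map is synthesized by the same route as the input map:
    Fourier synthesis at the map's recorded resolution when present,
    Gaussian-atom synthesis otherwise.
    """
    if dmap.d_min is not None:
        model_map = map_from_model_fourier(model, dmap.d_min,
                                           shape=dmap.shape)
    else:
        model_map = map_from_atoms(model, shape=dmap.shape)
    n = dmap.shape
    axes = [np.arange(n[i]) / n[i] for i in range(3)]
    fx, fy, fz = np.meshgrid(*axes, indexing="ij")
    frac = np.stack([fx.ravel(), fy.ravel(), fz.ravel()], axis=1)
    grid_xyz = frac @ dmap.cell.orthogonalization_matrix().T
    atoms = model.get_coords()
    if dmap.periodic:
        shifts = np.array([(i, j, k) for i in (-1, 0, 1)
                           for j in (-1, 0, 1) for k in (-1, 0, 1)], float)
        images = (atoms[:, None, :]
                  + (shifts @ dmap.cell.orthogonalization_matrix().T
                     )[None, :, :]).reshape(-1, 3)
    else:
        images = atoms
    tree = cKDTree(images)
    d, _ = tree.query(grid_xyz, k=1,
                      distance_upper_bound=mask_radius)
    mask = np.isfinite(d)
    if not mask.any():
        raise DataError("empty CC_mask mask")
    a = dmap.values.ravel()[mask]
    b = model_map.values.ravel()[mask]
    if a.std() == 0.0 or b.std() == 0.0:
        raise DataError("zero-variance map in CC_mask")
    return float(np.corrcoef(a, b)[0, 1])


def difference_profile(dmap: DensityMap, point_a, point_b, n_steps: int):
    """Map values at n_steps+1 even points from a to b, plus sigma units.

    Returns (fractions, values, sigma_values) where fractions run 0..1 and
    sigma units are (v - map mean) / map sd.
    """
    a = np.asarray(point_a, float)
    b = np.asarray(point_b, float)
    fr = np.linspace(0.0, 1.0, n_steps + 1)
    vals = np.array([interpolate(dmap, a + f * (b - a))[0] for f in fr])
    mean, sd = dmap.values.mean(), dmap.values.std()
    if sd == 0.0:
        sigma_vals = np.zeros_like(vals)
    else:
        sigma_vals = (vals - mean) / sd
    return fr, vals, sigma_vals


# --------------------------------------------------------------------------
# CCP4/MRC I/O (via gemmi)


def write_ccp4(dmap: DensityMap, path) -> None:
    import gemmi

    grid = gemmi.FloatGrid(*dmap.shape)
    grid.set_unit_cell(dmap.cell.to_gemmi())
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    arr = np.array(grid, copy=False)
    arr[...] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))


def read_ccp4(path, periodic: bool = True) -> DensityMap:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))            # normalize axis order to X fastest
    values = np.array(m.grid, copy=True).astype(float)
    c = m.grid.unit_cell
    return DensityMap(values, UnitCell(c.a, c.b, c.c, c.alpha, c.beta,
                                       c.gamma), periodic=periodic)
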