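"""Density-map operations: MRC/CCP4 I/O, model-map simulation, B-factor
sharpening and the global cross-correlation coefficient (CCC).

Grid convention: ``values[k, j, i]`` with i the fastest (x) axis, so the
voxel at index (k, j, i) is centered at ``origin + (i*sx, j*sy, k*sz)``.
Axis order in files is normalized to x-fastest on read.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .core_model import ModelStructure

#: Real-space Gaussian width per Å of resolution. With sigma = 0.356*d the
#: Fourier transform of the kernel falls to half its peak at spatial
#: frequency 1/d, a common definition of "resolution d" for simulated maps.
SIGMA_PER_RESOLUTION = 0.356

#: Half-width of the per-atom contribution box, in sigmas.
TRUNCATION_SIGMAS = 3.0


@dataclass
class DensityGrid:
    """A 3-D scalar field on a regular axis-aligned grid.

    values: array indexed (k, j, i), z slowest / x fastest.
    spacing: voxel size (sx, sy, sz) in Å.
    origin: position of the center of voxel (0, 0, 0), in Å.
    """
    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution_hint: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).copy()
        if np.any(self.spacing <= 0):
            raise ValueError(f"non-positive spacing {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        """(nx, ny, nz)."""
        nz, ny, nx = self.values.shape
        return nx, ny, nz

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "DensityGrid", atol: float = 1e-4) -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    def copy_geometry(self, values: np.ndarray | None = None) -> "DensityGrid":
        vals = np.zeros_like(self.values) if values is None else values
        return DensityGrid(vals, self.spacing.copy(), self.origin.copy(),
                           self.resolution_hint)

    def coord_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional (i, j, k) index of a coordinate (x, y, z)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def index_to_coord(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing


@dataclass(frozen=True)
class GridIndexSet:
    """A duplicate-free set of voxel indices (k, j, i) into one grid."""
    indices: np.ndarray  # (n, 3) int array of (k, j, i)

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("indices must be an (n, 3) array of (k, j, i)")
        uniq = np.unique(idx, axis=0)
        if len(uniq) != len(idx):
            raise ValueError("duplicate voxel indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, grid: DensityGrid) -> None:
        shape = np.asarray(grid.values.shape)
        if np.any(self.indices < 0) or np.any(self.indices >= shape):
            raise ValueError("voxel indices outside grid bounds")

    def take(self, grid: DensityGrid) -> np.ndarray:
        """Grid values at the member voxels, as a flat array."""
        k, j, i = self.indices.T
        return grid.values[k, j, i]


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O
# ---------------------------------------------------------------------------

def read_map(path: str) -> DensityGrid:
    """Read an MRC/CCP4 (2014 dialect) map.

    The origin is taken from the ORIGIN header record when any component is
    nonzero, otherwise from NxSTART * spacing. Axis order is normalized so
    that x is fastest. Modes 2 (float32) and 1 (int16) are accepted.
    """
    m = gemmi.read_ccp4_map(str(path))
    mode = m.header_i32(4)
    if mode not in (1, 2):
        raise ValueError(f"{path}: unsupported MRC mode {mode} "
                         "(only 2/float32 and 1/int16)")
    # raw header, before any gemmi normalization
    nstart_file = np.array([m.header_i32(i) for i in (5, 6, 7)])
    sampling = np.array([m.header_i32(i) for i in (8, 9, 10)])
    cell = np.array([m.header_float(i) for i in (11, 12, 13)])
    mapcrs = [m.header_i32(i) for i in (17, 18, 19)]  # crystal axis of col/row/sec
    origin_rec = np.array([m.header_float(i) for i in (50, 51, 52)])
    if sorted(mapcrs) != [1, 2, 3]:
        raise ValueError(f"{path}: invalid MAPC/MAPR/MAPS {mapcrs}")
    if np.any(sampling <= 0) or np.any(cell <= 0):
        raise ValueError(f"{path}: inconsistent header (sampling {sampling}, "
                         f"cell {cell})")
    arr = np.array(m.grid, copy=True)  # shape (ncol, nrow, nsec)
    dims_words = [m.header_i32(i) for i in (1, 2, 3)]
    if list(arr.shape) != dims_words:
        raise ValueError(f"{path}: header dims {dims_words} do not match "
                         f"data shape {arr.shape}")
    spacing = cell / sampling  # indexed by crystal axis (x, y, z)
    # permute data axes (col,row,sec) -> (x,y,z), then transpose to (z,y,x)
    perm = [mapcrs.index(ax + 1) for ax in range(3)]  # data axis holding x,y,z
    arr_xyz = np.transpose(arr, axes=perm)
    nstart = np.empty(3, dtype=int)
    for data_axis, crystal_axis in enumerate(mapcrs):
        nstart[crystal_axis - 1] = nstart_file[data_axis]
    if np.any(origin_rec != 0):
        origin = origin_rec.astype(float)
    else:
        origin = nstart * spacing
    values = np.ascontiguousarray(arr_xyz.T, dtype=np.float64)  # (z, y, x)
    return DensityGrid(values, spacing, origin)


def write_map(grid: DensityGrid, path: str) -> None:
    """Write a DensityGrid as MRC/CCP4 2014, mode 2 (float32), x fastest.

    The origin is stored in the ORIGIN record; NxSTART is written as zero.
    """
    nx, ny, nz = grid.dims
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(gemmi.UnitCell(nx * grid.spacing[0], ny * grid.spacing[1],
                                   nz * grid.spacing[2], 90, 90, 90))
    np.array(g, copy=False)[:] = np.ascontiguousarray(
        grid.values.T, dtype=np.float32)  # (x, y, z) order
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# model-derived density
# ---------------------------------------------------------------------------

_Z_CACHE: dict[str, int] = {}


def atomic_number(element: str) -> int:
    z = _Z_CACHE.get(element)
    if z is None:
        z = gemmi.Element(element).atomic_number
        if z == 0:
            raise ValueError(f"unknown element {element!r}")
        _Z_CACHE[element] = z
    return z


def _atom_weights(structure: ModelStructure) -> np.ndarray:
    return np.array([atomic_number(a.element) for a in structure.atoms],
                    dtype=float)


def grid_for_structure(coords: np.ndarray, resolution: float,
                       spacing: float | np.ndarray = 1.0,
                       pad: float | None = None) -> DensityGrid:
    """An empty grid covering the coordinates plus a truncation margin."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    sigma = SIGMA_PER_RESOLUTION * resolution
    if pad is None:
        pad = TRUNCATION_SIGMAS * sigma + float(np.max(spacing))
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    values = np.zeros((dims[2], dims[1], dims[0]))
    return DensityGrid(values, spacing, lo, resolution_hint=resolution)


def accumulate_gaussians(grid: DensityGrid, coords: np.ndarray,
                         weights: np.ndarray, sigma: float,
                         warn_clipped: bool = True) -> None:
    """Add weighted isotropic Gaussians to ``grid.values`` in place.

    Each atom contributes w * exp(-d^2 / 2 sigma^2) to every voxel in the
    cube of half-width TRUNCATION_SIGMAS * sigma around it.
    """
    nz, ny, nx = grid.values.shape
    dims = np.array([nx, ny, nz])
    half = TRUNCATION_SIGMAS * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    clipped = 0
    axes_1d = [grid.origin[d] + grid.spacing[d] * np.arange(dims[d])
               for d in range(3)]
    for pos, w in zip(coords, weights):
        frac = grid.coord_to_index(pos)
        lo = np.ceil((pos - half - grid.origin) / grid.spacing).astype(int)
        hi = np.floor((pos + half - grid.origin) / grid.spacing).astype(int)
        if np.any(frac < -half / grid.spacing) or np.any(
                frac > dims - 1 + half / grid.spacing):
            clipped += 1
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, dims - 1)
        if np.any(lo_c > hi_c):
            continue
        dx = axes_1d[0][lo_c[0]:hi_c[0] + 1] - pos[0]
        dy = axes_1d[1][lo_c[1]:hi_c[1] + 1] - pos[1]
        dz = axes_1d[2][lo_c[2]:hi_c[2] + 1] - pos[2]
        gx = np.exp(-dx * dx * inv2s2)
        gy = np.exp(-dy * dy * inv2s2)
        gz = np.exp(-dz * dz * inv2s2)
        grid.values[lo_c[2]:hi_c[2] + 1, lo_c[1]:hi_c[1] + 1,
                    lo_c[0]:hi_c[0] + 1] += w * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :])
    if clipped and warn_clipped:
        warnings.warn(f"{clipped} atom(s) outside the grid support; their "
                      "contributions were clipped", stacklevel=2)


def simulate_density(structure: ModelStructure, resolution: float,
                     spacing: float | np.ndarray = 1.0,
                     grid: DensityGrid | None = None,
                     sigma_factor: float = SIGMA_PER_RESOLUTION) -> DensityGrid:
    """Simulate a density map from an atomic model at a target resolution.

    Every atom contributes an isotropic Gaussian of weight equal to its
    atomic number with real-space sigma = sigma_factor * resolution,
    truncated at TRUNCATION_SIGMAS sigma. If ``grid`` is given, the output
    is sampled on exactly that geometry (voxel-wise comparability for
    SMOC/CCC); otherwise a grid with the requested spacing is created
    around the model.
    """
    if resolution <= 0:
        raise ValueError(f"non-positive resolution {resolution}")
    coords = structure.coords()
    weights = _atom_weights(structure)
    sigma = sigma_factor * resolution
    if grid is None:
        out = grid_for_structure(coords, resolution, spacing)
    else:
        out = grid.copy_geometry()
        out.resolution_hint = resolution
    accumulate_gaussians(out, coords, weights, sigma)
    return out


# ---------------------------------------------------------------------------
# sharpening and correlation
# ---------------------------------------------------------------------------

def sharpen_map(grid: DensityGrid, b_factor: float) -> DensityGrid:
    """Scale Fourier amplitudes by exp(-B s^2 / 4); negative B sharpens.

    s is the spatial-frequency magnitude in 1/Å. The s = 0 term is unscaled,
    so the mean density is preserved. B is in Å^2 (the crystallographic
    temperature-factor convention).
    """
    nz, ny, nx = grid.values.shape
    ft = np.fft.rfftn(grid.values)
    fz = np.fft.fftfreq(nz, d=grid.spacing[2])
    fy = np.fft.fftfreq(ny, d=grid.spacing[1])
    fx = np.fft.rfftfreq(nx, d=grid.spacing[0])
    s2 = (fz[:, None, None] ** 2 + fy[None, :, None] ** 2
          + fx[None, None, :] ** 2)
    ft *= np.exp(-b_factor * s2 / 4.0)
    out = np.fft.irfftn(ft, s=grid.values.shape, axes=(0, 1, 2))
    return DensityGrid(out, grid.spacing.copy(), grid.origin.copy(),
                       grid.resolution_hint)


def global_ccc(grid_a: DensityGrid, grid_b: DensityGrid,
               mask: GridIndexSet | None = None) -> float:
    """Mean-subtracted Pearson correlation between two maps on one grid.

    Invariant under positive affine transforms (a*rho + b, a > 0) of either
    map; contrast with SMOC, which is scale- but not offset-invariant.
    """
    if not grid_a.same_geometry(grid_b):
        raise ValueError("grids have different geometry")
    if mask is not None:
        mask.validate(grid_a)
        a = mask.take(grid_a)
        b = mask.take(grid_b)
    else:
        a = grid_a.values.ravel()
        b = grid_b.values.ravel()
    a = a - a.mean()
    b = b - b.mean()
    va = float(a @ a)
    vb = float(b @ b)
    if va <= 0 or vb <= 0:
        raise ValueError("zero variance over the correlation region")
    return float((a @ b) / np.sqrt(va * vb))
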