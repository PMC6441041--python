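"""Density-map data model, MRC2014 I/O and reciprocal/real-space primitives.

Conventions
-----------
* Grids are numpy arrays indexed ``[ix, iy, iz]`` (axis 0 = x), matching the
  standard MRC2014 column/row/section order.
* Voxel indices are 0-based; the physical position of voxel ``i`` is
  ``origin + i * voxel_size`` (Å).  All rigid transforms act on physical Å
  coordinates about an explicit centre.
* Files are MRC2014 mode 2 (float32); the origin is read from the ORIGIN
  header words.  I/O goes through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.fft as sfft
from scipy import ndimage
from scipy.signal import fftconvolve

from .transforms import RigidTransform, is_rotation_matrix

__all__ = [
    "DensityMap",
    "SoftMask",
    "MapFormatError",
    "read_map",
    "write_map",
    "rotate_map",
    "bfactor_filter",
    "sphere_smooth_mask",
    "threshold_for_volume",
    "soft_spherical_mask",
    "downsample_map",
]


class MapFormatError(ValueError):
    """Raised when an on-disk map cannot be interpreted as MRC2014."""


@dataclass
class DensityMap:
    """A 3D scalar density grid with physical voxel size and origin.

    Parameters
    ----------
    grid : ndarray
        Density values, shape (nx, ny, nz), arbitrary units.
    voxel_size : float
        Isotropic voxel edge in Å (default 1.35).
    origin : ndarray
        Physical position (Å) of voxel (0, 0, 0) in the map frame.
    """

    grid: np.ndarray
    voxel_size: float = 1.35
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 3D with at least one voxel per axis")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size**3)

    @property
    def center(self) -> np.ndarray:
        """Physical centre of the box (Å): midpoint of the index lattice."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.voxel_size

    def index_to_position(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size

    def position_to_index(self, pos) -> np.ndarray:
        return (np.asarray(pos, dtype=float) - self.origin) / self.voxel_size

    def like(self, grid: np.ndarray) -> "DensityMap":
        """A new map sharing this map's lattice metadata."""
        return DensityMap(grid, self.voxel_size, self.origin.copy())

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())


@dataclass
class SoftMask:
    """A [0, 1]-valued weight grid on the lattice of its parent map."""

    grid: np.ndarray
    voxel_size: float = 1.35
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        lo, hi = float(self.grid.min()), float(self.grid.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"mask values must lie in [0, 1], got [{lo}, {hi}]")
        self.grid = np.clip(self.grid, 0.0, 1.0)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def enclosed_volume(self) -> float:
        """Volume (Å³) of strictly positive mask support."""
        return float(np.count_nonzero(self.grid > 0) * self.voxel_size**3)


# ---------------------------------------------------------------------------
# MRC2014 I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_map(path) -> DensityMap:
    """Read an MRC2014 / CCP4 map file.

    The voxel size is derived from the unit cell and grid dimensions and must
    be isotropic to within 1e-3 Å.  The origin is taken from the ORIGIN header
    words (50–52); NXSTART is treated as 0 unless the origin is absent, in
    which case NXSTART·voxel is used.
    """
    import gemmi

    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise MapFormatError(f"not a readable MRC2014 map ({path}): {exc}") from exc
    grid = np.array(ccp4.grid.array, copy=True)
    nu, nv, nw = ccp4.grid.nu, ccp4.grid.nv, ccp4.grid.nw
    cell = ccp4.grid.unit_cell
    if min(cell.a, cell.b, cell.c) <= 0:
        raise MapFormatError(f"malformed header field CELLA (unit cell {cell})")
    vx, vy, vz = cell.a / nu, cell.b / nv, cell.c / nw
    if abs(vx - vy) > 1e-3 or abs(vx - vz) > 1e-3:
        raise MapFormatError(
            f"anisotropic voxel size ({vx:.4f}, {vy:.4f}, {vz:.4f}) Å is unsupported"
        )
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if not np.all(np.isfinite(origin)):
        raise MapFormatError("malformed header field ORIGIN (non-finite)")
    if np.all(origin == 0.0):
        nstart = np.array(
            [ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float
        )
        origin = nstart * vx
    return DensityMap(grid, float(round(vx, 6)), origin)


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC2014 mode 2 (float32).

    Grid values round-trip bit-exactly once cast to float32; voxel size and
    origin round-trip to float32 precision.
    """
    import gemmi

    nx, ny, nz = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid.array)[...] = dmap.grid.astype(np.float32)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * dmap.voxel_size, ny * dmap.voxel_size, nz * dmap.voxel_size,
            90.0, 90.0, 90.0,
        )
    )
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


def write_mask(mask: SoftMask, path) -> None:
    write_map(DensityMap(mask.grid, mask.voxel_size, mask.origin), path)


def read_mask(path) -> SoftMask:
    m = read_map(path)
    return SoftMask(np.clip(m.grid, 0.0, 1.0), m.voxel_size, m.origin)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def rotate_map(
    dmap: DensityMap,
    transform: RigidTransform,
    center=None,
    fill: float = 0.0,
) -> DensityMap:
    """Resample a map under a rigid transform about ``center`` (Å).

    The output at physical position p equals the input sampled (trilinear) at
    ``T⁻¹(p)``, where T rotates about ``center`` and then translates; voxels
    mapped from outside the box take ``fill``.
    """
    if not is_rotation_matrix(transform.rotation):
        raise ValueError("transform.rotation is not a proper rotation matrix")
    if center is None:
        center = dmap.center
    center = np.asarray(center, dtype=float)
    lo, hi = dmap.origin, dmap.index_to_position(np.array(dmap.shape) - 1)
    if np.any(center < lo - 1e-9) or np.any(center > hi + 1e-9):
        raise ValueError(f"center {center} outside map bounds [{lo}, {hi}]")
    Rt = transform.rotation.T
    c_idx = dmap.position_to_index(center)
    t_idx = transform.translation / dmap.voxel_size
    offset = c_idx - Rt @ (c_idx + t_idx)
    # snap lattice-exact rotations/offsets: float rounding (cos 90° ≈ 6e-17)
    # would otherwise push boundary voxels infinitesimally outside the grid,
    # where constant-mode interpolation replaces them with the fill value
    Rt = np.where(np.abs(Rt - np.rint(Rt)) < 1e-12, np.rint(Rt), Rt)
    offset = np.where(np.abs(offset - np.rint(offset)) < 1e-9,
                      np.rint(offset), offset)
    out = ndimage.affine_transform(
        dmap.grid.astype(float), Rt, offset=offset, order=1,
        mode="constant", cval=fill,
    )
    return dmap.like(out)


def downsample_map(dmap: DensityMap, factor: int) -> DensityMap:
    """Block-mean downsampling by an integer factor (for coarse searches)."""
    if factor == 1:
        return dmap
    nx, ny, nz = (s // factor for s in dmap.shape)
    g = dmap.grid[: nx * factor, : ny * factor, : nz * factor]
    g = g.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
    # block centre of block 0 sits (factor-1)/2 fine voxels from the old origin
    shift = (factor - 1) / 2.0 * dmap.voxel_size
    return DensityMap(g, dmap.voxel_size * factor, dmap.origin + shift)


# ---------------------------------------------------------------------------
# Reciprocal-space filter
# ---------------------------------------------------------------------------

def bfactor_filter(dmap: DensityMap, B: float) -> DensityMap:
    """Scale Fourier amplitudes by ``exp(−B·s²/4)`` (s in Å⁻¹).

    B > 0 blurs (attenuates high frequencies), B < 0 sharpens; the mean
    density (s = 0) is unchanged.  No frequency cutoff is applied, so the
    filter is exactly invertible by ``bfactor_filter(−B)``.
    """
    if B == 0:
        return dmap.copy()
    F = sfft.rfftn(dmap.grid.astype(float))
    s2 = _freq_s2(dmap.shape, dmap.voxel_size)
    out = sfft.irfftn(F * np.exp(-B * s2 / 4.0), s=dmap.shape)
    return dmap.like(out)


def _freq_s2(shape, voxel_size: float) -> np.ndarray:
    fx = sfft.fftfreq(shape[0], d=voxel_size)
    fy = sfft.fftfreq(shape[1], d=voxel_size)
    fz = sfft.rfftfreq(shape[2], d=voxel_size)
    return (
        fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    )


# ---------------------------------------------------------------------------
# Mask primitives
# ---------------------------------------------------------------------------

def _ball_kernel(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    ball = (d2 <= radius_vox**2).astype(float)
    return ball / ball.sum()


def sphere_smooth_mask(mask: SoftMask, radius: float) -> SoftMask:
    """Smooth a mask by normalised convolution with a constant-density ball.

    ``radius`` is in Å and must be at least one voxel.  Interior values stay
    at 1; the support dilates by at most ``radius``.
    """
    if radius < mask.voxel_size:
        raise ValueError(
            f"smoothing radius {radius} Å is below the voxel size "
            f"{mask.voxel_size} Å"
        )
    kernel = _ball_kernel(radius / mask.voxel_size)
    out = fftconvolve(mask.grid, kernel, mode="same")
    out = np.clip(out, 0.0, 1.0)
    prov = dict(mask.provenance)
    prov["smoothing_radius_A"] = float(radius)
    return SoftMask(out, mask.voxel_size, mask.origin.copy(), prov)


def threshold_for_volume(dmap, target_volume: float) -> float:
    """Largest threshold τ with (voxels ≥ τ)·voxel³ ≥ ``target_volume`` (Å³).

    Ties at the boundary density are all included, so the enclosed volume can
    exceed the target by the tied voxels; for distinct densities it is within
    one voxel volume.  Accepts a DensityMap or SoftMask.
    """
    vvol = float(dmap.voxel_size) ** 3
    values = np.asarray(dmap.grid, dtype=float).ravel()
    box_volume = values.size * vvol
    if not 0 < target_volume <= box_volume:
        raise ValueError(
            f"target_volume must be in (0, {box_volume:.1f}] Å³, got {target_volume}"
        )
    n = int(np.ceil(target_volume / vvol))
    return float(np.partition(values, values.size - n)[values.size - n])


def soft_spherical_mask(
    shape, voxel_size: float, center_idx=None, radius: float = 20.0,
    soft_edge: float = 0.0, origin=(0.0, 0.0, 0.0),
) -> SoftMask:
    """A spherical mask with an optional cosine-soft edge (Å units)."""
    shape = tuple(int(s) for s in shape)
    if center_idx is None:
        center_idx = (np.array(shape) - 1) / 2.0
    ax = [np.arange(s) - c for s, c in zip(shape, np.asarray(center_idx, float))]
    d = voxel_size * np.sqrt(
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    if soft_edge > 0:
        g = np.clip((radius + soft_edge - d) / soft_edge, 0.0, 1.0)
        g = np.where(d <= radius, 1.0, 0.5 - 0.5 * np.cos(np.pi * g))
        g[d <= radius] = 1.0
    else:
        g = (d <= radius).astype(float)
    return SoftMask(
        g, voxel_size, np.asarray(origin, float),
        {"kind": "sphere", "radius_A": radius, "soft_edge_A": soft_edge},
    )
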