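"""Synthetic two-horn spike phantoms with planted, recorded ground truth.

The generator emulates the C2-symmetric vertex spike of a large icosahedral
virus: each horn is a chain of identical asymmetric "pearl" domains planted
along a curved spine, adjacent domains related by a ~180° rotation about the
local spine axis and an ~11.5 Å translation along it, with the pearl centres
zig-zagging on alternating sides of the spine.  Pearls are analytic Gaussian
mixtures, so maps are rendered without interpolation and the C2 symmetry is
exact by construction (the second horn is the lattice mirror of the first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import DensityMap, bfactor_filter, rotate_map
from .transforms import RigidTransform, geodesic_angle_deg

__all__ = [
    "PearlSpec",
    "HornSpec",
    "GroundTruthEntry",
    "GroundTruth",
    "PearlModel",
    "build_pearl",
    "build_spike",
    "add_noise_and_blur",
]


@dataclass(frozen=True)
class PearlSpec:
    """Recipe for one asymmetric pearl domain.

    ``n_lobes`` Gaussian lobes (≥ 4 so the orientation is identifiable) are
    scattered over a fan-shaped sector; the spatial scale is calibrated so
    the volume enclosed above half-maximum is ``pearl_volume`` (Å³, default
    the expected volume of a ~320-residue protein domain).
    """

    n_lobes: int = 14
    lobe_sigma: float = 7.0
    pearl_volume: float = 45_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lobes < 4:
            raise ValueError("n_lobes must be ≥ 4 for an identifiable orientation")
        if self.lobe_sigma <= 0 or self.pearl_volume <= 0:
            raise ValueError("lobe_sigma and pearl_volume must be positive")


@dataclass(frozen=True)
class HornSpec:
    """Geometry of one horn: a pearl chain on a curved spine.

    The spine runs parallel to the surface (+x) for ``spine_straight`` Å and
    then curves up (+z) along an arc of radius ``spine_arc`` Å.  Pearl
    centres sit ``zigzag_offset`` Å off the spine on alternating sides (±y),
    consecutive frames related by ``inter_rotation`` about the local tangent
    and ``inter_translation`` along it.

    The ``*_jitter`` fields add small recorded per-link deviations (normal,
    truncated at 2 sd).  A chain of *exactly* identical screw links is
    invariant under its own screw operation, which makes per-domain
    registration degenerate; the real assembly is only approximately
    periodic, and the jitter emulates that while every planted link value
    remains recorded in the ground truth.  Set them to 0 for an exactly
    periodic chain.
    """

    n_domains: int = 10
    inter_rotation: float = 180.0
    inter_translation: float = 11.5
    spine_straight: float = 40.0
    spine_arc: float = 40.0
    stalk_length: float = 30.0
    zigzag_offset: float = 18.0
    start_radius: float = 15.0  # Å from the C2 axis to the first spine point
    spine_sigma: float = 4.5      # Å radius of the rope-like spine filament
    spine_amplitude: float = 0.6  # density of the spine relative to a pearl
    link_rotation_jitter: float = 2.0    # deg sd about the local axis
    link_translation_jitter: float = 0.3  # Å sd along the local axis
    zigzag_radial_jitter: float = 0.8     # Å sd on the lateral offset
    zigzag_azimuth_jitter: float = 4.0    # deg sd of the lateral direction

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("n_domains must be ≥ 2")


@dataclass(frozen=True)
class GroundTruthEntry:
    horn: int
    index: int
    transform: RigidTransform


@dataclass
class GroundTruth:
    """Planted transforms plus the map-generation parameters."""

    entries: list[GroundTruthEntry]
    voxel_size: float
    box: tuple[int, int, int]
    c2_center: np.ndarray
    params: dict = field(default_factory=dict)

    def transforms(self, horn: int | None = None) -> list[RigidTransform]:
        return [e.transform for e in self.entries if horn is None or e.horn == horn]

    def positions(self, horn: int | None = None) -> np.ndarray:
        return np.array(
            [e.transform.translation for e in self.entries
             if horn is None or e.horn == horn]
        )

    def c2_operation(self) -> RigidTransform:
        """The map's two-fold: 180° about z through the box centre."""
        C = np.diag([-1.0, -1.0, 1.0])
        c = np.asarray(self.c2_center, float)
        return RigidTransform(C, c - C @ c)

    def to_tsv(self, path) -> None:
        rows = []
        for e in self.entries:
            rot, tilt, psi = e.transform.euler_deg
            x, y, z = e.transform.translation
            rows.append(dict(horn=e.horn, index=e.index, x=x, y=y, z=z,
                             rot=rot, tilt=tilt, psi=psi))
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
        side = Path(path).with_suffix(".json")
        meta = dict(self.params)
        meta.update(voxel_size=self.voxel_size, box=list(self.box),
                    c2_center=list(map(float, self.c2_center)))
        side.write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        entries = [
            GroundTruthEntry(
                int(r.horn), int(r.index),
                RigidTransform.from_euler(r.rot, r.tilt, r.psi, (r.x, r.y, r.z)),
            )
            for r in df.itertuples()
        ]
        return cls(entries, float(meta["voxel_size"]), tuple(meta["box"]),
                   np.asarray(meta["c2_center"]), meta)


# ---------------------------------------------------------------------------
# Pearl model
# ---------------------------------------------------------------------------

@dataclass
class PearlModel:
    """Analytic saturated Gaussian-mixture pearl (Å, about the pearl centre).

    The scattered lobes give an irregular, orientation-identifiable
    envelope; the density sum is saturated at ``cap`` so the interior is
    protein-like flat and the half-max volume scales exactly with the cube
    of the coordinate scale (which makes the volume calibration a fixed
    point in one or two multiplicative steps).
    """

    centers: np.ndarray     # (k, 3)
    sigmas: np.ndarray      # (k,) per-lobe width, Å
    amplitudes: np.ndarray  # (k,)
    spec: PearlSpec
    cap: float = 1.15

    @property
    def extent(self) -> float:
        """Bounding radius (Å) beyond which the density is negligible."""
        return float((np.linalg.norm(self.centers, axis=1)
                      + 2.5 * self.sigmas).max())

    @property
    def core_radius(self) -> float:
        """Radius (Å) of the half-max support about the centre (+ margin)."""
        ref = self.render(1.5, int(np.ceil(2 * self.extent / 1.5)) | 1)
        g = ref.grid
        idx = np.argwhere(g >= 0.5 * g.max())
        d = np.linalg.norm((idx - np.array(g.shape) // 2) * 1.5, axis=1)
        return float(d.max() + 5.0)

    def density(self, points: np.ndarray) -> np.ndarray:
        """Evaluate at (..., 3) Å coordinates in the pearl frame."""
        p = np.asarray(points, float)
        out = np.zeros(p.shape[:-1])
        for c, s, a in zip(self.centers, self.sigmas, self.amplitudes):
            d2 = ((p - c) ** 2).sum(axis=-1)
            out += a * np.exp(-0.5 * d2 / s**2)
        return np.minimum(out, self.cap)

    def render(self, voxel_size: float, box: int) -> DensityMap:
        """Render centred in a cubic box; the pearl centre sits at voxel n//2."""
        n = int(box)
        ax = (np.arange(n) - n // 2) * voxel_size
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        return DensityMap(self.density(pts), voxel_size,
                          origin=-(n // 2) * voxel_size * np.ones(3))


def _half_max_volume(model: PearlModel, voxel: float = 1.5) -> float:
    box = int(np.ceil(2 * model.extent / voxel)) | 1
    g = model.render(voxel, box).grid
    return float(np.count_nonzero(g >= 0.5 * g.max()) * voxel**3)


def _self_correlation(model: PearlModel, step_deg: float = 30.0) -> float:
    """Best masked Pearson CC of the pearl with a non-trivially rotated copy.

    Measured inside a sphere of 1.1× the nominal pearl radius, i.e. over the
    molecular region the search actually correlates, not the empty box.
    """
    from .search import make_orientation_grid  # cycle-free: search imports maps only

    ref = model.render(3.0, int(np.ceil(2 * model.extent / 3.0)) | 1)
    r_half = (3 * model.spec.pearl_volume / (4 * np.pi)) ** (1.0 / 3.0)
    n = ref.shape[0]
    axl = (np.arange(n) - n // 2) * 3.0
    d = np.sqrt(axl[:, None, None] ** 2 + axl[None, :, None] ** 2
                + axl[None, None, :] ** 2)
    w = d <= 1.1 * r_half
    g0 = ref.grid[w]
    g0 = g0 - g0.mean()
    n0 = np.linalg.norm(g0)
    best = -1.0
    center = ref.index_to_position(np.array(ref.shape) // 2)
    for R in make_orientation_grid(step_deg).matrices:
        if geodesic_angle_deg(np.eye(3), R) < 1.5 * step_deg:
            continue
        rot = rotate_map(ref, RigidTransform(R), center=center).grid[w]
        rot = rot - rot.mean()
        nr = np.linalg.norm(rot)
        if nr > 0:
            best = max(best, float(g0 @ rot / (n0 * nr)))
    return best


def make_pearl_model(spec: PearlSpec, max_attempts: int = 30) -> PearlModel:
    """Draw a pearl, calibrate its half-max volume, reject self-symmetric ones.

    A candidate is rejected (and redrawn deterministically) unless its best
    non-identity rotational self-correlation, measured under the pearl's
    own spherical mask, stays below 0.9.
    """
    k, sigma = spec.n_lobes, spec.lobe_sigma
    # The domain is fan-shaped: thin along the spine (x in its own frame,
    # full thickness ≈ two link translations so that same-side neighbours
    # tile rather than interpenetrate), spanning a wide angular sector away
    # from the spine (+z).  This is the only family of shapes for which ten
    # 45,000 Å³ domains can repeat every 11.5 Å along a spine without
    # occupying each other's volume: the horn cross-section they must fill
    # is ≈ 4,300 Å², i.e. a ~35 Å-radius sector per domain.
    for attempt in range(max_attempts):
        rng = np.random.default_rng(int(spec.seed) * 1000 + attempt)
        x = rng.uniform(-8.0, 8.0, size=k)
        theta = rng.uniform(-1.3, 1.3, size=k)   # sector about +z
        rho = 4.0 + 22.0 * rng.uniform(0, 1, size=k) ** 0.7
        centers = np.stack([x, rho * np.sin(theta), rho * np.cos(theta)],
                           axis=1)
        centers -= centers.mean(axis=0)
        amps = rng.uniform(0.7, 1.0, size=k)
        model = PearlModel(centers, np.full(k, float(sigma)), amps, spec)
        # spatial rescale: with the saturated density the half-max volume
        # scales exactly with the cube of the coordinate scale
        for _ in range(6):
            v = _half_max_volume(model)
            f = (spec.pearl_volume / v) ** (1.0 / 3.0)
            model = PearlModel(model.centers * f, model.sigmas * f, amps, spec)
            if abs(f - 1.0) < 5e-3:
                break
        # centre on the density centroid so planted positions are centres
        ref = model.render(1.5, int(np.ceil(2 * model.extent / 1.5)) | 1)
        w = ref.grid / ref.grid.sum()
        idx = np.indices(ref.shape)
        com = np.array([float((idx[a] * w).sum()) for a in range(3)])
        shift = (com - np.array(ref.shape) // 2) * ref.voxel_size
        model = PearlModel(model.centers - shift, model.sigmas, amps, spec)
        if _self_correlation(model) < 0.9:
            return model
    raise RuntimeError("could not draw an asymmetric pearl (self-correlation ≥ 0.9)")


def build_pearl(spec: PearlSpec, voxel_size: float = 3.0,
                box: int | None = None) -> DensityMap:
    """Render the canonical pearl motif, centred, deterministic per seed."""
    model = make_pearl_model(spec)
    if box is None:
        box = int(np.ceil(2 * model.extent / voxel_size)) | 1
    return model.render(voxel_size, box)


# ---------------------------------------------------------------------------
# Spike assembly
# ---------------------------------------------------------------------------

def _trunc_normal(rng, sd: float, size=None):
    return np.clip(rng.normal(scale=sd, size=size) if sd > 0 else
                   np.zeros(size if size else ()), -2 * sd, 2 * sd)


def _spine_frames(horn: HornSpec, c2_center: np.ndarray, seed: int):
    """Planted frames for horn 0: centres c_i, rotations R_i, per-link values.

    The spine is a polyline stepped along the local tangent; consecutive
    frames are related *exactly* by the planted per-link rotation about /
    translation along the local spine axis (the nominal values plus the
    recorded jitter).
    """
    ds = horn.inter_translation
    straight, arc = horn.spine_straight, horn.spine_arc

    def tangent(s: float) -> np.ndarray:
        if s <= straight:
            return np.array([1.0, 0.0, 0.0])
        th = min((s - straight) / arc, np.pi / 2)
        return np.array([np.cos(th), 0.0, np.sin(th)])

    rng = np.random.default_rng(seed)
    # fixed attachment register: the pearl's outward axis (+z in its frame)
    # points along the first lateral direction (+y) and its thin axis along
    # the spine tangent, so the fans tile; the planted 180° flips alternate
    # them between the two sides
    R = RigidTransform.about_axis([1.0, 0.0, 0.0], -90.0).rotation
    p = c2_center + np.array([horn.start_radius, 0.0, -15.0])
    centers, rotations, axes, link_angles, link_trans = [], [], [], [], []
    spine_pts = []
    s = 0.0
    for i in range(horn.n_domains):
        n0 = np.array([0.0, (1.0 if i % 2 == 0 else -1.0), 0.0])
        a_here = tangent(s + ds / 2.0)
        phi = float(_trunc_normal(rng, horn.zigzag_azimuth_jitter))
        e = RigidTransform.about_axis(a_here, phi).rotation @ n0
        r_i = max(2.0, horn.zigzag_offset
                  + float(_trunc_normal(rng, horn.zigzag_radial_jitter)))
        centers.append(p + r_i * e)
        rotations.append(R)
        axes.append(a_here)
        ang = horn.inter_rotation + float(
            _trunc_normal(rng, horn.link_rotation_jitter))
        step = ds + float(_trunc_normal(rng, horn.link_translation_jitter))
        link_angles.append(ang)
        link_trans.append(step)
        R = RigidTransform.about_axis(a_here, ang).rotation @ R
        spine_pts.append(p.copy())
        p = p + step * a_here
        s += ds
    spine_pts.append(p.copy())
    return (np.array(centers), rotations, np.array(axes),
            np.array(link_angles[:-1]), np.array(link_trans[:-1]),
            np.array(spine_pts))


def _add_tube(grid, ax, a, b, sigma, amp) -> None:
    """Accumulate a Gaussian tube of width sigma along segment a→b."""
    lo = np.minimum(a, b) - 4 * sigma
    hi = np.maximum(a, b) + 4 * sigma
    i0 = np.maximum(0, np.searchsorted(ax, lo)).astype(int)
    i1 = np.minimum(len(ax) - 1, np.searchsorted(ax, hi)).astype(int)
    sub = np.stack(np.meshgrid(ax[i0[0]:i1[0] + 1], ax[i0[1]:i1[1] + 1],
                               ax[i0[2]:i1[2] + 1], indexing="ij"), axis=-1)
    ab = b - a
    L2 = float(ab @ ab)
    t = np.clip(((sub - a) @ ab) / max(L2, 1e-12), 0.0, 1.0)
    d2 = ((sub - a - t[..., None] * ab) ** 2).sum(axis=-1)
    grid[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1] += \
        amp * np.exp(-0.5 * d2 / sigma**2)


def build_spike(
    horn: HornSpec = HornSpec(),
    pearl: PearlSpec = PearlSpec(),
    box: int = 300,
    voxel_size: float = 1.35,
    stalk_amplitude: float = 0.5,
) -> tuple[DensityMap, GroundTruth]:
    """Render a noiseless C2-symmetric two-horn spike with ground truth.

    The C2 axis is z through the box centre; horn 1 is the exact lattice
    mirror of horn 0, so the map equals its own two-fold copy bit-for-bit.
    """
    model = make_pearl_model(pearl)
    n = int(box)
    origin = np.zeros(3)
    c2c = origin + (n - 1) / 2.0 * voxel_size * np.ones(3)
    centers, rotations, axes, link_angles, link_trans, spine_pts = \
        _spine_frames(horn, c2c, seed=pearl.seed + 77)

    lo = origin
    hi = origin + (n - 1) * voxel_size
    core = model.core_radius
    for i, c in enumerate(centers):
        if np.any(c - core < lo) or np.any(c + core > hi):
            raise ValueError(f"domain {i} of horn 0 does not fit in the box")

    grid = np.zeros((n, n, n))
    ax = origin[0] + np.arange(n) * voxel_size
    # the rope-like spine the pearls attach to: a Gaussian tube along the
    # (jittered) spine polyline; it breaks the pseudo-dihedral symmetry a
    # bare zig-zag chain of domains would have
    if horn.spine_amplitude > 0:
        peak_amp = min(1.0, model.cap)
        for a_pt, b_pt in zip(spine_pts[:-1], spine_pts[1:]):
            _add_tube(grid, ax, a_pt, b_pt, horn.spine_sigma,
                      horn.spine_amplitude * peak_amp)
        # connect the spine to the stalk top on the C2 axis
        _add_tube(grid, ax, c2c + np.array([0.0, 0.0, -15.0]), spine_pts[0],
                  horn.spine_sigma, horn.spine_amplitude * peak_amp)
    for c, R in zip(centers, rotations):
        i0 = np.maximum(0, np.floor((c - model.extent) / voxel_size).astype(int))
        i1 = np.minimum(n - 1, np.ceil((c + model.extent) / voxel_size).astype(int))
        sub = np.stack(np.meshgrid(ax[i0[0]:i1[0] + 1], ax[i0[1]:i1[1] + 1],
                                   ax[i0[2]:i1[2] + 1], indexing="ij"), axis=-1)
        local = (sub - c) @ R  # R⁻¹(p − c) row-wise
        grid[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1] += \
            model.density(local)

    # stalk: a Gaussian tube on the C2 axis below the spine start
    xx = ax - c2c[0]
    yy = ax - c2c[1]
    zz = ax - c2c[2]
    r2 = xx[:, None] ** 2 + yy[None, :] ** 2
    ztop = -15.0
    zbot = ztop - horn.stalk_length
    zmask = np.exp(-0.5 * (np.clip(zbot - zz, 0, None) ** 2
                           + np.clip(zz - ztop, 0, None) ** 2) / 6.0**2)
    stalk = stalk_amplitude * np.exp(-0.5 * r2 / 6.0**2)[:, :, None] * zmask[None, None, :]
    stalk = 0.5 * (stalk + stalk[::-1, ::-1, :])  # exact C2, guards rounding
    grid += stalk

    full = grid + grid[::-1, ::-1, :]  # add the mirrored horn: exact C2
    dmap = DensityMap(full, voxel_size, origin)

    C = np.diag([-1.0, -1.0, 1.0])
    entries = [GroundTruthEntry(0, i, RigidTransform(R, c))
               for i, (c, R) in enumerate(zip(centers, rotations))]
    entries += [
        GroundTruthEntry(1, i, RigidTransform(C @ R, c2c + C @ (c - c2c)))
        for i, (c, R) in enumerate(zip(centers, rotations))
    ]
    gt = GroundTruth(
        entries, voxel_size, (n, n, n), c2c,
        params=dict(horn=asdict(horn), pearl=asdict(pearl), box=n,
                    voxel_size=voxel_size, link_axes=axes.tolist(),
                    link_angles_deg=link_angles.tolist(),
                    link_translations_A=link_trans.tolist()),
    )
    return dmap, gt


def add_noise_and_blur(
    dmap: DensityMap, snr: float | None, B: float, seed: int = 0,
) -> DensityMap:
    """Add white Gaussian noise at a target SNR, then apply a B-factor blur.

    ``snr`` is the ratio of signal variance to noise variance measured inside
    the molecular region (density above 5% of the maximum) *before* the blur;
    ``snr=None`` (or inf) disables the noise.  Deterministic per seed.
    """
    g = dmap.grid.astype(float)
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        region = g > 0.05 * g.max()
        sigma = float(np.sqrt(g[region].var() / snr))
        rng = np.random.default_rng(seed)
        g = g + rng.normal(scale=sigma, size=g.shape)
    out = dmap.like(g)
    if B != 0:
        out = bfactor_filter(out, B)
    return out
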