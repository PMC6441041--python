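"""Sub-volume extraction, averaging, data-driven mask building and
pairwise local refinement.

This stage turns first-pass correlation peaks into a better motif: the map
is resampled into the common motif frame at every peak, the best-correlated
copies are averaged, the average is segmented by the watershed method, a
soft mask is grown from selected segments (sphere smoothing + volume
calibration), and the search is repeated with the refined motif/mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
import scipy.fft as sfft

from .maps import (DensityMap, SoftMask, sphere_smooth_mask,
                   threshold_for_volume)
from .search import (OrientationSet, Peak, PeakList, search_peaks,
                     make_orientation_grid)
from .transforms import RigidTransform, Rotation

__all__ = [
    "SubVolumeSet",
    "extract_subvolumes",
    "average_top_k",
    "watershed_segments",
    "build_motif_mask",
    "refine_search",
    "local_refine_pair",
    "interpolate_to_optimum",
]


@dataclass
class SubVolumeSet:
    """Map sub-volumes resampled onto a common motif-frame lattice."""

    volumes: np.ndarray        # (n_members, nx, ny, nz)
    validity: np.ndarray       # same shape, 1 where sampled inside the map
    transforms: list[RigidTransform]
    scores: list[float]
    voxel_size: float
    flagged: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return self.volumes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    def member(self, i: int) -> DensityMap:
        n = np.array(self.shape)
        return DensityMap(self.volumes[i], self.voxel_size,
                          origin=-(n // 2) * self.voxel_size)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for i, (t, s, f) in enumerate(zip(self.transforms, self.scores,
                                          self.flagged)):
            rot, tilt, psi = t.euler_deg
            x, y, z = t.translation
            rows.append(dict(member=i, x=x, y=y, z=z, rot=rot, tilt=tilt,
                             psi=psi, score=s, edge_flagged=f))
        return pd.DataFrame(rows)


def extract_subvolumes(dmap: DensityMap, peaks, box) -> SubVolumeSet:
    """Resample the map into the motif frame at every peak transform.

    ``box`` is the motif box shape (voxels).  The sub-volume voxel ``n//2``
    lands on the peak position; out-of-map voxels are zero-filled and
    recorded in the validity mask (members touching the edge are flagged,
    never dropped).
    """
    plist = peaks.cluster if isinstance(peaks, PeakList) else list(peaks)
    box = np.array([box] * 3 if np.isscalar(box) else box, dtype=int)
    vols = np.zeros((len(plist), *box))
    vals = np.zeros_like(vols)
    flags = []
    g = dmap.grid.astype(float)
    ones = np.ones_like(g)
    for i, p in enumerate(plist):
        R = p.transform.rotation
        # output index j -> map index: (R·(j − n//2)·v + t − origin)/v
        offset = dmap.position_to_index(p.transform.translation) \
            - R @ (box // 2).astype(float)
        vols[i] = ndimage.affine_transform(g, R, offset=offset, order=1,
                                           output_shape=tuple(box),
                                           mode="constant", cval=0.0)
        vals[i] = ndimage.affine_transform(ones, R, offset=offset, order=1,
                                           output_shape=tuple(box),
                                           mode="constant", cval=0.0)
        flags.append(bool(np.any(vals[i] < 1.0 - 1e-6)))
    return SubVolumeSet(vols, vals, [p.transform for p in plist],
                        [p.score for p in plist], dmap.voxel_size, flags)


def reference_consistency(subs: SubVolumeSet, reference: int | None = None,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Plain Pearson CC of every member against a reference member.

    Members whose first-pass orientation is wrong (e.g. flipped by the
    chain's pseudo-symmetry) extract into a different frame and correlate
    poorly with the reference at identity alignment, so this is a cheap
    consensus filter before averaging.  ``reference`` defaults to the
    highest-scoring member.
    """
    if reference is None:
        reference = int(np.argmax(subs.scores))
    w = np.ones(subs.shape) if mask is None else np.asarray(
        mask.grid if isinstance(mask, SoftMask) else mask, float)
    ref = subs.volumes[reference]
    W = w.sum()
    rm = (w * ref).sum() / W
    r0 = w * (ref - rm)
    rn = np.sqrt((w * (ref - rm) ** 2).sum())
    out = np.empty(len(subs))
    for i in range(len(subs)):
        g = subs.volumes[i]
        gm = (w * g).sum() / W
        gn = np.sqrt((w * (g - gm) ** 2).sum())
        out[i] = float((r0 * g).sum() / (rn * gn)) if rn > 0 and gn > 0 else 0.0
    return out


def average_top_k(subs: SubVolumeSet, k: int = 8,
                  by: str = "score") -> DensityMap:
    """Validity-weighted mean of the k best sub-volumes.

    ``by='score'`` ranks by search score; ``by='consistency'`` ranks by
    plain correlation to the best-scoring member, which rejects copies
    extracted in a wrong (pseudo-symmetric) orientation.
    """
    if k <= 0:
        raise ValueError("k must be ≥ 1")
    if k > len(subs):
        raise ValueError(f"k={k} exceeds the {len(subs)} members")
    key = np.asarray(subs.scores) if by == "score" \
        else reference_consistency(subs)
    order = np.argsort(-key, kind="stable")[:k]
    return average_members(subs, order)


def average_members(subs: SubVolumeSet, members) -> DensityMap:
    """Validity-weighted mean over an explicit member selection."""
    members = np.asarray(members, dtype=int)
    wsum = subs.validity[members].sum(axis=0)
    num = (subs.volumes[members] * subs.validity[members]).sum(axis=0)
    avg = np.divide(num, wsum, out=np.zeros_like(num), where=wsum > 1e-9)
    n = np.array(subs.shape)
    return DensityMap(avg, subs.voxel_size, origin=-(n // 2) * subs.voxel_size)


def watershed_segments(avg: DensityMap, level: float) -> np.ndarray:
    """Watershed segmentation of the density above ``level``.

    Catchment basins of the negated density are grown from its local maxima;
    returns an integer label volume (0 = below level)."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    g = np.asarray(avg.grid, dtype=float)
    region = g > level
    if not region.any():
        return np.zeros(g.shape, dtype=np.int32)
    coords = peak_local_max(g, labels=region, min_distance=2,
                            exclude_border=False)
    markers = np.zeros(g.shape, dtype=np.int32)
    for i, c in enumerate(coords, start=1):
        markers[tuple(c)] = i
    if markers.max() == 0:
        lab, _ = ndimage.label(region)
        return lab.astype(np.int32)
    return watershed(-g, markers=markers, mask=region).astype(np.int32)


def build_motif_mask(
    avg: DensityMap,
    segments: np.ndarray,
    seed_point=None,
    segment_ids=None,
    smooth_radius: float = 10.0,
    mask_volume: float = 60_000.0,
    seed_radius: float = 2.0,
) -> SoftMask:
    """Soft molecular-boundary mask from selected watershed segments.

    Segments overlapping a small ball (``seed_radius`` voxels) around
    ``seed_point`` — or the explicit ``segment_ids`` — are united, smoothed
    by convolution with a 10 Å sphere, and thresholded so the enclosed
    volume equals ``mask_volume`` (Å³); values below the threshold are
    zeroed, values above are kept soft.
    """
    if segment_ids is None:
        if seed_point is None:
            raise ValueError("give seed_point or segment_ids")
        seed = np.asarray(seed_point, dtype=int)
        if np.any(seed < 0) or np.any(seed >= np.array(avg.shape)):
            raise ValueError(f"seed_point {seed.tolist()} outside the box")
        idx = np.indices(avg.shape)
        ball = ((idx - seed.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) \
            <= seed_radius**2
        segment_ids = sorted(set(np.unique(segments[ball])) - {0})
        if not segment_ids:
            avail = sorted(set(np.unique(segments)) - {0})
            sizes = {int(s): int((segments == s).sum()) for s in avail}
            raise ValueError(
                f"no segment under seed {seed.tolist()}; available segments "
                f"(id: voxels) = {sizes}"
            )
    binary = np.isin(segments, list(segment_ids)).astype(float)
    mask = SoftMask(binary, avg.voxel_size, avg.origin.copy(),
                    {"segments": [int(s) for s in segment_ids]})
    smoothed = sphere_smooth_mask(mask, smooth_radius)
    support = smoothed.enclosed_volume()
    if support < mask_volume:
        raise ValueError(
            f"smoothed segment support ({support:.0f} Å³) is below the "
            f"requested mask volume ({mask_volume:.0f} Å³)"
        )
    tau = threshold_for_volume(smoothed, mask_volume)
    out = np.where(smoothed.grid >= tau, smoothed.grid, 0.0)
    # ties at exactly tau (common after ball convolution of a binary mask)
    # would overshoot the target volume; trim the excess tied voxels in
    # deterministic lexicographic order
    n_target = int(np.ceil(mask_volume / avg.voxel_size**3))
    excess = int(np.count_nonzero(out > 0)) - n_target
    if excess > 0:
        tied = np.argwhere(smoothed.grid == tau)
        for idx in map(tuple, tied[:excess]):
            out[idx] = 0.0
    prov = dict(smoothed.provenance)
    prov.update(threshold=float(tau), mask_volume_A3=float(mask_volume))
    return SoftMask(out, avg.voxel_size, avg.origin.copy(), prov)


def refine_search(
    dmap: DensityMap,
    avg_motif: DensityMap,
    refined_mask: SoftMask,
    grid: OrientationSet,
    min_separation: float,
    **kwargs,
) -> PeakList:
    """Repeat the correlation search with the refined motif and mask."""
    return search_peaks(dmap, avg_motif, refined_mask, grid, min_separation,
                        **kwargs)


# ---------------------------------------------------------------------------
# Pairwise local refinement
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _local_rotation_ball(step_deg: float, max_deg: float) -> np.ndarray:
    """Rotations within ``max_deg`` of identity, ~``step_deg`` apart."""
    mats = [np.eye(3)]
    beta = step_deg
    while beta <= max_deg + 1e-9:
        n_axes = max(6, int(np.ceil(4 * np.pi / (step_deg / beta) ** 2)))
        for u in _fibonacci_sphere(n_axes):
            mats.append(Rotation.from_rotvec(np.radians(beta) * u).as_matrix())
        beta += step_deg
    return np.array(mats)


def _pair_cc_oneway(A, B, w, rotations, max_shift):
    """max over rotations/shifts of masked CC(A, shift(rot(B))), static mask.

    The cyclic cross-correlation ``irfftn(F(w)·conj(F(B)))[s] = Σ_y
    w(y)·B(y−s)`` indexes shifts directly, with negative shifts wrapped; the
    search is restricted to |s| ≤ max_shift per axis.
    """
    shape = A.shape
    wa = w * A
    Fw = sfft.rfftn(w)
    FwA = sfft.rfftn(wa)
    W = float(w.sum())
    SA = float(wa.sum())
    VA = float((w * A * A).sum() - SA**2 / W)
    shift_vals = np.r_[np.arange(0, max_shift + 1), np.arange(-max_shift, 0)]
    windows = [(shift_vals % shape[a]).astype(int) for a in range(3)]
    best = (-np.inf, 0, (0, 0, 0))
    if VA <= 1e-12:
        return best
    c = np.array([s // 2 for s in B.shape], dtype=float)
    ix = np.ix_(*windows)
    for ri, R in enumerate(rotations):
        Rt = R.T
        Brot = ndimage.affine_transform(B, Rt, offset=c - Rt @ c, order=1)
        FB = sfft.rfftn(Brot)
        FB2 = sfft.rfftn(Brot * Brot)
        S1 = sfft.irfftn(Fw * np.conj(FB), s=shape)[ix]
        S2 = sfft.irfftn(Fw * np.conj(FB2), s=shape)[ix]
        Cc = sfft.irfftn(FwA * np.conj(FB), s=shape)[ix]
        varB = S2 - S1 * S1 / W
        num = Cc - SA * S1 / W
        good = varB > 1e-12
        cc = np.where(good, num / np.sqrt(np.where(good, varB, 1.0) * VA),
                      -np.inf)
        j = np.unravel_index(int(np.argmax(cc)), cc.shape)
        s = float(cc[j])
        if s > best[0]:
            best = (s, ri, tuple(int(shift_vals[a]) for a in j))
    return best


def local_refine_pair(
    volA,
    volB,
    mask: np.ndarray | None = None,
    angular_step: float = 4.0,
    max_excursion: float = 8.0,
    max_shift: int = 5,
    voxel_size: float | None = None,
):
    """Optimal local superposition of two same-lattice sub-volumes.

    Exhausts rotations within ``max_excursion`` degrees of identity in
    ``angular_step`` steps (plus identity), with the translational search
    done by FFT correlation at each rotation.  Both orderings are evaluated
    and the better mapped back, so the result is symmetric in its arguments.
    Returns ``(transform, cc)`` where ``transform`` maps B onto A (rotation
    about the box-centre voxel, translation in Å).
    """
    A = np.asarray(volA.grid if isinstance(volA, DensityMap) else volA, float)
    B = np.asarray(volB.grid if isinstance(volB, DensityMap) else volB, float)
    if A.shape != B.shape:
        raise ValueError("volumes must share a lattice")
    if voxel_size is None:
        voxel_size = volA.voxel_size if isinstance(volA, DensityMap) else 1.0
    w = np.ones_like(A) if mask is None else np.asarray(
        mask.grid if isinstance(mask, SoftMask) else mask, float)
    rotations = _local_rotation_ball(angular_step, max_excursion)
    sAB, riAB, shAB = _pair_cc_oneway(A, B, w, rotations, max_shift)
    sBA, riBA, shBA = _pair_cc_oneway(B, A, w, rotations, max_shift)
    if sAB >= sBA:
        R = rotations[riAB]
        t = np.array(shAB, float) * voxel_size
        T = RigidTransform(R, t)
        cc = sAB
    else:
        T = RigidTransform(rotations[riBA],
                           np.array(shBA, float) * voxel_size).inverse()
        cc = sBA
    return T, float(min(cc, 1.0))


# ---------------------------------------------------------------------------
# Bounded continuous interpolation of a fit (off by default in the search)
# ---------------------------------------------------------------------------

def interpolate_to_optimum(
    dmap: DensityMap,
    motif: DensityMap,
    mask: SoftMask,
    peak: Peak,
    max_rot_deg: float = 6.0,
    max_shift_vox: float = 1.0,
) -> Peak:
    """Continuous local optimisation of one peak, bounded to ≤6° and ≤1 voxel.

    The masked correlation is evaluated by sampling the map at the
    transformed motif lattice (trilinear), and optimised over a 6-vector
    (rotation-vector perturbation in degrees, shift in voxels) with Powell's
    method under box bounds.
    """
    from scipy.optimize import minimize

    n = np.array(motif.shape)
    jj = np.indices(motif.shape).reshape(3, -1).T - n // 2
    u = jj * motif.voxel_size
    m = motif.grid.ravel()
    w = mask.grid.ravel()
    W = w.sum()
    mu = (w * m).sum() / W
    k = w * (m - mu)
    Vm = (w * (m - mu) ** 2).sum()
    g = dmap.grid.astype(float)
    R0 = peak.transform.rotation
    t0 = peak.transform.translation

    def negcc(x):
        dR = Rotation.from_rotvec(np.radians(x[:3])).as_matrix()
        R = dR @ R0
        t = t0 + x[3:] * dmap.voxel_size
        pts = u @ R.T + t
        idx = (pts - dmap.origin).T / dmap.voxel_size
        vals = ndimage.map_coordinates(g, idx, order=1, mode="constant")
        S1 = (w * vals).sum()
        S2 = (w * vals * vals).sum()
        varM = S2 - S1 * S1 / W
        if varM <= 1e-12:
            return 0.0
        return -float((k * vals).sum() / np.sqrt(varM * Vm))

    res = minimize(negcc, np.zeros(6), method="Powell",
                   bounds=[(-max_rot_deg, max_rot_deg)] * 3
                          + [(-max_shift_vox, max_shift_vox)] * 3,
                   options=dict(xtol=1e-2, ftol=1e-6, maxiter=3))
    x = res.x if -res.fun >= peak.score else np.zeros(6)
    dR = Rotation.from_rotvec(np.radians(x[:3])).as_matrix()
    return Peak(RigidTransform(dR @ R0, t0 + x[3:] * dmap.voxel_size),
                float(max(-res.fun, peak.score)), peak.rank, peak.voxel,
                peak.orbit_id)
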