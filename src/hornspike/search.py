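"""Masked local cross-correlation search of a density motif against a map.

The score at translation t and rotation R is the Pearson correlation between
the R-rotated motif and the map, computed under the R-rotated soft mask
centred at t (mask-weighted means and variances).  All translations are
evaluated at once by FFT: with kernels k = w·(m − μ_m), w and the map
transforms F(M), F(M²),

    cov(t)   = Σ_x k(x)·M(t+x)
    var_M(t) = Σ_x w(x)·M²(t+x) − (Σ_x w(x)·M(t+x))² / W
    score(t) = cov / sqrt(var_M · V_m)

which is identical (to float rounding) to the direct-sum definition.  The
rotation grid is a near-uniform SO(3) sampling; peaks are picked by greedy
non-maximum suppression and a gap rule that isolates the leading cluster of
scores from the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy import ndimage

from .maps import DensityMap, SoftMask, downsample_map
from .transforms import RigidTransform, euler_to_matrix, geodesic_angle_deg

__all__ = [
    "OrientationSet",
    "Peak",
    "PeakList",
    "make_orientation_grid",
    "local_correlation",
    "search",
    "search_peaks",
    "find_peaks",
    "symmetry_reduce",
    "UndefinedScoreError",
]


class UndefinedScoreError(ValueError):
    """The mask carries (almost) no weight, so the correlation is undefined."""


# ---------------------------------------------------------------------------
# Orientation sampling
# ---------------------------------------------------------------------------

@dataclass
class OrientationSet:
    """A sampled set of rotations with near-uniform SO(3) coverage."""

    matrices: np.ndarray  # (N, 3, 3)
    eulers: np.ndarray    # (N, 3) ZYZ degrees
    angular_step: float
    symmetry: str = "C1"

    def __len__(self) -> int:
        return len(self.matrices)

    def nearest(self, R: np.ndarray) -> tuple[int, float]:
        """Index of and geodesic distance (deg) to the nearest member."""
        c = np.einsum("nij,ij->n", self.matrices, np.asarray(R))
        ang = np.degrees(np.arccos(np.clip((c - 1.0) / 2.0, -1.0, 1.0)))
        i = int(np.argmin(ang))
        return i, float(ang[i])


def _cyclic_order(symmetry: str) -> int:
    s = symmetry.strip().upper()
    if not (len(s) >= 2 and s[0] == "C" and s[1:].isdigit() and int(s[1:]) >= 1):
        raise ValueError(
            f"unknown symmetry label {symmetry!r}; supported: C1, C2, C3, ..."
        )
    return int(s[1:])


def make_orientation_grid(angular_step: float, symmetry: str = "C1") -> OrientationSet:
    """Near-uniform SO(3) grid at a given angular step (degrees).

    Tilt rings are spaced by ``angular_step``; the in-ring azimuthal spacing
    is scaled by 1/sin(tilt) so the surface density of directions is uniform;
    the in-plane angle is sampled at the same step.  For a cyclic symmetry
    Cn (about z) the azimuth is restricted to one fundamental sector, leaving
    one representative per left-coset orbit.
    """
    if not 0 < angular_step <= 90:
        raise ValueError("angular_step must be in (0, 90] degrees")
    order = _cyclic_order(symmetry)
    sector = 360.0 / order
    n_psi = int(np.ceil(360.0 / angular_step))
    psis = np.arange(n_psi) * 360.0 / n_psi
    n_tilt = int(np.ceil(180.0 / angular_step))
    eulers: list[tuple[float, float, float]] = []
    for it in range(n_tilt + 1):
        tilt = min(180.0, it * 180.0 / n_tilt)
        if tilt in (0.0, 180.0):
            # rot degenerates with psi; symmetry acts on the free angle
            for psi in psis[psis < sector - 1e-9]:
                eulers.append((0.0, tilt, float(psi)))
            continue
        n_rot = max(1, int(np.ceil(360.0 * np.sin(np.radians(tilt)) / angular_step)))
        rots = np.arange(n_rot) * 360.0 / n_rot
        for rot in rots[rots < sector - 1e-9]:
            for psi in psis:
                eulers.append((float(rot), float(tilt), float(psi)))
    eul = np.array(eulers)
    mats = np.array([euler_to_matrix(*e) for e in eul])
    return OrientationSet(mats, eul, float(angular_step), symmetry.strip().upper())


# ---------------------------------------------------------------------------
# Masked local correlation (FFT over all translations)
# ---------------------------------------------------------------------------

@dataclass
class _MapSpectra:
    """Precomputed map transforms shared across rotations."""

    F: np.ndarray
    F2: np.ndarray
    shape: tuple[int, int, int]
    variance: float


def _prepare_map(grid: np.ndarray) -> _MapSpectra:
    g = np.ascontiguousarray(grid, dtype=float)
    return _MapSpectra(sfft.rfftn(g), sfft.rfftn(g * g), g.shape, float(g.var()))


def _rotate_kernels(motif: np.ndarray, mask: np.ndarray, R: np.ndarray):
    """Rotate motif and mask together about the anchor voxel n//2 (trilinear)."""
    stack = np.stack([motif.astype(float), mask.astype(float)])
    c = np.array([s // 2 for s in motif.shape], dtype=float)
    Rt = np.asarray(R).T
    M4 = np.zeros((4, 4))
    M4[0, 0] = 1.0
    M4[1:, 1:] = Rt
    offset = np.concatenate(([0.0], c - Rt @ c))
    out = ndimage.affine_transform(stack, M4, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    return out[0], np.clip(out[1], 0.0, 1.0)


def _kernel_moments(m: np.ndarray, w: np.ndarray):
    W = float(w.sum())
    if W < 1e-9:
        raise UndefinedScoreError("mask weight is ~0 under this rotation")
    mu = float((w * m).sum() / W)
    k = w * (m - mu)
    Vm = float((w * (m - mu) ** 2).sum())
    return W, k, Vm


def _corr_terms(spec: _MapSpectra, kernel: np.ndarray):
    """Cyclic cross-correlation Σ_x kernel(x)·M(x+t) for all t, via FFT."""
    pad = np.zeros(spec.shape)
    sl = tuple(slice(0, s) for s in kernel.shape)
    pad[sl] = kernel
    return sfft.irfftn(np.conj(sfft.rfftn(pad)) * spec.F, s=spec.shape)


def local_correlation(
    dmap: DensityMap,
    motif: DensityMap,
    mask: SoftMask,
    R: np.ndarray | RigidTransform = None,
    *,
    variance_floor_rel: float = 1e-8,
    with_flags: bool = False,
    _spec: _MapSpectra | None = None,
):
    """Masked local Pearson correlation at every translation, one rotation.

    Returns a map-shaped score volume; the score at voxel v corresponds to
    the (rotated) motif anchored with its voxel n//2 at v.  Translations for
    which the motif box does not fit inside the map, or where the local map
    variance falls below ``variance_floor_rel``·var(map)·W, score 0 (the
    latter are flagged when ``with_flags``).
    """
    if R is None:
        R = np.eye(3)
    if isinstance(R, RigidTransform):
        R = R.rotation
    if abs(motif.voxel_size - dmap.voxel_size) > 1e-6 or \
            abs(mask.voxel_size - dmap.voxel_size) > 1e-6:
        raise ValueError("motif/mask voxel size must match the map")
    if motif.shape != mask.shape:
        raise ValueError("motif and mask must share one lattice")
    if any(ms > Ms for ms, Ms in zip(motif.shape, dmap.shape)):
        raise ValueError("motif box must fit inside the map")
    spec = _spec if _spec is not None else _prepare_map(dmap.grid)
    mrot, wrot = _rotate_kernels(motif.grid, mask.grid, R)
    W, k, Vm = _kernel_moments(mrot, wrot)
    scores, low = _score_volume(spec, wrot, k, W, Vm, variance_floor_rel)
    if with_flags:
        return scores, low
    return scores


def _score_volume(spec, w, k, W, Vm, variance_floor_rel):
    n = k.shape
    N = spec.shape
    sl = tuple(slice(0, s) for s in n)
    pad = np.zeros(N)
    pad[sl] = w
    Fw = sfft.rfftn(pad)
    S1 = sfft.irfftn(np.conj(Fw) * spec.F, s=N)
    S2 = sfft.irfftn(np.conj(Fw) * spec.F2, s=N)
    pad[...] = 0.0
    pad[sl] = k
    C = sfft.irfftn(np.conj(sfft.rfftn(pad)) * spec.F, s=N)
    varM = S2 - S1 * S1 / W
    floor = variance_floor_rel * spec.variance * W
    good = varM > floor
    denom = np.sqrt(np.where(good, varM, 1.0) * max(Vm, 1e-300))
    raw = np.where(good, C / denom, 0.0)
    if Vm <= 0:
        raw[...] = 0.0
        good[...] = False
    scores = np.zeros(N)
    valid = tuple(slice(0, N[a] - n[a] + 1) for a in range(3))
    shift = tuple(n[a] // 2 for a in range(3))
    dst = tuple(slice(shift[a], shift[a] + N[a] - n[a] + 1) for a in range(3))
    scores[dst] = np.clip(raw[valid], -1.0, 1.0)
    low = np.zeros(N, dtype=bool)
    low[dst] = ~good[valid]
    return scores, low


# ---------------------------------------------------------------------------
# 6D search
# ---------------------------------------------------------------------------

@dataclass
class ScoreField:
    """Best-over-rotations score volume plus the achieving rotation index."""

    scores: np.ndarray
    rot_index: np.ndarray
    grid: OrientationSet
    voxel_size: float
    origin: np.ndarray
    motif_shape: tuple[int, int, int]
    low_variance: np.ndarray | None = None

    def position_of(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, float) * self.voxel_size

    def rotation_of(self, idx) -> np.ndarray:
        return self.grid.matrices[int(self.rot_index[tuple(idx)])]


def search(
    dmap: DensityMap,
    motif: DensityMap,
    mask: SoftMask,
    grid: OrientationSet,
    *,
    variance_floor_rel: float = 1e-8,
) -> ScoreField:
    """Exhaustive 6D search: every grid rotation, every translation (FFT).

    Deterministic: for equal scores the lowest rotation index wins, so the
    result is independent of any parallel evaluation order.
    """
    spec = _prepare_map(dmap.grid)
    best = np.full(dmap.shape, -np.inf)
    argrot = np.zeros(dmap.shape, dtype=np.int32)
    anylow = np.zeros(dmap.shape, dtype=bool)
    for i, R in enumerate(grid.matrices):
        mrot, wrot = _rotate_kernels(motif.grid, mask.grid, R)
        W, k, Vm = _kernel_moments(mrot, wrot)
        sc, low = _score_volume(spec, wrot, k, W, Vm, variance_floor_rel)
        upd = sc > best
        best[upd] = sc[upd]
        argrot[upd] = i
        anylow |= low
    best[~np.isfinite(best)] = 0.0
    return ScoreField(best, argrot, grid, dmap.voxel_size, dmap.origin.copy(),
                      motif.shape, anylow)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    transform: RigidTransform
    score: float
    rank: int
    voxel: tuple[int, int, int] | None = None
    orbit_id: int = -1


@dataclass
class PeakList:
    """Ranked correlation peaks; the leading cluster is the significant set."""

    peaks: list[Peak]
    cluster_size: int
    sd_gap: float = 20.0
    min_separation: float = 0.0

    @property
    def cluster(self) -> list[Peak]:
        return self.peaks[: self.cluster_size]

    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.peaks])

    def positions(self) -> np.ndarray:
        return np.array([p.transform.translation for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.peaks:
            rot, tilt, psi = p.transform.euler_deg
            x, y, z = p.transform.translation
            rows.append(dict(index=p.rank, x=x, y=y, z=z, rot=rot, tilt=tilt,
                             psi=psi, score=p.score, orbit_id=p.orbit_id,
                             in_cluster=p.rank <= self.cluster_size))
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_star(self, path) -> None:
        from .startab import write_star_table

        df = self.to_frame().rename(columns={
            "index": "hsIndex", "x": "hsCoordinateX", "y": "hsCoordinateY",
            "z": "hsCoordinateZ", "rot": "rlnAngleRot", "tilt": "rlnAngleTilt",
            "psi": "rlnAnglePsi", "score": "hsScore", "orbit_id": "hsOrbitId",
            "in_cluster": "hsInCluster"})
        write_star_table(df, path, block="peaks")


def _leading_cluster_size(scores: np.ndarray, sd_gap: float) -> int:
    """Largest k ≥ 2 with mean(s₁..s_k) − s_{k+1} > sd_gap·sd(s₁..s_k)."""
    m = len(scores)
    for k in range(m - 1, 1, -1):
        top = scores[:k]
        sd = float(top.std(ddof=1))
        if float(top.mean()) - scores[k] > sd_gap * sd:
            return k
    return 0


def find_peaks(
    score_field,
    min_separation: float,
    n_max: int = 40,
    sd_gap: float = 20.0,
) -> PeakList:
    """Greedy non-maximum suppression plus the leading-cluster gap rule.

    Accepts a :class:`ScoreField` or a bare 3D array (unit voxel, zero
    origin, identity rotations).  ``min_separation`` is in Å.  Up to
    ``n_max`` peaks are retained in rank order; the reported cluster is the
    largest leading group whose mean exceeds the next peak's score by more
    than ``sd_gap`` sample standard deviations of the group.
    """
    if isinstance(score_field, ScoreField):
        vol = score_field.scores
        voxel = score_field.voxel_size
        origin = np.asarray(score_field.origin, float)
        get_R = lambda idx: score_field.rotation_of(idx)  # noqa: E731
        low = score_field.low_variance
    else:
        vol = np.asarray(score_field, dtype=float)
        voxel, origin = 1.0, np.zeros(3)
        get_R = lambda idx: np.eye(3)  # noqa: E731
        low = None
    flat = vol.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    sep_vox2 = (min_separation / voxel) ** 2
    accepted: list[tuple[int, int, int]] = []
    peaks: list[Peak] = []
    pos_arr = np.empty((0, 3))
    for lin in order:
        s = flat[lin]
        if not np.isfinite(s):
            continue
        idx = np.unravel_index(lin, vol.shape)
        if low is not None and low[idx]:
            continue
        if accepted:
            d2 = ((np.array(idx) - pos_arr) ** 2).sum(axis=1)
            if d2.min() < sep_vox2:
                continue
        accepted.append(idx)
        pos_arr = np.array(accepted, dtype=float)
        peaks.append(Peak(
            RigidTransform(get_R(idx), origin + np.array(idx, float) * voxel),
            float(s), len(peaks) + 1, tuple(int(i) for i in idx)))
        if len(peaks) >= n_max:
            break
    k = _leading_cluster_size(np.array([p.score for p in peaks]), sd_gap) \
        if len(peaks) >= 2 else 0
    return PeakList(peaks, k, sd_gap, min_separation)


# ---------------------------------------------------------------------------
# Two-stage (coarse + local exact) search returning peaks directly
# ---------------------------------------------------------------------------

def _downsample_mask(mask: SoftMask, factor: int) -> SoftMask:
    m = downsample_map(DensityMap(mask.grid, mask.voxel_size, mask.origin), factor)
    return SoftMask(np.clip(m.grid, 0, 1), m.voxel_size, m.origin, mask.provenance)


def _patch_scores(mapg, corner, pshape, w, k, W, Vm, floor):
    """Exact masked CC of one rotated kernel over a small translation window."""
    from numpy.lib.stride_tricks import sliding_window_view

    sl = tuple(slice(corner[a], corner[a] + pshape[a]) for a in range(3))
    P = mapg[sl]
    win = w.shape
    Wv = sliding_window_view(P, win)
    Wv2 = sliding_window_view(P * P, win)
    S1 = np.tensordot(Wv, w, axes=([3, 4, 5], [0, 1, 2]))
    S2 = np.tensordot(Wv2, w, axes=([3, 4, 5], [0, 1, 2]))
    C = np.tensordot(Wv, k, axes=([3, 4, 5], [0, 1, 2]))
    varM = S2 - S1 * S1 / W
    good = varM > floor
    sc = np.where(good, C / np.sqrt(np.where(good, varM, 1.0) * Vm), 0.0)
    return np.clip(sc, -1.0, 1.0)


def _polish_cell(dmap: DensityMap, motif: DensityMap, mask: SoftMask,
                 R0: np.ndarray, t0: np.ndarray,
                 max_rot_deg: float, max_shift_A: float):
    """Bounded continuous (rotation, translation) polish of one placement.

    Evaluates the masked correlation by sampling the map at the transformed
    motif lattice and maximises it with Powell's method inside a box of
    ``max_rot_deg`` (rotation-vector components) and ``max_shift_A``.
    Removes the score spread caused by grid quantisation, which would
    otherwise dominate the comparison between placements.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

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

    def negcc(x):
        dR = Rotation.from_rotvec(np.radians(x[:3])).as_matrix()
        pts = u @ (dR @ R0).T + t0 + x[3:]
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
                          + [(-max_shift_A, max_shift_A)] * 3,
                   options=dict(xtol=5e-2, ftol=1e-5, maxiter=2))
    x = res.x
    dR = Rotation.from_rotvec(np.radians(x[:3])).as_matrix()
    return dR @ R0, t0 + x[3:], float(-res.fun)


def search_peaks(
    dmap: DensityMap,
    motif: DensityMap,
    mask: SoftMask,
    grid: OrientationSet,
    min_separation: float,
    n_max: int = 40,
    sd_gap: float = 20.0,
    *,
    coarse_factor: int = 2,
    downsample: int = 2,
    n_candidates: int = 60,
    refine_radius: float | None = None,
    trans_window: int = 2,
    variance_floor_rel: float = 1e-8,
    polish: bool = True,
) -> PeakList:
    """Full-sampling peak search by a coarse FFT pass plus exact refinement.

    A full FFT search on a ``downsample``× coarser lattice with a
    ``coarse_factor``× coarser angular step proposes candidate translations;
    around each candidate every rotation of the *full* grid within
    ``refine_radius`` (default 1.5× the coarse step) of the coarse best, and
    every translation within ±``trans_window`` voxels, is scored exactly.
    With ``polish`` (default) each surviving candidate is then optimised
    continuously within one grid cell, so reported scores and transforms are
    free of the sampling-quantisation spread.
    """
    step = grid.angular_step
    if refine_radius is None:
        refine_radius = 1.5 * step * coarse_factor
    coarse_grid = make_orientation_grid(step * coarse_factor, grid.symmetry) \
        if coarse_factor > 1 else grid
    dmap_c = downsample_map(dmap, downsample)
    motif_c = downsample_map(motif, downsample)
    mask_c = _downsample_mask(mask, downsample)
    field_c = search(dmap_c, motif_c, mask_c, coarse_grid,
                     variance_floor_rel=variance_floor_rel)
    cand = find_peaks(field_c, min_separation, n_candidates, sd_gap)
    if not cand.peaks:
        return PeakList([], 0, sd_gap, min_separation)

    mapg = np.ascontiguousarray(dmap.grid, dtype=float)
    n = np.array(motif.shape)
    N = np.array(dmap.shape)
    floor = variance_floor_rel * float(mapg.var())
    T = trans_window
    # candidate full-res anchor voxels and coarse rotations
    cands = []
    for p in cand.peaks:
        v = np.rint(dmap.position_to_index(p.transform.translation)).astype(int)
        v = np.clip(v, n // 2, N - 1 - (n - n // 2 - 1))
        cands.append((tuple(v), p.transform.rotation))
    # fine rotations near each distinct coarse rotation
    fine = grid.matrices
    rot_lists = {}
    for _, Rc in cands:
        key = Rc.tobytes()
        if key in rot_lists:
            continue
        c = np.einsum("nij,ij->n", fine, Rc)
        ang = np.degrees(np.arccos(np.clip((c - 1.0) / 2.0, -1.0, 1.0)))
        rot_lists[key] = np.nonzero(ang <= refine_radius)[0]
    # group (candidate, rotation) work by rotation index
    by_rot: dict[int, list[int]] = {}
    for ci, (_, Rc) in enumerate(cands):
        for ri in rot_lists[Rc.tobytes()]:
            by_rot.setdefault(int(ri), []).append(ci)
    best = [(-np.inf, None, None) for _ in cands]
    for ri, cis in by_rot.items():
        mrot, wrot = _rotate_kernels(motif.grid, mask.grid, fine[ri])
        try:
            W, k, Vm = _kernel_moments(mrot, wrot)
        except UndefinedScoreError:
            continue
        if Vm <= 0:
            continue
        for ci in cis:
            v = np.array(cands[ci][0])
            corner = v - n // 2 - T
            lo_ok = np.maximum(corner, 0)
            hi_ok = np.minimum(corner + n + 2 * T, N)
            corner2 = lo_ok
            pshape = hi_ok - lo_ok
            if np.any(pshape < n):
                continue
            sc = _patch_scores(mapg, corner2, pshape, wrot, k, W, Vm, floor * W)
            j = np.unravel_index(int(np.argmax(sc)), sc.shape)
            s = float(sc[j])
            if s > best[ci][0]:
                anchor = corner2 + np.array(j) + n // 2
                best[ci] = (s, ri, tuple(int(a) for a in anchor))
    # optional continuous polish of each surviving candidate
    refined = [(s, ri, v) for (s, ri, v) in best if v is not None]
    if polish:
        polished = []
        for s, ri, v in refined:
            R1, t1, s1 = _polish_cell(
                dmap, motif, mask, fine[ri], dmap.index_to_position(v),
                max_rot_deg=0.75 * step, max_shift_A=1.5 * dmap.voxel_size)
            if s1 >= s:
                polished.append((s1, R1, t1, v))
            else:
                polished.append((s, fine[ri],
                                 dmap.index_to_position(v).astype(float), v))
        entries = [(s, R, t, v) for (s, R, t, v) in polished]
    else:
        entries = [(s, fine[ri], dmap.index_to_position(v).astype(float), v)
                   for (s, ri, v) in refined]
    # re-rank with NMS at full resolution
    entries.sort(key=lambda e: (-e[0], e[3]))
    sep2 = min_separation**2
    peaks: list[Peak] = []
    taken: list[np.ndarray] = []
    for s, R, t, v in entries:
        if any(((t - q) ** 2).sum() < sep2 for q in taken):
            continue
        taken.append(t)
        peaks.append(Peak(RigidTransform(R, t), s, len(peaks) + 1, v))
        if len(peaks) >= n_max:
            break
    k_sz = _leading_cluster_size(np.array([p.score for p in peaks]), sd_gap) \
        if len(peaks) >= 2 else 0
    return PeakList(peaks, k_sz, sd_gap, min_separation)


# ---------------------------------------------------------------------------
# Symmetry reduction of peak lists
# ---------------------------------------------------------------------------

@dataclass
class SymmetryReduction:
    unique: PeakList
    pairs: list[tuple[int, int]]       # indices into the input peak list
    unpaired: list[int]
    self_paired: list[int]


def symmetry_reduce(
    peaks: PeakList | list[Peak],
    axis_point,
    axis_dir=(0.0, 0.0, 1.0),
    tol: float = 3.0,
) -> SymmetryReduction:
    """Pair peaks with their two-fold images about a C2 axis.

    Each orbit keeps its higher-scoring member; peaks on the axis are
    self-paired and kept once; members without an image within ``tol`` Å are
    flagged unpaired (and kept).
    """
    plist = peaks.peaks if isinstance(peaks, PeakList) else list(peaks)
    src = peaks if isinstance(peaks, PeakList) else PeakList(plist, len(plist))
    c2 = RigidTransform.about_axis(np.asarray(axis_dir, float), 180.0)
    a = np.asarray(axis_point, float)
    pos = np.array([p.transform.translation for p in plist])
    img = (pos - a) @ c2.rotation.T + a
    used = np.zeros(len(plist), dtype=bool)
    pairs, unpaired, selfp = [], [], []
    rep_idx: list[int] = []
    for i in range(len(plist)):
        if used[i]:
            continue
        if np.linalg.norm(img[i] - pos[i]) <= tol:
            used[i] = True
            selfp.append(i)
            rep_idx.append(i)
            continue
        d = np.linalg.norm(pos - img[i], axis=1)
        d[used] = np.inf
        d[i] = np.inf
        j = int(np.argmin(d))
        if np.isfinite(d[j]) and d[j] <= tol:
            used[i] = used[j] = True
            pairs.append((i, j))
            rep_idx.append(i if plist[i].score >= plist[j].score else j)
        else:
            used[i] = True
            unpaired.append(i)
            rep_idx.append(i)
    rep_idx.sort(key=lambda i: -plist[i].score)
    oid = {}
    for o, (i, j) in enumerate(pairs):
        oid[i] = o
        oid[j] = o
    relabel = [
        Peak(plist[i].transform, plist[i].score, r + 1, plist[i].voxel,
             oid.get(i, -1))
        for r, i in enumerate(rep_idx)
    ]
    n_cluster = sum(1 for i in rep_idx if plist[i].rank <= src.cluster_size) \
        if src.cluster_size else len(relabel)
    uniq = PeakList(relabel, n_cluster, src.sd_gap, src.min_separation)
    return SymmetryReduction(uniq, pairs, unpaired, selfp)
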