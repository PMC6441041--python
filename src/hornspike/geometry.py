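"""Architecture of the spike from refined peaks: spine ordering, per-link
rigid decomposition, pairwise correlation statistics and composite rendering.

The decomposition turns consecutive peak transforms into the quantities the
architecture is described by: the rotation angle about the local spine axis
and the translation along it.  Because the domain centres zig-zag about the
spine, the local axis is estimated from the chain of consecutive-centre
mid-points, which lies on the spine itself for an alternating lateral
offset; raw displacement and window-smoothed variants are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .maps import DensityMap
from .refine import SubVolumeSet, local_refine_pair
from .search import Peak, PeakList
from .transforms import RigidTransform

__all__ = [
    "SpineChain",
    "CCMatrix",
    "assign_horns",
    "order_along_spine",
    "adjacent_transform_decomposition",
    "cc_statistics",
    "place_back",
    "AmbiguousChainError",
]


class AmbiguousChainError(ValueError):
    """Nearest-neighbour chaining found competing continuations."""


@dataclass
class SpineChain:
    """Ordered peak indices per horn, with per-link geometry once decomposed."""

    horns: list[list[int]]
    axes: list[np.ndarray] = field(default_factory=list)      # per link
    angles_deg: list[float] = field(default_factory=list)
    translations_A: list[float] = field(default_factory=list)
    link_horn: list[int] = field(default_factory=list)

    def terminal_indices(self) -> set[int]:
        """Peak indices of the two chain-end domains of each horn."""
        out: set[int] = set()
        for h in self.horns:
            out.update(h[:1] + h[-1:])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(horn=h, link=i, angle_deg=a, trans_A=t)
                for i, (h, a, t) in enumerate(
                    zip(self.link_horn, self.angles_deg, self.translations_A))]
        return pd.DataFrame(rows)


def assign_horns(positions: np.ndarray, axis_point, axis_dir=(0, 0, 1)):
    """Split peaks into the two horns of a C2 spike by side of the axis.

    Each position is projected perpendicular to the axis; the side of the
    first (top-ranked) peak defines horn 0.  Near-axis peaks (|⊥| < 1 Å)
    would be ambiguous and raise.
    """
    a = np.asarray(axis_point, float)
    d = np.asarray(axis_dir, float)
    d = d / np.linalg.norm(d)
    rel = positions - a
    perp = rel - np.outer(rel @ d, d)
    ref = perp[0]
    if np.linalg.norm(ref) < 1.0:
        raise ValueError("reference peak lies on the symmetry axis")
    side = perp @ ref
    if np.any(np.abs(side) < 1e-9):
        raise ValueError("peak exactly between horns; assign manually")
    return (side < 0).astype(int)


def order_along_spine(
    peaks,
    horn_of,
    start_reference=None,
    ambiguity_ratio: float = 1.05,
    method: str = "nearest",
) -> SpineChain:
    """Order the peaks of each horn from the stalk-proximal end outward.

    ``horn_of`` assigns each peak to a horn (0/1); ``start_reference`` (Å,
    default the centroid of all peaks) stands in for the stalk.  Two
    orderings are available:

    * ``"nearest"`` — greedy nearest-neighbour chain from the stalk-proximal
      peak.  If at any step the second-nearest continuation is within
      ``ambiguity_ratio`` of the nearest, an error lists the candidates.
      Correct for chains whose consecutive spacing is the smallest pairwise
      distance.
    * ``"radial"`` — sort by distance from the reference.  Robust for horns
      that grow monotonically away from the stalk even when the zig-zag
      makes same-side (next-nearest) domains closer to each other than
      consecutive ones.

    The result is independent of the input order.
    """
    plist = peaks.cluster if isinstance(peaks, PeakList) else list(peaks)
    pos = np.array([p.transform.translation for p in plist])
    horn_of = np.asarray(horn_of, int)
    if start_reference is None:
        start_reference = pos.mean(axis=0)
    ref = np.asarray(start_reference, float)
    if method not in ("nearest", "radial"):
        raise ValueError(f"unknown ordering method {method!r}")
    horns: list[list[int]] = []
    for h in sorted(set(horn_of.tolist())):
        members = np.nonzero(horn_of == h)[0]
        if len(members) < 2:
            horns.append(members.tolist())
            continue
        d0 = np.linalg.norm(pos[members] - ref, axis=1)
        if method == "radial":
            horns.append(members[np.lexsort((members, d0))].tolist())
            continue
        order_start = members[np.lexsort((members, d0))][0]
        chain = [int(order_start)]
        remaining = set(int(m) for m in members) - {int(order_start)}
        while remaining:
            cur = pos[chain[-1]]
            cand = sorted(remaining)
            d = np.linalg.norm(pos[cand] - cur, axis=1)
            o = np.argsort(d, kind="stable")
            if len(cand) > 1 and d[o[1]] < ambiguity_ratio * d[o[0]]:
                raise AmbiguousChainError(
                    f"ambiguous continuation after peak {chain[-1]}: "
                    f"candidates {cand[o[0]]} ({d[o[0]]:.2f} Å) and "
                    f"{cand[o[1]]} ({d[o[1]]:.2f} Å)"
                )
            nxt = int(cand[o[0]])
            chain.append(nxt)
            remaining.discard(nxt)
        horns.append(chain)
    return SpineChain(horns)


def _link_axes(centers: np.ndarray, method: str, window: int) -> np.ndarray:
    """Unit spine axis per link (between centres i and i+1)."""
    n = len(centers)
    if method == "midpoint":
        m = 0.5 * (centers[:-1] + centers[1:])
        axes = np.empty((n - 1, 3))
        for i in range(n - 1):
            lo, hi = max(0, i - 1), min(n - 2, i + 1)
            axes[i] = m[hi] - m[lo] if hi > lo else centers[i + 1] - centers[i]
    elif method == "displacement":
        disp = centers[1:] - centers[:-1]
        axes = np.empty_like(disp)
        for i in range(n - 1):
            lo, hi = max(0, i - window // 2), min(n - 1, i + 1 + window // 2)
            axes[i] = disp[lo:hi].sum(axis=0) if hi > lo else disp[i]
    else:
        raise ValueError(f"unknown axis method {method!r}")
    norms = np.linalg.norm(axes, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ValueError("zero displacement between consecutive domains")
    return axes / norms


def adjacent_transform_decomposition(
    chain: SpineChain,
    peaks,
    axis_method: str = "midpoint",
    window: int = 1,
) -> SpineChain:
    """Per-link (rotation angle about local axis, translation along it).

    For consecutive peaks the relative motion in the map frame is
    Δ = T_{i+1}∘T_i⁻¹; the reported angle is the twist of Δ's rotation about
    the local spine axis (folded into [0°, 180°]) and the translation is the
    centre-displacement component along that axis.  The axis is oriented
    with positive dot product along the ordered direction, making the
    translation positive; the decomposition is invariant under rigid motion
    of the whole map.
    """
    plist = peaks.cluster if isinstance(peaks, PeakList) else list(peaks)
    axes, angles, trans, link_horn = [], [], [], []
    for h, order in enumerate(chain.horns):
        centers = np.array([plist[i].transform.translation for i in order])
        if len(order) < 2:
            continue
        a = _link_axes(centers, axis_method, window)
        disp = centers[1:] - centers[:-1]
        flip = np.sign(np.einsum("ij,ij->i", a, disp))
        a = a * np.where(flip == 0, 1.0, flip)[:, None]
        for i in range(len(order) - 1):
            Ti = plist[order[i]].transform
            Tj = plist[order[i + 1]].transform
            delta = Tj @ Ti.inverse()
            angles.append(delta.twist_about_axis_deg(a[i]))
            trans.append(float(disp[i] @ a[i]))
            axes.append(a[i])
            link_horn.append(h)
    chain.axes = axes
    chain.angles_deg = angles
    chain.translations_A = trans
    chain.link_horn = link_horn
    return chain


# ---------------------------------------------------------------------------
# Pairwise correlation statistics
# ---------------------------------------------------------------------------

@dataclass
class CCMatrix:
    """Symmetric pairwise local-correlation matrix with summary statistics."""

    matrix: np.ndarray
    excluded: list[int]
    mean: float
    sd: float
    min: float
    max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.4f")


def cc_statistics(
    subs: SubVolumeSet,
    exclude=(),
    mask=None,
    angular_step: float = 4.0,
    max_excursion: float = 8.0,
) -> CCMatrix:
    """All-vs-all locally refined correlation coefficients.

    Every sub-volume is compared with every other by
    :func:`local_refine_pair`; summary statistics (mean, sd, min, max) are
    over the off-diagonal upper triangle, excluding members listed in
    ``exclude`` (typically the terminal domains of each horn, whose
    structure differs).
    """
    n = len(subs)
    if n < 2:
        raise ValueError("need at least two sub-volumes")
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            _, cc = local_refine_pair(subs.member(i), subs.member(j),
                                      mask=mask, angular_step=angular_step,
                                      max_excursion=max_excursion)
            M[i, j] = M[j, i] = cc
    keep = [i for i in range(n) if i not in set(exclude)]
    vals = np.array([M[i, j] for ii, i in enumerate(keep)
                     for j in keep[ii + 1:]])
    if len(vals) == 0:
        vals = M[np.triu_indices(n, 1)]
    return CCMatrix(M, sorted(set(exclude)), float(vals.mean()),
                    float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    float(vals.min()), float(vals.max()))


# ---------------------------------------------------------------------------
# Composite rendering
# ---------------------------------------------------------------------------

def place_back(motif: DensityMap, peaks, box, voxel_size=None,
               origin=(0.0, 0.0, 0.0)) -> DensityMap:
    """Render the motif at every peak transform into an empty box.

    Overlaps are max-composited.  ``box`` may be a shape tuple or an
    existing :class:`DensityMap` whose lattice is reused.
    """
    if isinstance(box, DensityMap):
        shape = box.shape
        voxel_size = box.voxel_size
        origin = box.origin
    else:
        shape = tuple(int(b) for b in (box if np.iterable(box) else [box] * 3))
        if voxel_size is None:
            voxel_size = motif.voxel_size
    plist = peaks.cluster if isinstance(peaks, PeakList) else list(peaks)
    out = np.zeros(shape)
    n = np.array(motif.shape)
    g = motif.grid.astype(float)
    origin = np.asarray(origin, float)
    half = np.linalg.norm(n * motif.voxel_size) / 2.0
    for p in plist:
        R = p.transform.rotation
        t = p.transform.translation
        cidx = (t - origin) / voxel_size
        lo = np.maximum(0, np.floor(cidx - half / voxel_size).astype(int))
        hi = np.minimum(np.array(shape), np.ceil(cidx + half / voxel_size)
                        .astype(int) + 1)
        if np.any(hi <= lo):
            continue
        # output index j -> motif index: Rᵀ·(j·v + origin − t)/v + n//2
        sub_shape = tuple(hi - lo)
        Rt = R.T
        offset = Rt @ (lo * voxel_size + origin - t) / motif.voxel_size + n // 2
        rendered = ndimage.affine_transform(
            g, Rt * (voxel_size / motif.voxel_size), offset=offset, order=1,
            output_shape=sub_shape, mode="constant", cval=0.0)
        sl = tuple(slice(lo[a], hi[a]) for a in range(3))
        out[sl] = np.maximum(out[sl], rendered)
    return DensityMap(out, voxel_size, origin)
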