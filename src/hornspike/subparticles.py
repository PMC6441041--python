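"""Sub-particle geometry for localized reconstruction of vertex spikes.

Given a whole-particle orientation and centre, the 60 icosahedral symmetry
copies of a 5-fold vertex vector collapse onto 12 unique vertex positions.
Each is projected into the image to give a 2D sub-particle offset, and its
signed distance d from the particle centre along the beam axis provides the
local defocus: ``local_defocus = defocus + d``.

Sign convention (the source data do not state one): the beam travels along
−z in the image frame, so d > 0 means the copy sits further from the
objective lens than the particle centre and its underfocus increases.  The
same d is applied to both defocus values of an astigmatic CTF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .transforms import RigidTransform, euler_to_matrix, matrix_to_euler

__all__ = [
    "ParticlePose",
    "SubParticle",
    "icosahedral_operators",
    "subparticles_for_vertex",
    "c5_equivalent_orientations",
    "write_subparticle_star",
    "read_subparticle_star",
]

_GOLDEN = (1.0 + 5.0**0.5) / 2.0
#: a 5-fold axis of the icosahedral setting used here (I1: 2-folds on x,y,z)
FIVEFOLD_AXIS = np.array([0.0, 1.0, _GOLDEN]) / np.sqrt(1.0 + _GOLDEN**2)


@dataclass(frozen=True)
class ParticlePose:
    """Whole-particle alignment: rotation (particle→image), centre, defocus."""

    rotation: np.ndarray
    center: tuple[float, float] = (0.0, 0.0)  # pixels in the image
    defocus: float = 0.0                      # Å, underfocus positive

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float).reshape(3, 3)
        RigidTransform(R)  # validates properness
        object.__setattr__(self, "rotation", R)
        if not np.isfinite(self.defocus):
            raise ValueError("defocus must be finite")

    @classmethod
    def from_euler(cls, rot, tilt, psi, center=(0.0, 0.0), defocus=0.0):
        return cls(euler_to_matrix(rot, tilt, psi), tuple(center), defocus)


@dataclass(frozen=True)
class SubParticle:
    offset_2d: tuple[float, float]  # pixels, relative to the particle centre
    d: float                        # Å along the beam axis (z)
    local_defocus: float            # Å = particle defocus + d
    orientation: np.ndarray         # composed rotation (3×3)
    vertex_id: int                  # 1–12


_ICOS_CACHE: np.ndarray | None = None


def icosahedral_operators() -> np.ndarray:
    """The 60 proper rotations of the icosahedral group, setting I1.

    In this setting the three 2-fold axes lie on x, y and z and a 5-fold
    axis along (0, 1, φ).  Generated by closure from a 2-fold about z and a
    72° rotation about the 5-fold axis; deterministic order (identity
    first, then sorted by quaternion).
    """
    global _ICOS_CACHE
    if _ICOS_CACHE is not None:
        return _ICOS_CACHE
    g1 = Rotation.from_rotvec(np.pi * np.array([0.0, 0.0, 1.0])).as_matrix()
    g2 = Rotation.from_rotvec(2 * np.pi / 5 * FIVEFOLD_AXIS).as_matrix()
    ops = [np.eye(3)]

    def known(M):
        return any(np.abs(M - O).max() < 1e-9 for O in ops)

    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for A in frontier:
            for G in (g1, g2):
                M = G @ A
                if not known(M):
                    ops.append(M)
                    nxt.append(M)
        frontier = nxt
    assert len(ops) == 60, f"closure produced {len(ops)} operators"
    quats = np.array([Rotation.from_matrix(M).as_quat() for M in ops])
    quats[quats[:, 3] < 0] *= -1  # canonical hemisphere
    order = np.lexsort(np.round(quats.T, 9))
    mats = np.array(ops)[order]
    ident = int(np.argmin([np.abs(M - np.eye(3)).max() for M in mats]))
    mats[[0, ident]] = mats[[ident, 0]]
    _ICOS_CACHE = mats
    return mats


def subparticles_for_vertex(
    pose: ParticlePose,
    vertex_vector,
    pixel_size: float,
    dedupe_tol: float = 1e-3,
) -> list[SubParticle]:
    """The 12 vertex sub-particles of one particle image.

    ``vertex_vector`` is the 3D position (Å, particle frame) of one 5-fold
    vertex.  Its 60 icosahedral copies are rotated into the image frame and
    deduplicated (5-fold site symmetry) to 12 unique positions at
    ``dedupe_tol`` pixels; each yields the projected 2D offset, the
    along-beam offset d (Å) and the local defocus.
    """
    v = np.asarray(vertex_vector, float)
    if np.linalg.norm(v) == 0:
        raise ValueError("vertex_vector must be non-zero")
    A = pose.rotation
    ops = icosahedral_operators()
    seen: list[np.ndarray] = []
    out: list[SubParticle] = []
    for O in ops:
        w = A @ (O @ v)
        if any(np.abs(w - s).max() < dedupe_tol * pixel_size for s in seen):
            continue
        seen.append(w)
        out.append(SubParticle(
            offset_2d=(float(w[0] / pixel_size), float(w[1] / pixel_size)),
            d=float(w[2]),
            local_defocus=float(pose.defocus + w[2]),
            orientation=A @ O,
            vertex_id=len(out) + 1,
        ))
    return out


def c5_equivalent_orientations(orientation, fivefold_axis=None) -> list[np.ndarray]:
    """The five orientations equivalent under the local C5 of a vertex.

    Composes the input with k·72° (k = 0..4) rotations about the 5-fold
    axis (particle frame); the k = 0 member is the input itself and every
    member maps the axis to the same image-frame vector.
    """
    if fivefold_axis is None:
        fivefold_axis = FIVEFOLD_AXIS
    ax = np.asarray(fivefold_axis, float)
    n = np.linalg.norm(ax)
    if n == 0:
        raise ValueError("fivefold_axis must be non-zero")
    ax = ax / n
    A = orientation.rotation if isinstance(orientation, RigidTransform) \
        else np.asarray(orientation, float)
    return [A @ Rotation.from_rotvec(np.radians(72.0 * k) * ax).as_matrix()
            for k in range(5)]


# ---------------------------------------------------------------------------
# STAR-table I/O
# ---------------------------------------------------------------------------

def write_subparticle_star(subparticles: list[SubParticle], path) -> None:
    from .startab import write_star_table

    rows = []
    for sp in subparticles:
        rot, tilt, psi = matrix_to_euler(sp.orientation)
        rows.append(dict(
            rlnOriginX=sp.offset_2d[0], rlnOriginY=sp.offset_2d[1],
            rlnAngleRot=rot, rlnAngleTilt=tilt, rlnAnglePsi=psi,
            rlnDefocusU=sp.local_defocus, rlnDefocusV=sp.local_defocus,
            hsBeamOffset=sp.d, hsVertexId=sp.vertex_id))
    write_star_table(pd.DataFrame(rows), path, block="subparticles")


def read_subparticle_star(path) -> list[SubParticle]:
    from .startab import read_star_table

    df = read_star_table(path)
    out = []
    for r in df.itertuples():
        out.append(SubParticle(
            offset_2d=(float(r.rlnOriginX), float(r.rlnOriginY)),
            d=float(r.hsBeamOffset),
            local_defocus=float(r.rlnDefocusU),
            orientation=euler_to_matrix(r.rlnAngleRot, r.rlnAngleTilt,
                                        r.rlnAnglePsi),
            vertex_id=int(r.hsVertexId)))
    return out
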