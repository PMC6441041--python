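import numpy as np
import pytest

from hornspike.geometry import (AmbiguousChainError, adjacent_transform_decomposition,
                                assign_horns, cc_statistics, order_along_spine,
                                place_back)
from hornspike.refine import SubVolumeSet
from hornspike.search import Peak
from hornspike.transforms import RigidTransform


def _screw_chain(n=8, angle=180.0, step=11.5, axis=(0, 0, 1), start=(0, 0, 0),
                 R0=None):
    """Planted screw chain: exact rotation about / translation along axis."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    R = np.eye(3) if R0 is None else R0
    p = np.asarray(start, float)
    peaks = []
    for i in range(n):
        peaks.append(Peak(RigidTransform(R, p.copy()), 1.0 - 0.01 * i, i + 1))
        link = RigidTransform.about_axis(axis, angle)
        R = link.rotation @ R
        p = p + step * axis
    return peaks


class TestOrderAlongSpine:
    def test_recovers_planted_order(self):
        peaks = _screw_chain(8)
        chain = order_along_spine(peaks, [0] * 8, start_reference=(0, 0, -5))
        assert chain.horns[0] == list(range(8))

    def test_order_invariant_under_shuffle(self):
        peaks = _screw_chain(8)
        perm = [3, 0, 6, 1, 7, 2, 5, 4]
        shuffled = [peaks[i] for i in perm]
        chain = order_along_spine(shuffled, [0] * 8,
                                  start_reference=(0, 0, -5))
        assert [perm[i] for i in chain.horns[0]] == list(range(8))

    def test_two_peaks_trivial_chain(self):
        peaks = _screw_chain(2)
        chain = order_along_spine(peaks, [0, 0], start_reference=(0, 0, -5))
        assert chain.horns[0] == [0, 1]

    def test_ambiguous_branch_raises(self):
        pos = [(0, 0, 0), (10, 0, 0), (20, 0, 0), (10, 10.2, 0)]
        peaks = [Peak(RigidTransform(np.eye(3), np.array(p, float)), 1.0, i + 1)
                 for i, p in enumerate(pos)]
        with pytest.raises(AmbiguousChainError):
            order_along_spine(peaks, [0] * 4, start_reference=(-5, 0, 0))


class TestAssignHorns:
    def test_two_sides_of_the_axis(self):
        pos = np.array([[20.0, 3.0, 5.0], [35.0, -4.0, 9.0],
                        [-20.0, -3.0, 5.0], [-35.0, 4.0, 9.0]])
        horns = assign_horns(pos, axis_point=(0, 0, 0))
        assert horns[0] == horns[1]
        assert horns[2] == horns[3]
        assert horns[0] != horns[2]


class TestDecomposition:
    def test_planted_screw_links_recovered_exactly(self):
        peaks = _screw_chain(6)
        chain = order_along_spine(peaks, [0] * 6, start_reference=(0, 0, -5))
        chain = adjacent_transform_decomposition(chain, peaks)
        assert np.allclose(chain.angles_deg, 180.0, atol=1e-6)
        assert np.allclose(chain.translations_A, 11.5, atol=1e-9)

    def test_identity_links(self):
        # pure translation: 0° about the axis, full step along it
        peaks = _screw_chain(5, angle=0.0)
        chain = order_along_spine(peaks, [0] * 5, start_reference=(0, 0, -5))
        chain = adjacent_transform_decomposition(chain, peaks)
        assert np.allclose(chain.angles_deg, 0.0, atol=1e-9)
        assert np.allclose(chain.translations_A, 11.5, atol=1e-9)

    def test_gauge_invariance_under_global_motion(self):
        axis = np.array([0.2, 0.1, 0.97])
        peaks = _screw_chain(6, angle=170.0, step=12.0, axis=axis)
        G = RigidTransform.from_euler(33.0, 71.0, -12.0, (40.0, -25.0, 13.0))
        moved = [Peak(G @ p.transform, p.score, p.rank) for p in peaks]
        ref0 = -5.0 * axis
        c0 = adjacent_transform_decomposition(
            order_along_spine(peaks, [0] * 6, start_reference=ref0), peaks)
        c1 = adjacent_transform_decomposition(
            order_along_spine(moved, [0] * 6, start_reference=G.apply(ref0)),
            moved)
        assert np.allclose(c0.angles_deg, c1.angles_deg, atol=1e-6)
        assert np.allclose(c0.translations_A, c1.translations_A, atol=1e-6)

    def test_gauge_invariance_under_motif_frame_flip(self):
        # a coherent right-multiplied gauge (e.g. a flipped but consistent
        # motif reference) cancels exactly in the link decomposition
        peaks = _screw_chain(6)
        F = RigidTransform.from_euler(77.0, 132.0, -8.0).rotation
        gauged = [Peak(RigidTransform(p.transform.rotation @ F,
                                      p.transform.translation),
                       p.score, p.rank) for p in peaks]
        c0 = adjacent_transform_decomposition(
            order_along_spine(peaks, [0] * 6, start_reference=(0, 0, -5)),
            peaks)
        c1 = adjacent_transform_decomposition(
            order_along_spine(gauged, [0] * 6, start_reference=(0, 0, -5)),
            gauged)
        assert np.allclose(c0.angles_deg, c1.angles_deg, atol=1e-9)
        assert np.allclose(c0.translations_A, c1.translations_A, atol=1e-9)

    def test_zigzag_midpoint_axis_cancels_lateral_offsets(self):
        # centres alternating ±r off the screw axis must not bias the
        # along-axis translation when the mid-point axis estimate is used
        base = _screw_chain(8)
        r = 6.0
        zig = []
        for i, p in enumerate(base):
            off = np.array([r * (1 if i % 2 == 0 else -1), 0.0, 0.0])
            zig.append(Peak(RigidTransform(p.transform.rotation,
                                           p.transform.translation + off),
                            p.score, p.rank))
        chain = order_along_spine(zig, [0] * 8, start_reference=(0, 0, -5))
        chain = adjacent_transform_decomposition(chain, zig)
        assert np.allclose(chain.translations_A, 11.5, atol=1e-9)
        assert np.allclose(chain.angles_deg, 180.0, atol=1e-6)

    def test_zero_displacement_raises(self):
        peaks = [Peak(RigidTransform(np.eye(3), np.zeros(3)), 1.0, 1),
                 Peak(RigidTransform(np.eye(3), np.zeros(3)), 0.9, 2)]
        chain = order_along_spine(peaks, [0, 0], ambiguity_ratio=1.0)
        with pytest.raises(ValueError):
            adjacent_transform_decomposition(chain, peaks)


class TestCCStatistics:
    def test_identical_members(self, rng):
        v = rng.normal(size=(12, 12, 12))
        vols = np.stack([v] * 4)
        subs = SubVolumeSet(vols, np.ones_like(vols), [RigidTransform()] * 4,
                            [1.0] * 4, 1.0, [False] * 4)
        cm = cc_statistics(subs)
        assert np.allclose(cm.matrix, 1.0, atol=1e-9)
        assert cm.sd == pytest.approx(0.0, abs=1e-9)

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        base = rng.normal(size=(12, 12, 12))
        vols = np.stack([base + 0.7 * rng.normal(size=base.shape)
                         for _ in range(4)])
        subs = SubVolumeSet(vols, np.ones_like(vols), [RigidTransform()] * 4,
                            [1.0] * 4, 1.0, [False] * 4)
        cm = cc_statistics(subs)
        assert np.allclose(cm.matrix, cm.matrix.T, atol=1e-6)
        assert np.allclose(np.diag(cm.matrix), 1.0)
        assert cm.matrix.min() >= -1.0 and cm.matrix.max() <= 1.0

    def test_exclusion_from_summary(self, rng):
        base = rng.normal(size=(10, 10, 10))
        vols = np.stack([base, base, rng.normal(size=base.shape)])
        subs = SubVolumeSet(vols, np.ones_like(vols), [RigidTransform()] * 3,
                            [1.0] * 3, 1.0, [False] * 3)
        cm_all = cc_statistics(subs)
        cm_excl = cc_statistics(subs, exclude=[2])
        assert cm_excl.mean > cm_all.mean
        assert cm_excl.excluded == [2]


class TestPlaceBack:
    def test_single_identity_peak_recenters_motif(self, gaussian_blob):
        center = gaussian_blob.center
        peak = Peak(RigidTransform(np.eye(3), center), 1.0, 1)
        out = place_back(gaussian_blob, [peak], gaussian_blob)
        a = gaussian_blob.grid.ravel()
        b = out.grid.ravel()
        cc = np.corrcoef(a, b)[0, 1]
        assert cc > 0.98  # trilinear placement at a half-voxel centre

    def test_separated_peaks_have_disjoint_supports(self):
        n = 9
        motif = np.zeros((n, n, n))
        motif[3:6, 3:6, 3:6] = 1.0
        from hornspike.maps import DensityMap

        m = DensityMap(motif, 1.0, origin=-(np.array([n] * 3) // 2) * 1.0)
        peaks = [Peak(RigidTransform(np.eye(3), np.array(p, float)), 1.0, i + 1)
                 for i, p in enumerate([(8, 8, 8), (24, 24, 24)])]
        out = place_back(m, peaks, (32, 32, 32), voxel_size=1.0)
        from scipy import ndimage

        labels, nlab = ndimage.label(out.grid > 0.5)
        assert nlab == 2
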