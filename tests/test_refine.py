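import numpy as np
import pytest

from hornspike.maps import DensityMap, SoftMask, soft_spherical_mask
from hornspike.refine import (average_top_k, build_motif_mask,
                              extract_subvolumes, local_refine_pair,
                              reference_consistency, watershed_segments)
from hornspike.search import Peak
from hornspike.transforms import RigidTransform, geodesic_angle_deg


def _peak(position, rotation=None, score=1.0, rank=1):
    R = np.eye(3) if rotation is None else rotation
    return Peak(RigidTransform(R, np.asarray(position, float)), score, rank)


@pytest.fixture()
def blob_map(gaussian_blob, rng):
    g = gaussian_blob.grid + 0.02 * rng.normal(size=gaussian_blob.shape)
    return DensityMap(g, 2.0)


class TestExtract:
    def test_identity_peak_equals_central_crop(self, blob_map):
        center = blob_map.index_to_position([16, 16, 16])
        subs = extract_subvolumes(blob_map, [_peak(center)], 9)
        crop = blob_map.grid[12:21, 12:21, 12:21]
        assert np.allclose(subs.volumes[0], crop, atol=1e-9)
        assert not subs.flagged[0]

    def test_corner_peak_is_flagged_with_validity(self, blob_map):
        corner = blob_map.index_to_position([1, 1, 1])
        subs = extract_subvolumes(blob_map, [_peak(corner)], 9)
        assert subs.flagged[0]
        assert subs.validity[0].min() == 0.0
        assert subs.validity[0].max() == 1.0

    def test_inverse_transform_round_trip(self, blob_map):
        # extraction through a rotation then placing back recovers the map
        from hornspike.geometry import place_back

        center = blob_map.index_to_position([16, 16, 16])
        T = RigidTransform.from_euler(25, 40, -15, center)
        subs = extract_subvolumes(blob_map, [_peak(center, T.rotation)], 17)
        motif = subs.member(0)
        composite = place_back(motif, [_peak(center, T.rotation)], blob_map)
        sel = composite.grid > 1e-6
        a = blob_map.grid[sel] - blob_map.grid[sel].mean()
        b = composite.grid[sel] - composite.grid[sel].mean()
        cc = a @ b / np.sqrt((a @ a) * (b @ b))
        assert cc >= 0.98


class TestAverage:
    def _subs(self, rng, n=5, shape=(9, 9, 9)):
        base = rng.normal(size=shape)
        vols = np.stack([base + 0.5 * rng.normal(size=shape) for _ in range(n)])
        from hornspike.refine import SubVolumeSet

        return SubVolumeSet(vols, np.ones_like(vols),
                            [RigidTransform()] * n,
                            list(np.linspace(1.0, 0.5, n)), 2.0,
                            [False] * n)

    def test_k1_equals_best_member(self, rng):
        subs = self._subs(rng)
        avg = average_top_k(subs, 1)
        assert np.allclose(avg.grid, subs.volumes[0])

    def test_identical_members_average_to_member(self, rng):
        from hornspike.refine import SubVolumeSet

        v = rng.normal(size=(7, 7, 7))
        subs = SubVolumeSet(np.stack([v] * 4), np.ones((4, 7, 7, 7)),
                            [RigidTransform()] * 4, [1.0] * 4, 1.0,
                            [False] * 4)
        avg = average_top_k(subs, 4)
        assert np.allclose(avg.grid, v, atol=1e-12)

    def test_k_zero_raises(self, rng):
        with pytest.raises(ValueError):
            average_top_k(self._subs(rng), 0)

    def test_averaging_beats_single_member(self, rng):
        # SNR gain: the mean of noisy copies correlates better with the
        # clean signal than any single copy (5 independent draws)
        base = rng.normal(size=(11, 11, 11))
        from hornspike.refine import SubVolumeSet

        n = 6
        vols = np.stack([base + 1.0 * rng.normal(size=base.shape)
                         for _ in range(n)])
        subs = SubVolumeSet(vols, np.ones_like(vols), [RigidTransform()] * n,
                            [1.0] * n, 1.0, [False] * n)
        avg = average_top_k(subs, n)

        def cc(a, b):
            a = a.ravel() - a.mean()
            b = b.ravel() - b.mean()
            return a @ b / np.sqrt((a @ a) * (b @ b))

        assert cc(avg.grid, base) > max(cc(v, base) for v in vols)

    def test_reference_consistency_ranks_matching_frames(self, rng):
        from hornspike.refine import SubVolumeSet

        base = rng.normal(size=(9, 9, 9))
        flipped = base[::-1, ::-1, :].copy()
        vols = np.stack([base, base + 0.3 * rng.normal(size=base.shape),
                         flipped])
        subs = SubVolumeSet(vols, np.ones_like(vols), [RigidTransform()] * 3,
                            [1.0, 0.9, 0.8], 1.0, [False] * 3)
        cons = reference_consistency(subs, reference=0)
        assert cons[0] == pytest.approx(1.0)
        assert cons[1] > cons[2]


class TestWatershed:
    def _blob(self, centers, sigma=3.0, n=32):
        ax = np.arange(n, dtype=float)
        g = np.zeros((n, n, n))
        for c in centers:
            d2 = ((ax[:, None, None] - c[0]) ** 2
                  + (ax[None, :, None] - c[1]) ** 2
                  + (ax[None, None, :] - c[2]) ** 2)
            g += np.exp(-0.5 * d2 / sigma**2)
        return DensityMap(g, 1.0)

    def test_single_blob_single_segment(self):
        m = self._blob([(16, 16, 16)])
        seg = watershed_segments(m, 0.1)
        assert seg.max() == 1

    def test_two_blobs_two_segments_with_centroids(self):
        m = self._blob([(10, 16, 16), (24, 16, 16)])
        seg = watershed_segments(m, 0.1)
        assert seg.max() == 2
        for label, cx in ((seg[10, 16, 16], 10), (seg[24, 16, 16], 24)):
            idx = np.argwhere(seg == label)
            assert abs(idx.mean(axis=0)[0] - cx) <= 1.0

    def test_segments_bounded_by_level_set(self):
        m = self._blob([(12, 16, 16), (22, 16, 16)])
        seg = watershed_segments(m, 0.2)
        assert np.count_nonzero(seg) <= np.count_nonzero(m.grid > 0.2)

    def test_empty_above_level(self):
        m = self._blob([(16, 16, 16)])
        seg = watershed_segments(m, 10.0)
        assert seg.max() == 0


class TestBuildMotifMask:
    @pytest.fixture()
    def blob(self):
        n = 48
        ax = (np.arange(n) - n / 2) * 1.35
        d2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
              + ax[None, None, :] ** 2)
        return DensityMap(np.exp(-0.5 * d2 / 12.0**2), 1.35)

    def test_volume_calibrated_to_target(self, blob):
        seg = watershed_segments(blob, 0.1)
        mask = build_motif_mask(blob, seg, seed_point=(24, 24, 24),
                                mask_volume=30_000.0)
        enclosed = np.count_nonzero(mask.grid > 0) * 1.35**3
        assert abs(enclosed - 30_000.0) <= 1.35**3 + 1e-6
        assert mask.grid.min() >= 0.0 and mask.grid.max() <= 1.0

    def test_mask_contains_half_max_support(self, blob):
        seg = watershed_segments(blob, 0.1)
        mask = build_motif_mask(blob, seg, seed_point=(24, 24, 24),
                                mask_volume=30_000.0)
        core = blob.grid >= 0.5 * blob.grid.max()
        assert np.all(mask.grid[core] > 0)

    def test_seed_outside_any_segment_lists_candidates(self, blob):
        seg = watershed_segments(blob, 0.1)
        with pytest.raises(ValueError, match="available segments"):
            build_motif_mask(blob, seg, seed_point=(1, 1, 1))


class TestLocalRefinePair:
    @pytest.fixture()
    def vol(self, rng):
        n = 20
        ax = (np.arange(n) - n // 2) * 2.0
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        g = np.zeros((n, n, n))
        for c, a in zip(rng.normal(scale=6, size=(6, 3)),
                        rng.uniform(0.5, 1, 6)):
            g += a * np.exp(-0.5 * ((pts - c) ** 2).sum(-1) / 4.0**2)
        return DensityMap(g, 2.0)

    def test_identical_volumes(self, vol):
        T, cc = local_refine_pair(vol, vol)
        assert cc == pytest.approx(1.0, abs=1e-9)
        assert T.rotation_angle_deg() < 1e-9

    def test_recovers_small_rotation(self, vol):
        from hornspike.maps import rotate_map

        rotated = rotate_map(vol, RigidTransform.about_axis([0, 0, 1], 4.0),
                             center=vol.index_to_position([10, 10, 10]))
        T, cc = local_refine_pair(vol, rotated)
        assert cc >= 0.99
        assert abs(T.rotation_angle_deg() - 4.0) <= 4.0

    def test_excursion_bound_respected(self, vol, rng):
        other = DensityMap(rng.normal(size=vol.shape), 2.0)
        T, _ = local_refine_pair(vol, other, max_excursion=8.0)
        assert T.rotation_angle_deg() <= 8.0 + 1e-6

    def test_symmetric_in_arguments(self, vol):
        from hornspike.maps import rotate_map

        other = rotate_map(vol, RigidTransform.about_axis([0, 1, 0], 6.0),
                           center=vol.index_to_position([10, 10, 10]))
        _, cc_ab = local_refine_pair(vol, other)
        _, cc_ba = local_refine_pair(other, vol)
        assert cc_ab == pytest.approx(cc_ba, abs=1e-6)

    def test_never_below_identity_alignment(self, vol, rng):
        other = DensityMap(vol.grid + 0.5 * rng.normal(size=vol.shape), 2.0)
        _, cc = local_refine_pair(vol, other)
        a = vol.grid.ravel() - vol.grid.mean()
        b = other.grid.ravel() - other.grid.mean()
        cc0 = a @ b / np.sqrt((a @ a) * (b @ b))
        assert cc >= cc0 - 1e-9
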