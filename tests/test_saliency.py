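"""Saliency bank behaviour, lateralization index and cluster counting."""

from __future__ import annotations

import numpy as np
import pytest

from salcomp.geometry import ScreenGeometry
from salcomp.saliency import (
    SaliencyConfig,
    count_saliency_clusters,
    fixation_cluster_overlap,
    frame_saliency,
    salience_lateralization_index,
    summed_saliency_map,
    video_saliency,
)
from salcomp.synthetic import generate_video, horizontal_flip


def disc_frame(geometry, x_deg, y_deg, radius_deg=1.0, value=1.0, background=0.0):
    xs = geometry.x_coords_deg()[None, :]
    ys = geometry.y_coords_deg()[:, None]
    frame = np.full((geometry.height_px, geometry.width_px, 3), background)
    inside = (xs - x_deg) ** 2 + (ys - y_deg) ** 2 <= radius_deg**2
    frame[inside] = value
    return frame


class TestFrameSaliency:
    def test_uniform_frame_is_all_zero(self, geometry):
        frame = np.full((geometry.height_px, geometry.width_px, 3), 0.5)
        sal, channels = frame_saliency(frame)
        assert np.all(sal == 0)
        for name, m in channels.as_dict().items():
            assert np.all(m == 0), name

    def test_identical_prev_frame_zeroes_temporal_channels(self, geometry):
        rng = np.random.default_rng(0)
        frame = rng.random((geometry.height_px, geometry.width_px, 3))
        _, channels = frame_saliency(frame, prev_frame=frame.copy())
        assert np.all(channels.flicker == 0)
        assert np.all(channels.motion == 0)
        assert channels.intensity.max() > 0  # spatial channels still respond

    def test_bright_disc_peak_inside_disc(self, geometry):
        frame = disc_frame(geometry, 5.0, -2.0)
        sal, _ = frame_saliency(frame)
        r, c = np.unravel_index(np.argmax(sal), sal.shape)
        x = geometry.x_coords_deg()[c]
        y = geometry.y_coords_deg()[r]
        assert (x - 5.0) ** 2 + (y + 2.0) ** 2 <= 1.0**2

    def test_shape_mismatch_raises(self, geometry):
        frame = np.zeros((geometry.height_px, geometry.width_px, 3))
        with pytest.raises(ValueError):
            frame_saliency(frame, prev_frame=frame[:-2])

    def test_non_negativity_on_random_frames(self, geometry):
        rng = np.random.default_rng(1)
        prev = None
        for _ in range(3):
            frame = rng.random((48, 64, 3))
            sal, channels = frame_saliency(frame, prev)
            assert sal.min() >= 0
            for m in channels.as_dict().values():
                assert m.min() >= 0
            prev = frame

    def test_mirror_metamorphic(self):
        """Saliency of the mirrored frame equals the mirrored saliency."""
        video, _ = generate_video("multi", "right", seed=4)
        prev = None
        for t in range(2):
            frame = video.frames[t]
            sal, _ = frame_saliency(frame, prev)
            sal_m, _ = frame_saliency(
                frame[:, ::-1], prev[:, ::-1] if prev is not None else None
            )
            np.testing.assert_allclose(sal_m, sal[:, ::-1], rtol=1e-6, atol=1e-12)
            prev = frame


class TestLateralizationIndex:
    def test_symmetric_map_gives_zero(self, geometry):
        m = np.zeros((geometry.height_px, geometry.width_px))
        m[:, 10] = 1.0
        m[:, geometry.width_px - 11] = 1.0
        hemi = salience_lateralization_index(m[None], geometry)
        assert hemi.sal_idx == pytest.approx(0.0, abs=1e-12)

    def test_all_right_salience_gives_plus_one(self, geometry):
        m = np.zeros((geometry.height_px, geometry.width_px))
        m[:, -20:] = 1.0  # far right of the exclusion band
        hemi = salience_lateralization_index(m[None], geometry)
        assert hemi.sal_idx == 1.0

    def test_hand_computed_ratio(self, geometry):
        # left-hemifield mean 0.2, right-hemifield mean 0.6 -> +0.5
        m = np.zeros((geometry.height_px, geometry.width_px))
        left = geometry.x_coords_deg() < -geometry.central_exclusion_deg
        right = geometry.x_coords_deg() > geometry.central_exclusion_deg
        m[:, left] = 0.2
        m[:, right] = 0.6
        hemi = salience_lateralization_index(m[None], geometry)
        assert hemi.sal_idx == pytest.approx(0.5)
        assert hemi.left == pytest.approx(0.2) and hemi.right == pytest.approx(0.6)

    def test_zero_map_flagged_undefined(self, geometry):
        hemi = salience_lateralization_index(
            np.zeros((1, geometry.height_px, geometry.width_px)), geometry
        )
        assert not hemi.defined and np.isnan(hemi.sal_idx)

    def test_scale_invariance(self, geometry):
        rng = np.random.default_rng(2)
        m = rng.random((3, geometry.height_px, geometry.width_px))
        a = salience_lateralization_index(m, geometry)
        b = salience_lateralization_index(7.3 * m, geometry)
        assert b.sal_idx == pytest.approx(a.sal_idx, abs=1e-12)

    def test_flip_negates_index_through_full_pipeline(self, geometry):
        """sal_idx(flip(video)) == -sal_idx(video) via recomputed maps."""
        for seed in (1, 2):
            video, _ = generate_video("multi", "right", seed=seed, n_frames=3)
            flipped = horizontal_flip(video)
            a = salience_lateralization_index(video_saliency(video.frames), geometry)
            b = salience_lateralization_index(video_saliency(flipped.frames), geometry)
            assert b.sal_idx == pytest.approx(-a.sal_idx, abs=1e-6)


class TestSummedMapAndClusters:
    def test_sum_of_identical_maps_doubles(self):
        m = np.random.default_rng(0).random((8, 8))
        np.testing.assert_allclose(summed_saliency_map([m, m]), 2 * m)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            summed_saliency_map(np.zeros((0, 8, 8)))

    def test_one_hot_maps_sum_to_k_positive_pixels(self):
        maps = np.zeros((4, 6, 6))
        for k in range(4):
            maps[k, k, k + 1] = 1.0
        assert int((summed_saliency_map(maps) > 0).sum()) == 4

    @pytest.mark.parametrize(
        "builder,expected",
        [
            (lambda m: m, 0),  # identically zero map
            (lambda m: _patch(m, [(2, 2)]), 1),
            (lambda m: _patch(m, [(2, 2), (10, 12)]), 2),
        ],
    )
    def test_small_map_counts(self, builder, expected):
        m = builder(np.zeros((16, 16)))
        n, labels = count_saliency_clusters(m)
        assert n == expected
        assert labels.max() == expected

    def test_count_invariant_under_scaling(self):
        rng = np.random.default_rng(3)
        m = np.where(rng.random((20, 20)) > 0.7, rng.random((20, 20)), 0.0)
        n1, _ = count_saliency_clusters(m)
        n2, _ = count_saliency_clusters(123.0 * m)
        assert n1 == n2

    def test_labels_match_floodfill_oracle(self):
        """Connected-component labels agree with an exhaustive 8-connected
        flood fill on random small maps."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            m = np.where(rng.random((16, 16)) > 0.6, rng.random((16, 16)), 0.0)
            n, labels = count_saliency_clusters(m)
            assert n == _floodfill_count(m > 0)
            # labels partition the support
            assert np.array_equal(labels > 0, m > (1e-6 * m.max() if m.max() > 0 else 0))

    def test_planted_blobs_recovered_from_video(self):
        video, truth = generate_video("multi", "left", seed=6)
        sv = video_saliency(video.frames)
        planted = truth.n_background_patches + len(truth.event_trajectories)
        assert sv.n_clusters == planted


class TestFixationClusterOverlap:
    def _fix(self, x, y):
        from salcomp.gaze import Fixation

        return Fixation(0.0, 0.1, x, y, 0, 11)

    def test_overlap_percentages(self, geometry):
        labels = np.zeros((geometry.height_px, geometry.width_px), dtype=int)
        labels[:, :30] = 1  # left patch
        inside = self._fix(-10.0, 0.0)
        outside = self._fix(10.0, 0.0)
        assert fixation_cluster_overlap([inside] * 4, labels, geometry) == 100.0
        assert fixation_cluster_overlap([outside] * 4, labels, geometry) == 0.0
        assert fixation_cluster_overlap([inside] * 3 + [outside], labels, geometry) == 75.0

    def test_empty_fixations_undefined(self, geometry):
        assert np.isnan(fixation_cluster_overlap([], np.zeros((4, 4), dtype=int), geometry))


def _patch(m, corners):
    for r, c in corners:
        m[r : r + 3, c : c + 3] = 1.0
    return m


def _floodfill_count(support: np.ndarray) -> int:
    seen = np.zeros_like(support, dtype=bool)
    count = 0
    H, W = support.shape
    for r in range(H):
        for c in range(W):
            if support[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if 0 <= nr < H and 0 <= nc < W and support[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                stack.append((nr, nc))
    return count
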