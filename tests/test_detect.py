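"""LoG detector: filter correctness, adaptive threshold, labeling, area filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitoflux as mf
from mitoflux.detect import (
    DetectionParams,
    autotune_detect,
    autotune_z,
    detect_puncta,
    filter_min_area,
    label_objects,
    log_filter,
    threshold_response,
)


def gaussian_blob(shape, center, sigma, amp):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


def dense_log_response(frame, sigma):
    """Independent oracle: negated scale-normalised LoG by explicit dense convolution."""
    r = int(np.ceil(6 * sigma))
    y, x = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    g = np.exp(-(x**2 + y**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    log_kernel = g * ((x**2 + y**2) / sigma**4 - 2 / sigma**2)
    from scipy.signal import convolve2d

    padded = np.pad(frame, r, mode="reflect")
    resp = convolve2d(padded, -(sigma**2) * log_kernel, mode="same")
    return resp[r:-r, r:-r]


class TestLogFilter:
    def test_constant_frame_zero_response(self):
        resp = log_filter(np.full((32, 32), 7.3), 3.0)
        assert np.abs(resp).max() < 1e-9

    def test_peak_at_blob_center_matches_convolution_oracle(self):
        frame = gaussian_blob((64, 64), (30, 25), 3.0, 100.0)
        resp = log_filter(frame, 3.0)
        assert np.unravel_index(np.argmax(resp), resp.shape) == (30, 25)
        oracle = dense_log_response(frame, 3.0)
        interior = (slice(10, 54), slice(10, 54))
        assert np.allclose(resp[interior], oracle[interior], atol=1e-3 * np.abs(oracle).max())

    def test_linearity_for_separated_blobs(self):
        a = gaussian_blob((96, 96), (25, 25), 3.0, 50.0)
        b = gaussian_blob((96, 96), (70, 70), 3.0, 80.0)
        assert np.allclose(
            log_filter(a + b, 3.0), log_filter(a, 3.0) + log_filter(b, 3.0), atol=1e-6
        )

    def test_rejects_non_finite(self):
        bad = np.ones((8, 8))
        bad[3, 3] = np.nan
        with pytest.raises(ValueError):
            log_filter(bad, 3.0)


class TestThresholdResponse:
    def test_hand_built_grid_threshold_arithmetic(self):
        # 24 zeros + one pixel at 10: mu = 0.4, sigma = sqrt(96/25)
        resp = np.zeros((5, 5))
        resp[2, 3] = 10.0
        mu = 10.0 / 25
        sd = np.sqrt((24 * mu**2 + (10 - mu) ** 2) / 25)
        assert sd == pytest.approx(np.sqrt(96 / 25))
        mask = threshold_response(resp, z=1.75)
        assert 10.0 > mu + 1.75 * sd  # the designed exceedance
        assert mask[2, 3] and mask.sum() == 1

    def test_large_z_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        resp = rng.normal(size=(40, 40))
        assert threshold_response(resp, z=1000.0).sum() == 0

    def test_zero_variance_warns_and_empties(self):
        with pytest.warns(UserWarning):
            mask = threshold_response(np.full((8, 8), 2.0), z=1.75)
        assert mask.sum() == 0

    def test_support_restricts_mask_and_statistics(self):
        resp = np.zeros((10, 10))
        resp[0, 0] = 100.0  # outside support, must never be selected
        resp[5, 5] = 5.0
        support = np.zeros((10, 10), dtype=bool)
        support[3:8, 3:8] = True
        mask = threshold_response(resp, z=1.75, support=support)
        assert not mask[0, 0]
        assert mask[5, 5]

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_mask_monotone_nonincreasing_in_z(self, seed):
        rng = np.random.default_rng(seed)
        resp = rng.normal(size=(30, 30))
        low = threshold_response(resp, z=1.0)
        high = threshold_response(resp, z=2.0)
        assert np.all(low | ~high)  # high-z mask is a subset


class TestLabelObjects:
    def test_empty_mask(self):
        assert label_objects(np.zeros((8, 8), dtype=bool), np.zeros((8, 8))) == []

    def test_diagonal_connectivity(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        frame = np.ones((5, 5))
        assert len(label_objects(mask, frame, connectivity=8)) == 1
        assert len(label_objects(mask, frame, connectivity=4)) == 2

    def test_matches_flood_fill_oracle(self):
        """Object count equals an independent BFS flood fill on random masks."""

        def flood_count(mask):
            seen = np.zeros_like(mask, dtype=bool)
            count = 0
            nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
            for r in range(mask.shape[0]):
                for c in range(mask.shape[1]):
                    if mask[r, c] and not seen[r, c]:
                        count += 1
                        stack = [(r, c)]
                        seen[r, c] = True
                        while stack:
                            cr, cc = stack.pop()
                            for dr, dc in nbrs:
                                nr, nc = cr + dr, cc + dc
                                if (
                                    0 <= nr < mask.shape[0]
                                    and 0 <= nc < mask.shape[1]
                                    and mask[nr, nc]
                                    and not seen[nr, nc]
                                ):
                                    seen[nr, nc] = True
                                    stack.append((nr, nc))
            return count

        rng = np.random.default_rng(7)
        for _ in range(100):
            mask = rng.random((16, 16)) < 0.35
            objs = label_objects(mask, rng.random((16, 16)))
            assert len(objs) == flood_count(mask)

    def test_intensities_sampled_from_frame(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[1, 2] = True
        frame = np.arange(16, dtype=float).reshape(4, 4)
        (obj,) = label_objects(mask, frame)
        assert obj.max_intensity == 6.0
        assert obj.mean_intensity == pytest.approx(5.5)
        assert obj.area_px == 2


class TestAreaFilter:
    @pytest.mark.parametrize(
        "area,min_area,kept",
        [(25, 25, False), (26, 25, True), (4, 4, False), (5, 4, True)],
    )
    def test_inclusive_boundary(self, area, min_area, kept):
        """Objects at the precision-limit area are removed, strictly larger kept."""
        mask = np.zeros((30, 30), dtype=bool)
        mask.flat[:area] = True
        mask = mask.reshape(30, 30)
        objs = label_objects(mask, np.ones((30, 30)))
        out = filter_min_area(objs, min_area)
        assert (len(out) > 0) == kept


class TestDetectPuncta:
    def test_recovers_ground_truth_at_high_snr(self, dense_scene):
        from conftest import match_detections

        truth, scene = dense_scene
        objs = detect_puncta(scene["gfp"], DetectionParams(support=truth.cell_mask))
        recall, precision, _ = match_detections(objs, truth)
        assert recall >= 0.9 and precision >= 0.9

    def test_noise_only_scene_false_positive_floor(self, noise_only_scene):
        """On a signal-free cell the adaptive threshold drops into the noise,
        so a small number of smoothed-noise clusters survive the 25-px area
        filter; they are rare and essentially never coincide across channels,
        so the dual-puncta readout stays clean."""
        from mitoflux.associate import build_dual_puncta

        truth, scene = noise_only_scene
        p = DetectionParams(support=truth.cell_mask)
        gfp = detect_puncta(scene["gfp"], p, "gfp")
        rfp = detect_puncta(scene["rfp"], p, "rfp")
        assert len(gfp) <= 20 and len(rfp) <= 20
        assert len(build_dual_puncta(gfp, rfp)) <= 5

    def test_signal_suppresses_noise_clusters(self, dense_scene):
        """With real puncta present the response SD rises and pure-noise
        clusters fall below the adaptive threshold: detections = true spots."""
        truth, scene = dense_scene
        objs = detect_puncta(scene["gfp"], DetectionParams(support=truth.cell_mask))
        assert len(objs) == len(truth.puncta)

    def test_count_nonincreasing_in_z(self, default_scene):
        truth, scene = default_scene
        counts = [
            len(detect_puncta(scene["gfp"], DetectionParams(z=z, support=truth.cell_mask)))
            for z in (1.75, 2.5)
        ]
        assert counts[1] <= counts[0]

    def test_affine_intensity_invariance(self, default_scene):
        """The z-score threshold makes detection scale-free: a*I+b gives the same mask."""
        truth, scene = default_scene
        p = DetectionParams(support=truth.cell_mask)
        base = detect_puncta(scene["gfp"], p)
        scaled = detect_puncta(3.7 * scene["gfp"] + 11.0, p)
        assert len(base) == len(scaled)
        for o1, o2 in zip(base, scaled):
            assert np.array_equal(o1.pixels, o2.pixels)


class TestAutotune:
    def test_ratio_one_matches_default_z(self, default_scene):
        truth, scene = default_scene
        p = DetectionParams(support=truth.cell_mask)
        tuned = autotune_detect(scene["gfp"], ratio=1.0, params=p)
        ref = detect_puncta(scene["gfp"], DetectionParams(support=truth.cell_mask, min_area_px=4))
        assert len(tuned) == len(ref)
        for a, b in zip(tuned, ref):
            assert np.array_equal(a.pixels, b.pixels)

    def test_autotune_increases_recall(self, default_scene):
        truth, scene = default_scene
        p = DetectionParams(support=truth.cell_mask)
        assert len(autotune_detect(scene["gfp"], ratio=3.75, params=p)) >= len(
            autotune_detect(scene["gfp"], ratio=1.0, params=p)
        )

    def test_mapping(self):
        assert autotune_z(3.75) == pytest.approx(1.75 / 3.75)
        with pytest.raises(ValueError):
            autotune_z(0)
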