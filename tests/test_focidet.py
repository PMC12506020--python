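"""Focus detection against brute-force LoG and lattice-enumeration oracles."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from bactorg import focidet, synthgen
from bactorg.focidet import DetectionParams, FocusDetection
from bactorg.synthgen import NOISELESS, NoiseModel

HIGH_SNR_NOISE = NoiseModel(background=100.0, read_sigma=5.0)


def brute_force_log_maxima(image, sigma, threshold):
    """Independent LoG response: explicit analytic kernel convolution plus
    exhaustive 3x3 neighborhood scan."""
    half = int(np.ceil(6 * sigma))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = xx**2 + yy**2
    # scale-normalized negative LoG kernel: sigma^2 * (2 - r^2/sigma^2)/... ,
    # written directly from the second derivative of the Gaussian
    g = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    kernel = -(sigma**2) * g * (r2 / sigma**4 - 2 / sigma**2)
    resp = convolve2d(np.asarray(image, dtype=float), kernel, mode="same", boundary="symm")
    maxima = []
    for y in range(1, resp.shape[0] - 1):
        for x in range(1, resp.shape[1] - 1):
            patch = resp[y - 1 : y + 2, x - 1 : x + 2]
            if resp[y, x] >= patch.max() and resp[y, x] > threshold:
                maxima.append((y, x))
    return maxima, resp


class TestDetectFoci:
    def test_blank_cell_no_detections(self, rod_mask):
        img = np.full(rod_mask.shape, 37.0)
        assert focidet.detect_foci(img, rod_mask) == []

    def test_single_focus_recovered_and_matches_oracle(self, rod_mask):
        truth = (33.0, 8.0)
        img = synthgen.render_foci(rod_mask, [truth], 500.0, noise=HIGH_SNR_NOISE, seed=1)
        params = DetectionParams(unsharp_amount=0.0, blur_sigma=0.0)
        dets = focidet.detect_foci(img, rod_mask, params)
        assert len(dets) == 1
        assert np.hypot(dets[0].x - truth[0], dets[0].y - truth[1]) <= 0.5
        maxima, _ = brute_force_log_maxima(img, params.log_sigma, params.quality_threshold)
        in_mask = [(y, x) for y, x in maxima if rod_mask[y, x]]
        assert in_mask == [(int(dets[0].y), int(dets[0].x))]

    def test_two_close_foci_resolved(self, rod_mask):
        pos = [(31.0, 8.0), (36.0, 8.0)]  # 5 px apart at blob diameter 3
        img = synthgen.render_foci(rod_mask, pos, 500.0, noise=NOISELESS)
        params = DetectionParams(unsharp_amount=0.0, blur_sigma=0.0)
        dets = focidet.detect_foci(img, rod_mask, params)
        assert len(dets) == 2
        found = sorted((d.x, d.y) for d in dets)
        for (fx, fy), (tx, ty) in zip(found, pos):
            assert np.hypot(fx - tx, fy - ty) <= 1.0

    def test_sorted_by_quality_with_deterministic_ties(self, rod_mask):
        img = synthgen.render_foci(rod_mask, [(20.0, 8.0), (45.0, 8.0)], [300.0, 600.0], noise=NOISELESS)
        dets = focidet.detect_foci(img, rod_mask, DetectionParams(unsharp_amount=0.0, blur_sigma=0.0))
        assert dets[0].quality >= dets[1].quality
        assert (dets[0].x, dets[0].y) == (45.0, 8.0)

    def test_empty_mask_empty_result(self):
        assert focidet.detect_foci(np.zeros((10, 10)), np.zeros((10, 10), bool)) == []

    def test_bad_blob_diameter_rejected(self, rod_mask):
        with pytest.raises(ValueError):
            focidet.detect_foci(np.zeros(rod_mask.shape), rod_mask, DetectionParams(blob_diameter_px=0))


class TestFocusIntensity:
    def test_uniform_image_lattice_count(self):
        # pixels with center within distance 2r = 3.0: enumerate dx^2+dy^2 <= 9
        expected = sum(
            1 for dx in range(-3, 4) for dy in range(-3, 4) if dx * dx + dy * dy <= 9
        )
        assert expected == 29
        det = FocusDetection(0, 0, x=10, y=10, r=1.5, quality=1.0)
        assert focidet.focus_intensity(np.ones((21, 21)), det) == 29.0

    def test_single_pixel_value(self):
        img = np.zeros((15, 15))
        img[7, 7] = 42.0
        det = FocusDetection(0, 0, x=7, y=7, r=1.5, quality=1.0)
        assert focidet.focus_intensity(img, det) == 42.0

    def test_linearity(self, rod_mask):
        img = synthgen.render_foci(rod_mask, [(33.0, 8.0)], 500.0, noise=NOISELESS)
        det = FocusDetection(0, 0, x=33, y=8, r=1.5, quality=1.0)
        assert focidet.focus_intensity(2 * img, det) == pytest.approx(
            2 * focidet.focus_intensity(img, det)
        )

    def test_additive_over_disjoint_foci_and_translation_invariant(self):
        img = np.zeros((40, 80))
        rng = np.random.default_rng(0)
        img[5:35, 5:35] = rng.random((30, 30))
        det_a = FocusDetection(0, 0, x=20, y=20, r=1.5, quality=1.0)
        val = focidet.focus_intensity(img, det_a)
        shifted = np.roll(img, (0, 40), axis=(0, 1))
        det_b = FocusDetection(0, 0, x=60, y=20, r=1.5, quality=1.0)
        assert focidet.focus_intensity(shifted, det_b) == pytest.approx(val)

    def test_circle_outside_image_rejected(self):
        det = FocusDetection(0, 0, x=100, y=100, r=1.5, quality=1.0)
        with pytest.raises(ValueError):
            focidet.focus_intensity(np.ones((10, 10)), det)


class TestFocusStats:
    def test_nn_spacing_two_foci(self, rod_morphology):
        dets = [
            FocusDetection(1, 0, x=20, y=13, r=1.5, quality=1.0),
            FocusDetection(1, 0, x=30, y=13, r=1.5, quality=1.0),
        ]
        stats = focidet.focus_stats(dets, rod_morphology, 60.0)
        assert stats.nn_spacing_um == pytest.approx([0.6, 0.6])

    def test_single_focus_empty_spacing(self, rod_morphology):
        dets = [FocusDetection(1, 0, x=20, y=13, r=1.5, quality=1.0)]
        stats = focidet.focus_stats(dets, rod_morphology, 60.0)
        assert stats.nn_spacing_um == []
        assert stats.focus_count == 1

    def test_focus_on_midline_zero_distance(self, rod_morphology):
        mx, my = rod_morphology.midline[len(rod_morphology.midline) // 2]
        dets = [FocusDetection(1, 0, x=mx, y=my, r=1.5, quality=1.0)]
        stats = focidet.focus_stats(dets, rod_morphology, 60.0)
        assert stats.medial_distance_um[0] == pytest.approx(0.0, abs=1e-12)

    def test_medial_distance_matches_dense_resampling_oracle(self, rod_morphology):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(10, 60, 20), rng.uniform(6, 20, 20)])
        # oracle: min distance over the midline resampled at 0.1 px steps
        mid = rod_morphology.midline
        seg = np.diff(mid, axis=0)
        arc = np.concatenate([[0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        s = np.arange(0, arc[-1], 0.1)
        dense = np.column_stack([np.interp(s, arc, mid[:, 0]), np.interp(s, arc, mid[:, 1])])
        for x, y in pts:
            oracle = np.sqrt(((dense - (x, y)) ** 2).sum(axis=1)).min()
            got = focidet.point_to_polyline_distance((x, y), mid)
            assert got == pytest.approx(oracle, abs=0.05)

    def test_whole_cell_intensity_per_length(self, rod_mask, rod_morphology):
        img = np.ones(rod_mask.shape)
        stats = focidet.focus_stats([], rod_morphology, 60.0, img, rod_mask)
        assert stats.whole_cell_intensity_per_length == pytest.approx(
            rod_mask.sum() / rod_morphology.length_um
        )


class TestDetectionFidelity:
    def test_recall_precision_on_separated_foci(self):
        # SNR 10, spacing >= 2x blob diameter: detector must be near-perfect
        hits = misses = spurious = 0
        for seed in range(20):
            mask = synthgen.make_cell_mask(3.5, 1.0)
            truth = [(15.0 + 7.0 * k, 8.0) for k in range(4)]
            img = synthgen.render_foci(
                mask, truth, 500.0, noise=NoiseModel(100.0, 50.0), seed=seed
            )
            dets = focidet.detect_foci(img, mask, DetectionParams())
            used = set()
            for tx, ty in truth:
                match = [
                    i
                    for i, d in enumerate(dets)
                    if i not in used and np.hypot(d.x - tx, d.y - ty) <= 2.0
                ]
                if match:
                    used.add(match[0])
                    hits += 1
                else:
                    misses += 1
            spurious += len(dets) - len(used)
        recall = hits / (hits + misses)
        precision = hits / (hits + spurious)
        assert recall >= 0.95 and precision >= 0.95
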