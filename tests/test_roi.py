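"""Chip detection, region labeling, reaction-ROI extraction, range derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucopad import (
    ChipNotFoundError,
    HSVRange,
    NoReactionDetectedError,
    PixelSampleSet,
    SyntheticSpec,
    derive_hsv_range,
    detect_chip,
    extract_reaction_roi,
    hsv_to_rgb,
    label_regions,
    render_chip,
    rgb_to_hsv,
)
from glucopad.roi import BLOOD_ZONE, CHIP, REACTION_ZONE, RegionLabelMap


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """Brute-force 8-connected components by BFS (independent oracle)."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp, stack = set(), [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(comp)
    return comps


class TestDetectChip:
    def test_synthetic_render_jaccard(self, noisy_render_90):
        img, gt = noisy_render_90
        roi = detect_chip(img)
        inter = np.count_nonzero(roi.mask & gt.chip_mask)
        union = np.count_nonzero(roi.mask | gt.chip_mask)
        assert inter / union >= 0.9

    def test_all_black_raises(self):
        with pytest.raises(ChipNotFoundError):
            detect_chip(np.zeros((40, 40, 3), dtype=np.uint8))

    def test_blank_white_raises(self):
        """A contrast-free frame has no separable object."""
        with pytest.raises(ChipNotFoundError):
            detect_chip(np.full((40, 40, 3), 255, dtype=np.uint8))

    def test_frame_entirely_chip_is_full_frame(self):
        """A close-up where the paper fills the frame: the interior colored
        zones give the contrast and hole-filling recovers the whole frame."""
        img = np.full((120, 200, 3), 245, dtype=np.uint8)
        yy, xx = np.mgrid[:120, :200]
        img[(yy - 60) ** 2 + (xx - 60) ** 2 <= 400] = (188, 30, 36)  # blood
        img[(yy - 60) ** 2 + (xx - 140) ** 2 <= 400] = hsv_to_rgb(110, 200, 220)
        roi = detect_chip(img)
        assert roi.bounding_box == (0, 0, 120, 200)
        assert roi.area == 120 * 200

    def test_tiny_bright_speck_rejected(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        img[50, 50] = (255, 255, 255)  # < 1% of the frame
        with pytest.raises(ChipNotFoundError):
            detect_chip(img)


class TestLabelRegions:
    def test_synthetic_centroids_inside_ground_truth(self, noisy_render_90):
        img, gt = noisy_render_90
        chip = detect_chip(img)
        labels = label_regions(rgb_to_hsv(img), chip)
        for zone, gt_mask in ((BLOOD_ZONE, gt.blood_mask),
                              (REACTION_ZONE, gt.reaction_mask)):
            pts = np.argwhere(labels.zone_mask(zone))
            assert len(pts) > 0
            cy, cx = (int(round(v)) for v in pts.mean(axis=0))
            assert gt_mask[cy, cx]

    def test_zones_inside_chip(self, noisy_render_90):
        img, _ = noisy_render_90
        chip = detect_chip(img)
        labels = label_regions(rgb_to_hsv(img), chip)
        for zone in (BLOOD_ZONE, REACTION_ZONE):
            assert not np.any(labels.zone_mask(zone) & ~chip.mask)

    def test_uniform_white_chip_has_empty_zones(self, clean_render_90):
        img, _ = clean_render_90
        chip = detect_chip(img)
        white = np.full_like(img, 245)
        labels = label_regions(rgb_to_hsv(white), chip)
        assert not labels.zone_mask(BLOOD_ZONE).any()
        assert not labels.zone_mask(REACTION_ZONE).any()
        assert np.array_equal(labels.zone_mask(CHIP), chip.mask)

    def test_fully_blue_chip_is_all_reaction(self, clean_render_90):
        img, _ = clean_render_90
        chip = detect_chip(img)
        blue = np.full_like(img, hsv_to_rgb(110, 200, 220))
        labels = label_regions(rgb_to_hsv(blue), chip)
        assert labels.zone_mask(REACTION_ZONE).sum() == chip.area


class TestExtractReactionRoi:
    def _labels_from_blobs(self, blobs: np.ndarray) -> RegionLabelMap:
        labels = np.where(blobs, REACTION_ZONE, CHIP).astype(np.uint8)
        return RegionLabelMap(labels)

    def test_largest_of_two_blobs(self):
        blobs = np.zeros((30, 30), dtype=bool)
        blobs[2:12, 2:12] = True  # 100 px
        blobs[20:25, 20:28] = True  # 40 px
        roi = extract_reaction_roi(self._labels_from_blobs(blobs))
        assert roi.area == 100
        assert roi.bounding_box == (2, 2, 12, 12)

    def test_single_blob_identity(self):
        blobs = np.zeros((10, 10), dtype=bool)
        blobs[3:6, 4:9] = True
        roi = extract_reaction_roi(self._labels_from_blobs(blobs))
        assert np.array_equal(roi.mask, blobs)

    def test_empty_reaction_zone_raises(self):
        labels = RegionLabelMap(np.full((5, 5), CHIP, dtype=np.uint8))
        with pytest.raises(NoReactionDetectedError):
            extract_reaction_roi(labels)

    def test_matches_flood_fill_oracle(self, rng):
        blobs = rng.random((25, 25)) < 0.35
        if not blobs.any():
            blobs[0, 0] = True
        comps = flood_fill_components(blobs)
        expected = max(len(c) for c in comps)
        roi = extract_reaction_roi(self._labels_from_blobs(blobs))
        assert roi.area == expected
        assert roi.area <= np.count_nonzero(blobs)

    def test_saturation_tie_break(self):
        blobs = np.zeros((10, 20), dtype=bool)
        blobs[1:3, 1:3] = True
        blobs[6:8, 15:17] = True  # same area, more saturated
        hsv = np.zeros((10, 20, 3), dtype=np.uint8)
        hsv[..., 1] = 50
        hsv[6:8, 15:17, 1] = 200
        roi = extract_reaction_roi(self._labels_from_blobs(blobs), hsv)
        assert roi.bounding_box == (6, 15, 8, 17)


class TestDeriveHsvRange:
    def test_degenerate_envelope(self):
        r = derive_hsv_range(PixelSampleSet(((120, 200, 200),)))
        assert r.lower == r.upper == (120, 200, 200)

    def test_envelope_arithmetic(self):
        samples = PixelSampleSet(((100, 60, 60), (110, 80, 200)))
        r = derive_hsv_range(samples, (5, 10, 10))
        assert r.lower == (95, 50, 50)
        assert r.upper == (115, 90, 210)

    def test_envelope_oracle_and_containment(self, rng):
        triples = tuple(
            (int(h), int(s), int(v))
            for h, s, v in zip(rng.integers(0, 180, 50),
                               rng.integers(0, 256, 50),
                               rng.integers(0, 256, 50))
        )
        margin = tuple(int(m) for m in rng.integers(0, 30, 3))
        r = derive_hsv_range(PixelSampleSet(triples), margin)
        arr = np.array(triples)
        lo = np.clip(arr.min(axis=0) - margin, 0, [179, 255, 255])
        up = np.clip(arr.max(axis=0) + margin, 0, [179, 255, 255])
        assert r.lower == tuple(lo) and r.upper == tuple(up)
        assert all(r.contains(t) for t in triples)

    @given(
        st.lists(
            st.tuples(st.integers(0, 179), st.integers(0, 255), st.integers(0, 255)),
            min_size=1, max_size=20,
        ),
        st.tuples(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)),
    )
    @settings(max_examples=100, deadline=None)
    def test_containment_property(self, triples, margin):
        r = derive_hsv_range(PixelSampleSet(tuple(triples)), margin)
        assert all(r.contains(t) for t in triples)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            PixelSampleSet(())


class TestFullLadderRobustness:
    def test_roi_extraction_succeeds_across_concentrations(self):
        """Every rung of the detection range yields a usable reacted ROI under
        the documented noise tolerance."""
        from glucopad import make_calibration_ladder

        tmpl = SyntheticSpec(noise_sd=5.0, illumination_gradient=0.10, seed=5)
        for img, gt in make_calibration_ladder(list(range(50, 141, 10)), tmpl):
            chip = detect_chip(img)
            labels = label_regions(rgb_to_hsv(img), chip)
            roi = extract_reaction_roi(labels)
            assert roi.area <= labels.zone_mask(REACTION_ZONE).sum()
            assert roi.area > 0
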