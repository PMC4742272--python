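from collections import deque

import numpy as np
import pytest

from chromoscore import (
    BinaryMask,
    GrayImage,
    ThresholdConfig,
    SyntheticNucleusSpec,
    assess_continuity,
    detect_nucleolus,
    extract_perinuclear_ring,
    generate_nucleus,
    inner_perimeter_length,
    segment_nucleus,
)
from chromoscore.segmentation import NoPerinuclearSignal, SegmentationError

from conftest import random_nucleus_spec


def _annulus_image(size=160, r_in=40, r_out=47, dn_ring=200, dn_bg=50,
                   crack=None, gap_deg=None):
    yy, xx = np.mgrid[:size, :size].astype(float)
    dist = np.hypot(yy - size / 2, xx - size / 2)
    ring = (dist >= r_in) & (dist < r_out)
    if gap_deg is not None:
        theta = np.degrees(np.arctan2(yy - size / 2, xx - size / 2)) % 360
        ring &= ~(theta < gap_deg)
    arr = np.full((size, size), dn_bg, np.uint8)
    arr[ring] = dn_ring
    if crack is not None:
        arr[:, crack][ring[:, crack]] = dn_bg  # 1-px column crack
    roi = BinaryMask(dist <= r_out + 5)
    return GrayImage(arr), roi, ring


def _bfs_components(mask):
    """Brute-force 8-connected component labeling (test oracle)."""
    seen = np.zeros_like(mask, bool)
    comps = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = np.zeros_like(mask, bool)
                queue = deque([(r0, c0)])
                seen[r0, c0] = comp[r0, c0] = True
                while queue:
                    r, c = queue.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < rows and 0 <= cc < cols
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = comp[rr, cc] = True
                                queue.append((rr, cc))
                comps.append(comp)
    return comps


def test_clean_annulus_is_extracted_exactly(cfg):
    image, roi, ring = _annulus_image()
    mask = extract_perinuclear_ring(image, roi, cfg)
    np.testing.assert_array_equal(mask.pixels, ring)


def test_no_signal_raises(cfg):
    image = GrayImage(np.full((50, 50), 120, np.uint8))
    roi = BinaryMask(np.ones((50, 50), bool))
    with pytest.raises(NoPerinuclearSignal):
        extract_perinuclear_ring(image, roi, cfg)


def test_largest_blob_wins_and_matches_bfs_oracle(cfg):
    arr = np.full((120, 120), 50, np.uint8)
    arr[5:35, 5:35] = 200  # 900 px
    arr[50:100, 30:110] = 200  # 4000 px
    image = GrayImage(arr)
    roi = BinaryMask(np.ones((120, 120), bool))
    chosen = extract_perinuclear_ring(image, roi, ThresholdConfig(closing_radius=0))
    comps = _bfs_components(arr >= 145)
    biggest = max(comps, key=lambda c: c.sum())
    assert biggest.sum() == 4000
    np.testing.assert_array_equal(chosen.pixels, biggest)


def test_continuity_verdicts(cfg):
    closed_img, roi, _ = _annulus_image()
    ring = extract_perinuclear_ring(closed_img, roi, cfg)
    continuous, interior = assess_continuity(ring, cfg)
    assert continuous and interior.area > 0

    gapped_img, roi, _ = _annulus_image(gap_deg=15)
    ring = extract_perinuclear_ring(gapped_img, roi, cfg)
    continuous, interior = assess_continuity(ring, cfg)
    assert not continuous and interior.area == 0

    # a 1-px crack is bridged by the default closing radius
    cracked_img, roi, _ = _annulus_image(crack=80)
    ring = extract_perinuclear_ring(cracked_img, roi, cfg)
    continuous, _ = assess_continuity(ring, cfg)
    assert continuous
    # ... but not when closing is disabled
    ring = extract_perinuclear_ring(cracked_img, roi, ThresholdConfig(closing_radius=0))
    continuous, _ = assess_continuity(ring, ThresholdConfig(closing_radius=0))
    assert not continuous


def test_continuity_equals_border_flood_fill_oracle(cfg):
    """Verdict == 'background flooded from the border reaches no enclosed
    region of qualifying size' (4-connected background flood)."""
    rng = np.random.default_rng(4)
    for gapped in (False, True, False, True, False, True):
        spec = random_nucleus_spec(rng, gapped=gapped)
        image, truth = generate_nucleus(spec)
        ring = extract_perinuclear_ring(image, truth.roi_mask, cfg)
        verdict, _ = assess_continuity(ring, cfg)

        bg = ~ring.pixels
        reached = np.zeros_like(bg)
        queue = deque()
        rows, cols = bg.shape
        for r in range(rows):
            for c in (0, cols - 1):
                if bg[r, c] and not reached[r, c]:
                    reached[r, c] = True
                    queue.append((r, c))
        for c in range(cols):
            for r in (0, rows - 1):
                if bg[r, c] and not reached[r, c]:
                    reached[r, c] = True
                    queue.append((r, c))
        while queue:
            r, c = queue.popleft()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and bg[rr, cc] \
                        and not reached[rr, cc]:
                    reached[rr, cc] = True
                    queue.append((rr, cc))
        enclosed = bg & ~reached
        oracle = enclosed.sum() >= cfg.min_interior_area
        assert verdict == oracle


def _interior_with_blobs(blob_fracs, size=130, radius=55, dn_blob=230):
    yy, xx = np.mgrid[:size, :size].astype(float)
    dist = np.hypot(yy - size / 2, xx - size / 2)
    interior = dist < radius
    arr = np.full((size, size), 100, np.uint8)
    col = 20
    blobs = []
    for frac in blob_fracs:
        blob_r = np.sqrt(frac * interior.sum() / np.pi)
        blob = np.hypot(yy - size / 2, xx - col) <= blob_r
        blob &= interior
        arr[blob] = dn_blob
        blobs.append(blob)
        col += int(4 * blob_r) + 6
    return GrayImage(arr), BinaryMask(interior), blobs


def test_nucleolus_detection_rules(cfg):
    image, interior, blobs = _interior_with_blobs([0.08])
    found = detect_nucleolus(image, interior, cfg)
    np.testing.assert_array_equal(found.pixels, blobs[0])

    image, interior, _ = _interior_with_blobs([0.001, 0.001, 0.001])
    assert detect_nucleolus(image, interior, cfg).area == 0

    image, interior, blobs = _interior_with_blobs([0.06, 0.09])
    found = detect_nucleolus(image, interior, cfg)
    areas = sorted(b.sum() for b in blobs)
    assert found.area == areas[-1]  # only the larger qualifies as *the* nucleolus
    np.testing.assert_array_equal(found.pixels, max(blobs, key=lambda b: b.sum()))


def test_perimeter_of_known_shapes():
    square = np.zeros((140, 140), bool)
    square[20:120, 20:120] = True
    assert inner_perimeter_length(BinaryMask(square)) == pytest.approx(400, rel=0.02)

    yy, xx = np.mgrid[:260, :260].astype(float)
    disk = np.hypot(yy - 130, xx - 130) < 100
    assert inner_perimeter_length(BinaryMask(disk)) == pytest.approx(
        2 * np.pi * 100, rel=0.02
    )

    single = np.zeros((9, 9), bool)
    single[4, 4] = True
    assert inner_perimeter_length(BinaryMask(single)) > 0


def test_perimeter_rejects_degenerate_inputs():
    with pytest.raises(SegmentationError):
        inner_perimeter_length(BinaryMask.empty((10, 10)))
    two = np.zeros((10, 10), bool)
    two[1, 1] = two[8, 8] = True
    with pytest.raises(SegmentationError):
        inner_perimeter_length(BinaryMask(two))


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


def test_segment_nucleus_recovers_ground_truth_masks(cfg):
    rng = np.random.default_rng(8)
    for _ in range(3):
        image, truth = generate_nucleus(random_nucleus_spec(rng))
        seg = segment_nucleus(image, truth.roi_mask, cfg)
        assert seg.continuous
        assert _iou(seg.ring_mask.pixels, truth.ring_mask.pixels) >= 0.95
        assert _iou(seg.interior_mask.pixels, truth.interior_mask.pixels) >= 0.95
        # invariants of the composed result
        assert not np.any(seg.interior_mask.pixels & seg.ring_mask.pixels)
        assert not np.any(seg.nucleolus_mask.pixels & ~seg.interior_mask.pixels)

    image, truth = generate_nucleus(random_nucleus_spec(rng, gapped=True))
    seg = segment_nucleus(image, truth.roi_mask, cfg)
    assert not seg.continuous
    assert seg.interior_mask.area == 0 and seg.inner_perimeter == 0


def test_segmentation_is_equivariant_under_translation_and_rotation(cfg):
    spec = SyntheticNucleusSpec(seed=21, inner_radius=45, ring_thickness=5,
                                particle_density=4, image_size=160)
    image, truth = generate_nucleus(spec)
    base = segment_nucleus(image, truth.roi_mask, cfg)

    shifted = GrayImage(np.roll(image.pixels, (7, -5), axis=(0, 1)))
    roi_shifted = BinaryMask(np.roll(truth.roi_mask.pixels, (7, -5), axis=(0, 1)))
    seg_t = segment_nucleus(shifted, roi_shifted, cfg)
    assert seg_t.continuous == base.continuous
    assert seg_t.ring_mask.area == base.ring_mask.area
    assert seg_t.interior_mask.area == base.interior_mask.area
    assert seg_t.inner_perimeter == pytest.approx(base.inner_perimeter, rel=1e-6)

    rotated = GrayImage(np.rot90(image.pixels).copy())
    roi_rot = BinaryMask(np.rot90(truth.roi_mask.pixels).copy())
    seg_r = segment_nucleus(rotated, roi_rot, cfg)
    assert seg_r.continuous == base.continuous
    assert seg_r.ring_mask.area == base.ring_mask.area
    assert seg_r.interior_mask.area == base.interior_mask.area
    assert seg_r.inner_perimeter == pytest.approx(base.inner_perimeter, rel=1e-6)


def test_supplied_nucleolus_mask_overrides_detection(cfg):
    rng = np.random.default_rng(12)
    spec = random_nucleus_spec(rng)
    image, truth = generate_nucleus(spec)
    override = np.zeros(image.shape, bool)
    override[100:110, 100:110] = True
    seg = segment_nucleus(image, truth.roi_mask, cfg,
                          nucleolus_mask=BinaryMask(override))
    expected = override & seg.interior_mask.pixels
    np.testing.assert_array_equal(seg.nucleolus_mask.pixels, expected)
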