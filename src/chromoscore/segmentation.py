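"""Perinuclear-ring extraction, continuity assessment and nucleus delineation.

The perinuclear condensed chromatin of a cardiomyocyte nucleus appears in a
calibrated micrograph as a dense rim (DN >= ``t_peri``).  Whether that rim is
a topologically closed ring is the first-step classifier: nuclei whose rim
fails to enclose an interior are "Group A" (discontinuous), the rest
"Group N" (continuous).  Continuity is decided by enclosure — hole-filling
the extracted rim and asking whether a sufficiently large interior remains —
rather than by measuring gap arcs, because the operational definition of
discontinuity is exactly that the nucleus cannot be clipped out of the field.

Connectivity convention: 8-connectivity for foreground components,
4-connectivity for the background flood fill (the standard complementary
pair that avoids topological paradoxes on the square grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .image_model import BinaryMask, GrayImage, ThresholdConfig


class NoPerinuclearSignal(ValueError):
    """No pixel in the nucleus ROI reaches the perinuclear threshold."""


class SegmentationError(ValueError):
    """Degenerate input to a segmentation step (empty/disconnected interior)."""


_BG_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connected background
_FG_STRUCTURE = ndimage.generate_binary_structure(2, 2)  # 8-connected foreground


@dataclass(frozen=True)
class NucleusSegmentation:
    """Full delineation of one nucleus.

    ``ring_mask`` is the perinuclear condensed chromatin, ``interior_mask``
    the nucleoplasm it encloses and ``nucleolus_mask`` the dense body (if
    any) excluded from the nucleoplasmic score.  For a discontinuous nucleus
    (``continuous`` False) the interior and nucleolus are empty and the
    inner perimeter is 0.
    """

    ring_mask: BinaryMask
    interior_mask: BinaryMask
    nucleolus_mask: BinaryMask
    continuous: bool
    inner_perimeter: float
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        ring = self.ring_mask.pixels
        interior = self.interior_mask.pixels
        nucleolus = self.nucleolus_mask.pixels
        if np.any(interior & ring):
            raise ValueError("interior and ring masks overlap")
        if np.any(nucleolus & ~interior):
            raise ValueError("nucleolus mask must be a subset of the interior")
        if not self.continuous and (interior.any() or self.inner_perimeter != 0):
            raise ValueError("discontinuous nucleus must have empty interior")
        if self.continuous and (not interior.any() or self.inner_perimeter <= 0):
            raise ValueError("continuous nucleus needs interior and perimeter > 0")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_FG_STRUCTURE)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _dominant_ring_component(mask: np.ndarray) -> np.ndarray:
    """Pick the connected component that encloses the most area.

    Components are ranked by their hole-filled pixel count (raw count as
    tie-break): a perinuclear rim encloses the whole nucleus and always
    outranks solid dense bodies such as the nucleolus, which can exceed a
    thin rim in raw pixel count.  Only the ten largest components are
    examined — anything smaller cannot be a rim.
    """
    labels, n = ndimage.label(mask, structure=_FG_STRUCTURE)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    candidates = np.argsort(counts)[::-1][: min(10, n)]
    best_label, best_key = 0, (-1, -1)
    for label in candidates:
        if counts[label] == 0:
            continue
        component = labels == label
        filled = int(
            ndimage.binary_fill_holes(component, structure=_BG_STRUCTURE).sum()
        )
        key = (filled, int(counts[label]))
        if key > best_key:
            best_key, best_label = key, label
    return labels == best_label


def extract_perinuclear_ring(
    image: GrayImage, nucleus_roi: BinaryMask, cfg: ThresholdConfig = ThresholdConfig()
) -> BinaryMask:
    """Isolate the perinuclear condensed-chromatin rim within a nucleus ROI.

    Thresholds at DN >= ``t_peri``, applies a morphological closing of radius
    ``closing_radius`` (bridging sub-resolution staining cracks), and keeps
    the dominant 8-connected component — the one enclosing the most area,
    so a large solid nucleolus never displaces a thin rim.  Raises
    :class:`NoPerinuclearSignal` when no ROI pixel reaches the threshold.
    """
    nucleus_roi.require_shape(image.shape)
    dense = (image.pixels >= cfg.t_peri) & nucleus_roi.pixels
    if not dense.any():
        raise NoPerinuclearSignal(
            f"no pixel >= {cfg.t_peri} inside the nucleus ROI"
        )
    if cfg.closing_radius > 0:
        r = cfg.closing_radius
        padded = np.pad(dense, r)
        closed = ndimage.binary_closing(padded, structure=morphology.disk(r))
        dense = closed[r:-r, r:-r] & nucleus_roi.pixels
    return BinaryMask(_dominant_ring_component(dense))


def assess_continuity(
    ring: BinaryMask, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[bool, BinaryMask]:
    """Decide ring continuity by enclosure.

    Hole-fills the rim (4-connected background) and takes the largest
    8-connected component of fill-minus-rim.  The ring is continuous when
    that enclosed interior reaches ``min_interior_area`` pixels, which
    rejects speck enclosures.  Returns ``(continuous, interior)``; a
    discontinuous ring yields an empty interior.
    """
    filled = ndimage.binary_fill_holes(ring.pixels, structure=_BG_STRUCTURE)
    interior = _largest_component(filled & ~ring.pixels)
    if interior.sum() >= cfg.min_interior_area:
        return True, BinaryMask(interior)
    return False, BinaryMask.empty(ring.shape)


def detect_nucleolus(
    image: GrayImage, interior: BinaryMask, cfg: ThresholdConfig = ThresholdConfig()
) -> BinaryMask:
    """Find the nucleolus as the dominant condensed body in the nucleoplasm.

    Candidate = largest 8-connected component of {DN >= t_cond} within the
    interior; it qualifies only when its area reaches ``nucleolus_min_frac``
    of the interior area (scattered heterochromatin specks never do).
    Returns an empty mask when nothing qualifies.
    """
    interior.require_shape(image.shape)
    if interior.area == 0:
        raise SegmentationError("interior mask is empty")
    dense = (image.pixels >= cfg.t_cond) & interior.pixels
    blob = _largest_component(dense)
    if blob.sum() >= cfg.nucleolus_min_frac * interior.area:
        return BinaryMask(blob)
    return BinaryMask.empty(interior.shape)


def inner_perimeter_length(interior: BinaryMask) -> float:
    """Length of the inner nuclear perimeter in pixel units.

    Traces the 0.5-level iso-contour between inside and outside pixel
    centers with marching squares and sums the segment lengths of the
    longest closed contour.  The indicator is lightly Gaussian-smoothed
    (sigma = 1 px) before contouring: the raw staircase contour of a
    digitized region systematically overestimates curved boundaries by
    ~5%, while the smoothed 0.5-level set tracks the underlying smooth
    boundary to well under 2% for both squares and disks.  Regions too
    small to survive smoothing (a few pixels) fall back to the raw binary
    contour, so degenerate inputs still return a small positive length.
    """
    px = interior.pixels
    if not px.any():
        raise SegmentationError("empty interior has no perimeter")
    _, n = ndimage.label(px, structure=_FG_STRUCTURE)
    if n != 1:
        raise SegmentationError("interior must be a single connected component")
    padded = np.pad(px.astype(np.float64), 3)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    field = smoothed if smoothed.max() >= 0.5 else padded
    contours = measure.find_contours(field, 0.5)
    lengths = [
        float(np.hypot(*np.diff(c, axis=0).T).sum()) for c in contours
    ]
    return max(lengths)


def segment_nucleus(
    image: GrayImage,
    nucleus_roi: BinaryMask,
    cfg: ThresholdConfig = ThresholdConfig(),
    nucleolus_mask: BinaryMask | None = None,
    nucleus_id: str = "",
) -> NucleusSegmentation:
    """Run the full per-nucleus segmentation on a calibrated image.

    Composes ring extraction, continuity assessment, nucleolus detection and
    perimeter measurement.  A supplied ``nucleolus_mask`` (e.g. a manual
    annotation) overrides automatic detection; it is clipped to the interior.
    """
    ring = extract_perinuclear_ring(image, nucleus_roi, cfg)
    continuous, interior = assess_continuity(ring, cfg)
    if not continuous:
        return NucleusSegmentation(
            ring_mask=ring,
            interior_mask=BinaryMask.empty(image.shape),
            nucleolus_mask=BinaryMask.empty(image.shape),
            continuous=False,
            inner_perimeter=0.0,
            nucleus_id=nucleus_id,
        )
    if nucleolus_mask is not None:
        nucleolus = BinaryMask(
            nucleolus_mask.require_shape(image.shape).pixels & interior.pixels
        )
    else:
        nucleolus = detect_nucleolus(image, interior, cfg)
    perimeter = inner_perimeter_length(interior)
    return NucleusSegmentation(
        ring_mask=ring,
        interior_mask=interior,
        nucleolus_mask=nucleolus,
        continuous=True,
        inner_perimeter=perimeter,
        nucleus_id=nucleus_id,
    )
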