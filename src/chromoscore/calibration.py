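"""Z-disk anchored grayscale calibration.

Electron-micrograph brightness varies with exposure and staining, so raw DN
are not comparable across images.  The sarcomeric Z-disk is used as an
internal density reference: each image is rescaled by a single multiplicative
gain so that the mean DN inside the Z-disk ROI lands on the target value
(default 159, the midpoint of the accepted window [154, 164]).  Chromatin
thresholds applied downstream are therefore relative to the Z-disk density.

The map is gain-only (anchored at DN 0) rather than affine: the correction
is a ratio to the reference density and DN 0 must stay "no signal".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_model import BinaryMask, GrayImage, ThresholdConfig

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Empty ROI, zero reference density, or unusable (saturated) image."""


@dataclass(frozen=True)
class CalibrationRecord:
    """Provenance of one calibration: the gain applied and what it achieved."""

    gain: float
    zdisk_mean_before: float
    zdisk_mean_after: float
    clipped_fraction: float

    def to_dict(self) -> dict:
        return {
            "gain": self.gain,
            "zdisk_mean_before": self.zdisk_mean_before,
            "zdisk_mean_after": self.zdisk_mean_after,
            "clipped_fraction": self.clipped_fraction,
        }


def _roi_mean(image: GrayImage, roi: BinaryMask) -> float:
    roi.require_shape(image.shape)
    if roi.area == 0:
        raise CalibrationError("Z-disk ROI is empty")
    return float(image.pixels[roi.pixels].mean())


def calibrate_to_zdisk(
    image: GrayImage, zdisk_roi: BinaryMask, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[GrayImage, CalibrationRecord]:
    """Rescale an image so the Z-disk ROI mean hits the calibration target.

    Every pixel is mapped to ``round(gain * DN)`` clamped to [0, 255] with
    ``gain = zdisk_target / roi_mean``.  Raises :class:`CalibrationError`
    when the ROI is empty or has zero mean, or when clipping at 255 leaves
    the recalculated ROI mean outside the accepted window (a saturated,
    unusable micrograph).
    """
    mean_before = _roi_mean(image, zdisk_roi)
    if mean_before <= 0:
        raise CalibrationError("Z-disk ROI mean is zero; cannot derive a gain")
    gain = cfg.zdisk_target / mean_before
    scaled = np.rint(image.pixels.astype(np.float64) * gain)
    clipped_fraction = float((scaled > 255).mean())
    out_pixels = np.clip(scaled, 0, 255).astype(np.uint8)
    out = image.with_pixels(out_pixels)
    mean_after = _roi_mean(out, zdisk_roi)
    if not (cfg.zdisk_lo <= mean_after <= cfg.zdisk_hi):
        raise CalibrationError(
            f"post-calibration Z-disk mean {mean_after:.1f} outside "
            f"[{cfg.zdisk_lo}, {cfg.zdisk_hi}]; image unusable"
        )
    if clipped_fraction > 0.01:
        logger.warning(
            "calibration clipped %.1f%% of pixels at 255 (gain %.3f)",
            100 * clipped_fraction,
            gain,
        )
    record = CalibrationRecord(
        gain=gain,
        zdisk_mean_before=mean_before,
        zdisk_mean_after=mean_after,
        clipped_fraction=clipped_fraction,
    )
    return out, record


def verify_calibration(
    image: GrayImage, zdisk_roi: BinaryMask, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[bool, float]:
    """Check that the Z-disk ROI mean lies in the accepted window.

    Returns ``(passed, measured_mean)``.
    """
    mean = _roi_mean(image, zdisk_roi)
    return cfg.zdisk_lo <= mean <= cfg.zdisk_hi, mean
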