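"""Percent interstitial fibrosis from Masson-trichrome RGB scans.

Collagen stains blue under Masson's trichrome; fibrosis is quantified as the
blue-pixel fraction of the tissue area, after excluding the endocardium
(supplied as a user mask — the exclusion is anatomical, not algorithmic).
Blue detection is a simple HSV band test, configurable for stain-to-stain
variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color

from .image_model import BinaryMask


class FibrosisError(ValueError):
    """Empty tissue area after endocardium exclusion."""


@dataclass(frozen=True)
class TrichromeImage:
    """An 8-bit RGB trichrome scan with tissue / endocardium annotations."""

    pixels: np.ndarray  # H x W x 3 uint8
    tissue_mask: BinaryMask
    endocardium_mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[-1] != 3:
            raise ValueError("trichrome image must be H x W x 3")
        if px.dtype != np.uint8:
            raise ValueError("trichrome image must be 8-bit per channel")
        object.__setattr__(self, "pixels", px)
        self.tissue_mask.require_shape(px.shape[:2])
        if self.endocardium_mask is not None:
            self.endocardium_mask.require_shape(px.shape[:2])
            if np.any(self.endocardium_mask.pixels & ~self.tissue_mask.pixels):
                raise ValueError("endocardium mask must lie within the tissue mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def detect_blue(
    image: TrichromeImage,
    hue_band: tuple[float, float] = (180.0, 260.0),
    sat_min: float = 0.2,
    val_min: float = 0.2,
) -> BinaryMask:
    """Flag blue (collagen) pixels by an HSV band test.

    A pixel is blue iff hue (degrees) lies in ``hue_band`` and both
    saturation and value reach their minima — the latter reject near-gray
    and near-black pixels whose hue is meaningless.
    """
    hsv = color.rgb2hsv(image.pixels)
    hue_deg = hsv[..., 0] * 360.0
    lo, hi = hue_band
    blue = (
        (hue_deg >= lo)
        & (hue_deg <= hi)
        & (hsv[..., 1] >= sat_min)
        & (hsv[..., 2] >= val_min)
    )
    return BinaryMask(blue)


def fibrosis_fraction(image: TrichromeImage, blue: BinaryMask) -> float:
    """Percent fibrosis: blue area over tissue area, endocardium excluded."""
    blue.require_shape(image.shape)
    region = image.tissue_mask.pixels.copy()
    if image.endocardium_mask is not None:
        region &= ~image.endocardium_mask.pixels
    denom = int(region.sum())
    if denom == 0:
        raise FibrosisError("no tissue left after endocardium exclusion")
    return 100.0 * int((blue.pixels & region).sum()) / denom
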