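"""Core image and mask data types shared by the whole pipeline.

Transmission-electron micrographs are handled as 8-bit grayscale grids of
integer digital numbers (DN, 0-255).  Region annotations (the Z-disk
reference, the nucleus neighbourhood, an optional nucleolus) travel as
boolean masks of identical shape, read either from 8-bit mask images
(nonzero = inside) or from plain-text polygon files rasterized with the
even-odd rule at pixel centers.

Conventions
-----------
* Coordinates are 0-based, row-major ``(row, col)``; intervals half-open.
* Areas are pixel counts; lengths are in pixel units.
* Thresholds follow the 256-level grayscale convention in which the
  "highest quartile" spans the top 64 levels: on the internal 0-255 scale
  the perinuclear band is DN >= 145, condensed chromatin is DN >= 192 and
  the Z-disk calibration window is [154, 164] with midpoint target 159.
  All of these live in :class:`ThresholdConfig` and are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from PIL import Image


class ImageFormatError(ValueError):
    """Unsupported file format or bit depth without an explicit conversion flag."""


class MaskShapeError(ValueError):
    """Mask shape does not match the image it annotates."""


class PolygonError(ValueError):
    """Malformed polygon annotation (fewer than three vertices, bad line)."""


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale micrograph.

    Attributes
    ----------
    pixels : numpy.ndarray
        2-D ``uint8`` array of digital numbers in [0, 255].
    pixel_size : float, optional
        Physical pixel pitch in nm/px, when known.
    source_id : str
        Free-form provenance label (file name, generator spec, ...).
    """

    pixels: np.ndarray
    pixel_size: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixel grid must be 2-D and non-empty")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("digital numbers must be integers")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("digital numbers must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean region-of-interest grid matching an image's shape."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask grid must be 2-D and non-empty")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        """Number of pixels inside the mask."""
        return int(self.pixels.sum())

    def require_shape(self, shape: tuple[int, int]) -> "BinaryMask":
        if self.pixels.shape != tuple(shape):
            raise MaskShapeError(
                f"mask shape {self.pixels.shape} != expected {tuple(shape)}"
            )
        return self

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "BinaryMask":
        return cls(np.zeros(shape, dtype=bool))


@dataclass(frozen=True)
class ThresholdConfig:
    """All grayscale thresholds and segmentation parameters in one place.

    ``t_peri`` delimits perinuclear condensed chromatin (the ring band),
    ``t_cond`` condensed chromatin (top grayscale quartile); both are applied
    inclusively as DN >= threshold.  ``zdisk_lo``/``zdisk_hi`` bound the
    calibration window for the sarcomeric Z-disk reference and
    ``zdisk_target`` is the gain target (window midpoint).
    """

    t_peri: int = 145
    t_cond: int = 192
    zdisk_lo: int = 154
    zdisk_hi: int = 164
    zdisk_target: int = 159
    closing_radius: int = 1
    min_interior_area: int = 500
    nucleolus_min_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.t_peri < self.t_cond <= 255):
            raise ValueError("require 0 < t_peri < t_cond <= 255")
        if not (self.zdisk_lo <= self.zdisk_target <= self.zdisk_hi):
            raise ValueError("require zdisk_lo <= zdisk_target <= zdisk_hi")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.min_interior_area < 1:
            raise ValueError("min_interior_area must be >= 1")
        if not (0.0 <= self.nucleolus_min_frac <= 1.0):
            raise ValueError("nucleolus_min_frac must lie in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdConfig":
        """Load a flat key/value config file (YAML syntax)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# readers / writers


def read_gray_image(path: str | Path, allow_convert: bool = False) -> GrayImage:
    """Read an 8-bit grayscale TIFF or PNG, preserving DN bit-exactly.

    Multi-channel or deeper-bit inputs raise :class:`ImageFormatError`
    unless ``allow_convert`` is set, in which case RGB is collapsed by
    luminance (ITU-R BT.601) and 16-bit data is rescaled by ``>> 8``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _IMAGE_SUFFIXES:
        raise ImageFormatError(f"unsupported image format: {path.name}")
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))

    if arr.ndim == 3:
        if not allow_convert:
            raise ImageFormatError(
                f"{path.name} is multi-channel; pass allow_convert=True "
                "for luminance conversion"
            )
        rgb = arr[..., :3].astype(np.float64)
        arr = np.rint(rgb @ [0.299, 0.587, 0.114]).astype(np.uint16)
    if arr.dtype != np.uint8:
        if not allow_convert:
            raise ImageFormatError(
                f"{path.name} has bit depth != 8; pass allow_convert=True"
            )
        if arr.dtype == np.uint16:
            arr = (arr >> 8).astype(np.uint8)
        else:
            arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return GrayImage(pixels=arr, source_id=path.name)


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as 8-bit PNG or TIFF (round-trip safe)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image.pixels)
    elif suffix == ".png":
        Image.fromarray(image.pixels, mode="L").save(path)
    else:
        raise ImageFormatError(f"unsupported output format: {path.name}")


def polygon_mask(
    vertices: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> BinaryMask:
    """Rasterize a closed polygon with the even-odd rule at pixel centers.

    Vertices are ``(row, col)`` in 0-based pixel-center coordinates; the
    polygon is implicitly closed from the last vertex back to the first.
    The crossing-parity test makes integer-aligned rectangles half-open:
    a rectangle (r0,c0)-(r1,c1) covers exactly [r0,r1) x [c0,c1).
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise PolygonError("polygon needs at least three (row, col) vertices")
    nr, nc = shape
    rr = np.arange(nr, dtype=float)[:, None]
    cc = np.arange(nc, dtype=float)[None, :]
    inside = np.zeros(shape, dtype=bool)
    r1s, c1s = verts[:, 0], verts[:, 1]
    r2s, c2s = np.roll(r1s, -1), np.roll(c1s, -1)
    for r1, c1, r2, c2 in zip(r1s, c1s, r2s, c2s):
        if r1 == r2:  # horizontal edge never crosses a horizontal ray
            continue
        crosses = (r1 > rr) != (r2 > rr)
        x_int = (c2 - c1) * (rr - r1) / (r2 - r1) + c1
        inside ^= crosses & (cc < x_int)
    return BinaryMask(inside)


def _parse_polygon_file(path: Path) -> list[tuple[float, float]]:
    verts: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise PolygonError(f"{path.name}:{lineno}: expected 'row,col'")
        try:
            verts.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PolygonError(f"{path.name}:{lineno}: {exc}") from exc
    if len(verts) < 3:
        raise PolygonError(f"{path.name}: polygon needs >= 3 vertices")
    return verts


def read_mask(path: str | Path, shape: tuple[int, int]) -> BinaryMask:
    """Read a region mask of the requested shape.

    PNG/TIFF files are interpreted as nonzero = inside; any other suffix is
    parsed as a plain-text polygon (one ``row,col`` vertex per line,
    ``#`` comments allowed) and rasterized with the even-odd rule.
    """
    path = Path(path)
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        if path.suffix.lower() == ".png":
            arr = np.asarray(Image.open(path))
        else:
            arr = tifffile.imread(str(path))
        if arr.ndim == 3:
            arr = arr[..., :3].any(axis=-1)
        return BinaryMask(arr != 0).require_shape(shape)
    return polygon_mask(_parse_polygon_file(path), shape)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (255 = inside)."""
    Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L").save(path)
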