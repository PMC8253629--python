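"""Image and region-of-interest data model, raster I/O, and region statistics.

All filters and metrics in this package operate on :class:`Image`, a thin
wrapper around a 2-D float64 array with a declared value range.  Integer
raster files (8/16-bit PNG and TIFF) are normalized to [0, 1] on read so
that intensity-dependent filter parameters (the Perona-Malik threshold ``k``,
the bilateral range scale) are independent of the source bit depth; pass
``raw=True`` to keep native units.

Regions of interest are axis-aligned rectangles or discs.  Disc membership
is evaluated at pixel centers: pixel ``(i, j)`` belongs to a disc with
center ``(ci, cj)`` and radius ``r`` iff ``(i-ci)**2 + (j-cj)**2 <= r**2``.
Coordinates are 0-based ``(row, column)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile


class ImageError(ValueError):
    """Invalid image data or unsupported raster input."""


class RegionError(ValueError):
    """Region is empty, out of bounds, or otherwise unusable."""


@dataclass(frozen=True)
class Image:
    """A 2-D grayscale image with a declared representable value range."""

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ImageError("pixels contain NaN or Inf")
        lo, hi = self.value_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ImageError(f"invalid value_range {self.value_range}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "Image":
        """Return a new Image sharing this image's value range."""
        return Image(pixels=pixels, value_range=self.value_range)


RegionRole = Literal["feature", "background"]


@dataclass(frozen=True)
class Region:
    """Rectangular or disc-shaped region of interest.

    Rectangles use half-open integer bounds ``(r0, c0, r1, c1)``; discs use an
    integer-or-float ``center=(row, col)`` and ``radius`` in pixels.  ``role``
    records whether the region samples the lesion (``feature``) or the
    surrounding tissue (``background``).
    """

    shape: Literal["rect", "disc"]
    role: RegionRole = "background"
    name: str = ""
    bounds: tuple[int, int, int, int] | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "rect":
            if self.bounds is None:
                raise RegionError("rect region requires bounds=(r0, c0, r1, c1)")
            r0, c0, r1, c1 = self.bounds
            if r1 <= r0 or c1 <= c0:
                raise RegionError(f"empty rectangle bounds {self.bounds}")
        elif self.shape == "disc":
            if self.center is None or self.radius is None:
                raise RegionError("disc region requires center and radius")
            if self.radius <= 0:
                raise RegionError(f"disc radius must be positive, got {self.radius}")
        else:
            raise RegionError(f"unknown region shape {self.shape!r}")

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of this region on an image of the given shape.

        Raises :class:`RegionError` if the region extends outside the image
        or resolves to an empty mask.
        """
        h, w = image_shape
        if self.shape == "rect":
            r0, c0, r1, c1 = self.bounds  # type: ignore[misc]
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise RegionError(f"rectangle {self.bounds} outside image {image_shape}")
            m = np.zeros((h, w), dtype=bool)
            m[r0:r1, c0:c1] = True
        else:
            ci, cj = self.center  # type: ignore[misc]
            r = float(self.radius)  # type: ignore[arg-type]
            if ci - r < -0.5 or cj - r < -0.5 or ci + r > h - 0.5 or cj + r > w - 0.5:
                raise RegionError(
                    f"disc center={self.center} radius={self.radius} outside image {image_shape}"
                )
            ii, jj = np.mgrid[0:h, 0:w]
            m = (ii - ci) ** 2 + (jj - cj) ** 2 <= r**2
        if not m.any():
            raise RegionError(f"region {self.name or self.shape} resolves to an empty mask")
        return m

    def pixel_count(self, image_shape: tuple[int, int]) -> int:
        return int(self.mask(image_shape).sum())

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "role": self.role, "shape": self.shape}
        if self.shape == "rect":
            d["bounds"] = list(self.bounds)  # type: ignore[arg-type]
        else:
            d["center"] = list(self.center)  # type: ignore[arg-type]
            d["radius"] = self.radius
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        shape = d["shape"]
        if shape == "rect":
            return cls(
                shape="rect",
                role=d.get("role", "background"),
                name=d.get("name", ""),
                bounds=tuple(d["bounds"]),
            )
        return cls(
            shape="disc",
            role=d.get("role", "background"),
            name=d.get("name", ""),
            center=tuple(d["center"]),
            radius=d["radius"],
        )


@dataclass(frozen=True)
class RegionStats:
    """Mean, standard deviation and pixel count of a masked region."""

    mean: float
    std: float
    n: int


def region_stats(image: Image, region: Region, ddof: int = 0) -> RegionStats:
    """Mean and standard deviation of the pixels inside ``region``.

    The population convention (``ddof=0``) is the default throughout the
    package; pass ``ddof=1`` for the sample convention.
    """
    m = region.mask(image.pixels.shape)
    vals = image.pixels[m]
    return RegionStats(
        mean=float(vals.mean()),
        std=float(vals.std(ddof=ddof)),
        n=int(vals.size),
    )


def load_rois(path: str | Path) -> list[Region]:
    """Load a list of regions from a JSON ROI file."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise RegionError("ROI file must contain a JSON list of region objects")
    return [Region.from_dict(d) for d in data]


def save_rois(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in regions], fh, indent=2)


def feature_background_pair(regions: Sequence[Region]) -> tuple[Region, Region]:
    """Pick the first feature and first background region from a list."""
    feature = next((r for r in regions if r.role == "feature"), None)
    background = next((r for r in regions if r.role == "background"), None)
    if feature is None or background is None:
        raise RegionError("ROI set must contain one 'feature' and one 'background' region")
    return feature, background


_INT_MAX = {np.uint8: 255, np.uint16: 65535}


def read_image(path: str | Path, convert: bool = False, raw: bool = False) -> Image:
    """Read a grayscale PNG or TIFF into a float64 :class:`Image`.

    Integer inputs are scaled to [0, 1] by the maximum of their bit depth
    (255 or 65535) unless ``raw=True``.  Multi-channel images are rejected
    unless ``convert=True``, which averages channels to luminance using the
    Rec. 601 weights.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ImageError(f"unsupported raster format {suffix!r} (use PNG or TIFF)")
    if arr.ndim == 3:
        if not convert:
            raise ImageError(
                f"{path.name} has {arr.shape[-1]} channels; pass convert=True for luminance"
            )
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.299, 0.587, 0.114])
    if arr.ndim != 2:
        raise ImageError(f"expected a 2-D image, got shape {arr.shape}")

    if np.issubdtype(arr.dtype, np.integer):
        maxval = float(np.iinfo(arr.dtype).max)
        if raw:
            return Image(arr.astype(np.float64), value_range=(0.0, maxval))
        return Image(arr.astype(np.float64) / maxval, value_range=(0.0, 1.0))
    px = arr.astype(np.float64)
    lo = min(0.0, float(px.min()))
    hi = max(1.0, float(px.max()))
    return Image(px, value_range=(lo, hi))


def write_image(
    image: Image, path: str | Path, depth: int | str = "float", clip: bool = True
) -> None:
    """Write an image as PNG/TIFF at 8-bit, 16-bit or float32/64 depth.

    ``depth`` is 8, 16 or ``"float"``.  At integer depths, pixel values are
    interpreted on the [0, 1] scale and quantized by rounding, so the
    round-trip error is at most half a quantization step.  Out-of-range
    values are clipped when ``clip=True`` and rejected otherwise.
    """
    path = Path(path)
    px = image.pixels
    suffix = path.suffix.lower()
    if depth == "float":
        if suffix == ".png":
            raise ImageError("PNG does not support float depth; use TIFF")
        tifffile.imwrite(path, px.astype(np.float64))
        return
    if depth not in (8, 16):
        raise ImageError(f"depth must be 8, 16 or 'float', got {depth!r}")
    if px.min() < 0.0 or px.max() > 1.0:
        if not clip:
            raise ImageError("pixel values outside [0, 1] at integer depth (clip=False)")
        px = np.clip(px, 0.0, 1.0)
    maxval = 255 if depth == 8 else 65535
    dtype = np.uint8 if depth == 8 else np.uint16
    quant = np.rint(px * maxval).astype(dtype)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, quant)
    elif suffix == ".png":
        iio.imwrite(path, quant)
    else:
        raise ImageError(f"unsupported raster format {suffix!r} (use PNG or TIFF)")
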