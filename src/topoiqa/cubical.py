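"""Cubical-complex representation of grayscale images.

A 2-D grayscale image is modelled with the T-construction: every pixel is a
top-dimensional 2-cube (square) carrying its intensity, and every face
(edge, vertex) carries the minimum intensity over the squares it bounds.
Sublevel sets of the resulting filtration are the "dark" regions of the
image thresholded at each luminescence level; foreground components obey
8-connectivity and holes 4-connectivity as a consequence of the min rule.

Coordinate convention: row-major, origin at the top-left pixel, 0-based
anchors.  Internally the complex is stored on the doubled grid of shape
``(2H+1, 2W+1)`` where cell ``(r, c)`` has dimension ``(r % 2) + (c % 2)``
(odd/odd -> square for pixel ``(r//2, c//2)``, mixed parity -> edge,
even/even -> vertex).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import minimum_filter

__all__ = [
    "ValidationError",
    "GrayImage",
    "FilteredCubicalComplex",
    "SublevelSet",
    "to_grayscale",
    "build_complex",
    "sublevel_set",
    "binarize",
]

#: ITU-R BT.601 luminance weights used for color -> grayscale conversion.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer intensities with a fixed luminescence depth.

    Parameters
    ----------
    values
        ``(H, W)`` integer array, entries in ``[0, depth - 1]``.
    depth
        Number of luminescence levels (256 for 8-bit images).
    """

    values: np.ndarray
    depth: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError(
                f"image must be a non-empty 2-D grid, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValidationError("intensities must be integers")
            arr = arr.astype(np.int64)
        if self.depth < 1:
            raise ValidationError(f"depth must be positive, got {self.depth}")
        if arr.min() < 0 or arr.max() > self.depth - 1:
            raise ValidationError(
                f"intensities must lie in [0, {self.depth - 1}], got range "
                f"[{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "values", arr.astype(np.int64))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    # -- plain-text serialization (fixture-friendly) ----------------------
    def to_text(self, path: str | os.PathLike) -> None:
        """Write as a plain-text matrix, one row per line."""
        np.savetxt(path, self.values, fmt="%d")

    @classmethod
    def from_text(cls, path: str | os.PathLike, depth: int = 256) -> "GrayImage":
        arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
        return cls(arr, depth=depth)


@dataclass(frozen=True)
class FilteredCubicalComplex:
    """Filtered cubical complex of an image under the min-extension.

    ``values[r, c]`` is the filtration value of the cell anchored at the
    doubled-grid coordinate ``(r, c)``; see the module docstring for the
    parity convention.  The complex of an ``H x W`` image has ``H * W``
    squares, ``H * (W + 1) + W * (H + 1)`` edges and ``(H+1) * (W+1)``
    vertices, and every face value is <= every coface value.
    """

    values: np.ndarray  # (2H+1, 2W+1) filtration values
    depth: int

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    @property
    def n_squares(self) -> int:
        h, w = self.image_shape
        return h * w

    @property
    def n_edges(self) -> int:
        h, w = self.image_shape
        return h * (w + 1) + w * (h + 1)

    @property
    def n_vertices(self) -> int:
        h, w = self.image_shape
        return (h + 1) * (w + 1)

    @staticmethod
    def cell_dimension(r: int, c: int) -> int:
        return (r % 2) + (c % 2)

    def dimension_grid(self) -> np.ndarray:
        """Array of cell dimensions matching :attr:`values`."""
        r = np.arange(self.values.shape[0]) % 2
        c = np.arange(self.values.shape[1]) % 2
        return r[:, None] + c[None, :]

    def pixel_values(self) -> np.ndarray:
        """The original image intensities (values of the 2-cubes)."""
        return self.values[1::2, 1::2]


@dataclass(frozen=True)
class SublevelSet:
    """Cells of a filtered complex with filtration value <= ``level``."""

    level: int
    mask: np.ndarray  # boolean, doubled-grid shape
    depth: int

    def contains(self, r: int, c: int) -> bool:
        return bool(self.mask[r, c])

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def cell_counts(self) -> tuple[int, int, int]:
        """(vertices, edges, squares) present in the sublevel set."""
        dims = (np.arange(self.mask.shape[0]) % 2)[:, None] + (
            np.arange(self.mask.shape[1]) % 2
        )[None, :]
        return tuple(int(np.sum(self.mask & (dims == d))) for d in range(3))


def to_grayscale(image: "str | os.PathLike | np.ndarray") -> GrayImage:
    """Convert a raster image (path or array) to an 8-bit :class:`GrayImage`.

    Color inputs are reduced with the ITU-R BT.601 luminance weights
    (0.299, 0.587, 0.114), rounded to the nearest integer; single-channel
    inputs pass through unchanged.
    """
    if isinstance(image, (str, Path)):
        from PIL import Image, UnidentifiedImageError

        try:
            with Image.open(image) as im:
                arr = np.asarray(im)
        except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
            raise OSError(f"cannot read image file {image!r}: {exc}") from exc
    else:
        arr = np.asarray(image)

    if arr.size == 0:
        raise ValidationError("image has zero size")
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        gray = np.rint(rgb @ np.asarray(BT601_WEIGHTS))
    elif arr.ndim == 3 and arr.shape[2] == 1:
        gray = arr[..., 0]
    else:
        raise ValidationError(f"unsupported image shape {arr.shape}")
    return GrayImage(np.clip(gray, 0, 255).astype(np.int64), depth=256)


def build_complex(img: GrayImage) -> FilteredCubicalComplex:
    """Build the filtered cubical complex of ``img`` (T-construction).

    Each pixel becomes a square valued at its intensity; each edge and
    vertex takes the minimum value over the squares it is a face of.
    """
    h, w = img.values.shape
    # sentinel must survive the filter's float round-trip exactly
    big = np.int64(2**62)
    doubled = np.full((2 * h + 1, 2 * w + 1), big, dtype=np.int64)
    doubled[1::2, 1::2] = img.values
    # A 3x3 minimum filter on the doubled grid realises the min-extension:
    # the window around a square contains only that square; around an edge,
    # its <=2 cofaces; around a vertex, its <=4 cofaces.
    values = minimum_filter(doubled, size=3, mode="constant", cval=big)
    return FilteredCubicalComplex(values=values, depth=img.depth)


def sublevel_set(cx: FilteredCubicalComplex, i: int) -> SublevelSet:
    """Cells with filtration value <= ``i`` (closed under faces)."""
    return SublevelSet(level=int(i), mask=cx.values <= i, depth=cx.depth)


def binarize(img: GrayImage, threshold: int) -> np.ndarray:
    """Boolean foreground mask: pixel is foreground iff value <= threshold.

    The foreground is the sublevel ("dark") set the filtration analyses.
    """
    if not (0 <= threshold <= img.depth - 1):
        raise ValidationError(
            f"threshold must be in [0, {img.depth - 1}], got {threshold}"
        )
    return img.values <= threshold
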