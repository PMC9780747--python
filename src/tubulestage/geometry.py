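"""Geometric primitives shared by the whole pipeline.

Conventions
-----------
Coordinates are 0-based with ``x`` the column and ``y`` the row index.
Boxes are half-open pixel rectangles ``[x0, x1) x [y0, y1)``, so an integer
box's area is an exact pixel count. All overlap ratios (IOU / Jaccard) are
computed on the discrete pixel lattice, which makes box IOU and mask IOU
mutually consistent: a filled box and its rectangle give identical numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Invalid geometric input (degenerate box, empty mask, out of bounds)."""


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned pixel rectangle ``[x0,x1) x [y0,y1)``."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise GeometryError(f"degenerate box {self!r}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x1, self.y1)


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Jaccard index of two boxes on the pixel lattice.

    For integer-coordinate half-open boxes the interval-overlap formula
    equals an explicit pixel count; float boxes (e.g. confidence-weighted
    merged boxes) use the same continuous formula.
    """
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def rotate_box(box: BoundingBox, k: int, size: int) -> BoundingBox:
    """Map a box under rotation of its ``size x size`` tile by ``k`` quarter
    turns counter-clockwise (the convention of ``np.rot90`` on a ``[y, x]``
    indexed image).

    Rotating by ``k`` then ``4 - k`` is the identity. The box must lie inside
    the tile.
    """
    if k not in (0, 1, 2, 3):
        raise GeometryError(f"k must be in 0..3, got {k}")
    if box.x0 < 0 or box.y0 < 0 or box.x1 > size or box.y1 > size:
        raise GeometryError(f"box {box} outside [0,{size})^2")
    b = box
    for _ in range(k):
        # one CCW quarter turn: pixel (x, y) -> (y, size-1-x)
        b = BoundingBox(b.y0, size - b.x1, b.y1, size - b.x0)
    return b


class PixelMask:
    """A set of pixels stored as a tight local boolean patch plus an offset.

    Keeps whole-slide tubule masks affordable: operations (area, IOU,
    union, point membership) only touch the occupied window.
    """

    __slots__ = ("x0", "y0", "data", "_area")

    def __init__(self, x0: int, y0: int, data: np.ndarray):
        data = np.asarray(data, dtype=bool)
        if data.ndim != 2:
            raise GeometryError("mask patch must be 2-D")
        self.x0 = int(x0)
        self.y0 = int(y0)
        self.data = data
        self._area = int(data.sum())

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PixelMask":
        """Build from a full-frame boolean array, cropping to the tight bbox."""
        arr = np.asarray(arr, dtype=bool)
        ys, xs = np.nonzero(arr)
        if ys.size == 0:
            return cls(0, 0, np.zeros((0, 0), dtype=bool))
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        return cls(int(x0), int(y0), arr[y0:y1, x0:x1].copy())

    # -- basic properties --------------------------------------------------
    @property
    def area(self) -> int:
        return self._area

    @property
    def bbox(self) -> BoundingBox:
        if self._area == 0:
            raise GeometryError("empty mask has no bbox")
        ys, xs = np.nonzero(self.data)
        return BoundingBox(
            self.x0 + int(xs.min()),
            self.y0 + int(ys.min()),
            self.x0 + int(xs.max()) + 1,
            self.y0 + int(ys.max()) + 1,
        )

    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.data)
        if ys.size == 0:
            raise GeometryError("empty mask has no centroid")
        return (self.x0 + float(xs.mean()), self.y0 + float(ys.mean()))

    def contains_point(self, x: float, y: float) -> bool:
        xi, yi = int(np.floor(x)) - self.x0, int(np.floor(y)) - self.y0
        if 0 <= yi < self.data.shape[0] and 0 <= xi < self.data.shape[1]:
            return bool(self.data[yi, xi])
        return False

    def translate(self, dx: int, dy: int) -> "PixelMask":
        return PixelMask(self.x0 + int(dx), self.y0 + int(dy), self.data)

    # -- set operations ----------------------------------------------------
    def _window(self, other: "PixelMask"):
        x0 = max(self.x0, other.x0)
        y0 = max(self.y0, other.y0)
        x1 = min(self.x0 + self.data.shape[1], other.x0 + other.data.shape[1])
        y1 = min(self.y0 + self.data.shape[0], other.y0 + other.data.shape[0])
        return x0, y0, x1, y1

    def intersection_area(self, other: "PixelMask") -> int:
        x0, y0, x1, y1 = self._window(other)
        if x1 <= x0 or y1 <= y0:
            return 0
        a = self.data[y0 - self.y0 : y1 - self.y0, x0 - self.x0 : x1 - self.x0]
        b = other.data[y0 - other.y0 : y1 - other.y0, x0 - other.x0 : x1 - other.x0]
        return int(np.logical_and(a, b).sum())

    def union(self, other: "PixelMask") -> "PixelMask":
        x0 = min(self.x0, other.x0)
        y0 = min(self.y0, other.y0)
        x1 = max(self.x0 + self.data.shape[1], other.x0 + other.data.shape[1])
        y1 = max(self.y0 + self.data.shape[0], other.y0 + other.data.shape[0])
        out = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        out[self.y0 - y0 : self.y0 - y0 + self.data.shape[0],
            self.x0 - x0 : self.x0 - x0 + self.data.shape[1]] |= self.data
        out[other.y0 - y0 : other.y0 - y0 + other.data.shape[0],
            other.x0 - x0 : other.x0 - x0 + other.data.shape[1]] |= other.data
        return PixelMask(x0, y0, out)

    def clip(self, x0: int, y0: int, x1: int, y1: int) -> "PixelMask":
        """Intersection with the half-open rectangle, in the same frame."""
        cx0, cy0 = max(self.x0, x0), max(self.y0, y0)
        cx1 = min(self.x0 + self.data.shape[1], x1)
        cy1 = min(self.y0 + self.data.shape[0], y1)
        if cx1 <= cx0 or cy1 <= cy0:
            return PixelMask(0, 0, np.zeros((0, 0), dtype=bool))
        patch = self.data[cy0 - self.y0 : cy1 - self.y0, cx0 - self.x0 : cx1 - self.x0]
        return PixelMask(cx0, cy0, patch)

    def rotate90(self, k: int, size: int) -> "PixelMask":
        """Rotate within a ``size x size`` tile frame, matching rotate_box."""
        if k % 4 == 0:
            return self
        h, w = self.data.shape
        bb = rotate_box(
            BoundingBox(self.x0, self.y0, self.x0 + w, self.y0 + h), k % 4, size
        )
        return PixelMask(int(bb.x0), int(bb.y0), np.rot90(self.data, k % 4))

    def paint(self, canvas: np.ndarray, value) -> None:
        """OR/assign the mask into a full-frame canvas (bool or scalar fill)."""
        h, w = self.data.shape
        view = canvas[self.y0 : self.y0 + h, self.x0 : self.x0 + w]
        if canvas.dtype == bool:
            view |= self.data
        else:
            view[self.data] = value

    def __eq__(self, other) -> bool:  # tests and round-trip checks
        if not isinstance(other, PixelMask):
            return NotImplemented
        if self.area != other.area:
            return False
        if self.area == 0:
            return True
        return self.intersection_area(other) == self.area


def mask_iou(a: PixelMask, b: PixelMask) -> float:
    """Jaccard index of two pixel sets."""
    if a.area == 0 or b.area == 0:
        raise GeometryError("mask_iou requires non-empty masks")
    inter = a.intersection_area(b)
    return inter / (a.area + b.area - inter)


def inscribed_ellipse_mask(box: BoundingBox) -> PixelMask:
    """Pixels whose centers lie inside the axis-aligned ellipse inscribed in
    ``box`` (boundary included: the ellipse inequality is tested with <=).

    Used as the cell region for antigen positivity, mirroring oval cell
    boundaries drawn around nuclei.
    """
    x0, y0 = int(np.floor(box.x0)), int(np.floor(box.y0))
    x1, y1 = int(np.ceil(box.x1)), int(np.ceil(box.y1))
    cx, cy = box.center
    a, b = box.width / 2.0, box.height / 2.0
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    u = (xs - cx) / a
    v = (ys - cy) / b
    inside = (u[None, :] ** 2 + v[:, None] ** 2) <= 1.0
    return PixelMask(x0, y0, inside)
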