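"""Core record types flowing through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .classes import CELL_CLASS_INDEX, STAGE_CLASS_INDEX
from .geometry import BoundingBox, PixelMask

CONF_SUM_TOL = 1e-6

#: nominal physical scale of the source scans, microns per pixel
DEFAULT_MICRONS_PER_PX = 0.161


@dataclass(frozen=True)
class SlideImage:
    """Single-channel grayscale slide (whole cross-section or one tile)."""

    pixels: np.ndarray
    microns_per_px: float = DEFAULT_MICRONS_PER_PX

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("SlideImage is single-channel; convert to grayscale first")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _top_two(conf: Mapping[str, float], order: Mapping[str, int]):
    """argmax and positive runner-up of a confidence map; ties break by the
    canonical class order."""
    items = sorted(conf.items(), key=lambda kv: (-kv[1], order.get(kv[0], 99)))
    top_class, top_conf = items[0]
    second = None
    for cls, val in items[1:]:
        if val > 0.0:
            second = cls
            break
    return top_class, top_conf, second


@dataclass(frozen=True)
class CellDetection:
    """One detected nucleus with its per-class confidence vector.

    ``source`` records provenance (tile id and rotation); ``n_merged`` counts
    how many raw detections were fused into this record.
    """

    box: BoundingBox
    conf: Mapping[str, float]
    top_class: str
    top_conf: float
    second_class: Optional[str] = None
    source: str = ""
    n_merged: int = 1

    def __post_init__(self) -> None:
        total = float(sum(self.conf.values()))
        if total > 1.0 + 1e-3:
            raise ValueError(f"confidence mass {total:.4f} exceeds 1")
        if abs(self.top_conf - max(self.conf.values())) > CONF_SUM_TOL:
            raise ValueError("top_conf must equal max of conf")
        if self.second_class is not None and self.second_class == self.top_class:
            raise ValueError("second_class must differ from top_class")

    @classmethod
    def from_conf(
        cls,
        box: BoundingBox,
        conf: Mapping[str, float],
        source: str = "",
        n_merged: int = 1,
        second_from_vector: bool = False,
    ) -> "CellDetection":
        top, top_conf, second = _top_two(conf, CELL_CLASS_INDEX)
        return cls(
            box=box,
            conf=dict(conf),
            top_class=top,
            top_conf=top_conf,
            second_class=second if second_from_vector else None,
            source=source,
            n_merged=n_merged,
        )

    def relabeled(self, new_class: str) -> "CellDetection":
        """Replace the top label (used when a hallmark cell is demoted to its
        second-best prediction); confidence vector is kept as evidence."""
        return replace(
            self,
            top_class=new_class,
            top_conf=max(self.conf.values()),
            second_class=None,
        )


@dataclass(frozen=True)
class TubuleFragment:
    """One predicted tubule mask on one tile, mapped to slide coordinates."""

    mask: PixelMask
    stage_conf: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        if self.mask.area == 0:
            raise ValueError("fragment mask must be non-empty")

    @property
    def area_px(self) -> int:
        return self.mask.area

    @property
    def top_stage(self) -> str:
        top, _, _ = _top_two(self.stage_conf, STAGE_CLASS_INDEX)
        return top


@dataclass
class Tubule:
    """A whole seminiferous tubule assembled from overlapping fragments."""

    id: int
    union_mask: PixelMask
    fragments: list[TubuleFragment]
    stage: Optional[str] = None
    stage_score: dict[str, float] = field(default_factory=dict)
    cells: list[int] = field(default_factory=list)

    @property
    def area_px(self) -> int:
        return self.union_mask.area
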