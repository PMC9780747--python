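"""Ground-truth annotation containers and COCO / VIA JSON dialects.

The canonical on-disk format is a COCO-dialect JSON: cell annotations are
bounding boxes with a cell-class category, tubule annotations carry a
segmentation as uncompressed column-major RLE plus a stage-class category.
Round-tripping write -> read is lossless on this data model. A VIA (VGG
Image Annotator) project importer maps rectangle regions with a ``class``
attribute to cells and polygon regions with a ``stage`` attribute to tubule
masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import polygon as draw_polygon

from .classes import (
    ANNOTATION_CELL_CLASSES,
    STAGE_CLASSES,
    validate_cell_class,
    validate_stage_class,
)
from .geometry import BoundingBox, PixelMask

#: tubule masks smaller than this many pixels (~1% of a 1024x1024 tile) are
#: uninformative slivers and are removed from training-style datasets
MIN_TUBULE_MASK_AREA = 12_000


class AnnotationError(ValueError):
    """Malformed annotation file; the message names the offending record."""


@dataclass(frozen=True)
class CellAnnotation:
    box: BoundingBox
    cls: str
    #: optional render geometry (cx, cy, rx, ry, theta) kept by the synthetic
    #: generator so marker channels can re-rasterize the nucleus; not persisted
    ellipse: Optional[tuple] = None

    def __post_init__(self) -> None:
        validate_cell_class(self.cls, dialect=True)


@dataclass(frozen=True)
class TubuleAnnotation:
    mask: PixelMask
    stage: str

    def __post_init__(self) -> None:
        validate_stage_class(self.stage)


@dataclass
class AnnotationSet:
    cells: list[CellAnnotation] = field(default_factory=list)
    tubules: list[TubuleAnnotation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def cell_stage_for(self, cell: CellAnnotation) -> Optional[str]:
        """Stage of the tubule containing the cell's center, if any."""
        cx, cy = cell.box.center
        for tub in self.tubules:
            if tub.mask.contains_point(cx, cy):
                return tub.stage
        return None


def filter_small_masks(ann: AnnotationSet, min_area: int = MIN_TUBULE_MASK_AREA) -> AnnotationSet:
    """Drop tubule masks strictly smaller than ``min_area`` pixels.

    Cells are untouched; a mask of exactly ``min_area`` pixels is kept.
    """
    kept = [t for t in ann.tubules if t.mask.area >= min_area]
    return AnnotationSet(cells=list(ann.cells), tubules=kept, meta=dict(ann.meta))


# ---------------------------------------------------------------------------
# uncompressed COCO RLE (column-major, starting with the zero run)
# ---------------------------------------------------------------------------

def mask_to_rle(mask: PixelMask, height: int, width: int) -> dict:
    full = np.zeros((height, width), dtype=bool)
    mask.paint(full, True)
    flat = full.flatten(order="F").astype(np.int8)
    # run-length: counts of alternating 0s/1s, starting with zeros
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(height), int(width)], "counts": counts}


def rle_to_mask(rle: dict) -> PixelMask:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise AnnotationError(f"RLE length {pos} does not match size {h}x{w}")
    return PixelMask.from_array(flat.reshape((h, w), order="F"))


# ---------------------------------------------------------------------------
# COCO dialect
# ---------------------------------------------------------------------------

_CELL_CAT_OFFSET = 1
_STAGE_CAT_OFFSET = 100


def _categories() -> list[dict]:
    cats = [
        {"id": _CELL_CAT_OFFSET + i, "name": c, "supercategory": "cell"}
        for i, c in enumerate(ANNOTATION_CELL_CLASSES)
    ]
    cats += [
        {"id": _STAGE_CAT_OFFSET + i, "name": s, "supercategory": "tubule_stage"}
        for i, s in enumerate(STAGE_CLASSES)
    ]
    return cats


def write_coco_annotations(ann: AnnotationSet, path, image_shape: tuple[int, int],
                           file_name: str = "slide.png") -> None:
    """Serialize an AnnotationSet to COCO-dialect JSON for one image."""
    h, w = image_shape
    annotations = []
    aid = 1
    for cell in ann.cells:
        b = cell.box
        annotations.append(
            {
                "id": aid,
                "image_id": 1,
                "category_id": _CELL_CAT_OFFSET + ANNOTATION_CELL_CLASSES.index(cell.cls),
                "bbox": [b.x0, b.y0, b.width, b.height],
                "area": b.area,
                "iscrowd": 0,
            }
        )
        aid += 1
    for tub in ann.tubules:
        bb = tub.mask.bbox
        annotations.append(
            {
                "id": aid,
                "image_id": 1,
                "category_id": _STAGE_CAT_OFFSET + STAGE_CLASSES.index(tub.stage),
                "bbox": [bb.x0, bb.y0, bb.width, bb.height],
                "area": tub.mask.area,
                "segmentation": mask_to_rle(tub.mask, h, w),
                "iscrowd": 0,
            }
        )
        aid += 1
    doc = {
        "images": [{"id": 1, "file_name": file_name, "width": int(w), "height": int(h)}],
        "categories": _categories(),
        "annotations": annotations,
        "info": dict(ann.meta),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_coco_annotations(path) -> AnnotationSet:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        cat_names = {c["id"]: c["name"] for c in doc["categories"]}
        cat_super = {c["id"]: c.get("supercategory", "") for c in doc["categories"]}
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"malformed categories block: {exc}") from exc
    cells, tubules = [], []
    for i, a in enumerate(doc.get("annotations", [])):
        try:
            name = cat_names[a["category_id"]]
            if cat_super[a["category_id"]] == "tubule_stage" or name in STAGE_CLASSES:
                tubules.append(TubuleAnnotation(mask=rle_to_mask(a["segmentation"]), stage=name))
            else:
                x, y, bw, bh = a["bbox"]
                cells.append(CellAnnotation(box=BoundingBox(x, y, x + bw, y + bh), cls=name))
        except (KeyError, ValueError, TypeError) as exc:
            raise AnnotationError(f"annotation record {i}: {exc}") from exc
    return AnnotationSet(cells=cells, tubules=tubules, meta=doc.get("info", {}) or {})


# ---------------------------------------------------------------------------
# VIA dialect (import only)
# ---------------------------------------------------------------------------

def read_via_annotations(path, image_shape: tuple[int, int]) -> AnnotationSet:
    """Import a VIA project/annotation JSON.

    Rectangle regions need a ``class`` attribute naming a cell class; polygon
    regions need a ``stage`` attribute naming a stage class. Anything else is
    rejected with the file key and region index.
    """
    with open(path) as fh:
        doc = json.load(fh)
    metadata = doc.get("_via_img_metadata", doc)
    h, w = image_shape
    cells, tubules = [], []
    for key, entry in metadata.items():
        regions = entry.get("regions", [])
        for i, region in enumerate(regions):
            where = f"{key!r} region {i}"
            shape = region.get("shape_attributes", {})
            attrs = region.get("region_attributes", {})
            name = shape.get("name")
            if name == "rect":
                cls = attrs.get("class")
                if cls not in ANNOTATION_CELL_CLASSES:
                    raise AnnotationError(f"{where}: unknown cell class {cls!r}")
                x, y = shape["x"], shape["y"]
                cells.append(
                    CellAnnotation(
                        box=BoundingBox(x, y, x + shape["width"], y + shape["height"]),
                        cls=cls,
                    )
                )
            elif name == "polygon":
                stage = attrs.get("stage")
                if stage not in STAGE_CLASSES:
                    raise AnnotationError(f"{where}: unknown stage {stage!r}")
                xs = np.asarray(shape["all_points_x"], dtype=float)
                ys = np.asarray(shape["all_points_y"], dtype=float)
                rr, cc = draw_polygon(ys, xs, shape=(h, w))
                full = np.zeros((h, w), dtype=bool)
                full[rr, cc] = True
                if not full.any():
                    raise AnnotationError(f"{where}: polygon rasterizes to empty mask")
                tubules.append(TubuleAnnotation(mask=PixelMask.from_array(full), stage=stage))
            else:
                raise AnnotationError(f"{where}: unsupported shape {name!r}")
    return AnnotationSet(cells=cells, tubules=tubules)
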