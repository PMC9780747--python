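"""Dataset augmentation with consistent label transforms.

Each input (image + annotations) is expanded into ``len(variants)`` outputs,
so image and label counts scale exactly by the number of variants. A variant
is a sequence of atomic transforms; geometric atoms (flips, quarter-turn
rotations) are applied to boxes and masks as well as pixels, photometric
atoms (blur, brightness) touch pixels only.

Two shipped presets reproduce the bookkeeping of the reference datasets:
the 12-variant cell preset (4 rotations x {identity, blur, brightness}) and
the 9-variant tubule preset (3 flips x {identity, blur, brightness}).
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage as ndi

from .annotations import AnnotationSet, CellAnnotation, TubuleAnnotation
from .geometry import BoundingBox, PixelMask, rotate_box

Atom = tuple
Variant = Sequence[Atom]

#: 424 images x 12 variants = 5088 images; 52 807 labels x 12 = 633 684
CELL_AUGMENT_PRESET: list[Variant] = [
    (("rot90", k),) + extra
    for k in range(4)
    for extra in ((), (("blur", 1.2),), (("brightness", 1.25),))
]

#: 3097 images x 9 variants = 27 873 images
TUBULE_AUGMENT_PRESET: list[Variant] = [
    (flip,) + extra
    for flip in (("identity",), ("flip-h",), ("flip-v",))
    for extra in ((), (("blur", 1.2),), (("brightness", 1.25),))
]

_KNOWN = {"identity", "flip-h", "flip-v", "rot90", "blur", "brightness"}


def _flip_box_h(b: BoundingBox, w: int) -> BoundingBox:
    return BoundingBox(w - b.x1, b.y0, w - b.x0, b.y1)


def _flip_box_v(b: BoundingBox, h: int) -> BoundingBox:
    return BoundingBox(b.x0, h - b.y1, b.x1, h - b.y0)


def _apply_atom(atom: Atom, image: np.ndarray, ann: AnnotationSet):
    name = atom[0]
    h, w = image.shape
    if name == "identity":
        return image, ann
    if name == "flip-h":
        img = image[:, ::-1]
        cells = [CellAnnotation(_flip_box_h(c.box, w), c.cls) for c in ann.cells]
        tubs = [
            TubuleAnnotation(
                PixelMask(w - (t.mask.x0 + t.mask.data.shape[1]), t.mask.y0,
                          t.mask.data[:, ::-1]),
                t.stage,
            )
            for t in ann.tubules
        ]
        return img, AnnotationSet(cells, tubs, dict(ann.meta))
    if name == "flip-v":
        img = image[::-1, :]
        cells = [CellAnnotation(_flip_box_v(c.box, h), c.cls) for c in ann.cells]
        tubs = [
            TubuleAnnotation(
                PixelMask(t.mask.x0, h - (t.mask.y0 + t.mask.data.shape[0]),
                          t.mask.data[::-1, :]),
                t.stage,
            )
            for t in ann.tubules
        ]
        return img, AnnotationSet(cells, tubs, dict(ann.meta))
    if name == "rot90":
        k = atom[1] % 4
        if k == 0:
            return image, ann
        if h != w:
            raise ValueError("rot90 augmentation requires square images")
        img = np.rot90(image, k)
        cells = [CellAnnotation(rotate_box(c.box, k, w), c.cls) for c in ann.cells]
        tubs = [TubuleAnnotation(t.mask.rotate90(k, w), t.stage) for t in ann.tubules]
        return img, AnnotationSet(cells, tubs, dict(ann.meta))
    if name == "blur":
        img = ndi.gaussian_filter(image.astype(float), sigma=atom[1])
        return np.clip(img, 0, 255).astype(image.dtype), ann
    if name == "brightness":
        img = image.astype(float) * atom[1]
        return np.clip(img, 0, 255).astype(image.dtype), ann
    raise ValueError(f"unknown transform {name!r}")


def apply_variant(variant: Variant, image: np.ndarray, ann: AnnotationSet):
    for atom in variant:
        if atom[0] not in _KNOWN:
            raise ValueError(f"unknown transform {atom[0]!r}")
        image, ann = _apply_atom(atom, image, ann)
    return image, ann


def augment_dataset(
    items: Iterable[tuple[np.ndarray, AnnotationSet]],
    variants: Sequence[Variant],
) -> Iterator[tuple[np.ndarray, AnnotationSet]]:
    """Lazily yield every variant of every input item, labels transformed
    consistently; output count = n_items * len(variants)."""
    for atom_list in variants:
        for atom in atom_list:
            if atom[0] not in _KNOWN:
                raise ValueError(f"unknown transform {atom[0]!r}")
    for image, ann in items:
        for variant in variants:
            yield apply_variant(variant, image, ann)


def augmented_counts(n_images: int, n_labels: int, variants: Sequence[Variant]) -> tuple[int, int]:
    """Exact dataset bookkeeping: counts scale by the number of variants."""
    return n_images * len(variants), n_labels * len(variants)
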