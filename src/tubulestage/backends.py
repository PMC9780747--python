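"""Pluggable detection backends.

The pipeline talks to any object implementing :class:`DetectorBackend`:
``detect_cells(tile)`` returning cell detections and ``segment_tubules(tile)``
returning tubule mask fragments, both in the tile's (possibly rotated) frame.
Score thresholds live in the *contract*, not in the backends, so every
backend is filtered identically: cell detections below 0.5 and tubule
fragments below 0.3 confidence are suppressed.

Two reference backends ship with the package: a ground-truth oracle with
injectable noise (label flips, box jitter, drops) enabling end-to-end tests
without trained neural weights, and a classical blob detector that finds
nuclei by thresholding + connected components and classifies them by nearest
centroid in (area, mean intensity, axis ratio) feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .annotations import AnnotationSet
from .classes import CELL_CLASSES, STAGE_CLASSES
from .geometry import BoundingBox, PixelMask, rotate_box
from .synth import RenderParams, class_feature_centroids
from .tiling import Tile
from .types import CellDetection, TubuleFragment

CELL_SCORE_MIN = 0.5     # inference threshold of the cell detector contract
TUBULE_SCORE_MIN = 0.3   # inference threshold of the tubule segmenter contract


@runtime_checkable
class DetectorBackend(Protocol):
    def detect_cells(self, tile: Tile) -> list[CellDetection]: ...

    def segment_tubules(self, tile: Tile) -> list[TubuleFragment]: ...


def apply_score_thresholds(
    cells: Iterable[CellDetection],
    fragments: Iterable[TubuleFragment],
    cell_min: float = CELL_SCORE_MIN,
    tubule_min: float = TUBULE_SCORE_MIN,
):
    """Contract-level confidence filtering applied to every backend."""
    kept_cells = [c for c in cells if c.top_conf >= cell_min]
    kept_frags = [f for f in fragments if max(f.stage_conf.values()) >= tubule_min]
    return kept_cells, kept_frags


# ---------------------------------------------------------------------------
# oracle backend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleNoise:
    """Noise model for the ground-truth oracle.

    With every parameter at zero the oracle reproduces ground truth with
    confidence 1. ``conf_true`` / ``conf_flipped`` form the map from emission
    correctness to the confidence placed on the emitted label; the remaining
    mass is spread uniformly over the other classes.
    """

    label_flip_prob: float = 0.0
    box_jitter_px: int = 0
    drop_prob: float = 0.0
    conf_true: float = 1.0
    conf_flipped: float = 0.75
    seed: int = 0


def _conf_vector(labels: tuple[str, ...], emitted: str, mass: float) -> dict[str, float]:
    rest = (1.0 - mass) / (len(labels) - 1) if len(labels) > 1 else 0.0
    return {c: (mass if c == emitted else rest) for c in labels}


class OracleBackend:
    """Emits ground truth restricted to the tile, with optional noise.

    Each cell is emitted exactly once, by the base-lattice tile that owns
    its box center, with the box clipped to that tile (a cell crossing a
    seam of both lattices at once is contained whole by no tile, so
    ownership-with-clipping is the only emission rule that loses nothing
    and duplicates nothing). Tubule masks are clipped to every tile they
    touch, which is precisely what fragments tubules across the mosaic.
    Deterministic given the noise seed and tile offset.
    """

    def __init__(self, truth: AnnotationSet, noise: OracleNoise | None = None):
        self.truth = truth
        self.noise = noise or OracleNoise()

    def _rng(self, tile: Tile, stream: int):
        return np.random.default_rng(
            (self.noise.seed, tile.x, tile.y, tile.rotation, stream)
        )

    def detect_cells(self, tile: Tile) -> list[CellDetection]:
        nz = self.noise
        out: list[CellDetection] = []
        x0t, y0t, s = tile.x, tile.y, tile.size
        for cell in self.truth.cells:
            b = cell.box
            cx, cy = b.center
            owner = (int(cx // s) * s, int(cy // s) * s)
            if (x0t, y0t) != owner:
                continue
            # noise is intrinsic to the cell (keyed on its truth box), so a
            # simulated miss or mislabel is consistent across the rotation
            # ensemble instead of being voted away by it
            rng = np.random.default_rng(
                (nz.seed, int(b.x0), int(b.y0), int(b.x1), int(b.y1), 1)
            )
            if nz.drop_prob > 0 and rng.random() < nz.drop_prob:
                continue
            if b.x0 < x0t or b.y0 < y0t or b.x1 > x0t + s or b.y1 > y0t + s:
                b = BoundingBox(
                    max(b.x0, x0t), max(b.y0, y0t),
                    min(b.x1, x0t + s), min(b.y1, y0t + s),
                )
            label, mass = cell.cls, nz.conf_true
            if nz.label_flip_prob > 0 and rng.random() < nz.label_flip_prob:
                others = [c for c in CELL_CLASSES if c != cell.cls]
                label = others[int(rng.integers(len(others)))]
                mass = nz.conf_flipped
            local = b.translate(-x0t, -y0t)
            if nz.box_jitter_px > 0:
                j = nz.box_jitter_px
                dx0, dy0, dx1, dy1 = rng.integers(-j, j + 1, size=4)
                nx0 = min(max(local.x0 + dx0, 0), s - 1)
                ny0 = min(max(local.y0 + dy0, 0), s - 1)
                nx1 = max(min(local.x1 + dx1, s), nx0 + 1)
                ny1 = max(min(local.y1 + dy1, s), ny0 + 1)
                local = BoundingBox(nx0, ny0, nx1, ny1)
            if tile.rotation:
                local = rotate_box(local, tile.rotation, s)
            out.append(
                CellDetection.from_conf(
                    box=local,
                    conf=_conf_vector(CELL_CLASSES, label, mass),
                    source=f"{tile.id}:r{tile.rotation}",
                )
            )
        return out

    def segment_tubules(self, tile: Tile) -> list[TubuleFragment]:
        nz = self.noise
        rng = self._rng(tile, 2)
        out: list[TubuleFragment] = []
        x0t, y0t, s = tile.x, tile.y, tile.size
        for tub in self.truth.tubules:
            clipped = tub.mask.clip(x0t, y0t, x0t + s, y0t + s)
            if clipped.area == 0:
                continue
            stage, mass = tub.stage, nz.conf_true
            if nz.label_flip_prob > 0 and rng.random() < nz.label_flip_prob:
                others = [c for c in STAGE_CLASSES if c != tub.stage]
                stage = others[int(rng.integers(len(others)))]
                mass = nz.conf_flipped
            local = clipped.translate(-x0t, -y0t)
            if tile.rotation:
                local = local.rotate90(tile.rotation, s)
            out.append(
                TubuleFragment(
                    mask=local,
                    stage_conf=_conf_vector(STAGE_CLASSES, stage, mass),
                    source=f"{tile.id}:r{tile.rotation}",
                )
            )
        return out


# ---------------------------------------------------------------------------
# classical baseline backend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineParams:
    intensity_floor: float = 65.0    # nucleus/background split (8-bit)
    min_area: int = 12               # px; discards noise specks
    max_area: int = 3000             # px; discards fused clumps
    softmax_tau: float = 0.25        # temperature in normalized feature space
    # feature scales: area px, intensity, axis ratio
    feature_scale: tuple[float, float, float] = (100.0, 35.0, 0.6)


class BaselineBackend:
    """Weights-free classical detector for synthetic slides.

    Nuclei: pixels above an intensity floor -> connected components -> size
    filter. Classification: nearest centroid in the (area, mean intensity,
    major/minor axis ratio) space against the documented per-class centroids
    of the synthetic renderer; confidence is a softmax over negative squared
    feature distances. Tubule segmentation is a crude foreground-blob pass
    with an uninformative uniform stage confidence — the baseline
    demonstrates detection plumbing, not staging.
    """

    def __init__(self, params: BaselineParams | None = None,
                 render_params: RenderParams | None = None):
        self.params = params or BaselineParams()
        cents = class_feature_centroids(render_params)
        self._classes = [c for c in CELL_CLASSES if c in cents]
        self._centroids = np.array(
            [self._scale(cents[c]) for c in self._classes], dtype=float
        )

    def _scale(self, feats) -> np.ndarray:
        s = self.params.feature_scale
        return np.array([feats[0] / s[0], feats[1] / s[1], feats[2] / s[2]])

    def detect_cells(self, tile: Tile) -> list[CellDetection]:
        img = np.asarray(tile.image, dtype=float)
        fg = img > self.params.intensity_floor
        if not fg.any():
            return []
        labels, _n = ndi.label(fg)
        out: list[CellDetection] = []
        for region in regionprops(labels, intensity_image=img):
            if not (self.params.min_area <= region.area <= self.params.max_area):
                continue
            minor = max(region.axis_minor_length, 1.0)
            ratio = max(region.axis_major_length / minor, 1.0)
            feats = self._scale((region.area, region.intensity_mean, ratio))
            d2 = ((self._centroids - feats) ** 2).sum(axis=1)
            logits = -d2 / self.params.softmax_tau
            w = np.exp(logits - logits.max())
            conf = w / w.sum()
            y0, x0, y1, x1 = region.bbox
            out.append(
                CellDetection.from_conf(
                    box=BoundingBox(x0, y0, x1, y1),
                    conf=dict(zip(self._classes, conf.tolist())),
                    source=f"{tile.id}:r{tile.rotation}",
                )
            )
        return out

    def segment_tubules(self, tile: Tile) -> list[TubuleFragment]:
        img = np.asarray(tile.image, dtype=float)
        smooth = ndi.gaussian_filter(img, sigma=12.0)
        fg = ndi.binary_fill_holes(smooth > 22.0)
        labels, n = ndi.label(fg)
        out = []
        # near-uniform prior peaked on the modal stage so fragments clear the
        # 0.3 contract threshold; baseline staging is explicitly uninformative
        prior = {s: (0.32 if s == "I-V" else 0.17) for s in STAGE_CLASSES}
        for i in range(1, n + 1):
            mask = PixelMask.from_array(labels == i)
            if mask.area < 500:
                continue
            out.append(TubuleFragment(mask=mask, stage_conf=prior, source=tile.id))
        return out


def fuse_pachytene(cells: list[CellDetection]) -> list[CellDetection]:
    """Fuse annotation-dialect pachytene subclasses into ``Spc-Pach``.

    Early and late pachytene confidence entries are summed into the fused
    class; detections without subclass entries pass through unchanged. The
    output vocabulary has exactly the 9 output classes.
    """
    from .classes import PACHYTENE_FUSED, PACHYTENE_SUBCLASSES

    out = []
    for det in cells:
        if not any(sub in det.conf for sub in PACHYTENE_SUBCLASSES):
            out.append(det)
            continue
        conf = {}
        for cls, val in det.conf.items():
            key = PACHYTENE_FUSED if cls in PACHYTENE_SUBCLASSES else cls
            conf[key] = conf.get(key, 0.0) + val
        out.append(
            CellDetection.from_conf(
                box=det.box,
                conf=conf,
                source=det.source,
                n_merged=det.n_merged,
                second_from_vector=det.second_class is not None,
            )
        )
    return out
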