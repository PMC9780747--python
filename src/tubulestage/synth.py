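"""Synthetic DAPI-like testis cross-section generator with exact ground truth.

The generator emulates the structure a chromatin stain reveals: elliptical
seminiferous tubule cross-sections bounded by a peritubular (myoid) ring,
with germ cells arranged in radial layers whose composition is fixed by the
epithelial stage (spermatogonia and Sertoli nuclei on the basement membrane,
spermatocytes mid-epithelium, spermatids toward the lumen; late elongating
spermatids bundled in early stages). It does not imitate real DAPI texture;
instead each cell class gets a distinctive (size, intensity, elongation)
signature so that a classical detector can separate the classes and every
pipeline step is testable against known truth.

Stage composition rules encode the defining criteria of the five pooled
stage classes: stages I-V and VI-VIII contain round spermatids, stages IX
and X-XI lack them, and stage XII is defined by the presence of meiotic
metaphase plates and/or secondary spermatocytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotations import AnnotationSet, CellAnnotation, TubuleAnnotation
from .classes import CELL_CLASSES, STAGE_CLASSES
from .geometry import BoundingBox, PixelMask
from .types import SlideImage


class PackingError(RuntimeError):
    """Dart-throwing placement exceeded its attempt budget."""


# ---------------------------------------------------------------------------
# stage composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageCompositionRule:
    """Which cell classes a stage must / may / must not contain, their radial
    placement (fraction of tubule radius, basal=0 .. lumen=1 measured from the
    wall inward is encoded directly as a radial fraction band), and per-class
    count ranges for one tubule cross-section."""

    stage: str
    counts: Mapping[str, tuple[int, int]]        # class -> inclusive count range
    forbidden: frozenset[str]
    required_any: frozenset[str] = frozenset()   # at least one cell among these
    bundled: frozenset[str] = frozenset()        # classes placed in angular bundles

    @property
    def required(self) -> frozenset[str]:
        return frozenset(c for c, (lo, _) in self.counts.items() if lo > 0)

    @property
    def allowed(self) -> frozenset[str]:
        return frozenset(self.counts)


# Radial band (fraction of local radius from center) per cell class; somatic
# and mitotic cells sit basally (near the wall), spermatids luminally.
RADIAL_BANDS: dict[str, tuple[float, float]] = {
    "Sert": (0.80, 0.92),
    "Spg": (0.80, 0.92),
    "Spc-prePach": (0.62, 0.74),
    "Spc-Pach": (0.44, 0.58),
    "Spc-sec": (0.40, 0.55),
    "m2m": (0.40, 0.55),
    "RS": (0.24, 0.38),
    "elSpt-early": (0.16, 0.30),
    "elSpt-late": (0.12, 0.26),
}

STAGE_RULES: dict[str, StageCompositionRule] = {
    "I-V": StageCompositionRule(
        stage="I-V",
        counts={
            "Sert": (2, 4), "Spg": (2, 4), "Spc-Pach": (4, 7),
            "RS": (7, 12), "elSpt-late": (5, 9),
        },
        forbidden=frozenset({"Spc-prePach", "Spc-sec", "m2m", "elSpt-early"}),
        bundled=frozenset({"elSpt-late"}),
    ),
    "VI-VIII": StageCompositionRule(
        stage="VI-VIII",
        counts={
            "Sert": (2, 4), "Spg": (1, 3), "Spc-prePach": (2, 4),
            "Spc-Pach": (4, 7), "RS": (7, 12), "elSpt-late": (5, 9),
        },
        forbidden=frozenset({"Spc-sec", "m2m", "elSpt-early"}),
    ),
    "IX": StageCompositionRule(
        stage="IX",
        counts={
            "Sert": (2, 4), "Spg": (1, 3), "Spc-prePach": (3, 5),
            "Spc-Pach": (4, 7), "elSpt-early": (6, 10),
        },
        forbidden=frozenset({"RS", "elSpt-late", "Spc-sec", "m2m"}),
    ),
    "X-XI": StageCompositionRule(
        stage="X-XI",
        counts={
            "Sert": (2, 4), "Spc-prePach": (3, 5), "Spc-Pach": (4, 7),
            "elSpt-early": (6, 10),
        },
        forbidden=frozenset({"RS", "elSpt-late", "Spg", "Spc-sec", "m2m"}),
    ),
    "XII": StageCompositionRule(
        stage="XII",
        counts={
            "Sert": (2, 4), "Spc-prePach": (2, 4), "Spc-Pach": (3, 6),
            "m2m": (1, 3), "Spc-sec": (1, 3), "elSpt-late": (4, 7),
        },
        forbidden=frozenset({"RS", "elSpt-early", "Spg"}),
        required_any=frozenset({"m2m", "Spc-sec"}),
    ),
}

#: default stage mix: early stages occupy most of the cycle, stage XII is rare
DEFAULT_STAGE_MIX: dict[str, float] = {
    "I-V": 0.40, "VI-VIII": 0.25, "IX": 0.10, "X-XI": 0.15, "XII": 0.10,
}


# ---------------------------------------------------------------------------
# rendering parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRender:
    """Nuclear appearance of one cell class: equivalent radius (px), mean
     8-bit intensity, major/minor axis ratio, and texture amplitude."""

    radius: float
    intensity: float
    axis_ratio: float = 1.0
    texture: float = 6.0


# Class signatures are pairwise separated in (area, intensity, axis ratio)
# so a nearest-centroid classifier over those features is learnable.
CELL_RENDER_DEFAULTS: dict[str, CellRender] = {
    "Sert":        CellRender(radius=10.0, intensity=80.0),
    "Spg":         CellRender(radius=8.0, intensity=150.0),
    "Spc-prePach": CellRender(radius=6.0, intensity=110.0),
    "Spc-Pach":    CellRender(radius=12.0, intensity=185.0),
    "Spc-sec":     CellRender(radius=9.0, intensity=230.0),
    "m2m":         CellRender(radius=7.0, intensity=250.0, axis_ratio=3.0),
    "RS":          CellRender(radius=5.0, intensity=165.0),
    "elSpt-early": CellRender(radius=4.5, intensity=215.0, axis_ratio=2.0),
    "elSpt-late":  CellRender(radius=3.5, intensity=245.0, axis_ratio=2.8),
}


@dataclass(frozen=True)
class MarkerRule:
    """A fluorescent marker's known truth: which cell classes are positive,
    at which stages (None = all), and at what rendered intensity."""

    positive_classes: frozenset[str]
    positive_stages: Optional[frozenset[str]] = None
    contrast: float = 180.0
    background: float = 6.0

    def is_positive(self, cls: str, stage: Optional[str]) -> bool:
        if cls not in self.positive_classes:
            return False
        if self.positive_stages is None:
            return True
        return stage is not None and stage in self.positive_stages


@dataclass(frozen=True)
class RenderParams:
    cells: Mapping[str, CellRender] = field(default_factory=lambda: dict(CELL_RENDER_DEFAULTS))
    tubule_radius: tuple[float, float] = (90.0, 140.0)
    tubule_axis_ratio: tuple[float, float] = (0.75, 1.0)
    wall_intensity: float = 55.0
    wall_thickness: float = 5.0
    epithelium_intensity: float = 28.0
    lumen_intensity: float = 14.0
    background: float = 10.0
    noise_sigma: float = 3.0
    radius_jitter: float = 0.08
    intensity_jitter: float = 8.0
    #: tissue keeps this distance from the scan border (real cross-sections
    #: sit interior to the scanned frame); equal to the tiling shift so every
    #: object enjoys the two-lattice double coverage
    border_margin: float = 512.0
    markers: Mapping[str, MarkerRule] = field(default_factory=dict)


def class_feature_centroids(params: RenderParams | None = None) -> dict[str, tuple[float, float, float]]:
    """(area, intensity, axis ratio) centroid per class, as rendered; the
    classical baseline detector classifies against these."""
    cells = (params or RenderParams()).cells
    return {
        c: (math.pi * r.radius ** 2, r.intensity, r.axis_ratio)
        for c, r in cells.items()
    }


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(cx: float, cy: float, rx: float, ry: float, theta: float,
                  shape: tuple[int, int]) -> PixelMask:
    """Rotated-ellipse pixel set (centers tested), clipped to the frame."""
    rmax = max(rx, ry)
    x0 = max(int(math.floor(cx - rmax)) - 1, 0)
    x1 = min(int(math.ceil(cx + rmax)) + 1, shape[1])
    y0 = max(int(math.floor(cy - rmax)) - 1, 0)
    y1 = min(int(math.ceil(cy + rmax)) + 1, shape[0])
    if x1 <= x0 or y1 <= y0:
        return PixelMask(0, 0, np.zeros((0, 0), dtype=bool))
    xs = np.arange(x0, x1) + 0.5 - cx
    ys = np.arange(y0, y1) + 0.5 - cy
    X, Y = np.meshgrid(xs, ys)
    ct, st = math.cos(theta), math.sin(theta)
    u = (X * ct + Y * st) / rx
    v = (-X * st + Y * ct) / ry
    return PixelMask(x0, y0, (u * u + v * v) <= 1.0)


@dataclass(frozen=True)
class _TubuleGeom:
    cx: float
    cy: float
    rx: float
    ry: float
    theta: float
    stage: str


def _point_on_band(rng, geom: _TubuleGeom, band: tuple[float, float]):
    f = rng.uniform(*band)
    phi = rng.uniform(0.0, 2 * math.pi)
    return _band_point(geom, f, phi)


def _band_point(geom: _TubuleGeom, f: float, phi: float):
    ct, st = math.cos(geom.theta), math.sin(geom.theta)
    ex, ey = f * geom.rx * math.cos(phi), f * geom.ry * math.sin(phi)
    return geom.cx + ex * ct - ey * st, geom.cy + ex * st + ey * ct


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_tubules(rng, n: int, shape: tuple[int, int], params: RenderParams,
                   attempt_budget: int) -> list[tuple[float, float, float, float, float]]:
    placed: list[tuple[float, float, float, float, float]] = []
    gap = 14.0
    attempts = 0
    while len(placed) < n:
        if attempts >= attempt_budget:
            raise PackingError(
                f"placed {len(placed)}/{n} tubules in {attempt_budget} attempts; "
                "enlarge the slide or shrink tubule radii"
            )
        attempts += 1
        rx = rng.uniform(*params.tubule_radius)
        ry = rx * rng.uniform(*params.tubule_axis_ratio)
        theta = rng.uniform(0.0, math.pi)
        rmax = max(rx, ry)
        margin = max(rmax + params.wall_thickness + 4, params.border_margin)
        if shape[1] - margin <= margin or shape[0] - margin <= margin:
            raise PackingError("slide too small for the configured tubule radii")
        cx = rng.uniform(margin, shape[1] - margin)
        cy = rng.uniform(margin, shape[0] - margin)
        ok = True
        for (pcx, pcy, prx, pry, _pt) in placed:
            if math.hypot(cx - pcx, cy - pcy) < rmax + max(prx, pry) + gap:
                ok = False
                break
        if ok:
            placed.append((cx, cy, rx, ry, theta))
    return placed


def _auto_slide_side(n_tubules: int, params: RenderParams) -> int:
    rmax = params.tubule_radius[1] + params.wall_thickness + 20
    area = n_tubules * math.pi * rmax ** 2 / 0.32
    side = int(math.ceil(math.sqrt(area))) + 2 * int(params.border_margin)
    side = max(side, 1024)
    # full multiples of the tile size so the base lattice covers the slide
    return ((side + 1023) // 1024) * 1024


def _draw_counts(rng, rule: StageCompositionRule) -> dict[str, int]:
    counts = {c: int(rng.integers(lo, hi + 1)) for c, (lo, hi) in rule.counts.items()}
    if rule.required_any and not any(counts.get(c, 0) for c in rule.required_any):
        counts[sorted(rule.required_any)[0]] = 1
    return counts


def _place_cells_in_tubule(rng, geom: _TubuleGeom, rule: StageCompositionRule,
                           params: RenderParams, shape: tuple[int, int]):
    """Dart-throw cell nuclei into radial bands; returns per-cell geometry."""
    cells: list[tuple[str, float, float, float, float, float]] = []
    counts = _draw_counts(rng, rule)
    # place hallmark classes first so required_any survives crowding
    order = sorted(counts, key=lambda c: (c not in rule.required_any, CELL_CLASSES.index(c)))
    bundle_phis = [rng.uniform(0, 2 * math.pi) for _ in range(int(rng.integers(2, 4)))]
    for cls in order:
        render = params.cells[cls]
        band = RADIAL_BANDS[cls]
        for _ in range(counts[cls]):
            r_eq = render.radius * (1.0 + rng.uniform(-params.radius_jitter, params.radius_jitter))
            ratio = render.axis_ratio
            rx, ry = r_eq * math.sqrt(ratio), r_eq / math.sqrt(ratio)
            placed = False
            for _attempt in range(60):
                if cls in rule.bundled:
                    phi = rng.choice(bundle_phis) + rng.normal(0.0, 0.25)
                    f = rng.uniform(*band)
                    x, y = _band_point(geom, f, phi)
                else:
                    x, y = _point_on_band(rng, geom, band)
                # elongated nuclei point toward the tubule center
                theta = math.atan2(geom.cy - y, geom.cx - x) if ratio > 1.01 else rng.uniform(0, math.pi)
                rmax = max(rx, ry)
                if not (rmax < x < shape[1] - rmax and rmax < y < shape[0] - rmax):
                    continue
                clear = True
                for (_c, px, py, prx, pry, _th) in cells:
                    if math.hypot(x - px, y - py) < rmax + max(prx, pry) + 2.0:
                        clear = False
                        break
                if clear:
                    cells.append((cls, x, y, rx, ry, theta))
                    placed = True
                    break
            if not placed and cls in rule.required_any and not any(
                c[0] in rule.required_any for c in cells
            ):
                # hallmark cell must exist: drop the spacing constraint
                x, y = _point_on_band(rng, geom, band)
                cells.append((cls, x, y, rx, ry, rng.uniform(0, math.pi)))
    return cells


def generate_slide(
    n_tubules: int,
    stage_mix: Mapping[str, float] | None = None,
    params: RenderParams | None = None,
    seed: int = 0,
    slide_shape: Optional[tuple[int, int]] = None,
    attempt_budget_per_tubule: int = 400,
    rules: Mapping[str, StageCompositionRule] | None = None,
) -> tuple[SlideImage, AnnotationSet, dict[str, np.ndarray]]:
    """Render a synthetic slide; returns (image, ground truth, marker channels).

    Fully deterministic given ``seed``. ``stage_mix`` must sum to 1; stages
    are drawn per tubule from it. Marker channels (one per entry in
    ``params.markers``) are co-registered grayscale images in which exactly
    the rule-positive nuclei are bright.
    """
    params = params or RenderParams()
    rules = dict(rules) if rules is not None else STAGE_RULES
    mix = dict(stage_mix or DEFAULT_STAGE_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"stage_mix sums to {total}, expected 1")
    for s in mix:
        if s not in STAGE_CLASSES:
            raise ValueError(f"unknown stage {s!r} in stage_mix")
    rng = np.random.default_rng(seed)
    if slide_shape is None:
        side = _auto_slide_side(n_tubules, params)
        slide_shape = (side, side)
    shape = (int(slide_shape[0]), int(slide_shape[1]))

    canvas = np.full(shape, params.background, dtype=np.float64)
    stages = list(mix)
    probs = np.array([mix[s] for s in stages])
    placed = _place_tubules(rng, n_tubules, shape, params,
                            attempt_budget=attempt_budget_per_tubule * n_tubules)

    tubule_anns: list[TubuleAnnotation] = []
    cell_anns: list[CellAnnotation] = []
    cell_stage: list[str] = []
    for (cx, cy, rx, ry, theta) in placed:
        stage = str(rng.choice(stages, p=probs))
        geom = _TubuleGeom(cx, cy, rx, ry, theta, stage)
        wt = params.wall_thickness
        outer = _ellipse_mask(cx, cy, rx + wt, ry + wt, theta, shape)
        inner = _ellipse_mask(cx, cy, rx, ry, theta, shape)
        lumen = _ellipse_mask(cx, cy, 0.30 * rx, 0.30 * ry, theta, shape)
        outer.paint(canvas, params.wall_intensity)
        inner.paint(canvas, params.epithelium_intensity)
        lumen.paint(canvas, params.lumen_intensity)
        tubule_anns.append(TubuleAnnotation(mask=inner, stage=stage))

        for (cls, x, y, crx, cry, cth) in _place_cells_in_tubule(
            rng, geom, rules[stage], params, shape
        ):
            nucleus = _ellipse_mask(x, y, crx, cry, cth, shape)
            if nucleus.area == 0:
                continue
            render = params.cells[cls]
            level = render.intensity + rng.uniform(-params.intensity_jitter,
                                                   params.intensity_jitter)
            h, w = nucleus.data.shape
            patch = canvas[nucleus.y0 : nucleus.y0 + h, nucleus.x0 : nucleus.x0 + w]
            texture = rng.normal(0.0, render.texture, size=(h, w))
            patch[nucleus.data] = np.clip(level + texture, 0, 255)[nucleus.data]
            cell_anns.append(
                CellAnnotation(box=nucleus.bbox, cls=cls, ellipse=(x, y, crx, cry, cth))
            )
            cell_stage.append(stage)

    if params.noise_sigma > 0:
        canvas += rng.normal(0.0, params.noise_sigma, size=shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)

    markers: dict[str, np.ndarray] = {}
    for name, rule in params.markers.items():
        ch = np.full(shape, rule.background, dtype=np.float64)
        for cell, stage in zip(cell_anns, cell_stage):
            if rule.is_positive(cell.cls, stage):
                x, y, crx, cry, cth = cell.ellipse
                _ellipse_mask(x, y, crx, cry, cth, shape).paint(ch, rule.contrast)
        ch += rng.normal(0.0, 1.5, size=shape)
        markers[name] = np.clip(ch, 0, 255).astype(np.uint8)

    ann = AnnotationSet(
        cells=cell_anns,
        tubules=tubule_anns,
        meta={"seed": int(seed), "n_tubules": n_tubules, "stage_mix": mix},
    )
    return SlideImage(pixels=image), ann, markers


def generate_ko_slide(mode: str, n_tubules: int, stage_mix=None, params=None,
                      seed: int = 0, **kwargs):
    """Synthetic knockout phenotypes.

    ``miwi``: spermatogenic arrest at the round-spermatid step — no
    elongating spermatids are generated at any stage (composition change).
    ``spef2``: elongating spermatids render with distorted, more elongated
    shapes but carry wild-type labels (appearance change only).
    """
    params = params or RenderParams()
    if mode == "miwi":
        arrested = {
            s: replace(
                r,
                counts={c: rng_ for c, rng_ in r.counts.items()
                        if c not in ("elSpt-early", "elSpt-late")},
                forbidden=r.forbidden | frozenset({"elSpt-early", "elSpt-late"}),
                bundled=frozenset(),
            )
            for s, r in STAGE_RULES.items()
        }
        return generate_slide(n_tubules, stage_mix, params, seed,
                              rules=arrested, **kwargs)
    if mode == "spef2":
        cells = dict(params.cells)
        for cls in ("elSpt-early", "elSpt-late"):
            r = cells[cls]
            cells[cls] = replace(r, axis_ratio=r.axis_ratio + 1.5, texture=r.texture + 6.0)
        return generate_slide(n_tubules, stage_mix, replace(params, cells=cells),
                              seed, **kwargs)
    raise ValueError(f"unknown KO mode {mode!r}")


def truth_crosstab(ann: AnnotationSet):
    """Ground-truth cell class x stage count table (pandas DataFrame)."""
    import pandas as pd

    table = pd.DataFrame(0, index=list(CELL_CLASSES), columns=list(STAGE_CLASSES))
    for cell in ann.cells:
        stage = ann.cell_stage_for(cell)
        if stage is not None:
            table.loc[cell.cls, stage] += 1
    return table
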