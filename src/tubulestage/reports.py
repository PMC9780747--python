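"""Report generation: crosstab tables, overlays, JSON/CSV output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classes import CELL_CLASSES, STAGE_CLASSES
from .types import CellDetection, SlideImage, Tubule

# deterministic palettes (RGB)
STAGE_PALETTE = {
    "I-V": (66, 135, 245),
    "VI-VIII": (52, 168, 83),
    "IX": (251, 188, 5),
    "X-XI": (234, 67, 53),
    "XII": (171, 71, 188),
}
CELL_PALETTE = {
    "Sert": (158, 158, 158),
    "Spg": (0, 188, 212),
    "Spc-prePach": (63, 81, 181),
    "Spc-Pach": (33, 150, 243),
    "Spc-sec": (255, 112, 67),
    "m2m": (244, 67, 54),
    "RS": (76, 175, 80),
    "elSpt-early": (255, 235, 59),
    "elSpt-late": (255, 152, 0),
}


def crosstab_report(
    cells: Sequence[CellDetection],
    tubules: Sequence[Tubule],
    assignment: Sequence[Optional[int]],
) -> pd.DataFrame:
    """Cell class x epithelial stage count table over assigned cells.

    Rows are the 9 cell classes in canonical order, columns the 5 stage
    classes; a Total row and column are appended. Interstitial cells are not
    counted (the matrix total equals the number of assigned cells).
    """
    stage_by_id = {t.id: t.stage for t in tubules}
    table = pd.DataFrame(0, index=list(CELL_CLASSES), columns=list(STAGE_CLASSES))
    for cell, tub_id in zip(cells, assignment):
        if tub_id is None:
            continue
        stage = stage_by_id.get(tub_id)
        if stage is None:
            continue
        table.loc[cell.top_class, stage] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def _draw_mask_contour(canvas: np.ndarray, tubule: Tubule, color) -> None:
    from scipy import ndimage as ndi

    m = tubule.union_mask
    edge = m.data & ~ndi.binary_erosion(m.data, iterations=2)
    ys, xs = np.nonzero(edge)
    canvas[ys + m.y0, xs + m.x0] = color


def render_overlay(
    slide: SlideImage,
    cells: Sequence[CellDetection],
    tubules: Sequence[Tubule],
    out_path,
) -> None:
    """Write a PNG of the slide with stage-colored tubule contours and
    class-colored cell boxes; a legend strip lists only the classes present."""
    import imageio.v3 as iio

    rgb = np.stack([slide.pixels] * 3, axis=-1).astype(np.uint8)
    for tub in tubules:
        color = STAGE_PALETTE.get(tub.stage, (255, 255, 255))
        _draw_mask_contour(rgb, tub, color)
    h, w = slide.pixels.shape
    for cell in cells:
        color = CELL_PALETTE.get(cell.top_class, (255, 255, 255))
        x0, y0 = max(int(cell.box.x0), 0), max(int(cell.box.y0), 0)
        x1, y1 = min(int(cell.box.x1), w - 1), min(int(cell.box.y1), h - 1)
        rgb[y0, x0:x1] = color
        rgb[y1, x0:x1] = color
        rgb[y0:y1, x0] = color
        rgb[y0:y1, x1] = color

    present_stages = sorted({t.stage for t in tubules if t.stage},
                            key=STAGE_CLASSES.index)
    present_cells = sorted({c.top_class for c in cells}, key=CELL_CLASSES.index)
    legend_entries = [(s, STAGE_PALETTE[s]) for s in present_stages] + [
        (c, CELL_PALETTE[c]) for c in present_cells
    ]
    if legend_entries:
        strip = np.zeros((14, rgb.shape[1], 3), dtype=np.uint8)
        swatch = max(rgb.shape[1] // max(len(legend_entries), 1), 1)
        for i, (_name, color) in enumerate(legend_entries):
            strip[:, i * swatch : (i + 1) * swatch] = color
        rgb = np.concatenate([rgb, strip], axis=0)
    iio.imwrite(out_path, rgb)


def write_reports(result, out_dir) -> None:
    """Per-tubule JSON, per-cell CSV, and the crosstab CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tubule_records = [
        {
            "id": t.id,
            "stage": t.stage,
            "stage_score": t.stage_score,
            "n_fragments": len(t.fragments),
            "area_px": t.area_px,
            "n_cells": len(t.cells),
        }
        for t in result.tubules
    ]
    with open(out / "tubules.json", "w") as fh:
        json.dump(tubule_records, fh, indent=1)
    rows = []
    for i, (cell, tub_id) in enumerate(zip(result.cells, result.assignment)):
        rows.append(
            {
                "id": i,
                "class": cell.top_class,
                "second_class": cell.second_class or "",
                "tubule_id": tub_id if tub_id is not None else "",
                "x0": cell.box.x0,
                "y0": cell.box.y0,
                "x1": cell.box.x1,
                "y1": cell.box.y1,
                "confidence": cell.top_conf,
                "n_merged": cell.n_merged,
            }
        )
    pd.DataFrame(rows).to_csv(out / "cells.csv", index=False)
    result.crosstab().to_csv(out / "crosstab.csv")
    with open(out / "pipeline_log.json", "w") as fh:
        json.dump(result.log, fh, indent=1)
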