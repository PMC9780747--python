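"""Antigen expression profiling over staged cell predictions.

A fluorescent marker channel co-registered with the DAPI analysis image is
overlaid on the predicted cells. Each cell's region is the axis-aligned
ellipse inscribed in its bounding box (an oval cell boundary around the
nucleus). A cell is positive when its region's mean luminosity is strictly
above the marker threshold T AND at least 65% of region pixels exceed T/2 —
the two-clause rule guards against a few saturated pixels dragging a mostly
dark region over the line. T is set per marker by the user (empirically, as
with any immunofluorescence quantification); luminosity is measured on raw
channel intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classes import CELL_CLASSES, STAGE_CLASSES
from .geometry import GeometryError, inscribed_ellipse_mask
from .types import CellDetection, Tubule


@dataclass(frozen=True)
class PositivityRule:
    """Per-marker positivity criterion.

    ``threshold``: luminosity threshold T in raw intensity units (> 0).
    ``half_fraction_min``: minimum fraction of region pixels above T/2.
    """

    threshold: float
    half_fraction_min: float = 0.65

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not (0.0 < self.half_fraction_min <= 1.0):
            raise ValueError("half_fraction_min must be in (0, 1]")


def antigen_positive(cell: CellDetection, channel: np.ndarray, rule: PositivityRule) -> bool:
    """Apply the two-clause positivity rule to one cell."""
    region = inscribed_ellipse_mask(cell.box)
    h, w = channel.shape
    if region.x0 < 0 or region.y0 < 0 or region.x0 + region.data.shape[1] > w \
            or region.y0 + region.data.shape[0] > h:
        raise GeometryError("cell region extends outside the marker channel")
    patch = channel[
        region.y0 : region.y0 + region.data.shape[0],
        region.x0 : region.x0 + region.data.shape[1],
    ].astype(float)[region.data]
    if patch.size == 0:
        return False
    mean_ok = patch.mean() > rule.threshold
    frac_ok = np.mean(patch > rule.threshold / 2.0) >= rule.half_fraction_min
    return bool(mean_ok and frac_ok)


@dataclass
class ExpressionProfile:
    """(cell class, stage) resolved positivity fractions and counts.

    ``fraction`` is NaN where no cells of that class were seen at that stage
    (undefined, never silently zero).
    """

    counts: pd.DataFrame        # positives
    totals: pd.DataFrame

    @property
    def fraction(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.totals.replace(0, np.nan)

    def to_csv(self, path) -> None:
        out = pd.concat(
            {"positive": self.counts, "total": self.totals, "fraction": self.fraction},
            axis=1,
        )
        out.to_csv(path)


def expression_profile(
    cells: Sequence[CellDetection],
    tubules: Sequence[Tubule],
    assignment: Sequence[Optional[int]],
    channel: np.ndarray,
    rule: PositivityRule,
) -> ExpressionProfile:
    """Positivity counts per (cell class, tubule stage) over assigned cells.

    Interstitial cells have no stage and are excluded, so the totals table
    matches the staged crosstab exactly.
    """
    stage_by_id = {t.id: t.stage for t in tubules}
    pos = pd.DataFrame(0, index=list(CELL_CLASSES), columns=list(STAGE_CLASSES))
    tot = pd.DataFrame(0, index=list(CELL_CLASSES), columns=list(STAGE_CLASSES))
    for cell, tub_id in zip(cells, assignment):
        if tub_id is None:
            continue
        stage = stage_by_id[tub_id]
        if stage is None:
            continue
        tot.loc[cell.top_class, stage] += 1
        if antigen_positive(cell, channel, rule):
            pos.loc[cell.top_class, stage] += 1
    return ExpressionProfile(counts=pos, totals=tot)


def plot_expression_profile(profile: ExpressionProfile, out_path, title: str = "") -> None:
    """Bar chart of positivity fractions: one bar group per cell class, one
    colored bar per stage; stages with no cells of a class are omitted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = profile.fraction
    fig, ax = plt.subplots(figsize=(10, 3.2))
    width = 0.16
    x = np.arange(len(CELL_CLASSES))
    for k, stage in enumerate(STAGE_CLASSES):
        vals = frac[stage].to_numpy(dtype=float)
        ax.bar(x + (k - 2) * width, np.nan_to_num(vals), width, label=stage)
    ax.set_xticks(x, CELL_CLASSES, rotation=45, ha="right")
    ax.set_ylabel("fraction positive")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7, ncols=5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def class_intensity_histograms(
    cells: Sequence[CellDetection], channel: np.ndarray, bins: int = 32
) -> dict[str, np.ndarray]:
    """Per-class histogram of mean region luminosity; an aid for choosing T
    (no automatic threshold is claimed)."""
    means: dict[str, list[float]] = {}
    for cell in cells:
        region = inscribed_ellipse_mask(cell.box)
        patch = channel[
            region.y0 : region.y0 + region.data.shape[0],
            region.x0 : region.x0 + region.data.shape[1],
        ].astype(float)[region.data]
        if patch.size:
            means.setdefault(cell.top_class, []).append(float(patch.mean()))
    return {
        cls: np.histogram(vals, bins=bins, range=(0, 255))[0]
        for cls, vals in means.items()
    }
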