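"""Controlled vocabularies for seminiferous epithelial cell types and stages.

The mouse seminiferous epithelial cycle has 12 stages; cross-sections are
pooled here into 5 stage classes (I-V, VI-VIII, IX, X-XI, XII), each with a
characteristic germ-cell association. Cells are classified into 9 output
types: the somatic Sertoli cell plus 8 spermatogenic categories spanning
mitotic spermatogonia through condensing elongating spermatids.

Annotation sources may distinguish early and late pachytene spermatocytes;
those two subclasses carry no extra information downstream and must be fused
into the single ``Spc-Pach`` class before any pipeline output.
"""

from __future__ import annotations

# Output cell classes, in canonical (basal -> luminal developmental) order.
CELL_CLASSES: tuple[str, ...] = (
    "Sert",
    "Spg",
    "Spc-prePach",
    "Spc-Pach",
    "Spc-sec",
    "m2m",
    "RS",
    "elSpt-early",
    "elSpt-late",
)

# Extra subclasses admitted by the annotation dialect only; fused before output.
PACHYTENE_SUBCLASSES: tuple[str, ...] = ("Spc-Pach-early", "Spc-Pach-late")
PACHYTENE_FUSED = "Spc-Pach"

#: All labels an annotation file may legally carry.
ANNOTATION_CELL_CLASSES: tuple[str, ...] = CELL_CLASSES + PACHYTENE_SUBCLASSES

# Stage classes in cycle order.
STAGE_CLASSES: tuple[str, ...] = ("I-V", "VI-VIII", "IX", "X-XI", "XII")

# Cell classes that are hallmarks of stage XII (meiotic metaphase plates and
# secondary spermatocytes); the stage-XII consistency rules key on these.
STAGE_XII_MARKER_CLASSES: frozenset[str] = frozenset({"m2m", "Spc-sec"})

CELL_CLASS_INDEX = {c: i for i, c in enumerate(CELL_CLASSES)}
STAGE_CLASS_INDEX = {s: i for i, s in enumerate(STAGE_CLASSES)}


def fuse_class_label(label: str) -> str:
    """Map an annotation-dialect cell label to the 9-class output vocabulary."""
    if label in PACHYTENE_SUBCLASSES:
        return PACHYTENE_FUSED
    return label


def validate_cell_class(label: str, *, dialect: bool = False) -> str:
    allowed = ANNOTATION_CELL_CLASSES if dialect else CELL_CLASSES
    if label not in allowed:
        raise ValueError(f"unknown cell class {label!r}")
    return label


def validate_stage_class(label: str) -> str:
    if label not in STAGE_CLASSES:
        raise ValueError(f"unknown stage class {label!r}")
    return label
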