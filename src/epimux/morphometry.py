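"""Aggregate labelling, shape descriptors and morphology classification.

Connected components (8-connected) of the union mask are measured and
classified as Lewy-body-like (compact, near-circular), Lewy-neurite-like
(elongated by axis ratio or by skeleton elongation), punctate (below a
diameter cut-off), or left unclassified.  Numeric rule thresholds are
configurable substitutes for expert visual calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

__all__ = [
    "AggregateObject",
    "MorphologyRules",
    "MorphologyDistribution",
    "label_aggregates",
    "classify_morphology",
    "morphology_distribution",
    "diameter_um",
]

CIRCULARITY_CAP = 1.1  # digitisation can push 4*pi*A/P^2 slightly above 1

MORPH_CLASSES = ("lewy_body", "lewy_neurite", "punctate", "unclassified")


@dataclass(frozen=True)
class MorphologyRules:
    lb_min_circularity: float = 0.6
    lb_max_aspect: float = 2.0
    ln_min_aspect: float = 3.0
    ln_min_skeleton_elongation: float = 3.0
    punctate_max_diameter_um: float = 2.0

    @classmethod
    def from_config(cls, config) -> "MorphologyRules":
        return cls(
            lb_min_circularity=config.lb_min_circularity,
            lb_max_aspect=config.lb_max_aspect,
            ln_min_aspect=config.ln_min_aspect,
            ln_min_skeleton_elongation=config.ln_min_skeleton_elongation,
            punctate_max_diameter_um=config.punctate_max_diameter_um,
        )


@dataclass
class AggregateObject:
    """One connected component with shape descriptors."""

    id: int
    footprint: np.ndarray  # full-frame boolean mask
    area_px: int
    pixel_size_um: float
    perimeter_px: float
    circularity: float
    aspect_ratio: float
    feret_diameter_px: float
    centroid: tuple[float, float]
    skeleton_elongation: float = math.nan
    morph_class: str = "unclassified"

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def equivalent_diameter_um(self) -> float:
        return 2.0 * math.sqrt(self.area_um2 / math.pi)

    @property
    def feret_diameter_um(self) -> float:
        return self.feret_diameter_px * self.pixel_size_um


@dataclass
class MorphologyDistribution:
    """Per-class share of total aggregate area and object counts."""

    area_share_pct: dict[str, float]
    counts: dict[str, int]
    total_area_px: int
    defined: bool = True


def _skeleton_elongation(footprint_patch: np.ndarray) -> float:
    """Skeleton length over mean width: L / (A / L) = L^2 / A."""
    skel = skeletonize(footprint_patch)
    length = int(skel.sum())
    if length == 0:
        return 0.0
    return length**2 / float(footprint_patch.sum())


def label_aggregates(
    union_mask: np.ndarray,
    pixel_size_um: float,
    min_object_px: int = 5,
    rules: MorphologyRules | None = None,
) -> list[AggregateObject]:
    """8-connected components of the union mask, measured and classified.

    The perimeter uses the Crofton approximation, which stabilises
    circularity on small digitised objects.
    """
    union_mask = np.asarray(union_mask, dtype=bool)
    rules = rules or MorphologyRules()
    labels = cc_label(union_mask, connectivity=2)
    objects: list[AggregateObject] = []
    for prop in regionprops(labels):
        if prop.area < min_object_px:
            continue
        footprint = labels == prop.label
        perimeter = float(prop.perimeter_crofton)
        circularity = (
            min(CIRCULARITY_CAP, 4.0 * math.pi * prop.area / perimeter**2)
            if perimeter > 0
            else CIRCULARITY_CAP
        )
        minor = prop.axis_minor_length
        aspect = prop.axis_major_length / minor if minor > 1e-9 else math.inf
        aspect = max(1.0, aspect)
        obj = AggregateObject(
            id=len(objects),
            footprint=footprint,
            area_px=int(prop.area),
            pixel_size_um=pixel_size_um,
            perimeter_px=perimeter,
            circularity=circularity,
            aspect_ratio=aspect,
            feret_diameter_px=float(prop.feret_diameter_max),
            centroid=tuple(prop.centroid),
            skeleton_elongation=_skeleton_elongation(prop.image),
        )
        obj.morph_class = classify_morphology(obj, rules)
        objects.append(obj)
    return objects


def classify_morphology(obj: AggregateObject, rules: MorphologyRules) -> str:
    if obj.equivalent_diameter_um < rules.punctate_max_diameter_um:
        return "punctate"
    if obj.circularity >= rules.lb_min_circularity and obj.aspect_ratio <= rules.lb_max_aspect:
        return "lewy_body"
    if (
        obj.aspect_ratio >= rules.ln_min_aspect
        or obj.skeleton_elongation >= rules.ln_min_skeleton_elongation
    ):
        return "lewy_neurite"
    return "unclassified"


def morphology_distribution(objects: list[AggregateObject]) -> MorphologyDistribution:
    """Share of total aggregate area (and counts) per morphology class."""
    counts = {c: 0 for c in MORPH_CLASSES}
    areas = {c: 0 for c in MORPH_CLASSES}
    for obj in objects:
        counts[obj.morph_class] += 1
        areas[obj.morph_class] += obj.area_px
    total = sum(areas.values())
    if total == 0:
        return MorphologyDistribution(
            area_share_pct={c: math.nan for c in MORPH_CLASSES},
            counts=counts,
            total_area_px=0,
            defined=False,
        )
    return MorphologyDistribution(
        area_share_pct={c: 100.0 * a / total for c, a in areas.items()},
        counts=counts,
        total_area_px=total,
    )


def diameter_um(obj: AggregateObject) -> dict[str, float]:
    """Equivalent-circle and maximum Feret diameters in micrometres."""
    return {
        "equivalent_diameter_um": obj.equivalent_diameter_um,
        "feret_diameter_um": obj.feret_diameter_um,
    }
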