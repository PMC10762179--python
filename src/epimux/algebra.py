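"""Set algebra on co-registered binary channel masks.

Total immunolabelling is the union of all channel masks.  The area unique
to one epitope is obtained by subtracting the union of every other channel
from the total, and the overlapping area is what remains of the total once
every unique area has been removed.  Both subtraction-form quantities admit
per-pixel identities (unique = labelled by this epitope and no other;
overlap = covered by at least two channels) that are enforced by the test
suite rather than assumed here.

All areas are integer pixel counts; physical areas derive as
``px * pixel_size_um ** 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "EpitopeAreaReport",
    "total_area",
    "unique_area",
    "overlap_area",
    "epitope_report",
    "aggregate_composition",
]


def _as_bool(mask) -> np.ndarray:
    """Accept a ChannelMask or a raw boolean array."""
    arr = getattr(mask, "mask", mask)
    arr = np.asarray(arr)
    if arr.dtype != bool:
        arr = arr.astype(bool)
    return arr


def _check_shapes(masks: Mapping[str, object]) -> dict[str, np.ndarray]:
    if not masks:
        raise ValueError("at least one channel mask is required")
    arrs = {name: _as_bool(m) for name, m in masks.items()}
    shapes = {a.shape for a in arrs.values()}
    if len(shapes) != 1:
        raise ValueError(f"channel masks are not co-registered: shapes {sorted(shapes)}")
    return arrs


def total_area(masks: Mapping[str, object]) -> int:
    """Pixel count of the union of all channel masks."""
    arrs = _check_shapes(masks)
    union = np.zeros(next(iter(arrs.values())).shape, dtype=bool)
    for a in arrs.values():
        union |= a
    return int(union.sum())


def unique_area(masks: Mapping[str, object], epitope: str) -> int:
    """Area labelled exclusively by ``epitope``.

    Computed in subtraction form: total minus the union of the other
    channels.
    """
    arrs = _check_shapes(masks)
    if epitope not in arrs:
        raise KeyError(f"unknown epitope label {epitope!r}; have {sorted(arrs)}")
    others = {k: v for k, v in arrs.items() if k != epitope}
    if not others:
        return int(arrs[epitope].sum())
    return total_area(arrs) - total_area(others)


def overlap_area(masks: Mapping[str, object]) -> int:
    """Area covered by two or more channels: total minus every unique area."""
    arrs = _check_shapes(masks)
    tot = total_area(arrs)
    return tot - sum(unique_area(arrs, e) for e in arrs)


@dataclass
class EpitopeAreaReport:
    """Decomposition of total immunolabelling into unique and overlap areas.

    Percentages are normalised to the total immunolabelled area;
    ``pathology_load_pct`` is the total normalised to the quantified region
    area.  When ``total_area_px`` is zero the percentage fields are NaN and
    ``percentages_defined`` is False.
    """

    total_area_px: int
    unique_area_px: dict[str, int]
    overlap_area_px: int
    region_area_px: int
    pixel_size_um: float | None = None
    case_id: str = ""
    region_label: str = ""
    unique_pct: dict[str, float] = field(default_factory=dict)
    overlap_pct: float = math.nan
    pathology_load_pct: float = math.nan
    percentages_defined: bool = True

    def __post_init__(self) -> None:
        if self.total_area_px != sum(self.unique_area_px.values()) + self.overlap_area_px:
            raise ValueError("additivity violated: total != sum(unique) + overlap")
        if self.total_area_px > 0:
            self.unique_pct = {
                e: 100.0 * a / self.total_area_px for e, a in self.unique_area_px.items()
            }
            self.overlap_pct = 100.0 * self.overlap_area_px / self.total_area_px
            self.percentages_defined = True
        else:
            self.unique_pct = {e: math.nan for e in self.unique_area_px}
            self.overlap_pct = math.nan
            self.percentages_defined = False
        if self.region_area_px > 0:
            self.pathology_load_pct = 100.0 * self.total_area_px / self.region_area_px

    def _um2(self, px: int) -> float:
        if self.pixel_size_um is None:
            return math.nan
        return px * self.pixel_size_um**2

    @property
    def total_area_um2(self) -> float:
        return self._um2(self.total_area_px)

    @property
    def overlap_area_um2(self) -> float:
        return self._um2(self.overlap_area_px)

    @property
    def unique_area_um2(self) -> dict[str, float]:
        return {e: self._um2(a) for e, a in self.unique_area_px.items()}


def epitope_report(
    masks: Mapping[str, object],
    region_mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
    case_id: str = "",
    region_label: str = "",
) -> EpitopeAreaReport:
    """Assemble the full unique/overlap decomposition for one image.

    Mask foreground falling outside ``region_mask`` is clipped to the
    region before quantification.
    """
    arrs = _check_shapes(masks)
    shape = next(iter(arrs.values())).shape
    if region_mask is not None:
        region = _as_bool(region_mask)
        if region.shape != shape:
            raise ValueError("region_mask shape differs from channel masks")
        arrs = {e: a & region for e, a in arrs.items()}
        region_area = int(region.sum())
    else:
        region_area = int(np.prod(shape))
    if region_area == 0:
        raise ValueError("region of quantification has zero area")

    uniq = {e: unique_area(arrs, e) for e in arrs}
    tot = total_area(arrs)
    return EpitopeAreaReport(
        total_area_px=tot,
        unique_area_px=uniq,
        overlap_area_px=tot - sum(uniq.values()),
        region_area_px=region_area,
        pixel_size_um=pixel_size_um,
        case_id=case_id,
        region_label=region_label,
    )


def aggregate_composition(
    footprint: np.ndarray,
    masks: Mapping[str, object],
    pixel_size_um: float | None = None,
) -> EpitopeAreaReport:
    """Unique/overlap decomposition restricted to one aggregate's footprint.

    ``footprint`` may be an AggregateObject (its ``.footprint`` is used) or
    a boolean array.
    """
    fp = _as_bool(getattr(footprint, "footprint", footprint))
    return epitope_report(masks, region_mask=fp, pixel_size_um=pixel_size_um)
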