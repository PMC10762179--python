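"""Proteinase-K digestion time-course quantification.

Per-epitope signal is measured at each digestion timepoint and expressed
as a percentage of the pre-treatment (t = 0) value.  Two measurement modes
are provided: thresholded foreground area (default) and integrated
background-corrected intensity inside the t = 0 union footprint.  Values
above 100% are legitimate (epitope unmasking early in digestion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from epimux.image_io import AnalysisConfig, MultiplexImage
from epimux.segment import segment_channel

__all__ = [
    "PKTimeSeries",
    "RetentionFit",
    "measure_timepoint",
    "normalize_series",
    "fit_retention",
]

UNMASKING_WINDOW_MIN = 15.0  # early digestion can unmask epitopes; the decay
# fit therefore only uses timepoints strictly beyond this


@dataclass
class PKTimeSeries:
    """Per-epitope quantities across timepoints, normalised to t = 0.

    ``normalized_pct[e][i] == 100 * raw[e][i] / raw[e][0]``; the value at
    the first timepoint is exactly 100.
    """

    subject_id: str
    timepoints_min: list[float]
    raw: dict[str, list[float]]
    normalized_pct: dict[str, list[float]] = field(default_factory=dict)
    excluded_epitopes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timepoints_min or self.timepoints_min[0] != 0:
            raise ValueError("series must start at the pre-treatment timepoint (0)")
        n = len(self.timepoints_min)
        for e, vals in self.raw.items():
            if len(vals) != n:
                raise ValueError(f"epitope {e!r}: {len(vals)} values for {n} timepoints")


@dataclass
class RetentionFit:
    """Per-timepoint retention estimates and an exponential decay rate."""

    epitope: str
    timepoints_min: list[float]
    retention: list[float]  # normalized_pct / 100
    decay_rate_per_min: float  # NaN when undefined


def measure_timepoint(
    image: MultiplexImage,
    config: AnalysisConfig,
    footprint: np.ndarray | None = None,
    mode: str | None = None,
) -> dict[str, float]:
    """Per-epitope quantity for one acquisition round.

    mode "area": thresholded foreground area in pixels (restricted to
    ``footprint`` when given).  mode "intensity": integrated intensity
    inside ``footprint`` after subtracting the median intensity of the
    surrounding background; requires a footprint (normally the t = 0 union
    mask, since acquisitions are co-registered).
    """
    mode = mode or config.pk_mode
    out: dict[str, float] = {}
    if mode == "area":
        for e, channel in image.channels.items():
            cm = segment_channel(channel, config, epitope=e, region_mask=image.region_mask)
            mask = cm.mask if footprint is None else (cm.mask & footprint)
            out[e] = float(mask.sum())
        return out
    if mode == "intensity":
        if footprint is None:
            raise ValueError("intensity mode requires the t=0 union footprint")
        fp = np.asarray(footprint, dtype=bool)
        for e, channel in image.channels.items():
            if fp.shape != channel.shape:
                raise ValueError("footprint shape differs from channel")
            background = float(np.median(channel[~fp])) if (~fp).any() else 0.0
            quantity = float(channel[fp].sum()) - background * int(fp.sum())
            out[e] = max(0.0, quantity)
        return out
    raise ValueError(f"unknown mode {mode!r}")


def normalize_series(
    subject_id: str,
    timepoints_min: Sequence[float],
    raw: Mapping[str, Sequence[float]],
) -> PKTimeSeries:
    """Express each epitope's quantities relative to its t = 0 value.

    Epitopes with a zero pre-treatment quantity cannot be normalised; they
    are excluded and recorded in ``excluded_epitopes``.
    """
    timepoints = [float(t) for t in timepoints_min]
    if not timepoints or timepoints[0] != 0:
        raise ValueError("no t=0 (pre-treatment) measurement")
    kept: dict[str, list[float]] = {}
    normalized: dict[str, list[float]] = {}
    excluded: list[str] = []
    for e, vals in raw.items():
        vals = [float(v) for v in vals]
        if any(v < 0 for v in vals):
            raise ValueError(f"negative quantity for epitope {e!r}")
        if vals[0] <= 0:
            excluded.append(e)
            continue
        kept[e] = vals
        normalized[e] = [100.0 * v / vals[0] for v in vals]
    return PKTimeSeries(
        subject_id=subject_id,
        timepoints_min=timepoints,
        raw=kept,
        normalized_pct=normalized,
        excluded_epitopes=excluded,
    )


def fit_retention(series: PKTimeSeries) -> dict[str, RetentionFit]:
    """Retention per timepoint plus an exponential decay-rate estimate.

    The rate comes from a least-squares fit of log-retention against time
    over timepoints strictly beyond the unmasking window (> 15 min); with
    fewer than two such timepoints the rate is NaN.
    """
    fits: dict[str, RetentionFit] = {}
    t = np.asarray(series.timepoints_min, dtype=float)
    for e, pct in series.normalized_pct.items():
        retention = [p / 100.0 for p in pct]
        late = [
            (ti, r)
            for ti, r in zip(t, retention)
            if ti > UNMASKING_WINDOW_MIN and r > 0
        ]
        if len(late) >= 2:
            tt = np.array([x for x, _ in late])
            rr = np.log([r for _, r in late])
            slope = np.polyfit(tt, rr, 1)[0]
            rate = -float(slope)
        else:
            rate = math.nan
        fits[e] = RetentionFit(
            epitope=e,
            timepoints_min=list(series.timepoints_min),
            retention=retention,
            decay_rate_per_min=rate,
        )
    return fits
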