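"""Synthetic multiplex immunofluorescence scenes with exact ground truth.

Renders simulated Lewy pathology — compact bodies with uniform core labelling
and peripherally concentrated ring labelling, thread/club neurites (including
single-epitope populations), punctate lysosomal and glial aggregates carried
by a single channel, and diffuse low-intensity monomeric background — plus
detector noise and multiplicative per-epitope signal retention across
digestion timepoints.  Every render is accompanied by noiseless per-aggregate
per-epitope masks from which exact area decompositions can be enumerated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import distance_transform_edt

from epimux.algebra import EpitopeAreaReport
from epimux.image_io import DEFAULT_EPITOPES, MultiplexImage

__all__ = [
    "EpitopePattern",
    "AggregateSpec",
    "SceneSpec",
    "GroundTruth",
    "PKModel",
    "render_scene",
    "expected_report",
    "simulate_pk_series",
    "random_scene",
    "complementary_cohort_specs",
    "pk_subject_spec",
    "export_ground_truth",
]

KINDS = ("lewy_body", "lewy_neurite", "punctate_lysosomal", "glial")
PATTERNS = ("absent", "uniform", "peripheral_ring", "punctate")


@dataclass(frozen=True)
class EpitopePattern:
    """Spatial labelling pattern of one epitope on one aggregate."""

    pattern: str = "absent"
    peak: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern != "absent" and self.peak <= 0:
            raise ValueError("peak intensity must be > 0 for a non-absent pattern")


@dataclass
class AggregateSpec:
    """One simulated aggregate.

    ``size_um`` is the body/punctum diameter or the neurite length;
    ``thickness_um``, ``orientation_rad``, ``curvature`` and the club
    parameters apply to neurite-shaped kinds only.
    """

    kind: str
    centroid: tuple[float, float]  # (row, col), pixels
    size_um: float
    epitope_profile: dict[str, EpitopePattern]
    thickness_um: float = 1.0
    orientation_rad: float = 0.0
    curvature: float = 0.15  # std-dev of per-step heading change, radians
    club_end: bool = False
    club_factor: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown aggregate kind {self.kind!r}")
        if self.size_um <= 0 or self.thickness_um <= 0:
            raise ValueError("size and thickness must be > 0")
        profile = {
            e: (p if isinstance(p, EpitopePattern) else EpitopePattern(**p))
            for e, p in self.epitope_profile.items()
        }
        self.epitope_profile = profile
        if all(p.pattern == "absent" for p in profile.values()):
            raise ValueError("at least one epitope pattern must be non-absent")


@dataclass
class SceneSpec:
    """Full description of one renderable scene; ``seed`` fixes the output."""

    shape: tuple[int, int]
    pixel_size_um: float
    aggregates: list[AggregateSpec]
    monomer_background: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    poisson_scale: float = 0.0
    seed: int = 0
    ring_fraction: float = 0.25  # annulus width as a fraction of the radius
    channel_panel: tuple[str, ...] | None = None  # explicit channel list

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.noise_sigma < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (0 < self.ring_fraction <= 1):
            raise ValueError("ring_fraction must lie in (0, 1]")
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        self.aggregates = [
            a if isinstance(a, AggregateSpec) else AggregateSpec(**a) for a in self.aggregates
        ]

    @property
    def epitopes(self) -> tuple[str, ...]:
        if self.channel_panel is not None:
            return tuple(self.channel_panel)
        labels: list[str] = []
        for agg in self.aggregates:
            for e in agg.epitope_profile:
                if e not in labels:
                    labels.append(e)
        for e in self.monomer_background:
            if e not in labels:
                labels.append(e)
        if not labels:
            return tuple(DEFAULT_EPITOPES)
        # scenes that only use panel labels render the complete panel, so
        # unlabelled channels come out as pure background
        if all(e in DEFAULT_EPITOPES for e in labels):
            return tuple(DEFAULT_EPITOPES)
        return tuple(labels)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneSpec":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        d["aggregates"] = [
            AggregateSpec(
                kind=a["kind"],
                centroid=tuple(a["centroid"]),
                size_um=a["size_um"],
                epitope_profile={
                    e: EpitopePattern(**p) for e, p in a["epitope_profile"].items()
                },
                **{
                    k: a[k]
                    for k in ("thickness_um", "orientation_rad", "curvature",
                              "club_end", "club_factor")
                    if k in a
                },
            )
            for a in d["aggregates"]
        ]
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SceneSpec":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class GroundTruth:
    """Noiseless per-aggregate masks plus everything derived from them."""

    aggregate_masks: list[dict[str, np.ndarray]]
    kinds: list[str]
    footprints: list[np.ndarray]
    region_mask: np.ndarray
    pixel_size_um: float
    # noiseless integrated intensity per aggregate per epitope
    integrated_intensity: list[dict[str, float]] = field(default_factory=list)
    sizes_um: list[float] = field(default_factory=list)

    def channel_mask(self, epitope: str) -> np.ndarray:
        """Union of this epitope's masks across aggregates."""
        out = np.zeros(self.region_mask.shape, dtype=bool)
        for masks in self.aggregate_masks:
            if epitope in masks:
                out |= masks[epitope]
        return out

    @property
    def epitopes(self) -> tuple[str, ...]:
        labels: list[str] = []
        for masks in self.aggregate_masks:
            for e in masks:
                if e not in labels:
                    labels.append(e)
        return tuple(labels)


@dataclass
class PKModel:
    """Multiplicative per-epitope signal retention over digestion time.

    ``retention[epitope][t]`` scales the rendered aggregate intensity at
    timepoint ``t`` (minutes); factors above 1 model epitope unmasking.
    Only aggregates of the ``affected_kinds`` are scaled.
    """

    timepoints_min: Sequence[float]
    retention: dict[str, dict[float, float]]
    affected_kinds: tuple[str, ...] = KINDS

    def __post_init__(self) -> None:
        tps = list(self.timepoints_min)
        if not tps or tps[0] != 0:
            raise ValueError("timepoints must start at 0 (pre-treatment)")
        if sorted(tps) != tps or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be strictly increasing")
        for e, by_t in self.retention.items():
            for t, f in by_t.items():
                if f < 0:
                    raise ValueError(f"retention factor < 0 for ({e}, {t})")
            if by_t.get(0, 1.0) != 1.0:
                raise ValueError(f"retention at t=0 must equal 1 for {e!r}")
        self.timepoints_min = tps

    def factor(self, epitope: str, t: float) -> float:
        return float(self.retention.get(epitope, {}).get(t, 1.0))


# ---------------------------------------------------------------------------
# Rasterisation


def _structure_rng(seed: int, index: int) -> np.random.Generator:
    # Separate stream from the noise generator so digestion series keep
    # identical structures across timepoints.
    return np.random.default_rng([seed, 1000 + index])


def _disc(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _neurite_footprint(spec: AggregateSpec, shape, px: float, rng) -> np.ndarray:
    """Thickened smoothed random-walk polyline; optionally one inflated end."""
    length_px = max(2, int(round(spec.size_um / px)))
    half_w = max(1.0, spec.thickness_um / (2 * px))
    heading = spec.orientation_rad
    # walk outward from the centroid so the centroid stays on the path
    pts = [np.asarray(spec.centroid, dtype=float)]
    for _ in range(length_px - 1):
        heading += rng.normal(0.0, spec.curvature)
        pts.append(pts[-1] + np.array([math.sin(heading), math.cos(heading)]))
    footprint = np.zeros(shape, dtype=bool)
    for p in pts:
        footprint |= _disc(shape, p, half_w)
    if spec.club_end:
        footprint |= _disc(shape, pts[-1], half_w * spec.club_factor)
    return footprint


def _footprint(spec: AggregateSpec, shape, px: float, rng) -> np.ndarray:
    if spec.kind in ("lewy_body", "punctate_lysosomal"):
        return _disc(shape, spec.centroid, spec.size_um / (2 * px))
    return _neurite_footprint(spec, shape, px, rng)


def _pattern_mask(
    pattern: str,
    footprint: np.ndarray,
    spec: AggregateSpec,
    px: float,
    ring_fraction: float,
    rng,
) -> np.ndarray:
    if pattern == "uniform":
        return footprint
    if pattern == "peripheral_ring":
        # Ring = pixels within ring_fraction * nominal radius of the
        # footprint boundary (exact annulus for disc-shaped kinds).
        if spec.kind in ("lewy_body", "punctate_lysosomal"):
            nominal_radius = spec.size_um / (2 * px)
        else:
            nominal_radius = max(1.0, spec.thickness_um / (2 * px))
        width = max(1.0, ring_fraction * nominal_radius)
        depth = distance_transform_edt(footprint)
        return footprint & (depth <= width)
    if pattern == "punctate":
        coords = np.argwhere(footprint)
        n_puncta = max(3, coords.shape[0] // 40)
        chosen = coords[rng.choice(coords.shape[0], size=n_puncta, replace=True)]
        mask = np.zeros(footprint.shape, dtype=bool)
        for r, c in chosen:
            mask |= _disc(footprint.shape, (r, c), max(1.0, 0.5 / px))
        return mask & footprint
    raise ValueError(f"unknown pattern {pattern!r}")


def _render(
    spec: SceneSpec,
    retention: Mapping[str, float] | None = None,
    affected_kinds: Sequence[str] = KINDS,
    noise_seed: int | None = None,
) -> tuple[MultiplexImage, GroundTruth]:
    epitopes = spec.epitopes
    shape = spec.shape
    px = spec.pixel_size_um
    channels = {e: np.zeros(shape, dtype=np.float64) for e in epitopes}

    aggregate_masks: list[dict[str, np.ndarray]] = []
    footprints: list[np.ndarray] = []
    intensities: list[dict[str, float]] = []
    for i, agg in enumerate(spec.aggregates):
        rng = _structure_rng(spec.seed, i)
        footprint = _footprint(agg, shape, px, rng)
        if not footprint.any():
            raise ValueError(f"aggregate {i} ({agg.kind}) falls entirely outside the image")
        masks: dict[str, np.ndarray] = {}
        sums: dict[str, float] = {}
        for e in epitopes:
            prof = agg.epitope_profile.get(e, EpitopePattern())
            if prof.pattern == "absent":
                continue
            pmask = _pattern_mask(prof.pattern, footprint, agg, px, spec.ring_fraction, rng)
            factor = 1.0
            if retention is not None and agg.kind in affected_kinds:
                factor = retention.get(e, 1.0)
            if factor > 0:
                channels[e][pmask] += prof.peak * factor
                masks[e] = pmask
                sums[e] = float(prof.peak * factor * pmask.sum())
            else:
                sums[e] = 0.0
        aggregate_masks.append(masks)
        footprints.append(footprint)
        intensities.append(sums)

    for e in epitopes:
        channels[e] += spec.monomer_background.get(e, 0.0)

    if spec.noise_sigma > 0 or spec.poisson_scale > 0:
        seed = spec.seed if noise_seed is None else noise_seed
        noise_rng = np.random.default_rng(seed)
        for e in epitopes:  # fixed order keeps renders bit-reproducible
            img = channels[e]
            if spec.noise_sigma > 0:
                img = img + noise_rng.normal(0.0, spec.noise_sigma, shape)
            if spec.poisson_scale > 0:
                img = img + noise_rng.normal(0.0, 1.0, shape) * np.sqrt(
                    np.clip(img, 0, None)
                ) * spec.poisson_scale
            channels[e] = img
    channels = {e: np.clip(a, 0.0, None) for e, a in channels.items()}

    image = MultiplexImage(channels=channels, pixel_size_um=px)
    gt = GroundTruth(
        aggregate_masks=aggregate_masks,
        kinds=[a.kind for a in spec.aggregates],
        footprints=footprints,
        region_mask=np.ones(shape, dtype=bool),
        pixel_size_um=px,
        integrated_intensity=intensities,
        sizes_um=[a.size_um for a in spec.aggregates],
    )
    return image, gt


def render_scene(spec: SceneSpec) -> tuple[MultiplexImage, GroundTruth]:
    """Render one scene; the ground truth holds the pre-noise masks."""
    return _render(spec)


def expected_report(gt: GroundTruth, region_mask: np.ndarray | None = None) -> EpitopeAreaReport:
    """Exact area decomposition by per-pixel coverage enumeration.

    This is deliberately computed from coverage counts (how many epitope
    masks label each pixel) rather than by the subtraction-form algebra of
    :mod:`epimux.algebra`, so the two routes stay independent.
    """
    epitopes = gt.epitopes
    region = gt.region_mask if region_mask is None else np.asarray(region_mask, dtype=bool)
    shape = region.shape
    stack = (
        np.stack([gt.channel_mask(e) & region for e in epitopes])
        if epitopes
        else np.zeros((0,) + shape, dtype=bool)
    )
    coverage = stack.sum(axis=0)
    unique = {
        e: int((stack[i] & (coverage == 1)).sum()) for i, e in enumerate(epitopes)
    }
    return EpitopeAreaReport(
        total_area_px=int((coverage >= 1).sum()),
        unique_area_px=unique,
        overlap_area_px=int((coverage >= 2).sum()),
        region_area_px=int(region.sum()),
        pixel_size_um=gt.pixel_size_um,
    )


def simulate_pk_series(
    spec: SceneSpec, model: PKModel
) -> tuple[list[MultiplexImage], list[GroundTruth]]:
    """One render per digestion timepoint.

    Aggregate intensity is scaled by the retention factor before noise;
    per-timepoint noise uses ``seed XOR timepoint-index`` so the series is
    reproducible yet independent across timepoints, and timepoint 0 equals
    :func:`render_scene` bit-exactly.
    """
    images: list[MultiplexImage] = []
    truths: list[GroundTruth] = []
    epitopes = spec.epitopes
    for t_idx, t in enumerate(model.timepoints_min):
        retention = {e: model.factor(e, t) for e in epitopes}
        img, gt = _render(
            spec,
            retention=retention,
            affected_kinds=model.affected_kinds,
            noise_seed=spec.seed ^ t_idx,
        )
        images.append(img)
        truths.append(gt)
    return images, truths


def export_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    """Per-epitope label TIFFs (pixel value = aggregate id + 1) + CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for e in gt.epitopes:
        label = np.zeros(gt.region_mask.shape, dtype=np.uint16)
        for i, masks in enumerate(gt.aggregate_masks):
            if e in masks:
                label[masks[e]] = i + 1
        tifffile.imwrite(str(out_dir / f"gt_{e}.tif"), label)
    rows = []
    for i, (kind, size, masks) in enumerate(zip(gt.kinds, gt.sizes_um, gt.aggregate_masks)):
        rows.append(
            {
                "aggregate_id": i,
                "kind": kind,
                "size_um": size,
                "composition": ";".join(sorted(masks)),
                "area_px": int(gt.footprints[i].sum()),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "gt_manifest.csv", index=False)


# ---------------------------------------------------------------------------
# Reference scene builders (used by tests, the acceptance report and the CLI
# `simulate` command; paper-informed size ranges).

LB_DIAMETER_RANGE_UM = (5.0, 55.0)
LN_LENGTH_RANGE_UM = (3.0, 25.0)

_DEFAULT_PEAK = 160.0


def _lb_profile(peak: float = _DEFAULT_PEAK) -> dict[str, EpitopePattern]:
    # Uniform core labelling in the N-terminus channel; ring-dominant
    # labelling for pS129 / C-terminus.
    return {
        "Nterm": EpitopePattern("uniform", peak),
        "pS129": EpitopePattern("peripheral_ring", peak),
        "Cterm": EpitopePattern("peripheral_ring", peak * 0.9),
    }


def _ln_profile(population: str, peak: float = _DEFAULT_PEAK) -> dict[str, EpitopePattern]:
    if population == "shared":
        return {
            "Nterm": EpitopePattern("uniform", peak),
            "pS129": EpitopePattern("uniform", peak),
            "Cterm": EpitopePattern("uniform", peak * 0.9),
        }
    if population == "n_exclusive":
        return {"Nterm": EpitopePattern("uniform", peak)}
    if population == "ps129_exclusive":
        return {"pS129": EpitopePattern("uniform", peak)}
    raise ValueError(population)


def _grid_positions(shape, n, margin, rng) -> list[tuple[float, float]]:
    """Jittered grid placement keeping aggregates apart and inside the frame."""
    side = int(np.ceil(np.sqrt(n)))
    rows = np.linspace(margin, shape[0] - margin, side)
    cols = np.linspace(margin, shape[1] - margin, side)
    cells = [(r, c) for r in rows for c in cols]
    order = rng.permutation(len(cells))[:n]
    jitter = min(6.0, margin / 4)
    return [
        (cells[i][0] + rng.uniform(-jitter, jitter), cells[i][1] + rng.uniform(-jitter, jitter))
        for i in order
    ]


def random_scene(
    seed: int,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.5,
    n_lewy_bodies: int = 3,
    n_lewy_neurites: int = 4,
    n_punctate: int = 3,
    n_glial: int = 2,
    noise_sigma: float = 2.0,
    poisson_scale: float = 0.0,
    monomer_background: Mapping[str, float] | None = None,
) -> SceneSpec:
    """Mixed-pathology reference scene with non-overlapping aggregates."""
    rng = np.random.default_rng([seed, 77])
    n = n_lewy_bodies + n_lewy_neurites + n_punctate + n_glial
    margin = 40.0
    positions = _grid_positions(shape, n, margin, rng)
    aggregates: list[AggregateSpec] = []
    it = iter(positions)
    for _ in range(n_lewy_bodies):
        aggregates.append(
            AggregateSpec(
                kind="lewy_body",
                centroid=next(it),
                size_um=rng.uniform(8.0, 28.0),
                epitope_profile=_lb_profile(peak=rng.uniform(140.0, 200.0)),
            )
        )
    populations = ["shared", "n_exclusive", "ps129_exclusive"]
    for j in range(n_lewy_neurites):
        aggregates.append(
            AggregateSpec(
                kind="lewy_neurite",
                centroid=next(it),
                size_um=rng.uniform(10.0, 25.0),
                thickness_um=rng.uniform(1.0, 1.8),
                orientation_rad=rng.uniform(0, 2 * math.pi),
                curvature=0.12,
                club_end=bool(j % 3 == 0),
                epitope_profile=_ln_profile(populations[j % 3], peak=rng.uniform(140.0, 200.0)),
            )
        )
    for _ in range(n_punctate):
        aggregates.append(
            AggregateSpec(
                kind="punctate_lysosomal",
                centroid=next(it),
                size_um=rng.uniform(1.0, 1.8),
                epitope_profile={"Nterm": EpitopePattern("uniform", rng.uniform(140.0, 200.0))},
            )
        )
    for _ in range(n_glial):
        aggregates.append(
            AggregateSpec(
                kind="glial",
                centroid=next(it),
                size_um=rng.uniform(8.0, 16.0),
                thickness_um=1.0,
                orientation_rad=rng.uniform(0, 2 * math.pi),
                curvature=0.12,
                epitope_profile={"Nterm": EpitopePattern("uniform", rng.uniform(140.0, 200.0))},
            )
        )
    if monomer_background is None:
        monomer_background = {"Cterm": 8.0}
    return SceneSpec(
        shape=shape,
        pixel_size_um=pixel_size_um,
        aggregates=aggregates,
        monomer_background=dict(monomer_background),
        noise_sigma=noise_sigma,
        poisson_scale=poisson_scale,
        seed=seed,
    )


def complementary_cohort_specs(
    n_cases: int,
    seed: int,
    shape: tuple[int, int] = (384, 384),
    noise_sigma: float = 2.0,
) -> list[SceneSpec]:
    """Cohort whose N-exclusive and pS129-exclusive unique fractions trade off.

    Case i carries ``n_exclusive`` neurites in proportion f_i and
    ``ps129_exclusive`` neurites in proportion 1 - f_i (plus a small shared
    population), so across cases the two unique percentages are strongly
    negatively correlated.
    """
    specs: list[SceneSpec] = []
    rng = np.random.default_rng([seed, 99])
    n_ln_total = 8
    for i in range(n_cases):
        f = i / max(1, n_cases - 1)
        n_excl = int(round(f * n_ln_total))
        positions = _grid_positions(shape, n_ln_total + 2, 36.0, rng)
        it = iter(positions)
        aggregates = []
        for j in range(n_ln_total):
            pop = "n_exclusive" if j < n_excl else "ps129_exclusive"
            aggregates.append(
                AggregateSpec(
                    kind="lewy_neurite",
                    centroid=next(it),
                    size_um=rng.uniform(12.0, 22.0),
                    thickness_um=1.4,
                    orientation_rad=rng.uniform(0, 2 * math.pi),
                    curvature=0.1,
                    epitope_profile=_ln_profile(pop, peak=170.0),
                )
            )
        # small shared population so every channel is present in every case
        for _ in range(2):
            aggregates.append(
                AggregateSpec(
                    kind="lewy_neurite",
                    centroid=next(it),
                    size_um=10.0,
                    thickness_um=1.2,
                    orientation_rad=rng.uniform(0, 2 * math.pi),
                    curvature=0.1,
                    epitope_profile=_ln_profile("shared", peak=170.0),
                )
            )
        specs.append(
            SceneSpec(
                shape=shape,
                pixel_size_um=0.5,
                aggregates=aggregates,
                monomer_background={"Cterm": 8.0},
                noise_sigma=noise_sigma,
                seed=seed + 1000 * (i + 1),
            )
        )
    return specs


def pk_subject_spec(
    seed: int,
    shape: tuple[int, int] = (96, 96),
    noise_sigma: float = 2.0,
) -> SceneSpec:
    """Single representative aggregate for digestion time-course experiments."""
    rng = np.random.default_rng([seed, 55])
    return SceneSpec(
        shape=shape,
        pixel_size_um=0.5,
        aggregates=[
            AggregateSpec(
                kind="glial",
                centroid=(shape[0] / 2, shape[1] / 2),
                size_um=rng.uniform(10.0, 14.0),
                thickness_um=1.6,
                orientation_rad=rng.uniform(0, 2 * math.pi),
                curvature=0.1,
                epitope_profile={
                    "Nterm": EpitopePattern("uniform", 170.0),
                    "pS129": EpitopePattern("uniform", 160.0),
                    "Cterm": EpitopePattern("uniform", 150.0),
                },
            )
        ],
        monomer_background={"Cterm": 6.0},
        noise_sigma=noise_sigma,
        seed=seed,
    )
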