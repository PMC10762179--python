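"""Image, report and configuration I/O.

Images are multi-channel TIFF / OME-TIFF, one plane per epitope antibody.
Reports are flat CSV tables. Configuration is YAML or JSON.

Conventions: arrays are row-major with the origin at the top-left, 0-based;
pixel areas convert to physical units as ``px * pixel_size_um ** 2``.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from epimux.algebra import EpitopeAreaReport

__all__ = [
    "MultiplexImage",
    "AnalysisConfig",
    "read_multiplex",
    "write_multiplex",
    "write_report",
    "read_report",
    "parse_channel_map",
    "REPORT_COLUMNS",
]

DEFAULT_EPITOPES = ("Nterm", "pS129", "Cterm")


@dataclass
class MultiplexImage:
    """Co-registered per-epitope intensity channels with pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    region_mask: np.ndarray | None = None
    case_id: str = ""
    region_label: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree in shape: {sorted(shapes)}")
        self.channels = {e: np.asarray(a, dtype=np.float64) for e, a in self.channels.items()}
        for e, a in self.channels.items():
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {e!r} has non-finite intensities")
            if a.min() < 0:
                raise ValueError(f"channel {e!r} has negative intensities")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.region_mask is not None:
            self.region_mask = np.asarray(self.region_mask, dtype=bool)
            if self.region_mask.shape != self.shape:
                raise ValueError("region_mask shape differs from channels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def epitopes(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass
class AnalysisConfig:
    """Validated parameters for segmentation, morphometry and statistics."""

    channel_map: dict[int, str] = field(
        default_factory=lambda: {i: e for i, e in enumerate(DEFAULT_EPITOPES)}
    )
    pixel_size_um: float | None = None
    blur_sigma_px: float = 20.0
    n_bins: int = 256
    monomer_floor_mode: str = "quantile_of_background"
    monomer_floor_value: float = 0.999
    min_object_px: int = 5
    # morphology rules
    lb_min_circularity: float = 0.6
    lb_max_aspect: float = 2.0
    ln_min_aspect: float = 3.0
    ln_min_skeleton_elongation: float = 3.0
    punctate_max_diameter_um: float = 2.0
    # PK quantification
    pk_mode: str = "area"  # or "intensity"
    statistics_alpha: float = 0.05

    def __post_init__(self) -> None:
        labels = list(self.channel_map.values())
        if len(set(labels)) != len(labels):
            raise ValueError("channel_map assigns one epitope to several channels")
        if self.blur_sigma_px <= 0:
            raise ValueError("blur_sigma_px must be > 0")
        if not (0 < self.statistics_alpha < 1):
            raise ValueError("statistics_alpha must lie in (0, 1)")
        if self.monomer_floor_mode not in ("absolute", "quantile_of_background"):
            raise ValueError(f"unknown monomer_floor_mode {self.monomer_floor_mode!r}")
        if self.pk_mode not in ("area", "intensity"):
            raise ValueError(f"unknown pk_mode {self.pk_mode!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "channel_map" in d:
            d["channel_map"] = {int(k): str(v) for k, v in dict(d["channel_map"]).items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["channel_map"] = {str(k): v for k, v in self.channel_map.items()}
        return d


def parse_channel_map(text: str) -> dict[int, str]:
    """Parse a CLI channel map like ``"0=Nterm,1=pS129,2=Cterm"``."""
    out: dict[int, str] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        idx, _, label = part.partition("=")
        if not label:
            raise ValueError(f"malformed channel-map entry {part!r}")
        out[int(idx)] = label.strip()
    if not out:
        raise ValueError("empty channel map")
    return out


# ---------------------------------------------------------------------------
# TIFF I/O


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    if not tif.ome_metadata:
        return None
    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            size = el.get("PhysicalSizeX")
            if size is not None:
                return float(size)
    return None


def write_multiplex(image: MultiplexImage, path: str | Path, dtype=np.uint16) -> None:
    """Export as multi-channel OME-TIFF, quantised to 16-bit.

    Channel names carry the epitope labels and the pixel size is written
    into the OME metadata.
    """
    stack = np.stack([image.channels[e] for e in image.epitopes]).astype(np.float64)
    stack = np.clip(np.rint(stack), 0, np.iinfo(dtype).max).astype(dtype)
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(image.epitopes)},
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_multiplex(
    path: str | Path,
    channel_map: Mapping[int, str],
    pixel_size_um: float | None = None,
    case_id: str = "",
    region_label: str = "",
) -> MultiplexImage:
    """Read a TIFF / OME-TIFF and name its planes per ``channel_map``.

    The pixel size is taken from OME metadata when present, else from the
    ``pixel_size_um`` argument; if neither is available an error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta_pixel = _ome_pixel_size(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a (C, Y, X) stack, got shape {data.shape}")
    n_channels = data.shape[0]
    missing = [i for i in channel_map if i >= n_channels or i < 0]
    if missing:
        raise ValueError(
            f"channel_map references channel(s) {missing} but file has {n_channels}"
        )
    size = meta_pixel if meta_pixel is not None else pixel_size_um
    if size is None:
        raise ValueError(f"{path}: no pixel size in metadata and none configured")
    channels = {label: data[idx].astype(np.float64) for idx, label in channel_map.items()}
    return MultiplexImage(
        channels=channels,
        pixel_size_um=float(size),
        case_id=case_id or path.stem,
        region_label=region_label,
    )


# ---------------------------------------------------------------------------
# Report CSV

REPORT_COLUMNS = [
    "case_id",
    "region",
    "region_area_px",
    "total_area_px",
    "total_area_um2",
    "unique_Nterm_px",
    "unique_pS129_px",
    "unique_Cterm_px",
    "overlap_px",
    "unique_Nterm_pct",
    "unique_pS129_pct",
    "unique_Cterm_pct",
    "overlap_pct",
    "pathology_load_pct",
]


def _report_row(report: EpitopeAreaReport) -> dict:
    row = {
        "case_id": report.case_id,
        "region": report.region_label,
        "region_area_px": report.region_area_px,
        "total_area_px": report.total_area_px,
        "total_area_um2": report.total_area_um2,
        "overlap_px": report.overlap_area_px,
        "overlap_pct": report.overlap_pct,
        "pathology_load_pct": report.pathology_load_pct,
    }
    for e, a in report.unique_area_px.items():
        row[f"unique_{e}_px"] = a
        row[f"unique_{e}_pct"] = report.unique_pct[e]
    return row


def write_report(
    reports: EpitopeAreaReport | Iterable[EpitopeAreaReport],
    path: str | Path,
    epitopes: Sequence[str] = DEFAULT_EPITOPES,
) -> pd.DataFrame:
    """Write one CSV row per (case, region). Returns the frame written."""
    if isinstance(reports, EpitopeAreaReport):
        reports = [reports]
    columns = (
        ["case_id", "region", "region_area_px", "total_area_px", "total_area_um2"]
        + [f"unique_{e}_px" for e in epitopes]
        + ["overlap_px"]
        + [f"unique_{e}_pct" for e in epitopes]
        + ["overlap_pct", "pathology_load_pct"]
    )
    frame = pd.DataFrame([_report_row(r) for r in reports], columns=columns)
    frame.to_csv(path, index=False)
    return frame


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
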