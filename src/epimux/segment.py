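"""Background subtraction and per-channel thresholding.

The segmentation pipeline is: Gaussian-blur background subtraction, Otsu
thresholding of the residual, raising the threshold to a monomer floor so
that diffuse low-intensity (monomeric) signal is excluded, binarisation,
and removal of sub-resolution speckle objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as _cc_label

__all__ = ["ChannelMask", "subtract_background", "otsu_threshold", "segment_channel"]


class ConstantChannelError(ValueError):
    """Raised when a threshold is requested for a constant-intensity array."""


@dataclass
class ChannelMask:
    """Binary segmentation of one epitope channel.

    The effective binarisation threshold is ``max(otsu_threshold,
    floor_applied)``; foreground is strictly greater than it.
    """

    epitope: str
    mask: np.ndarray
    otsu_threshold: float
    floor_applied: float
    n_foreground_px: int = field(default=-1)
    n_speckle_px_removed: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_foreground_px < 0:
            self.n_foreground_px = int(self.mask.sum())
        if self.n_foreground_px != int(self.mask.sum()):
            raise ValueError("n_foreground_px inconsistent with mask")

    @property
    def effective_threshold(self) -> float:
        return max(self.otsu_threshold, self.floor_applied)


def subtract_background(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Subtract a Gaussian-blurred estimate of the background.

    Returns ``channel - gaussian_blur(channel, sigma)`` clipped below at
    zero.  The blur uses reflect boundary handling.

    Parameters
    ----------
    channel : 2-D intensity array (finite values).
    sigma : blur standard deviation in pixels, > 0.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite pixels")
    blurred = gaussian_filter(channel, sigma=sigma, mode="reflect")
    return np.clip(channel - blurred, 0.0, None)


def otsu_threshold(channel: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximising between-class variance.

    The intensity range is binned into ``n_bins`` equal-width bins and the
    returned value is the bin edge that maximises the between-class
    variance of the split; ties are broken toward the smallest qualifying
    threshold.  Foreground is defined downstream as pixels strictly
    greater than the returned threshold.

    Raises
    ------
    ConstantChannelError
        If the array has fewer than two distinct values.
    """
    values = np.asarray(channel, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty channel")
    if not np.all(np.isfinite(values)):
        raise ValueError("channel contains non-finite pixels")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ConstantChannelError("threshold undefined for a constant image")

    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])

    # Cumulative zeroth and first moments; split t puts bins 0..t in the
    # background class and t+1.. in the foreground class.
    w = np.cumsum(counts).astype(np.float64)
    m = np.cumsum(counts * centers)
    w0 = w[:-1]
    w1 = w[-1] - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (m[-1] - m[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    best = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximiser
    return float(edges[best + 1])


def _background_quantile_floor(
    residual: np.ndarray, otsu: float, quantile: float
) -> float:
    """Monomer floor: high quantile of intensities outside the Otsu foreground."""
    background = residual[residual <= otsu]
    if background.size == 0:
        return otsu
    return float(np.quantile(background, quantile))


def segment_channel(
    channel: np.ndarray,
    config,
    epitope: str = "",
    region_mask: np.ndarray | None = None,
) -> ChannelMask:
    """Segment one epitope channel into an aggregate foreground mask.

    Pipeline: :func:`subtract_background` with ``config.blur_sigma_px``,
    :func:`otsu_threshold` on the residual (restricted to ``region_mask``
    when given), raise the threshold to the monomer floor, binarise
    (strictly greater), and drop objects smaller than
    ``config.min_object_px`` (8-connected).

    A residual that is constant (e.g. a scene containing nothing but flat
    monomer background) yields an empty mask rather than an error.
    """
    residual = subtract_background(channel, config.blur_sigma_px)
    if region_mask is not None:
        region = np.asarray(region_mask, dtype=bool)
        if region.shape != residual.shape:
            raise ValueError("region_mask shape differs from channel")
        sample = residual[region]
    else:
        region = None
        sample = residual

    try:
        otsu = otsu_threshold(sample, n_bins=config.n_bins)
    except ConstantChannelError:
        empty = np.zeros(residual.shape, dtype=bool)
        return ChannelMask(epitope=epitope, mask=empty, otsu_threshold=float(sample.flat[0]),
                           floor_applied=float(sample.flat[0]))

    if config.monomer_floor_mode == "absolute":
        floor = float(config.monomer_floor_value)
    elif config.monomer_floor_mode == "quantile_of_background":
        floor = _background_quantile_floor(sample, otsu, config.monomer_floor_value)
    else:
        raise ValueError(f"unknown monomer_floor_mode {config.monomer_floor_mode!r}")

    threshold = max(otsu, floor)
    mask = residual > threshold
    if region is not None:
        mask &= region
    n_before = int(mask.sum())
    if config.min_object_px > 1 and mask.any():
        labels = _cc_label(mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= config.min_object_px
        keep[0] = False
        mask = keep[labels]
    n_removed_px = n_before - int(mask.sum())
    return ChannelMask(
        epitope=epitope,
        mask=mask,
        otsu_threshold=otsu,
        floor_applied=floor,
        n_speckle_px_removed=n_removed_px,
    )
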