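"""Quantification statistics for two-channel fluorescence images.

Three statistics, matching how Miro-client recruitment is scored in cells:

* **mitochondrial enrichment ratio** -- mean client-channel intensity over a
  thresholded mitochondrial-marker mask divided by the mean intensity over
  the rest of the cell; 1.0 means no enrichment.
* **punctum enrichment** -- integrated client density inside punctum masks
  (e.g. ER-mitochondria contact-site foci) divided by the integrated density
  of the whole cell; a fraction in [0, 1].
* **crop coefficient of variation** -- population SD / mean of the client
  channel over a small square crop (canonically 8 um^2), a heterogeneity
  readout for partial recruitment that does not need a mitochondrial mask
  in the client channel.

Masks always derive from a marker channel (or are supplied explicitly),
never from the client channel, to avoid circular thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

DEFAULT_CROP_AREA_UM2 = 8.0


@dataclass
class ImageChannel:
    """A single-channel image with physical pixel size in micrometres/pixel."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImageChannel expects a 2-D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/pixel)")


@dataclass
class RegionMask:
    mask: np.ndarray
    kind: str = "mitochondria"  # mitochondria | cell | punctum

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnrichmentResult:
    statistic: str
    value: float
    on_region: float
    off_region: Optional[float]
    n_on: int
    n_off: Optional[int]


def threshold_mask(marker: ImageChannel, method: str = "otsu",
                   manual_threshold: Optional[float] = None,
                   kind: str = "mitochondria") -> RegionMask:
    """Threshold a marker channel into a boolean region mask.

    ``method='otsu'`` (default) picks the threshold automatically and
    requires a non-constant image; ``method='manual'`` uses
    ``manual_threshold``.  Pixels strictly above the threshold are selected.
    """
    img = marker.pixels
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual thresholding requires manual_threshold")
        thr = float(manual_threshold)
    elif method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError(
                "constant image: automatic thresholding is undefined; "
                "supply method='manual' with manual_threshold")
        thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return RegionMask(img > thr, kind=kind)


def _check_shapes(channel: ImageChannel, *masks: RegionMask) -> None:
    for m in masks:
        if m.mask.shape != channel.pixels.shape:
            raise ValueError(f"mask shape {m.mask.shape} does not match image "
                             f"shape {channel.pixels.shape}")


def mito_enrichment_ratio(client: ImageChannel, mito_mask: RegionMask,
                          cell_mask: RegionMask) -> EnrichmentResult:
    """Mean client intensity on mitochondria / mean over the rest of the cell."""
    _check_shapes(client, mito_mask, cell_mask)
    if np.any(mito_mask.mask & ~cell_mask.mask):
        raise ValueError("mitochondrial mask must lie within the cell mask")
    if mito_mask.n_pixels == 0:
        raise ValueError("empty mitochondrial mask")
    off = cell_mask.mask & ~mito_mask.mask
    if not off.any():
        raise ValueError("empty off-mitochondria region; cannot form ratio")
    on_mean = float(client.pixels[mito_mask.mask].mean())
    off_mean = float(client.pixels[off].mean())
    if off_mean <= 0:
        raise ValueError("zero mean intensity outside mitochondria")
    return EnrichmentResult(
        statistic="mito_enrichment_ratio",
        value=on_mean / off_mean,
        on_region=on_mean, off_region=off_mean,
        n_on=mito_mask.n_pixels, n_off=int(off.sum()),
    )


def punctum_enrichment(signal: ImageChannel, punctum_mask: RegionMask,
                       cell_mask: RegionMask) -> EnrichmentResult:
    """Integrated density in puncta / integrated density of the whole cell."""
    _check_shapes(signal, punctum_mask, cell_mask)
    if np.any(punctum_mask.mask & ~cell_mask.mask):
        raise ValueError("punctum mask must lie within the cell mask")
    total = float(signal.pixels[cell_mask.mask].sum())
    if total <= 0:
        raise ValueError("zero whole-cell integrated density")
    on = float(signal.pixels[punctum_mask.mask].sum())
    return EnrichmentResult(
        statistic="punctum_enrichment",
        value=on / total,
        on_region=on, off_region=total - on,
        n_on=punctum_mask.n_pixels, n_off=int(cell_mask.n_pixels - punctum_mask.n_pixels),
    )


def crop_side_pixels(crop_area_um2: float, pixel_size: float) -> int:
    """Side of the square crop in pixels: floor(sqrt(area)/pixel_size), min 2."""
    return max(2, int(np.floor(np.sqrt(crop_area_um2) / pixel_size)))


def crop_cov_heterogeneity(client: ImageChannel, crop_center: tuple[int, int],
                           crop_area_um2: float = DEFAULT_CROP_AREA_UM2,
                           ) -> EnrichmentResult:
    """Coefficient of variation (population SD / mean) over a square crop.

    ``crop_center`` is (row, col) in pixels; the crop covers ``crop_area_um2``
    (8 um^2 canonically).  Scale-invariant: multiplying the image by k > 0
    leaves the value unchanged.
    """
    side = crop_side_pixels(crop_area_um2, client.pixel_size)
    r0 = crop_center[0] - side // 2
    c0 = crop_center[1] - side // 2
    r1, c1 = r0 + side, c0 + side
    h, w = client.pixels.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(f"{side}x{side} crop at {crop_center} does not fit "
                         f"inside image of shape {(h, w)}")
    crop = client.pixels[r0:r1, c0:c1]
    mean = float(crop.mean())
    if mean <= 0:
        raise ValueError("zero mean intensity in crop; CoV undefined")
    return EnrichmentResult(
        statistic="crop_cov",
        value=float(crop.std(ddof=0)) / mean,
        on_region=mean, off_region=None,
        n_on=crop.size, n_off=None,
    )


def read_tiff_channels(path: str | Path, pixel_size: Optional[float] = None,
                       ) -> list[ImageChannel]:
    """Read a multi-channel TIFF into ImageChannels.

    Pixel size is taken from the TIFF resolution tags when present (dots per
    micron convention) unless overridden.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        if pixel_size is None:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                if num > 0:
                    pixel_size = den / num  # resolution stored as pixels per unit
        if pixel_size is None:
            raise ValueError("pixel size not found in TIFF metadata; pass pixel_size")
    if arr.ndim == 2:
        arr = arr[None]
    return [ImageChannel(plane.astype(float), pixel_size) for plane in arr]
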