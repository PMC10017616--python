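"""HU-window segmentation of epicardial adipose tissue and per-series metrics.

EAT is defined operationally: every voxel inside the pericardial mask whose
attenuation lies in an inclusive Hounsfield-unit window (default
[−190, −30] HU; the contrast-enhanced CTA series additionally gets a widened
[−190, 0] HU variant). From the segmented voxel set we compute the paper
trio of metrics — volume in mL, mean attenuation, and noise (the SD of HU
values within the segmentation) — plus the 1-HU-bin attenuation histogram
used for inter-series distribution comparison.

Conventions (fixed, documented choices):

* Both window bounds are inclusive, which makes the integer bin count
  ``upper − lower + 1`` (161 for the default window).
* Histogram bin *b* is centered on the integer HU value *b* and covers
  ``[b − 0.5, b + 0.5)``; segmentation guarantees every selected voxel falls
  into a bin of the window.
* The noise SD uses the sample convention (n − 1 denominator) by default.
* An empty segmentation yields missing (NaN) metrics with a warning rather
  than an exception, mirroring a failed measurement on a workstation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import GridMismatchError, MaskGrid, VolumeGrid, grids_compatible

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HUWindow:
    """An inclusive integer attenuation window [lower, upper] in HU."""

    lower: int = -190
    upper: int = -30

    def __post_init__(self) -> None:
        if self.lower != int(self.lower) or self.upper != int(self.upper):
            raise ValueError("window bounds must be integers (1-HU bins are integer-centered)")
        object.__setattr__(self, "lower", int(self.lower))
        object.__setattr__(self, "upper", int(self.upper))
        if self.lower >= self.upper:
            raise ValueError(f"window lower bound {self.lower} must be < upper {self.upper}")

    @property
    def n_bins(self) -> int:
        """Number of 1-HU bins: upper − lower + 1 (161 for [−190, −30])."""
        return self.upper - self.lower + 1

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(self.lower, self.upper + 1)

    def __str__(self) -> str:
        return f"[{self.lower}, {self.upper}] HU"


#: Fat window used on all series.
DEFAULT_WINDOW = HUWindow(-190, -30)
#: Widened window applied to the contrast-enhanced CTA series (CTA_0).
WIDE_CTA_WINDOW = HUWindow(-190, 0)


@dataclass
class EATSegmentation:
    """Voxels inside the pericardial mask whose HU lies in the window."""

    flags: np.ndarray
    window: HUWindow
    voxel_volume_mm3: float
    series_label: str
    patient_id: str

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())


@dataclass
class EATMetrics:
    """Per-series summary: volume, mean attenuation, noise, voxel count."""

    patient_id: str
    series_label: str
    window: HUWindow
    volume_ml: float
    mean_hu: float
    noise_sd_hu: float
    voxel_count: int


@dataclass
class EATHistogram:
    """1-HU-bin attenuation histogram of a segmentation.

    ``counts[i]`` is the number of voxels in the bin centered on
    ``window.lower + i``; ``normalized`` divides by the total segmented voxel
    count so the frequencies sum to 1 for a nonempty segmentation.
    """

    window: HUWindow
    counts: np.ndarray
    patient_id: str = ""
    series_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.window.n_bins,):
            raise ValueError(
                f"expected {self.window.n_bins} bins for window {self.window}, "
                f"got {self.counts.shape}"
            )

    @property
    def n_bins(self) -> int:
        return self.window.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return self.window.bin_centers

    @property
    def total_voxels(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        total = self.total_voxels
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def segment_eat(volume: VolumeGrid, mask: MaskGrid, window: HUWindow = DEFAULT_WINDOW) -> EATSegmentation:
    """Select mask voxels with ``lower ≤ HU ≤ upper`` (both bounds inclusive)."""
    if not grids_compatible(volume.shape, volume.spacing, mask.shape, mask.spacing):
        raise GridMismatchError(
            f"volume grid {volume.shape}/{volume.spacing} does not match "
            f"mask grid {mask.shape}/{mask.spacing}"
        )
    if not mask.flags.any():
        raise ValueError("mask is empty")
    v = volume.values
    flags = mask.flags & (v >= window.lower) & (v <= window.upper)
    return EATSegmentation(
        flags=flags,
        window=window,
        voxel_volume_mm3=volume.voxel_volume_mm3,
        series_label=volume.series_label,
        patient_id=volume.patient_id,
    )


def eat_volume_ml(seg: EATSegmentation) -> float:
    """Segmented volume in mL: voxel count × voxel volume (mm³) / 1000."""
    return seg.voxel_count * seg.voxel_volume_mm3 / 1000.0


def eat_mean_hu(seg: EATSegmentation, volume: VolumeGrid) -> float:
    """Mean attenuation over the segmented voxels; NaN (with warning) if empty."""
    if seg.voxel_count == 0:
        warnings.warn("empty segmentation: mean attenuation is undefined", stacklevel=2)
        return float("nan")
    return float(volume.values[seg.flags].mean())


def eat_noise_hu(seg: EATSegmentation, volume: VolumeGrid, ddof: int = 1) -> float:
    """Noise = SD of HU values within the segmentation (sample SD by default)."""
    if seg.voxel_count < ddof + 1:
        warnings.warn("segmentation too small for an SD estimate", stacklevel=2)
        return float("nan")
    return float(volume.values[seg.flags].std(ddof=ddof))


def _bin_indices(values: np.ndarray, window: HUWindow) -> np.ndarray:
    # bin b covers [b − 0.5, b + 0.5); floor(v + 0.5) maps a value to its bin center
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(np.int64) - window.lower


def histogram_from_values(
    values: np.ndarray,
    window: HUWindow = DEFAULT_WINDOW,
    patient_id: str = "",
    series_label: str = "",
) -> EATHistogram:
    """Bin in-window HU values into 1-HU integer-centered bins.

    All values must already satisfy ``lower ≤ v ≤ upper``; use
    :func:`segment_eat` to enforce that on volumes.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < window.lower or values.max() > window.upper):
        raise ValueError(f"values outside window {window}")
    idx = _bin_indices(values, window)
    counts = np.bincount(idx, minlength=window.n_bins)
    return EATHistogram(window, counts, patient_id=patient_id, series_label=series_label)


def eat_histogram(seg: EATSegmentation, volume: VolumeGrid) -> EATHistogram:
    """1-HU-bin histogram of the segmented attenuation values."""
    return histogram_from_values(
        volume.values[seg.flags],
        seg.window,
        patient_id=seg.patient_id,
        series_label=seg.series_label,
    )


def quantify_series(
    volume: VolumeGrid, mask: MaskGrid, window: HUWindow = DEFAULT_WINDOW
) -> tuple[EATMetrics, EATHistogram]:
    """Segment one series and compute its metrics and histogram in one pass."""
    seg = segment_eat(volume, mask, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = EATMetrics(
            patient_id=volume.patient_id,
            series_label=volume.series_label,
            window=window,
            volume_ml=eat_volume_ml(seg),
            mean_hu=eat_mean_hu(seg, volume),
            noise_sd_hu=eat_noise_hu(seg, volume),
            voxel_count=seg.voxel_count,
        )
    if seg.voxel_count == 0:
        logger.warning(
            "empty EAT segmentation for patient %s series %s window %s",
            volume.patient_id, volume.series_label, window,
        )
    return metrics, eat_histogram(seg, volume)
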