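"""Seeded multi-series cardiac phantoms with exactly countable EAT ground truth.

The phantom is a nest of concentric spheres in physical (mm) space — blood
pool, myocardial shell, epicardial fat shell, pericardial sac — voxelized on
a regular grid (under anisotropic spacing the spheres become ellipsoids in
index space). The pericardial mask is the sac interior; the fat shell is the
ground-truth EAT, identical in location across all series of a patient, so
the true fat voxel count and volume are known exactly.

Per series, fat voxels draw i.i.d. from ``Normal(fat_mu + shift_delta,
sqrt(fat_sigma² + extra_noise_sigma²))``. The default series models are
*calibrated*: published EAT attenuation statistics are measured inside the
[−190, −30] HU window, i.e. they are moments of a truncated distribution,
so the generative (μ, σ) of each series is obtained by numerically inverting
the truncated-normal mean/SD to reproduce the measured in-window values
(TNC −81.1/32.5, VNC_Conv −75.4/31.0, VNC_PC −79.1/30.3, CTA −83.1/32.3 HU).
:func:`calibrate_fat_model` performs that inversion; the frozen constants
below are its output for the default window.

Non-fat tissues are constant plates far outside the fat window (blood,
myocardium, background), with iodine enhancement of the blood pool on the
CTA series; they exercise the mask/window logic without contributing to the
segmentation. Noise is i.i.d. Gaussian per voxel — no CT texture or
correlation model, since every downstream metric is a first-order histogram
statistic. Optional Gaussian smoothing emulates partial-volume blur and is
off by default so exact-recovery checks hold.

Randomness: one master seed; per-patient and per-series substreams derive
from ``numpy.random.SeedSequence(master, spawn_key=...)``, so changing the
seed changes voxel noise but never geometry or truth counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import (
    CohortManifest,
    MaskGrid,
    SERIES_LABELS,
    VolumeGrid,
    write_manifest,
    write_mask,
    write_volume,
)
from .quantify import DEFAULT_WINDOW, EATHistogram, HUWindow, histogram_from_values

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeriesModel:
    """Generative fat-attenuation model of one CT series.

    ``fat_mu`` is the base (TNC) mean; ``shift_delta`` the additive offset of
    this series relative to that base; ``fat_sigma`` the series' generative
    SD; ``extra_noise_sigma`` optional additional Gaussian noise.
    """

    series_label: str
    fat_mu: float
    fat_sigma: float
    shift_delta: float = 0.0
    extra_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.fat_sigma < 0 or self.extra_noise_sigma < 0:
            raise ValueError("fat_sigma and extra_noise_sigma must be >= 0")
        if self.series_label == "TNC" and self.shift_delta != 0.0:
            raise ValueError("the TNC base model must have shift_delta = 0")

    @property
    def mean(self) -> float:
        return self.fat_mu + self.shift_delta

    @property
    def total_sigma(self) -> float:
        return math.hypot(self.fat_sigma, self.extra_noise_sigma)


def truncated_normal_stats(mu: float, sigma: float,
                           window: HUWindow = DEFAULT_WINDOW) -> tuple[float, float]:
    """Closed-form mean and SD of Normal(mu, sigma) truncated to the window."""
    a = (window.lower - mu) / sigma
    b = (window.upper - mu) / sigma
    d = stats.truncnorm(a, b, loc=mu, scale=sigma)
    return float(d.mean()), float(d.std())


def calibrate_fat_model(inwindow_mean: float, inwindow_sd: float,
                        window: HUWindow = DEFAULT_WINDOW) -> tuple[float, float]:
    """Invert the window truncation: find (μ, σ) of the untruncated normal
    whose truncated mean/SD on the window equal the measured in-window values.
    """

    def residual(p):
        m, s = truncated_normal_stats(p[0], p[1], window)
        return [m - inwindow_mean, s - inwindow_sd]

    sol = optimize.fsolve(residual, [inwindow_mean, inwindow_sd + 5.0], xtol=1e-12,
                          full_output=True)
    p, _, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"calibration failed to converge: {msg}")
    return float(p[0]), float(p[1])


# Calibrated generative constants for the default window (see module docstring;
# targets: in-window mean/SD of −81.1/32.5, −75.4/31.0, −79.1/30.3, −83.1/32.3 HU).
_TNC_MU, _TNC_SIGMA = -65.9398, 43.4815
DEFAULT_SERIES_MODELS: tuple[SeriesModel, ...] = (
    SeriesModel("TNC", _TNC_MU, _TNC_SIGMA, 0.0),
    SeriesModel("VNC_Conv", _TNC_MU, 44.8121, shift_delta=12.7479),
    SeriesModel("VNC_PC", _TNC_MU, 38.6740, shift_delta=-1.8039),
    SeriesModel("CTA", _TNC_MU, 41.1964, shift_delta=-5.8013),
)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, tissue attenuations and series models of one phantom.

    Radii are in mm and must be strictly increasing
    (blood < myocardium < fat < sac); the fat shell between ``r_myocardium``
    and ``r_fat`` is the ground-truth EAT. Defaults give a fat shell of
    roughly 195 mL on an 84³ grid at 1.5 mm isotropic spacing.
    """

    shape: tuple[int, int, int] = (84, 84, 84)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    r_blood: float = 30.0
    r_myocardium: float = 40.0
    r_fat: float = 48.0
    r_sac: float = 52.0
    hu_blood: float = 45.0
    hu_blood_cta: float = 350.0
    hu_myocardium: float = 40.0
    hu_background: float = -500.0
    series_models: tuple[SeriesModel, ...] = DEFAULT_SERIES_MODELS
    smoothing_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        radii = (self.r_blood, self.r_myocardium, self.r_fat, self.r_sac)
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise ValueError(f"radii must be strictly increasing, got {radii}")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        labels = [m.series_label for m in self.series_models]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate series labels in series_models")

    def scaled(self, factor: float) -> "PhantomParams":
        """Params with all radii scaled by ``factor`` (volume scales by factor³)."""
        return replace(
            self,
            r_blood=self.r_blood * factor,
            r_myocardium=self.r_myocardium * factor,
            r_fat=self.r_fat * factor,
            r_sac=self.r_sac * factor,
        )


@dataclass
class PhantomTruth:
    """Exact ground truth of one generated phantom."""

    true_fat_voxel_count: int
    true_fat_volume_ml: float
    series_means: dict[str, float]
    series_shifts: dict[str, float]
    seed: int


def _radius_field(params: PhantomParams) -> np.ndarray:
    """Distance (mm) of each voxel center from the grid center."""
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * d
        for n, d in zip(params.shape, params.spacing)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    return np.sqrt(xx**2 + yy**2 + zz**2)


def phantom_tissue_masks(params: PhantomParams) -> dict[str, np.ndarray]:
    """Boolean tissue regions: blood, myocardium, fat, sac (interior), background."""
    r = _radius_field(params)
    blood = r <= params.r_blood
    myocardium = (r > params.r_blood) & (r <= params.r_myocardium)
    fat = (r > params.r_myocardium) & (r <= params.r_fat)
    sac = r <= params.r_sac
    return {"blood": blood, "myocardium": myocardium, "fat": fat,
            "sac": sac, "background": ~sac}


def _series_rng(seed: int, series_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(series_index,)))


def sample_fat_values(model: SeriesModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n fat-voxel attenuations from the series' generative normal."""
    return rng.normal(model.mean, model.total_sigma, size=n)


def generate_phantom(
    params: PhantomParams, seed: int, patient_id: str = "P000"
) -> tuple[dict[str, VolumeGrid], MaskGrid, PhantomTruth]:
    """Generate all series of one phantom patient plus mask and ground truth.

    All series share one grid and one fat-voxel set; per-series fat values
    draw from the series' own substream of ``seed``. Deterministic for fixed
    (params, seed).
    """
    tissues = phantom_tissue_masks(params)
    fat = tissues["fat"]
    n_fat = int(fat.sum())
    if n_fat == 0:
        raise ValueError("fat shell is empty on this grid; enlarge radii or grid")
    voxel_mm3 = float(np.prod(params.spacing))
    truth = PhantomTruth(
        true_fat_voxel_count=n_fat,
        true_fat_volume_ml=n_fat * voxel_mm3 / 1000.0,
        series_means={m.series_label: m.mean for m in params.series_models},
        series_shifts={m.series_label: m.shift_delta for m in params.series_models},
        seed=seed,
    )
    series: dict[str, VolumeGrid] = {}
    for idx, model in enumerate(params.series_models):
        rng = _series_rng(seed, idx)
        vol = np.full(params.shape, params.hu_background, dtype=np.float64)
        blood_hu = params.hu_blood_cta if model.series_label == "CTA" else params.hu_blood
        vol[tissues["blood"]] = blood_hu
        vol[tissues["myocardium"]] = params.hu_myocardium
        vol[fat] = sample_fat_values(model, n_fat, rng)
        if params.smoothing_fwhm_mm > 0:
            from scipy.ndimage import gaussian_filter

            sigma_vox = [
                params.smoothing_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / d
                for d in params.spacing
            ]
            vol = gaussian_filter(vol, sigma=sigma_vox)
        series[model.series_label] = VolumeGrid(
            vol, params.spacing, model.series_label, patient_id
        )
    mask = MaskGrid(tissues["sac"], params.spacing)
    return series, mask, truth


def apply_series_model(
    base: VolumeGrid,
    fat_mask: np.ndarray,
    model: SeriesModel,
    seed: int,
    blood_mask: np.ndarray | None = None,
    blood_hu: float | None = None,
) -> VolumeGrid:
    """Derive a series from a base volume: shift + noise on fat, blood rules.

    Fat voxels get ``shift_delta`` plus ``Normal(0, extra_noise_sigma)``
    noise; if a blood mask and target attenuation are given (iodine
    enhancement on CTA), blood voxels are set to that value. The input volume
    is not modified.
    """
    fat_mask = np.asarray(fat_mask, dtype=bool)
    if fat_mask.shape != base.shape:
        raise ValueError(f"fat mask shape {fat_mask.shape} does not match volume {base.shape}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = np.array(base.values, dtype=np.float64, copy=True)
    n_fat = int(fat_mask.sum())
    noise = rng.normal(0.0, model.extra_noise_sigma, size=n_fat) if model.extra_noise_sigma > 0 else 0.0
    values[fat_mask] = values[fat_mask] + model.shift_delta + noise
    if blood_mask is not None and blood_hu is not None:
        blood_mask = np.asarray(blood_mask, dtype=bool)
        if blood_mask.shape != base.shape:
            raise ValueError("blood mask shape does not match volume")
        values[blood_mask] = blood_hu
    return VolumeGrid(values, base.spacing, model.series_label, base.patient_id)


@dataclass
class CohortPatient:
    patient_id: str
    series: dict[str, VolumeGrid]
    mask: MaskGrid
    truth: PhantomTruth


def _patient_seed(master_seed: int, patient_index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(patient_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def iter_cohort(
    n_patients: int,
    seed: int,
    base_params: PhantomParams | None = None,
    volume_range_ml: tuple[float, float] = (100.0, 300.0),
):
    """Yield phantom patients one at a time (memory-friendly cohort generator).

    Per-patient target fat volumes are drawn uniformly inside
    ``volume_range_ml`` (slightly inset so voxelization cannot leave the
    range) and realised by scaling all radii by the cube root of the volume
    ratio. Per-patient seeds derive deterministically from the master seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params = base_params or PhantomParams()
    shell_mm3 = (4.0 / 3.0) * math.pi * (params.r_fat**3 - params.r_myocardium**3)
    base_volume_ml = shell_mm3 / 1000.0
    lo, hi = volume_range_ml
    if not 0 < lo < hi:
        raise ValueError(f"invalid volume range {volume_range_ml}")
    # 3% inset keeps voxelized counts inside the configured range
    inset = 0.03 * (hi - lo)
    vol_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC0, 0)))
    targets = vol_rng.uniform(lo + inset, hi - inset, size=n_patients)
    for i in range(n_patients):
        pid = f"P{i:03d}"
        factor = (targets[i] / base_volume_ml) ** (1.0 / 3.0)
        p_params = params.scaled(factor)
        p_seed = _patient_seed(seed, i)
        series, mask, truth = generate_phantom(p_params, p_seed, patient_id=pid)
        yield CohortPatient(pid, series, mask, truth)


def generate_cohort(
    n_patients: int,
    seed: int,
    out_dir: str | Path | None = None,
    base_params: PhantomParams | None = None,
    volume_range_ml: tuple[float, float] = (100.0, 300.0),
) -> tuple[list[CohortPatient], CohortManifest]:
    """Generate a phantom cohort, optionally writing it to disk.

    With ``out_dir`` set, writes one NIfTI volume per (patient, series), one
    mask per patient, ``manifest.csv`` and ``truth.json``; paths in the
    returned manifest point at the written files. Without ``out_dir`` the
    cohort is returned in memory and manifest paths are placeholders.
    """
    patients = list(
        iter_cohort(n_patients, seed, base_params=base_params,
                    volume_range_ml=volume_range_ml)
    )
    rows = []
    truth_records = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for pat in patients:
        if out is not None:
            mask_path = out / f"{pat.patient_id}_mask.nii.gz"
            write_mask(pat.mask, mask_path)
        else:
            mask_path = f"{pat.patient_id}_mask.nii.gz"
        for label, vol in pat.series.items():
            if out is not None:
                vol_path = out / f"{pat.patient_id}_{label}.nii.gz"
                write_volume(vol, vol_path)
            else:
                vol_path = f"{pat.patient_id}_{label}.nii.gz"
            rows.append(
                {"patient_id": pat.patient_id, "series_label": label,
                 "volume_path": str(vol_path), "mask_path": str(mask_path)}
            )
        truth_records[pat.patient_id] = {
            "true_fat_voxel_count": pat.truth.true_fat_voxel_count,
            "true_fat_volume_ml": pat.truth.true_fat_volume_ml,
            "series_means": pat.truth.series_means,
            "series_shifts": pat.truth.series_shifts,
            "seed": pat.truth.seed,
        }
    manifest = CohortManifest(pd.DataFrame(rows))
    if out is not None:
        write_manifest(manifest, out / "manifest.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump({"master_seed": seed, "patients": truth_records}, fh,
                      indent=2, sort_keys=True)
    return patients, manifest


def simulate_histogram_cohort(
    models: Sequence[SeriesModel],
    n_patients: int,
    n_voxels: int,
    rng: np.random.Generator,
    window: HUWindow = DEFAULT_WINDOW,
) -> dict[tuple[str, str], EATHistogram]:
    """Per-patient in-window histograms sampled directly from the series models.

    Skips the 3-D voxelization: each patient's fat attenuations draw straight
    from each series' generative normal, out-of-window values are discarded
    (exactly what segmentation does), and the remainder is binned. Useful for
    distance experiments where only the HU distribution matters.
    """
    cohort: dict[tuple[str, str], EATHistogram] = {}
    for i in range(n_patients):
        pid = f"P{i:03d}"
        for model in models:
            vals = sample_fat_values(model, n_voxels, rng)
            vals = vals[(vals >= window.lower) & (vals <= window.upper)]
            cohort[(pid, model.series_label)] = histogram_from_values(
                vals, window, patient_id=pid, series_label=model.series_label)
    return cohort


def simulate_volume_pairs(
    n_patients: int,
    rng: np.random.Generator,
    scale: float = 0.97,
    noise_cv: float = 0.02,
    volume_range_ml: tuple[float, float] = (100.0, 300.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Lightweight paired-volume cohort: reference volumes uniform in range,
    comparator = scale · reference · (1 + Normal(0, noise_cv)).

    Used for statistical-recovery and calibration experiments where the full
    3-D phantom would only add runtime, not information.
    """
    x = rng.uniform(*volume_range_ml, size=n_patients)
    y = scale * x * (1.0 + rng.normal(0.0, noise_cv, size=n_patients))
    return x, y
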