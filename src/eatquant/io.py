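"""Reading and writing volumes, masks, cohort manifests, and result tables.

Volumes and masks travel as NIfTI-1 files (``.nii``/``.nii.gz``); grid
geometry (voxel spacing in mm) comes from the file header. A cohort manifest
maps patients to their per-series volume files and a single pericardial mask,
either as a CSV with header ``patient_id,series_label,volume_path,mask_path``
or an equivalent JSON array of row objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised CT series labels. TNC is the true non-contrast reference;
#: VNC_Conv / VNC_PC are the conventional and calcium-preserving virtual
#: non-contrast reconstructions; CTA is the contrast-enhanced angiography.
SERIES_LABELS = ("TNC", "VNC_Conv", "VNC_PC", "CTA")

#: Per-axis tolerance (mm) when checking that two grids share a spacing.
SPACING_TOL_MM = 1e-3

MANIFEST_COLUMNS = ["patient_id", "series_label", "volume_path", "mask_path"]


class VolumeLoadError(ValueError):
    """A volume or mask file could not be loaded or failed validation."""


class GridMismatchError(ValueError):
    """Two grids that must coincide differ in shape or spacing."""


class ManifestError(ValueError):
    """A cohort manifest is malformed or inconsistent."""


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three strictly positive values, got {spacing}")
    return spacing


def grids_compatible(
    shape_a: tuple[int, ...],
    spacing_a: tuple[float, float, float],
    shape_b: tuple[int, ...],
    spacing_b: tuple[float, float, float],
    tol_mm: float = SPACING_TOL_MM,
) -> bool:
    """True if two grids share a shape and a spacing within ``tol_mm`` per axis.

    The check is symmetric in its two arguments.
    """
    if tuple(shape_a) != tuple(shape_b):
        return False
    return all(abs(a - b) <= tol_mm for a, b in zip(spacing_a, spacing_b))


@dataclass
class VolumeGrid:
    """A 3-D scalar field of CT attenuation values (HU) on a regular grid.

    Parameters
    ----------
    values
        3-D array of attenuation in Hounsfield units.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all strictly positive.
    series_label
        One of :data:`SERIES_LABELS`.
    patient_id
        Identifier of the patient the series belongs to.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    series_label: str
    patient_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.values.ndim}-D")
        self.spacing = _check_spacing(self.spacing)
        if self.series_label not in SERIES_LABELS:
            raise ValueError(
                f"unknown series label {self.series_label!r}; allowed: {SERIES_LABELS}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains NaN or Inf voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class MaskGrid:
    """A 3-D boolean field marking the pericardial interior."""

    flags: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {self.flags.ndim}-D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise VolumeLoadError(f"expected 3-D volume in {path}, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path: str | Path, series_label: str, patient_id: str) -> VolumeGrid:
    """Load a NIfTI attenuation volume.

    Values are taken as stored (nibabel applies the format's scale/intercept;
    no further rescaling). NaN/Inf voxels make the load fail.
    """
    data, spacing = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise VolumeLoadError(f"volume {path} contains NaN or Inf voxels")
    return VolumeGrid(data, spacing, series_label, patient_id)


def write_volume(volume: VolumeGrid, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine built from the spacing."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, reference: VolumeGrid) -> MaskGrid:
    """Load a pericardial mask and validate it against a reference volume's grid.

    Any nonzero voxel counts as "inside the pericardium" (tolerant of label
    maps). The mask must match the reference shape exactly and the spacing
    within :data:`SPACING_TOL_MM` per axis, and must contain at least one
    true voxel.
    """
    data, spacing = _load_nifti(path)
    if not grids_compatible(data.shape, spacing, reference.shape, reference.spacing):
        raise GridMismatchError(
            f"mask {path} grid {data.shape}/{spacing} does not match reference "
            f"{reference.shape}/{reference.spacing}"
        )
    flags = data != 0
    if not flags.any():
        raise VolumeLoadError(f"mask {path} is empty (no nonzero voxels)")
    return MaskGrid(flags, spacing)


def write_mask(mask: MaskGrid, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.flags.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


@dataclass
class CohortManifest:
    """Validated mapping of patients to series volume files and mask files.

    ``rows`` is a DataFrame with columns ``patient_id, series_label,
    volume_path, mask_path`` — one row per (patient, series).
    """

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows).copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        df = df[MANIFEST_COLUMNS].astype(str)
        bad = sorted(set(df["series_label"]) - set(SERIES_LABELS))
        if bad:
            raise ManifestError(
                f"unknown series labels {bad}; allowed labels: {list(SERIES_LABELS)}"
            )
        dup = df.duplicated(subset=["patient_id", "series_label"])
        if dup.any():
            pairs = df.loc[dup, ["patient_id", "series_label"]].values.tolist()
            raise ManifestError(f"duplicate (patient, series) rows: {pairs}")
        for pid, grp in df.groupby("patient_id"):
            if grp["mask_path"].nunique() != 1:
                raise ManifestError(f"patient {pid} has more than one mask path")
            if len(grp) < 2:
                raise ManifestError(f"patient {pid} has fewer than 2 series")
        self.rows = df.sort_values(["patient_id", "series_label"]).reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.rows["patient_id"].unique())

    def series_for(self, patient_id: str) -> pd.DataFrame:
        return self.rows[self.rows["patient_id"] == patient_id]

    def mask_path_for(self, patient_id: str) -> str:
        return self.series_for(patient_id)["mask_path"].iloc[0]


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest from CSV or JSON (chosen by file suffix)."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype=str)
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(manifest.rows.to_dict(orient="records"), indent=2))
    else:
        manifest.rows.to_csv(path, index=False)
    return path


def write_results(
    out_dir: str | Path,
    per_patient_metrics: pd.DataFrame,
    comparisons: pd.DataFrame,
    histograms: pd.DataFrame,
    run_info: Mapping | None = None,
) -> dict[str, Path]:
    """Write the standard output bundle of a run.

    Produces ``metrics.csv`` (per patient × series × window), ``comparisons.csv``
    (pairwise agreement statistics), ``histograms.csv`` (one row per
    patient × series of normalized 1-HU-bin frequencies) and
    ``run_summary.json`` (config echo, seed, version). Raises before writing
    anything if the metrics table is empty, so a failed run leaves no partial
    bundle.
    """
    out_dir = Path(out_dir)
    if per_patient_metrics is None or len(per_patient_metrics) == 0:
        raise ValueError("refusing to write results for an empty cohort")
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    paths = {
        "metrics": out_dir / "metrics.csv",
        "comparisons": out_dir / "comparisons.csv",
        "histograms": out_dir / "histograms.csv",
        "summary": out_dir / "run_summary.json",
    }
    per_patient_metrics.to_csv(paths["metrics"], index=False)
    comparisons.to_csv(paths["comparisons"], index=False)
    histograms.to_csv(paths["histograms"], index=False)
    summary = {"version": __version__}
    if run_info:
        summary.update({k: v for k, v in run_info.items()})
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return paths
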