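"""Orchestration: simulate → quantify → compare as reproducible runs.

Measurement *variants* extend the series labels with the window used: the
TNC, VNC_Conv and VNC_PC series are measured with the fat window
[−190, −30] HU only, while the contrast-enhanced CTA series is measured
twice — ``CTA_-30`` (same window) and ``CTA_0`` (widened upper bound 0 HU,
probing the underestimation of fat attenuation under iodine). Volume
agreement is reported for all variant pairs; attenuation, noise and
histogram-distance comparisons are restricted to the four equal-window
variants, so ``CTA_0`` never enters a histogram distance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import agreement as agr
from .histograms import HistogramDistanceTable, distance_table
from .io import (
    CohortManifest,
    GridMismatchError,
    VolumeGrid,
    read_manifest,
    read_mask,
    read_volume,
    write_results,
)
from .phantom import CohortPatient, PhantomParams, generate_cohort, iter_cohort
from .quantify import (
    DEFAULT_WINDOW,
    EATHistogram,
    HUWindow,
    WIDE_CTA_WINDOW,
    quantify_series,
)

logger = logging.getLogger(__name__)

#: Canonical ordering of measurement variants in reports.
VARIANT_ORDER = ("TNC", "VNC_Conv", "VNC_PC", "CTA_-30", "CTA_0")
#: Variants measured with the common fat window (histogram-comparable).
EQUAL_WINDOW_VARIANTS = ("TNC", "VNC_Conv", "VNC_PC", "CTA_-30")


def variant_label(series_label: str, window: HUWindow) -> str:
    """Report label of a (series, window) measurement."""
    if series_label == "CTA":
        return f"CTA_{window.upper}"
    return series_label


def windows_for_series(series_label: str) -> list[HUWindow]:
    """Default measurement windows: fat window everywhere, plus CTA_0 on CTA."""
    if series_label == "CTA":
        return [DEFAULT_WINDOW, WIDE_CTA_WINDOW]
    return [DEFAULT_WINDOW]


@dataclass
class QuantifyResult:
    """Per-patient metric rows plus per-(patient, variant) histograms."""

    metrics: pd.DataFrame
    histograms: dict[tuple[str, str], EATHistogram]
    failures: list[dict] = field(default_factory=list)


METRIC_COLUMNS = [
    "patient_id", "series_label", "variant", "window_lower", "window_upper",
    "volume_ml", "mean_hu", "noise_sd_hu", "voxel_count",
]


def _quantify_patient(
    series: Mapping[str, VolumeGrid], mask, rows: list, histograms: dict
) -> None:
    for label in sorted(series):
        vol = series[label]
        for window in windows_for_series(label):
            metrics, hist = quantify_series(vol, mask, window)
            variant = variant_label(label, window)
            rows.append(
                {"patient_id": vol.patient_id, "series_label": label,
                 "variant": variant, "window_lower": window.lower,
                 "window_upper": window.upper, "volume_ml": metrics.volume_ml,
                 "mean_hu": metrics.mean_hu, "noise_sd_hu": metrics.noise_sd_hu,
                 "voxel_count": metrics.voxel_count}
            )
            histograms[(vol.patient_id, variant)] = hist


def quantify_cohort(patients: Iterable[CohortPatient]) -> QuantifyResult:
    """Quantify an in-memory phantom cohort."""
    rows: list = []
    histograms: dict = {}
    for pat in patients:
        _quantify_patient(pat.series, pat.mask, rows, histograms)
    return QuantifyResult(pd.DataFrame(rows, columns=METRIC_COLUMNS), histograms)


def quantify_manifest(manifest: CohortManifest) -> QuantifyResult:
    """Quantify a cohort from disk, continuing past per-patient failures.

    A patient whose files cannot be read or whose grids mismatch is recorded
    in ``failures`` and skipped; the run fails only if every patient fails.
    """
    rows: list = []
    histograms: dict = {}
    failures: list[dict] = []
    for pid in manifest.patient_ids:
        try:
            entries = manifest.series_for(pid)
            series: dict[str, VolumeGrid] = {}
            reference_vol = None
            for _, row in entries.iterrows():
                vol = read_volume(row["volume_path"], row["series_label"], pid)
                series[row["series_label"]] = vol
                reference_vol = reference_vol or vol
            mask = read_mask(manifest.mask_path_for(pid), reference_vol)
            _quantify_patient(series, mask, rows, histograms)
            logger.info("quantified patient %s (%d series)", pid, len(series))
        except (OSError, ValueError, GridMismatchError) as exc:
            logger.warning("patient %s failed: %s", pid, exc)
            failures.append({"patient_id": pid, "error": str(exc)})
    if not rows:
        raise RuntimeError("all patients failed to quantify")
    return QuantifyResult(pd.DataFrame(rows, columns=METRIC_COLUMNS), histograms, failures)


@dataclass
class CompareResult:
    comparisons: pd.DataFrame
    distances: HistogramDistanceTable | None
    reports: list[agr.AgreementReport] = field(default_factory=list, repr=False)


def _paired_sample(metrics: pd.DataFrame, metric: str,
                   ref: str, comp: str) -> agr.PairedSample | None:
    wide = metrics.pivot_table(index="patient_id", columns="variant",
                               values=metric, aggfunc="first")
    if ref not in wide.columns or comp not in wide.columns:
        return None
    try:
        return agr.PairedSample(
            patient_ids=wide.index.to_numpy(), x=wide[ref].to_numpy(),
            y=wide[comp].to_numpy(), metric=metric,
            reference_label=ref, comparator_label=comp,
        )
    except ValueError as exc:
        logger.warning("%s %s vs %s: %s", metric, comp, ref, exc)
        return None


def _report_row(report: agr.AgreementReport) -> dict:
    reg = report.regression
    return {
        "metric": report.metric,
        "reference": report.reference_label,
        "comparator": report.comparator_label,
        "n": report.n,
        "mean_diff": report.differences.mean_diff,
        "median_diff": report.differences.median_diff,
        "pct_diff_primary": report.differences.pct_diff_primary,
        "pct_diff_ratio_of_means": report.differences.pct_diff_ratio_of_means,
        "slope": reg.slope if reg else float("nan"),
        "intercept": reg.intercept if reg else float("nan"),
        "r2": reg.r2 if reg else float("nan"),
        "shapiro_p": report.shapiro_p,
        "test": report.test.test,
        "p_raw": report.test.p,
        "p_adjusted": report.p_adjusted,
    }


def compare_cohort(
    quantified: QuantifyResult,
    reference_label: str = "TNC",
    alpha: float = 0.05,
) -> CompareResult:
    """Run all pairwise agreement analyses on a quantified cohort.

    Volume: every variant pair (reference = earlier variant in the canonical
    order). Mean attenuation and noise: pairs among the equal-window
    variants. Histogram distances: each equal-window comparator vs the
    reference. Bonferroni family size m = number of comparisons within each
    metric's table.
    """
    metrics = quantified.metrics
    present = [v for v in VARIANT_ORDER if v in set(metrics["variant"])]
    if reference_label not in present:
        raise ValueError(f"reference series {reference_label!r} absent from cohort")
    equal_window = [v for v in present if v in EQUAL_WINDOW_VARIANTS]

    plan = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            plan.append(("volume_ml", a, b))
    for i, a in enumerate(equal_window):
        for b in equal_window[i + 1:]:
            plan.append(("mean_hu", a, b))
            plan.append(("noise_sd_hu", a, b))

    reports: list[agr.AgreementReport] = []
    for metric, ref, comp in plan:
        sample = _paired_sample(metrics, metric, ref, comp)
        if sample is not None:
            reports.append(agr.compare_pair(sample, alpha=alpha))

    # Bonferroni within each metric family
    rows = []
    for metric in ("volume_ml", "mean_hu", "noise_sd_hu"):
        family = [r for r in reports if r.metric == metric]
        if not family:
            continue
        adjusted = agr.adjust_bonferroni([r.test.p for r in family], m=len(family))
        for rep, p_adj in zip(family, adjusted):
            rep.p_adjusted = float(p_adj)
            rows.append(_report_row(rep))
    comparisons = pd.DataFrame(rows)

    hist_equal = {
        (pid, var): h for (pid, var), h in quantified.histograms.items()
        if var in equal_window
    }
    distances = None
    if len(equal_window) >= 2 and reference_label in equal_window:
        distances = distance_table(hist_equal, reference_label=reference_label)
    return CompareResult(comparisons, distances, reports)


def histograms_frame(
    histograms: Mapping[tuple[str, str], EATHistogram]
) -> pd.DataFrame:
    """Long-to-wide table: one row per (patient, variant), one column per bin.

    Bin columns span the union of windows present; rows measured with a
    narrower window carry NaN in bins outside it.
    """
    if not histograms:
        return pd.DataFrame()
    lowers = [h.window.lower for h in histograms.values()]
    uppers = [h.window.upper for h in histograms.values()]
    centers = np.arange(min(lowers), max(uppers) + 1)
    rows = []
    for (pid, var), h in sorted(histograms.items()):
        row: dict = {"patient_id": pid, "variant": var,
                     "window_lower": h.window.lower, "window_upper": h.window.upper}
        freq = dict(zip(h.bin_centers, h.normalized))
        for c in centers:
            row[f"hu_{c}"] = freq.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Everything one end-to-end phantom study produces."""

    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    distances: HistogramDistanceTable | None
    truths: dict[str, float]
    out_paths: dict | None = None


def run_study(
    n_patients: int,
    seed: int,
    base_params: PhantomParams | None = None,
    volume_range_ml: tuple[float, float] = (100.0, 300.0),
    reference_label: str = "TNC",
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Simulate, quantify, and compare a phantom cohort end to end (in memory).

    Patients are generated and quantified one at a time, so the full cohort
    of volumes never resides in memory at once. With ``out_dir`` set, the
    standard result bundle is written there.
    """
    rows: list = []
    histograms: dict = {}
    truths: dict[str, float] = {}
    for pat in iter_cohort(n_patients, seed, base_params=base_params,
                           volume_range_ml=volume_range_ml):
        _quantify_patient(pat.series, pat.mask, rows, histograms)
        truths[pat.patient_id] = pat.truth.true_fat_volume_ml
    quantified = QuantifyResult(pd.DataFrame(rows, columns=METRIC_COLUMNS), histograms)
    compared = compare_cohort(quantified, reference_label=reference_label, alpha=alpha)
    out_paths = None
    if out_dir is not None:
        out_paths = write_results(
            out_dir,
            quantified.metrics,
            compared.comparisons,
            histograms_frame(histograms),
            run_info={"n_patients": n_patients, "seed": seed,
                      "volume_range_ml": list(volume_range_ml),
                      "reference": reference_label, "alpha": alpha},
        )
        if compared.distances is not None:
            compared.distances.per_patient.to_csv(
                Path(out_dir) / "distances.csv", index=False)
            compared.distances.summary.to_csv(
                Path(out_dir) / "distances_summary.csv", index=False)
    return StudyResult(quantified.metrics, compared.comparisons,
                       compared.distances, truths, out_paths)


@dataclass
class RunConfig:
    """Configuration of a pipeline run, loadable from YAML or JSON."""

    mode: str = "study"              # simulate | quantify | compare | study
    n_patients: int = 42
    seed: int = 0
    manifest: str | None = None
    out_dir: str = "eatquant_out"
    reference: str = "TNC"
    alpha: float = 0.05
    volume_range_ml: tuple[float, float] = (100.0, 300.0)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "volume_range_ml" in raw:
            raw["volume_range_ml"] = tuple(raw["volume_range_ml"])
        return cls(**raw)
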