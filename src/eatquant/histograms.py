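"""Comparison of normalized attenuation histograms across CT series.

The distribution of attenuation values within the EAT segmentation is
summarised per patient and series as a voxel-count-normalized 1-HU-bin
histogram; two series are compared with the Euclidean distance

    ‖q − p‖₂ = √( Σᵢ (qᵢ − pᵢ)² )

over their common bin grid. Only histograms built with the same window enter
a comparison (the widened CTA_0 window is excluded by construction: its bin
grid differs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import EATHistogram

logger = logging.getLogger(__name__)


def _as_normalized(h) -> np.ndarray:
    if isinstance(h, EATHistogram):
        return h.normalized
    return np.asarray(h, dtype=float)


def _check_common_grid(q, p) -> None:
    if isinstance(q, EATHistogram) and isinstance(p, EATHistogram):
        if q.window != p.window:
            raise ValueError(
                f"histogram bin grids differ ({q.window} vs {p.window}); only "
                "series with equal windows are comparable"
            )
    qa, pa = _as_normalized(q), _as_normalized(p)
    if qa.shape != pa.shape:
        raise ValueError(f"histogram bin grids differ: {qa.shape} vs {pa.shape}")


def euclidean_distance(q, p) -> float:
    """Euclidean distance between two normalized histograms on one bin grid.

    Accepts :class:`~eatquant.quantify.EATHistogram` objects (normalized
    internally) or plain frequency arrays. For normalized histograms the
    distance lies in [0, √2], the upper bound attained by disjoint supports.
    """
    _check_common_grid(q, p)
    return float(np.linalg.norm(_as_normalized(q) - _as_normalized(p)))


def average_histograms(histograms: Sequence) -> np.ndarray:
    """Per-bin arithmetic mean of normalized histograms (cohort-average curve)."""
    if len(histograms) == 0:
        raise ValueError("cannot average an empty list of histograms")
    first = histograms[0]
    for h in histograms[1:]:
        _check_common_grid(first, h)
    stack = np.stack([_as_normalized(h) for h in histograms])
    return stack.mean(axis=0)


@dataclass
class HistogramDistanceTable:
    """Per-patient Euclidean distances to the reference series, plus summaries.

    ``per_patient`` has columns ``patient_id, comparator, distance``;
    ``summary`` has ``comparator, mean_distance, sd_distance, n_patients``.
    """

    per_patient: pd.DataFrame
    summary: pd.DataFrame
    reference_label: str


def distance_table(
    histograms: Mapping[tuple[str, str], EATHistogram],
    reference_label: str = "TNC",
) -> HistogramDistanceTable:
    """Compute per-patient distances of every comparator series to the reference.

    ``histograms`` maps ``(patient_id, series_label)`` to the patient's
    histogram for that series; all histograms must share one bin grid.
    Distances are computed patient-wise and then summarised as mean ± SD per
    comparator. Patients missing either the reference or the comparator are
    excluded pairwise (with a logged count).
    """
    patients = sorted({pid for pid, _ in histograms})
    comparators = sorted({s for _, s in histograms if s != reference_label})
    rows = []
    for comp in comparators:
        n_excluded = 0
        for pid in patients:
            ref = histograms.get((pid, reference_label))
            other = histograms.get((pid, comp))
            if ref is None or other is None:
                n_excluded += 1
                continue
            rows.append(
                {"patient_id": pid, "comparator": comp,
                 "distance": euclidean_distance(other, ref)}
            )
        if n_excluded:
            logger.warning(
                "distance %s vs %s: %d patient(s) excluded for missing series",
                comp, reference_label, n_excluded,
            )
    per_patient = pd.DataFrame(rows, columns=["patient_id", "comparator", "distance"])
    summaries = []
    for comp in comparators:
        d = per_patient.loc[per_patient["comparator"] == comp, "distance"]
        if len(d) == 0:
            raise ValueError(
                f"no overlapping patients for pair ({comp}, {reference_label})"
            )
        summaries.append(
            {"comparator": comp,
             "mean_distance": float(d.mean()),
             "sd_distance": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
             "n_patients": int(len(d))}
        )
    summary = pd.DataFrame(
        summaries, columns=["comparator", "mean_distance", "sd_distance", "n_patients"]
    )
    return HistogramDistanceTable(per_patient, summary, reference_label)
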