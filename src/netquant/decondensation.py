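"""Nuclear-decondensation classification of NETotic events.

Early NETosis unpacks chromatin: the nucleus enlarges while its per-pixel
stain intensity falls. Thresholds are calibrated from control nuclei as
control mean + k x SD (area) and control mean - k x SD (intensity), k = 2 by
default — the conventional two-sigma control band of plate screening. A
nucleus is called NETotic only when it is *simultaneously* larger than the
area threshold and dimmer than the intensity threshold (strict inequalities;
the boundary is non-NETotic). Per-well aggregation yields the percentage of
NET-forming events; per-(condition, timepoint) aggregation yields the
time-course with SEM across replicate wells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nucleus_segmentation import NucleusRecord

__all__ = [
    "ThresholdSet",
    "WellSummary",
    "CalibrationError",
    "calibrate",
    "classify_netotic",
    "well_decondensation_summary",
    "timecourse",
    "retained",
]

_METHODS = ("unstim_calibrated", "pma_calibrated")


class CalibrationError(ValueError):
    """Raised when too few control nuclei are available to set thresholds."""


@dataclass
class ThresholdSet:
    """Calibrated area/intensity cutoffs plus provenance."""

    area_threshold: float
    intensity_threshold: float
    method: str
    k_area: float
    k_intensity: float
    source_wells: list[str]
    n_control_nuclei: int


@dataclass
class WellSummary:
    """Per-well decondensation aggregates over retained (non-excluded) nuclei."""

    n_nuclei: int
    n_netotic: int
    pct_netotic: float | None
    mean_area: float | None
    mean_intensity: float | None
    n_apoptotic: int = 0
    apoptotic_fraction: float = 0.0
    flagged_empty: bool = False


def retained(records: list[NucleusRecord]) -> list[NucleusRecord]:
    """Nuclei eligible for NETotic statistics: not apoptotic, not on border."""
    return [r for r in records if not r.apoptotic_flag and not r.on_border]


def calibrate(
    control_nuclei: list[NucleusRecord],
    method: str = "unstim_calibrated",
    k_area: float = 2.0,
    k_intensity: float = 2.0,
    min_control_nuclei: int = 50,
    source_wells: list[str] | None = None,
) -> ThresholdSet:
    """Derive area/intensity thresholds from a control nucleus population.

    area_threshold = mean(areas) + k_area x SD(areas);
    intensity_threshold = mean(intensities) - k_intensity x SD(intensities).
    ``method`` records which control population was imaged (unstimulated
    untreated neutrophils for induction screens, PMA-stimulated untreated for
    inhibition screens). Apoptotic/border nuclei are dropped before fitting.
    A zero-SD (degenerate) population falls back to mean +/- 1 unit with a
    warning; fewer than ``min_control_nuclei`` nuclei raise.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown calibration method {method!r}; expected {_METHODS}")
    if k_area <= 0 or k_intensity <= 0:
        raise ValueError("k_area and k_intensity must be positive")
    nuclei = retained(control_nuclei)
    if len(nuclei) < min_control_nuclei:
        raise CalibrationError(
            f"calibration needs >= {min_control_nuclei} control nuclei, got {len(nuclei)}"
        )
    areas = np.array([r.area for r in nuclei], dtype=float)
    intens = np.array([r.mean_intensity for r in nuclei], dtype=float)
    sd_area = float(areas.std(ddof=1))
    sd_int = float(intens.std(ddof=1))
    if sd_area == 0.0:
        warnings.warn("zero SD in control areas; using mean + 1 px", stacklevel=2)
        area_thr = float(areas.mean()) + 1.0
    else:
        area_thr = float(areas.mean() + k_area * sd_area)
    if sd_int == 0.0:
        warnings.warn("zero SD in control intensities; using mean - 1 unit", stacklevel=2)
        int_thr = float(intens.mean()) - 1.0
    else:
        int_thr = float(intens.mean() - k_intensity * sd_int)
    return ThresholdSet(
        area_threshold=area_thr,
        intensity_threshold=int_thr,
        method=method,
        k_area=k_area,
        k_intensity=k_intensity,
        source_wells=list(source_wells or []),
        n_control_nuclei=len(nuclei),
    )


def classify_netotic(
    nuclei: list[NucleusRecord], thresholds: ThresholdSet
) -> list[NucleusRecord]:
    """Set the NETotic call: enlarged AND dimmed, both strictly."""
    return [
        replace(
            r,
            netotic=(r.area > thresholds.area_threshold)
            and (r.mean_intensity < thresholds.intensity_threshold),
        )
        for r in nuclei
    ]


def well_decondensation_summary(
    nuclei: list[NucleusRecord], thresholds: ThresholdSet
) -> WellSummary:
    """Aggregate one well: classify retained nuclei, report %NETotic.

    Apoptotic and border nuclei are excluded from the NETotic statistics but
    counted into ``apoptotic_fraction`` (flagged / all detected), which the
    screening layer uses to reject apoptosis-confounded compounds. A well
    with zero retained nuclei returns pct_netotic None and is flagged.
    """
    n_all = len(nuclei)
    n_apo = sum(1 for r in nuclei if r.apoptotic_flag)
    kept = classify_netotic(retained(nuclei), thresholds)
    if not kept:
        return WellSummary(
            n_nuclei=0, n_netotic=0, pct_netotic=None, mean_area=None,
            mean_intensity=None, n_apoptotic=n_apo,
            apoptotic_fraction=(n_apo / n_all) if n_all else 0.0,
            flagged_empty=True,
        )
    n_net = sum(1 for r in kept if r.netotic)
    return WellSummary(
        n_nuclei=len(kept),
        n_netotic=n_net,
        pct_netotic=100.0 * n_net / len(kept),
        mean_area=float(np.mean([r.area for r in kept])),
        mean_intensity=float(np.mean([r.mean_intensity for r in kept])),
        n_apoptotic=n_apo,
        apoptotic_fraction=(n_apo / n_all) if n_all else 0.0,
    )


def timecourse(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM trajectories per (condition, timepoint) across wells.

    ``summaries`` needs columns condition, timepoint_min, pct_netotic,
    mean_area, mean_intensity (one row per well; None pct rows are dropped).
    SEM is across replicate wells and is NaN for singleton cells. Missing
    (condition, timepoint) combinations are simply absent rows.
    """
    required = {"condition", "timepoint_min", "pct_netotic", "mean_area", "mean_intensity"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    df = summaries.dropna(subset=["pct_netotic"])
    rows = []
    for (cond, tp), grp in df.groupby(["condition", "timepoint_min"], sort=True):
        n = len(grp)
        row = {"condition": cond, "timepoint_min": tp, "n_wells": n}
        for col in ("pct_netotic", "mean_area", "mean_intensity"):
            vals = grp[col].astype(float)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sem"] = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
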