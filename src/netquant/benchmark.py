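"""Reference reproduction panels.

Self-contained routines that regenerate the package's headline numbers from
scratch: the unstimulated/PMA time-course morphometry (control nuclear-area
band, stimulated enlargement, intensity gaps, %NET-forming events) and the
56-compound screening funnel. They exist so the same computation backs both
the test suite (at reduced panel sizes) and the reproduction script.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
so panels are reproducible and wells are independently seeded.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .decondensation import calibrate, well_decondensation_summary
from .nucleus_segmentation import SegmentationParams, flag_apoptotic, segment_nuclei
from .pipeline import run_all
from .synth_fields import preset

__all__ = ["simulate_well_records", "timecourse_panel", "screen_panel"]

UNSTIM_TIMEPOINTS = (0, 60, 120, 180, 240)
PAIRED_TIMEPOINTS = (60, 120, 180)


def simulate_well_records(
    preset_name: str,
    seed: int,
    fields_per_well: int = 4,
    n_cells: int = 80,
    shape: tuple[int, int] = (640, 640),
    seg_params: SegmentationParams | None = None,
) -> list:
    """Generate one well of fields and return its pooled nucleus records."""
    from .synth_fields import generate_field

    seg_params = seg_params or SegmentationParams()
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 7])
    records = []
    for child in ss.spawn(fields_per_well):
        params = preset(preset_name, n_cells=n_cells)
        field, _ = generate_field(params, shape=shape,
                                  seed=int(child.generate_state(1)[0] & 0x7FFFFFFF))
        labels, recs = segment_nuclei(field, seg_params)
        recs = flag_apoptotic(labels, field, seg_params, recs)
        records.extend(recs)
    return records


def timecourse_panel(
    seed: int = 1,
    wells_per_point: int = 4,
    wells_240: int = 8,
    fields_per_well: int = 4,
    n_cells: int = 80,
    shape: tuple[int, int] = (640, 640),
) -> dict:
    """Recompute the time-course morphometry numbers end-to-end.

    Simulates unstimulated wells at 0-240 min and PMA wells at 60-240 min,
    segments every field, calibrates decondensation thresholds (k = 2) on
    unstimulated wells, and reports:

    - ``unstim_mean_area``: pooled mean nuclear area of unstimulated wells
      (the 500-700 px control band),
    - ``pma240_mean_area``: pooled mean nuclear area of 4-h PMA wells,
    - ``intensity_gap_early``: mean unstimulated-minus-PMA nuclear-intensity
      gap over 60-180 min,
    - ``intensity_gap_240``: the same gap at 240 min,
    - ``pma240_pct_netotic``: mean %NET-forming events across 4-h PMA wells,
    - ``unstim_max_pct_netotic``: the worst (largest) per-timepoint mean
      %NETotic over unstimulated wells.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11])

    def well_seed(child) -> int:
        return int(child.generate_state(1)[0] & 0x7FFFFFFF)

    unstim: dict[int, list[list]] = {}
    for t in UNSTIM_TIMEPOINTS:
        n_wells = wells_240 if t == 240 else wells_per_point
        unstim[t] = [
            simulate_well_records(f"unstim_{t}", well_seed(c), fields_per_well, n_cells, shape)
            for c in ss.spawn(n_wells)
        ]
    pma: dict[int, list[list]] = {}
    for t in PAIRED_TIMEPOINTS:
        pma[t] = [
            simulate_well_records(f"pma_{t}", well_seed(c), fields_per_well, n_cells, shape)
            for c in ss.spawn(wells_per_point)
        ]
    pma[240] = [
        simulate_well_records("pma_240", well_seed(c), fields_per_well, n_cells, shape)
        for c in ss.spawn(wells_240)
    ]

    # thresholds: calibrated on 8 unstimulated control wells (k = 2)
    calib_wells = (unstim[0] + unstim[60] + unstim[120] + unstim[180])[:8]
    calib_records = [r for well in calib_wells for r in well]
    thresholds = calibrate(calib_records, method="unstim_calibrated")

    def summaries(wells: list[list]) -> list:
        return [well_decondensation_summary(recs, thresholds) for recs in wells]

    unstim_summ = {t: summaries(wells) for t, wells in unstim.items()}
    pma_summ = {t: summaries(wells) for t, wells in pma.items()}

    def pooled_mean(summ_lists, attr: str) -> float:
        num = sum(getattr(s, attr) * s.n_nuclei for sl in summ_lists for s in sl)
        den = sum(s.n_nuclei for sl in summ_lists for s in sl)
        return num / den

    unstim_area = pooled_mean(list(unstim_summ.values()), "mean_area")
    pma240_area = pooled_mean([pma_summ[240]], "mean_area")

    gaps = []
    for t in PAIRED_TIMEPOINTS:
        gu = pooled_mean([unstim_summ[t]], "mean_intensity")
        gp = pooled_mean([pma_summ[t]], "mean_intensity")
        gaps.append(gu - gp)
    gap_early = float(np.mean(gaps))
    gap_240 = pooled_mean([unstim_summ[240]], "mean_intensity") - \
        pooled_mean([pma_summ[240]], "mean_intensity")

    pma240_pct = float(np.mean([s.pct_netotic for s in pma_summ[240]]))
    unstim_max_pct = max(
        float(np.mean([s.pct_netotic for s in unstim_summ[t]])) for t in UNSTIM_TIMEPOINTS
    )

    n_nuclei = sum(s.n_nuclei for sl in unstim_summ.values() for s in sl) + \
        sum(s.n_nuclei for sl in pma_summ.values() for s in sl)
    return {
        "unstim_mean_area": float(unstim_area),
        "pma240_mean_area": float(pma240_area),
        "intensity_gap_early": float(gap_early),
        "intensity_gap_240": float(gap_240),
        "pma240_pct_netotic": pma240_pct,
        "unstim_max_pct_netotic": unstim_max_pct,
        "thresholds": thresholds,
        "n_nuclei": int(n_nuclei),
    }


def screen_panel(seed: int, out_dir: Path | str, config=None) -> dict:
    """Run the full default-fixture screen and return its funnel dict."""
    return run_all(config, out_dir, seed=seed)
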