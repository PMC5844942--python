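"""End-to-end drivers: images on disk -> nuclei -> well summaries -> screen calls.

These functions glue the stage modules together the way the CLI exposes
them: segment every field of a plate directory, calibrate decondensation
thresholds per plate from that plate's unstimulated untreated wells,
summarise wells, and (for screens) score compounds and emit the funnel.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import synth_fields
from .decondensation import calibrate, well_decondensation_summary
from .hcs_screen import (
    ScreenConfig,
    apply_filters,
    call_modulator,
    compound_responses,
    funnel_counts,
)
from .net_detection import NetDetectionParams, detect_nets, well_net_signal
from .nucleus_segmentation import (
    NucleusRecord,
    SegmentationParams,
    flag_apoptotic,
    segment_nuclei,
)
from .plate_io import PlateLayout, read_field, find_fields

__all__ = [
    "segment_directory",
    "records_from_frame",
    "well_summaries",
    "run_screen_analysis",
    "run_all",
]

NUCLEI_COLUMNS = [
    "plate", "well", "field_index", "label", "area", "mean_intensity",
    "integrated_intensity", "centroid_row", "centroid_col", "on_border",
    "apoptotic_flag",
]


def segment_directory(
    images_dir: Path | str,
    seg_params: SegmentationParams | None = None,
    net_params: NetDetectionParams | None = None,
    detect_net_regions: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every field pair in a directory; optionally detect NETs.

    Returns ``(nuclei, net_wells)``: one row per retained nucleus, and one
    row per well of aggregated NET signal (empty frame when detection is
    off). Fields are processed one at a time so memory stays flat.
    """
    seg_params = seg_params or SegmentationParams()
    net_params = net_params or NetDetectionParams()
    nuclei_rows: list[dict] = []
    net_by_well: dict[tuple[str, str], list] = {}
    for entry in find_fields(images_dir):
        field = read_field(entry["nuclear_path"], entry["dna_path"],
                           entry["plate_id"], entry["well"], entry["field_index"])
        labels, records = segment_nuclei(field, seg_params)
        records = flag_apoptotic(labels, field, seg_params, records)
        for rec in records:
            nuclei_rows.append({
                "plate": entry["plate_id"], "well": entry["well"],
                "field_index": entry["field_index"], "label": rec.label,
                "area": rec.area, "mean_intensity": rec.mean_intensity,
                "integrated_intensity": rec.integrated_intensity,
                "centroid_row": rec.centroid[0], "centroid_col": rec.centroid[1],
                "on_border": rec.on_border, "apoptotic_flag": rec.apoptotic_flag,
            })
        if detect_net_regions:
            regions, _ = detect_nets(field, labels, net_params)
            net_by_well.setdefault((entry["plate_id"], entry["well"]), []).append(regions)
    nuclei = pd.DataFrame(nuclei_rows, columns=NUCLEI_COLUMNS)
    net_rows = [
        {"plate": plate, "well": well, **well_net_signal(regions)}
        for (plate, well), regions in sorted(net_by_well.items())
    ]
    net_wells = pd.DataFrame(net_rows, columns=["plate", "well", "net_signal",
                                                "n_regions", "total_net_area"])
    return nuclei, net_wells


def records_from_frame(df: pd.DataFrame) -> list[NucleusRecord]:
    """Rehydrate NucleusRecord objects from nuclei-table rows."""
    return [
        NucleusRecord(
            label=int(r.label), area=int(r.area),
            mean_intensity=float(r.mean_intensity),
            integrated_intensity=float(r.integrated_intensity),
            centroid=(float(r.centroid_row), float(r.centroid_col)),
            on_border=bool(r.on_border), apoptotic_flag=bool(r.apoptotic_flag),
        )
        for r in df.itertuples()
    ]


def well_summaries(
    nuclei: pd.DataFrame,
    layout: PlateLayout,
    k_area: float = 2.0,
    k_intensity: float = 2.0,
    control_condition: str = "unstimulated",
    min_control_nuclei: int = 50,
) -> pd.DataFrame:
    """Per-well decondensation summaries with per-plate calibration.

    For each plate, thresholds are calibrated on that plate's untreated
    wells of ``control_condition``; every well on the plate is then
    summarised against those thresholds. Wells present in the layout but
    yielding no nuclei appear with pct_netotic NaN.
    """
    rows: list[dict] = []
    for plate, plate_layout in layout.table.groupby("plate"):
        ctrl_wells = plate_layout[
            (plate_layout["condition"] == control_condition)
            & (plate_layout["compound"] == "")
        ]["well"].tolist()
        ctrl_nuclei = nuclei[(nuclei["plate"] == plate) & nuclei["well"].isin(ctrl_wells)]
        thresholds = calibrate(
            records_from_frame(ctrl_nuclei),
            method="unstim_calibrated" if control_condition == "unstimulated" else "pma_calibrated",
            k_area=k_area, k_intensity=k_intensity,
            min_control_nuclei=min_control_nuclei,
            source_wells=ctrl_wells,
        )
        plate_nuclei = nuclei[nuclei["plate"] == plate]
        for lrow in plate_layout.itertuples():
            well_df = plate_nuclei[plate_nuclei["well"] == lrow.well]
            summ = well_decondensation_summary(records_from_frame(well_df), thresholds)
            rows.append({
                "plate": plate, "well": lrow.well, "condition": lrow.condition,
                "compound": lrow.compound, "dose_molar": lrow.dose_molar,
                "timepoint_min": lrow.timepoint_min, "replicate": lrow.replicate,
                "n_nuclei": summ.n_nuclei, "n_netotic": summ.n_netotic,
                "pct_netotic": summ.pct_netotic, "mean_area": summ.mean_area,
                "mean_intensity": summ.mean_intensity,
                "n_apoptotic": summ.n_apoptotic,
                "apoptotic_fraction": summ.apoptotic_fraction,
                "area_threshold": thresholds.area_threshold,
                "intensity_threshold": thresholds.intensity_threshold,
            })
    return pd.DataFrame(rows)


def run_screen_analysis(
    summaries: pd.DataFrame, config: ScreenConfig | None = None
) -> tuple[pd.DataFrame, list, dict]:
    """Score compounds, call modulators, filter, and build the funnel."""
    config = config or ScreenConfig()
    responses = compound_responses(summaries, config)
    results = [
        call_modulator(grp, config)
        for _, grp in responses.groupby("compound", sort=True)
    ]
    results = apply_filters(results, responses, config)
    return responses, results, funnel_counts(results)


def _results_frame(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "compound": r.compound_name,
            "induction_hit": r.induction_hit,
            "inhibition_hit": r.inhibition_hit,
            "enhancement_hit": r.enhancement_hit,
            "modulator_class": r.modulator_class,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
            "max_z_unstim": max(r.z_unstim),
            "min_z_pma": min(r.z_pma),
            "max_z_pma": max(r.z_pma),
        })
    return pd.DataFrame(rows)


def run_all(
    fixture_config: dict | Path | str | None,
    out_dir: Path | str,
    seed: int = 1,
    screen_config: ScreenConfig | None = None,
    seg_params: SegmentationParams | None = None,
    detect_net_regions: bool = True,
) -> dict:
    """Full pipeline: simulate -> segment -> decondense -> netdetect -> screen.

    Writes images, nuclei.csv, well_summary.csv, compound_results.csv,
    dose_response.csv and screen_funnel.json under ``out_dir``; returns the
    funnel dict. The fixture's exclusion list is adopted into the screen
    config unless the caller supplies one explicitly.
    """
    out_dir = Path(out_dir)
    cfg = synth_fields.load_screen_config(fixture_config) \
        if (fixture_config is None or isinstance(fixture_config, (str, Path))) else fixture_config
    if screen_config is None:
        screen_config = ScreenConfig(exclusion_list=dict(cfg.get("exclusion_list", {})))
    layout, _, _ = synth_fields.generate_screen(cfg, out_dir, seed=seed)
    nuclei, net_wells = segment_directory(out_dir / "images", seg_params,
                                          detect_net_regions=detect_net_regions)
    nuclei.to_csv(out_dir / "nuclei.csv", index=False)
    if detect_net_regions:
        net_wells.to_csv(out_dir / "well_net_signal.csv", index=False)
    summaries = well_summaries(nuclei, layout)
    summaries.to_csv(out_dir / "well_summary.csv", index=False)
    responses, results, funnel = run_screen_analysis(summaries, screen_config)
    responses.to_csv(out_dir / "dose_response.csv", index=False)
    _results_frame(results).to_csv(out_dir / "compound_results.csv", index=False)
    with open(out_dir / "screen_funnel.json", "w") as fh:
        json.dump(funnel, fh, indent=2)
    return funnel
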