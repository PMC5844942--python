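"""Threshold calibration and NETotic classification rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netquant.decondensation import (
    CalibrationError,
    ThresholdSet,
    calibrate,
    classify_netotic,
    timecourse,
    well_decondensation_summary,
)
from netquant.nucleus_segmentation import NucleusRecord


def make_records(areas, intensities, **flags):
    return [
        NucleusRecord(label=i + 1, area=int(a), mean_intensity=float(m),
                      integrated_intensity=float(a * m), centroid=(0.0, 0.0), **flags)
        for i, (a, m) in enumerate(zip(areas, intensities))
    ]


THR = ThresholdSet(area_threshold=700.0, intensity_threshold=1040.0,
                   method="unstim_calibrated", k_area=2.0, k_intensity=2.0,
                   source_wells=[], n_control_nuclei=100)


class TestCalibrate:
    def test_identical_controls_use_epsilon_rule(self):
        recs = make_records([600] * 60, [1200] * 60)
        with pytest.warns(UserWarning):
            thr = calibrate(recs)
        assert thr.area_threshold == pytest.approx(601.0)
        assert thr.intensity_threshold == pytest.approx(1199.0)

    def test_thresholds_match_closed_form_mean_plus_2sd(self, rng):
        areas = rng.normal(600, 50, 10_000)
        intensities = rng.normal(1200, 80, 10_000)
        thr = calibrate(make_records(areas, intensities))
        assert 695 <= thr.area_threshold <= 705
        assert thr.intensity_threshold == pytest.approx(
            intensities.mean() - 2 * intensities.std(ddof=1), rel=1e-6)

    def test_pma_calibrated_method_recorded(self, rng):
        # inhibition-side calibration: same formulas on PMA-stimulated controls
        areas = rng.normal(800, 300, 400).clip(150)
        intensities = rng.normal(950, 150, 400).clip(200)
        thr = calibrate(make_records(areas, intensities), method="pma_calibrated",
                        source_wells=["B01", "B02"])
        assert thr.method == "pma_calibrated"
        assert thr.source_wells == ["B01", "B02"]
        assert thr.area_threshold > float(np.mean(areas))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown calibration method"):
            calibrate(make_records([600] * 60, [1200] * 60), method="median_based")

    def test_too_few_controls_raises_with_count(self):
        with pytest.raises(CalibrationError, match="10"):
            calibrate(make_records([600] * 10, [1200] * 10))

    def test_apoptotic_and_border_nuclei_dropped_before_fitting(self):
        good = make_records([600] * 60, [1200] * 60)
        bad = make_records([3000] * 30, [200] * 30, apoptotic_flag=True)
        with pytest.warns(UserWarning):  # remaining SD is zero
            thr = calibrate(good + bad)
        assert thr.n_control_nuclei == 60
        assert thr.area_threshold == pytest.approx(601.0)

    def test_shift_equivariance_of_intensity_threshold(self, rng):
        """Adding c to every intensity shifts the threshold by exactly c and
        leaves every NETotic call unchanged."""
        areas = rng.normal(600, 50, 500)
        intensities = rng.normal(1200, 80, 500)
        c = 137.5
        thr0 = calibrate(make_records(areas, intensities))
        thr1 = calibrate(make_records(areas, intensities + c))
        assert thr1.intensity_threshold - thr0.intensity_threshold == pytest.approx(c)
        assert thr1.area_threshold == pytest.approx(thr0.area_threshold)
        test_areas = rng.normal(900, 300, 200)
        test_int = rng.normal(1000, 200, 200)
        calls0 = [r.netotic for r in classify_netotic(make_records(test_areas, test_int), thr0)]
        calls1 = [r.netotic for r in classify_netotic(make_records(test_areas, test_int + c), thr1)]
        assert calls0 == calls1


class TestClassify:
    @pytest.mark.parametrize("area,intensity,expected", [
        (700, 700, False),     # boundary area -> strictly non-NETotic
        (1150, 700, True),     # enlarged AND dimmed
        (1150, 1150, False),   # enlarged only
        (600, 700, False),     # dimmed only
        (701, 1040, False),    # boundary intensity
    ])
    def test_and_rule_with_strict_inequalities(self, area, intensity, expected):
        (rec,) = classify_netotic(make_records([area], [intensity]), THR)
        assert rec.netotic is expected


class TestWellSummary:
    def test_pct_arithmetic(self):
        recs = make_records([600] * 4 + [1200] * 6, [1200] * 4 + [700] * 6)
        summary = well_decondensation_summary(recs, THR)
        assert summary.n_nuclei == 10
        assert summary.n_netotic == 6
        assert summary.pct_netotic == pytest.approx(60.0)

    def test_zero_netotic(self):
        summary = well_decondensation_summary(make_records([600] * 10, [1200] * 10), THR)
        assert summary.pct_netotic == 0.0

    def test_zero_retained_flagged_not_error(self):
        recs = make_records([600] * 3, [1200] * 3, apoptotic_flag=True)
        summary = well_decondensation_summary(recs, THR)
        assert summary.pct_netotic is None
        assert summary.flagged_empty
        assert summary.apoptotic_fraction == pytest.approx(1.0)

    @given(
        areas=st.lists(st.integers(100, 5000), min_size=1, max_size=40),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_pct_bounds_property(self, areas, seed):
        rng = np.random.default_rng(seed)
        intensities = rng.uniform(200, 2000, len(areas))
        summary = well_decondensation_summary(make_records(areas, intensities), THR)
        assert 0.0 <= summary.pct_netotic <= 100.0
        assert summary.n_netotic <= summary.n_nuclei


class TestTimecourse:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["condition", "timepoint_min",
                                           "pct_netotic", "mean_area", "mean_intensity"])

    def test_single_well_has_nan_sem(self):
        df = self._frame([("PMA", 240, 60.0, 1100.0, 700.0)])
        out = timecourse(df)
        assert len(out) == 1
        assert np.isnan(out.loc[0, "pct_netotic_sem"])
        assert out.loc[0, "pct_netotic_mean"] == pytest.approx(60.0)

    def test_replicates_mean_and_sem(self):
        df = self._frame([("PMA", 240, 50.0, 1000.0, 700.0),
                          ("PMA", 240, 70.0, 1200.0, 720.0)])
        out = timecourse(df)
        assert out.loc[0, "pct_netotic_mean"] == pytest.approx(60.0)
        assert out.loc[0, "pct_netotic_sem"] == pytest.approx(10.0)

    def test_missing_condition_is_absent_not_error(self):
        df = self._frame([("unstimulated", 0, 0.0, 600.0, 1200.0)])
        out = timecourse(df)
        assert set(out["condition"]) == {"unstimulated"}
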