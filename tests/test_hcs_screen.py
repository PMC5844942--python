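"""Hit calling: robust z, modulator taxonomy, filters, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netquant.hcs_screen import (
    ScreenConfig,
    apply_filters,
    call_modulator,
    compound_responses,
    funnel_counts,
    normalize_doseresponse,
    robust_z,
)

DOSES = [1e-9, 1e-8, 1e-7, 1e-6, 1e-5]


def response_table(compound, z_unstim, z_pma, apo=0.02):
    n = len(z_unstim)
    return pd.DataFrame({
        "compound": [compound] * n,
        "dose_molar": DOSES[:n],
        "pct_netotic_unstim": np.abs(z_unstim),
        "pct_netotic_pma": 10 + np.asarray(z_pma, dtype=float),
        "apoptotic_fraction_unstim": [apo] * n,
        "apoptotic_fraction_pma": [apo] * n,
        "z_unstim": z_unstim,
        "z_pma": z_pma,
    })


def summaries_frame(rows):
    return pd.DataFrame(rows, columns=["condition", "compound", "dose_molar",
                                       "pct_netotic", "apoptotic_fraction"])


class TestRobustZ:
    def test_hand_arithmetic_example(self):
        # controls: median 2, MAD 1 -> compound at 12% gives z ~ 6.745
        controls = np.array([1.0, 2.0, 3.0, 2.0, 1.0, 3.0, 2.0])
        z = robust_z(np.array([12.0]), controls, sigma_floor=0.1)
        assert z[0] == pytest.approx(10 / 1.4826, rel=1e-4)

    def test_sigma_floor_guards_degenerate_controls(self):
        z = robust_z(np.array([5.0]), np.zeros(10), sigma_floor=1.0)
        assert z[0] == pytest.approx(5.0)


class TestCompoundResponses:
    def _base_rows(self):
        rows = [("unstimulated", "", 0.0, p, 0.0) for p in (0.0, 1.0, 0.0, 2.0, 1.0, 0.0)]
        rows += [("PMA", "", 0.0, p, 0.0) for p in (24, 26, 25, 27, 23, 25)]
        return rows

    def test_compound_identical_to_controls_has_small_z(self):
        rows = self._base_rows()
        rows += [("unstimulated", "X", d, 0.5, 0.0) for d in DOSES]
        rows += [("PMA", "X", d, 25.0, 0.0) for d in DOSES]
        out = compound_responses(summaries_frame(rows))
        assert (out["z_unstim"].abs() < 1.5).all()
        assert (out["z_pma"].abs() < 1.5).all()

    def test_row_order_invariance(self):
        rows = self._base_rows()
        rows += [("unstimulated", "X", d, 30.0, 0.0) for d in DOSES]
        rows += [("PMA", "X", d, 2.0, 0.0) for d in DOSES]
        fwd = compound_responses(summaries_frame(rows))
        rev = compound_responses(summaries_frame(rows[::-1]))
        pd.testing.assert_frame_equal(fwd, rev)

    def test_missing_control_condition_is_hard_error(self):
        rows = [("PMA", "", 0.0, 25.0, 0.0)] * 4
        rows += [("PMA", "X", 1e-9, 2.0, 0.0)]
        with pytest.raises(ValueError, match="unstimulated"):
            compound_responses(summaries_frame(rows))


class TestCallModulator:
    def test_biphasic_inhibit_low_induce_high(self):
        res = call_modulator(response_table("R", [0] * 5, [-4.0, -3.5, 0.0, 3.2, 4.0]))
        assert res.inhibition_hit and res.enhancement_hit
        assert res.modulator_class == "biphasic"

    def test_biphasic_induce_low_inhibit_high(self):
        res = call_modulator(response_table("B", [0] * 5, [3.5, 3.2, 0.0, -4.0, -4.1]))
        assert res.modulator_class == "biphasic"

    def test_all_small_z_is_none(self):
        res = call_modulator(response_table("N", [0.5, -0.8, 0.2, 0.9, -0.3],
                                            [0.1, -0.9, 0.8, 0.5, -0.2]))
        assert not res.is_hit and res.modulator_class == "none"

    def test_single_significant_dose_is_not_a_hit_at_default(self):
        res = call_modulator(response_table("S", [0, 0, 0, 0, 4.0], [0] * 5))
        assert not res.induction_hit

    def test_inducer_inhibitor_enhancer_classes(self):
        assert call_modulator(response_table("I", [0, 0, 4, 5, 6], [0] * 5)).modulator_class == "inducer"
        assert call_modulator(response_table("H", [0] * 5, [0, -4, -5, -5, -6])).modulator_class == "inhibitor"
        assert call_modulator(response_table("E", [0] * 5, [0, 0, 4, 5, 6])).modulator_class == "enhancer"

    def test_fewer_than_two_doses_rejected(self):
        with pytest.raises(ValueError, match="2 doses"):
            call_modulator(response_table("X", [0.0], [0.0]))

    @given(
        z_pma=st.lists(st.floats(-8, 8, allow_nan=False), min_size=5, max_size=5),
        z_un=st.lists(st.floats(-8, 8, allow_nan=False), min_size=5, max_size=5),
    )
    @settings(max_examples=80, deadline=None)
    def test_raising_z_cut_never_adds_a_hit(self, z_pma, z_un):
        table = response_table("P", z_un, z_pma)
        loose = call_modulator(table, ScreenConfig(z_cut=2.5))
        strict = call_modulator(table, ScreenConfig(z_cut=3.5))
        for attr in ("induction_hit", "inhibition_hit", "enhancement_hit"):
            assert getattr(loose, attr) or not getattr(strict, attr)


class TestApplyFilters:
    def test_no_filters_selected_equals_hits(self):
        tables = [response_table("A", [0, 0, 4, 5, 6], [0] * 5),
                  response_table("B", [0] * 5, [0] * 5)]
        results = [call_modulator(t) for t in tables]
        out = apply_filters(results, pd.concat(tables), ScreenConfig())
        funnel = funnel_counts(out)
        assert funnel["selected_names"] == ["A"]
        assert funnel["induction_hits"] == 1

    def test_apoptotic_phenotype_excluded_at_hit_dose(self):
        table = response_table("C", [0, 0, 4, 5, 6], [0] * 5, apo=0.5)
        out = apply_filters([call_modulator(table)], table, ScreenConfig())
        assert out[0].excluded and out[0].exclusion_reason == "apoptotic_phenotype"

    def test_apoptosis_at_non_hit_dose_is_tolerated(self):
        table = response_table("C", [0, 0, 4, 5, 6], [0] * 5, apo=0.02)
        table.loc[0, "apoptotic_fraction_unstim"] = 0.9  # dose with z=0
        out = apply_filters([call_modulator(table)], table, ScreenConfig())
        assert not out[0].excluded

    def test_exclusion_list_reason(self):
        table = response_table("D", [0, 0, 4, 5, 6], [0] * 5)
        cfg = ScreenConfig(exclusion_list={"D": "neutropenia"})
        out = apply_filters([call_modulator(table)], table, cfg)
        assert out[0].excluded and out[0].exclusion_reason == "exclusion_list"

    def test_funnel_is_nested_and_complete(self):
        tables = [
            response_table("A", [0, 0, 4, 5, 6], [0] * 5),
            response_table("B", [0] * 5, [0, -4, -5, -5, -6]),
            response_table("C", [0, 0, 4, 5, 6], [0] * 5, apo=0.6),
            response_table("D", [0] * 5, [0] * 5),
        ]
        cfg = ScreenConfig(exclusion_list={"B": "x"})
        results = apply_filters([call_modulator(t) for t in tables], pd.concat(tables), cfg)
        funnel = funnel_counts(results)
        hits = {r.compound_name for r in results if r.is_hit}
        selected = set(funnel["selected_names"])
        assert selected <= hits <= {"A", "B", "C", "D"}
        assert funnel["screened"] == 4
        assert selected == {"A"}


class TestNormalize:
    def _readouts(self):
        return pd.DataFrame({
            "plate": ["p1", "p1", "p2", "p2"],
            "treatment": ["media", "drug", "media", "drug"],
            "value": [100.0, 300.0, 30.0, 90.0],
        })

    def test_media_normalizes_to_one(self):
        df = self._readouts()
        norm, summary = normalize_doseresponse(df)
        media = norm[norm["treatment"] == "media"]["normalized"]
        assert (media == 1.0).all()

    def test_donor_harmonization(self):
        norm, summary = normalize_doseresponse(self._readouts())
        drug = norm[norm["treatment"] == "drug"]["normalized"]
        assert list(drug) == pytest.approx([3.0, 3.0])
        row = summary[summary["treatment"] == "drug"].iloc[0]
        assert row["mean"] == pytest.approx(3.0)

    def test_missing_media_well_errors(self):
        df = self._readouts()
        df = df[~((df["plate"] == "p2") & (df["treatment"] == "media"))]
        with pytest.raises(ValueError, match="p2"):
            normalize_doseresponse(df)

    def test_nonpositive_media_errors(self):
        df = self._readouts()
        df.loc[df["plate"] == "p2", "value"] = [0.0, 90.0]
        with pytest.raises(ValueError, match="p2"):
            normalize_doseresponse(df)
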