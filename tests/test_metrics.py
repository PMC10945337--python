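import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hybridose.metrics import (
    classify_cohort,
    cohort_summary,
    dose_ratio,
    internuclide_ratios,
    load_cohort_doses,
    load_psa_changes,
    pcwg3_classify,
    relative_ti,
    round_half_away,
    summarize_cohort_table,
    therapeutic_index,
    ti_table,
)

TB_KIDNEY = [0.638, 0.537, 0.942, 0.483, 0.284, 0.974]
TB_LIVER = [0.290, 0.167, 0.196, 0.090, 0.051, 0.093]


class TestCohortSummary:
    def test_kidney_column(self):
        mean, sd = cohort_summary(TB_KIDNEY)
        assert round_half_away(mean, 3) == 0.643
        assert round_half_away(sd, 3) == 0.247

    def test_liver_column(self):
        mean, sd = cohort_summary(TB_LIVER)
        assert round_half_away(mean, 3) == 0.148
        assert round_half_away(sd, 3) == 0.080

    def test_population_not_sample_sd(self):
        # the sample (n-1) convention would give 0.270 for the kidney column
        _, sd = cohort_summary(TB_KIDNEY)
        assert sd == pytest.approx(np.std(TB_KIDNEY, ddof=0))
        assert round(np.std(TB_KIDNEY, ddof=1), 3) != round(sd, 3)

    def test_identical_values_zero_sd(self):
        assert cohort_summary([0.5] * 6) == (0.5, 0.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([1.0])


class TestDoseRatio:
    def test_equal_means_unity(self):
        assert dose_ratio(0.5, 0.5) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            dose_ratio(1.0, 0.0)

    def test_kidney_and_parotid_cohort_factors(self):
        doses = load_cohort_doses()
        ratios = internuclide_ratios(doses).set_index("region_id")
        assert round_half_away(ratios.loc["kidneys", "mean_dose_ratio"], 2) == 1.18
        assert round_half_away(ratios.loc["parotid", "mean_dose_ratio"], 2) == 1.10


class TestTherapeuticIndex:
    def test_tumor_over_organ(self):
        assert therapeutic_index(6.0, 0.6) == pytest.approx(10.0)
        assert therapeutic_index(0.6, 0.6) == pytest.approx(1.0)

    def test_phantom_ti_equals_true_dose_ratio(self, noiseless_spec):
        from hybridose.phantom import true_dose

        lesion = true_dose(noiseless_spec, "lesion_1").dose_Gy_per_GBq
        kidney = true_dose(noiseless_spec, "kidneys").dose_Gy_per_GBq
        assert therapeutic_index(lesion, kidney) == pytest.approx(
            lesion / kidney, rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100))
    def test_calibration_invariance(self, tumor, organ, scale):
        base = therapeutic_index(tumor, organ)
        assert therapeutic_index(scale * tumor, scale * organ) == \
            pytest.approx(base, rel=1e-12)

    def test_relative_ti_division(self):
        assert relative_ti(2.63, 5.69) == pytest.approx(0.462, abs=5e-4)
        assert relative_ti(1.0, 1.0) == 1.0

    @given(st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100))
    def test_relative_ti_reciprocity(self, a, b):
        assert relative_ti(a, b) * relative_ti(b, a) == pytest.approx(
            1.0, rel=1e-12)


class TestPcwg3:
    @pytest.mark.parametrize("change, expected", [
        (-53.4, "PR"), (-24.2, "SD"), (-18.6, "SD"),
        (18.0, "SD"), (48.6, "PD"), (73.2, "PD"),
    ])
    def test_cohort_values(self, change, expected):
        assert pcwg3_classify(change) == expected

    @pytest.mark.parametrize("boundary", [-50.0, 25.0])
    def test_strict_boundaries_are_stable_disease(self, boundary):
        assert pcwg3_classify(boundary) == "SD"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pcwg3_classify(float("nan"))

    def test_packaged_cohort_class_counts(self):
        classes = classify_cohort(load_psa_changes())["category"]
        assert classes.value_counts().to_dict() == {"SD": 3, "PD": 2, "PR": 1}


class TestTiTable:
    @staticmethod
    def _tables():
        organ = pd.DataFrame({
            "patient_id": ["p1"] * 2,
            "region_id": ["kidneys"] * 2,
            "nuclide": ["Tb161", "Lu177"],
            "dose_Gy_per_GBq": [0.5, 0.4],
        })
        tumor = pd.DataFrame({
            "patient_id": ["p1"] * 4,
            "nuclide": ["Tb161", "Tb161", "Lu177", "Lu177"],
            "dose_Gy_per_GBq": [6.0, 4.0, 2.0, 3.0],
        })
        return organ, tumor

    def test_per_patient_ti_and_rti(self):
        organ, tumor = self._tables()
        out = ti_table(organ, tumor)
        row = out.iloc[0]
        assert row["ti_Tb161"] == pytest.approx(5.0 / 0.5)
        assert row["ti_Lu177"] == pytest.approx(2.5 / 0.4)
        assert row["rti"] == pytest.approx((5.0 / 0.5) / (2.5 / 0.4))

    def test_equal_doses_give_unit_rti(self):
        organ, tumor = self._tables()
        organ["dose_Gy_per_GBq"] = 0.5
        tumor["dose_Gy_per_GBq"] = 3.0
        assert ti_table(organ, tumor)["rti"].iloc[0] == pytest.approx(1.0)

    def test_shuffled_rows_identical_result(self):
        organ, tumor = self._tables()
        a = ti_table(organ, tumor)
        b = ti_table(organ.sample(frac=1, random_state=0),
                     tumor.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a, b)

    def test_unpaired_keys_rejected(self):
        organ, tumor = self._tables()
        with pytest.raises(ValueError, match="unpaired|missing"):
            ti_table(organ.iloc[:1], tumor)


def test_summary_covers_all_region_nuclide_cells():
    summary = summarize_cohort_table(load_cohort_doses())
    assert len(summary) == 8  # 4 regions x 2 nuclides
    assert (summary["n"] == 6).all()
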