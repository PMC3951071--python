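import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemrbe.dose_response import fit_lq
from hemrbe.isoeffect import (
    DEFAULT_PAIRING,
    IsoeffectError,
    RBETableRow,
    average_rbe,
    fit_rbe_trend,
    fitted_rbe_with_ci,
    invert_lq,
    rbe_per_animal,
)

from conftest import make_records

REF_DOSES = np.array([5, 7.5, 7.7, 10, 15, 20.0])


def reference_fit(a, b=0.0, timepoint="d1"):
    """Noise-free reference fit with known coefficients."""
    y = np.exp(-a * REF_DOSES - b * REF_DOSES**2)
    fit = fit_lq(REF_DOSES, y, np.full(6, 3.0))
    fit.timepoint = timepoint
    fit.arm = "reference"
    return fit


class TestInvert:
    @pytest.mark.parametrize("a,b,fraction,expected", [
        (0.1, 0.0, 0.5, 6.9315),
        (0.1, 0.0, 1.0, 0.0),
        (0.05, 0.01, math.exp(-0.75), 6.5139),   # positive root of 0.01 D^2 + 0.05 D = 0.75
    ])
    def test_closed_forms(self, a, b, fraction, expected):
        assert invert_lq((a, b), fraction) == pytest.approx(expected, abs=1e-4)

    def test_fraction_above_one_maps_to_zero_dose(self):
        assert invert_lq((0.1, 0.001), 1.3) == 0.0

    def test_flat_curve_cannot_produce_effect(self):
        with pytest.raises(IsoeffectError, match="flat"):
            invert_lq((0.0, 0.0), 0.5)

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(IsoeffectError):
            invert_lq((0.1, 0.0), 0.0)

    def test_stable_at_tiny_quadratic_coefficient(self):
        # b at the zero bound (~1e-30) must not destroy the linear solution.
        assert invert_lq((0.1, 1e-30), 0.5) == pytest.approx(math.log(2) / 0.1, rel=1e-12)

    @given(a=st.floats(0.01, 0.3), b=st.floats(0, 0.01),
           y=st.floats(0.01, 1.0))
    @settings(deadline=None, max_examples=100)
    def test_roundtrip_with_evaluate(self, a, b, y):
        from hemrbe.dose_response import evaluate_lq
        d = invert_lq((a, b), y)
        assert evaluate_lq((a, b), d) == pytest.approx(y, abs=1e-10)

    @given(a=st.floats(0.01, 0.3), b=st.floats(0, 0.01),
           y1=st.floats(0.01, 0.99), y2=st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=60)
    def test_strictly_decreasing_in_fraction(self, a, b, y1, y2):
        lo, hi = sorted([y1, y2])
        if hi > lo:
            assert invert_lq((a, b), hi) < invert_lq((a, b), lo)


class TestPerAnimalRBE:
    def test_closed_form_example(self):
        a = math.log(2) / 10.0  # fraction 0.5 at exactly 10 Gy
        fit = reference_fit(a)
        records = make_records({5.0: [0.5]})
        (pt,) = rbe_per_animal(fit, records)
        assert pt.dose_isoeffective == pytest.approx(10.0, abs=1e-6)
        assert pt.rbe == pytest.approx(2.0, abs=1e-6)

    def test_scale_law_triples_rbe(self):
        a_ref = 0.05
        fit = reference_fit(a_ref)
        fractions = {d: [math.exp(-3 * a_ref * d)] for d in (5.0, 7.7, 10.0)}
        points = rbe_per_animal(fit, make_records(fractions))
        for pt in points:
            assert pt.rbe == pytest.approx(3.0, abs=1e-6)

    def test_day4_pairs_with_reference_day7(self):
        fit = reference_fit(0.05, timepoint="d7")
        records = make_records({5.0: [0.6]}, timepoint="d4")
        (pt,) = rbe_per_animal(fit, records)
        assert pt.timepoint_reference == "d7"
        assert DEFAULT_PAIRING["d4"] == "d7"

    def test_missing_pairing_raises(self):
        fit = reference_fit(0.05, timepoint="d7")
        records = make_records({5.0: [0.6]}, timepoint="d4")
        with pytest.raises(IsoeffectError, match="pairing"):
            rbe_per_animal(fit, records, pairing_map={"d1": "d1"})

    def test_no_effect_animal_gets_rbe_zero(self):
        fit = reference_fit(0.05)
        (pt,) = rbe_per_animal(fit, make_records({5.0: [1.2]}))
        assert pt.ok
        assert pt.dose_isoeffective == 0.0
        assert pt.rbe == 0.0


class TestTrendFit:
    def test_exact_line_interpolated(self):
        doses = np.array([2, 4, 6, 8.0])
        rbes = 3.0 - 0.1 * doses
        trend = fit_rbe_trend(doses, rbes)
        assert trend.c0 == pytest.approx(3.0, abs=1e-10)
        assert trend.c1 == pytest.approx(-0.1, abs=1e-10)
        assert trend.c2 == pytest.approx(0.0, abs=1e-10)
        assert trend.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_saturated_design_hits_per_dose_means(self, rng):
        doses = np.repeat([5.0, 7.7, 10.0], 3)
        rbes = 2.5 + rng.normal(0, 0.3, 9)
        trend = fit_rbe_trend(doses, rbes)
        for d in (5.0, 7.7, 10.0):
            fitted = trend.c0 + trend.c1 * d + trend.c2 * d * d
            assert fitted == pytest.approx(rbes[doses == d].mean(), abs=1e-8)

    def test_flat_truth_recovered_on_average(self, rng):
        c0s, c1s, c2s = [], [], []
        for _ in range(200):
            doses = np.repeat([5.0, 7.7, 10.0], 3)
            trend = fit_rbe_trend(doses, 2.5 + rng.normal(0, 0.3, 9))
            c0s.append(trend.c0); c1s.append(trend.c1); c2s.append(trend.c2)
        assert np.mean(c0s) == pytest.approx(2.5, abs=0.25)
        assert abs(np.mean(c1s)) < 0.08
        assert abs(np.mean(c2s)) < 0.006

    def test_too_few_doses(self):
        with pytest.raises(IsoeffectError, match="distinct"):
            fit_rbe_trend([5.0, 5.0, 10.0, 10.0], [2, 2, 3, 3])


class TestCI:
    def test_zero_residual_collapses(self):
        doses = np.repeat([5.0, 7.7, 10.0], 2)
        rbes = 2.0 + 0.1 * doses
        trend = fit_rbe_trend(doses, rbes)
        row = fitted_rbe_with_ci(trend, 7.7)
        assert row.ci_low == pytest.approx(row.rbe_fitted, abs=1e-8)
        assert row.ci_high == pytest.approx(row.rbe_fitted, abs=1e-8)

    def test_center_dose_has_narrowest_interval(self, rng):
        doses = np.repeat([5.0, 7.5, 10.0], 3)
        trend = fit_rbe_trend(doses, 2.5 + rng.normal(0, 0.3, 9))
        widths = {}
        for d in (5.0, 7.5, 10.0):
            row = fitted_rbe_with_ci(trend, d)
            widths[d] = row.ci_high - row.ci_low
        assert widths[7.5] <= widths[5.0]
        assert widths[7.5] <= widths[10.0]

    def test_saturated_design_disables_ci(self):
        trend = fit_rbe_trend([5.0, 7.7, 10.0], [2.0, 2.5, 3.0])
        row = fitted_rbe_with_ci(trend, 5.0)
        assert row.ci_low is None and row.ci_high is None


class TestAverage:
    def test_hand_computed(self):
        rows = [RBETableRow(dose_test=d, rbe_fitted=v) for d, v in
                [(5, 2.0), (7.7, 3.0), (10, 4.0)]]
        mean, sem = average_rbe(rows)
        assert mean == pytest.approx(3.0)
        assert sem == pytest.approx(1.0 / math.sqrt(3), abs=1e-10)

    def test_repeated_value_zero_sem(self):
        rows = [RBETableRow(dose_test=d, rbe_fitted=2.5) for d in (5, 7.7, 10)]
        assert average_rbe(rows)[1] == 0.0

    def test_gated_rows_excluded_by_default(self):
        rows = [RBETableRow(dose_test=5, rbe_fitted=2.0),
                RBETableRow(dose_test=7.7, rbe_fitted=3.0),
                RBETableRow(dose_test=10, rbe_fitted=99.0, gated=True)]
        mean, _ = average_rbe(rows)
        assert mean == pytest.approx(2.5)

    def test_empty_selection_raises(self):
        rows = [RBETableRow(dose_test=5, rbe_fitted=2.0, gated=True)]
        with pytest.raises(IsoeffectError):
            average_rbe(rows)
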