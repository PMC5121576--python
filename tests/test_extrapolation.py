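"""Cross-species series transform, refit, report table, and travel advisory."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from altiop import (
    RigidityCoefficient,
    extrapolation_table,
    fit_human_series,
    fit_iop_altitude,
    predict_travel_iop,
    transform_series_to_human,
)

HUMAN_ORDER = ["pallikaris", "friedenwald", "dastiridou_mean", "dastiridou_max"]


def oracle_transform(y, e_source, e_target):
    """Independent brute-force chain: baseline-referenced rigidity rescale."""
    y = np.asarray(y, float)
    return y[0] * 10 ** (e_target * (np.log10(y / y[0]) / e_source))


class TestTransform:
    def test_identity_at_equal_rigidity(self, rabbit_trips, coefficients):
        e = coefficients["rabbit_mean"]
        for series in rabbit_trips:
            ex = transform_series_to_human(series, e, e)
            np.testing.assert_allclose(
                ex.pressures(), series.pressures("applanation"), rtol=1e-12
            )
            assert ex.baseline_pressure == series.pressures("applanation")[0]

    @pytest.mark.parametrize(
        "coeff_name, expected",
        [("friedenwald", 36.42), ("dastiridou_max", 59.4)],
    )
    def test_peak_station_of_benchmark_eye(self, trips_by_id, coefficients, coeff_name, expected):
        # rabbit 16 -> 32 mmHg from baseline to the 3198 m station
        ex = transform_series_to_human(
            trips_by_id["SF6_100"], coefficients["rabbit_mean"], coefficients[coeff_name]
        )
        peak = dict(ex.points)[3198.0]
        assert peak == pytest.approx(expected, abs=0.05)

    def test_matches_oracle_on_every_eye_and_coefficient(self, rabbit_trips, coefficients):
        e_r = coefficients["rabbit_mean"]
        for series in rabbit_trips:
            for name in HUMAN_ORDER:
                ex = transform_series_to_human(series, e_r, coefficients[name])
                np.testing.assert_allclose(
                    ex.pressures(),
                    oracle_transform(series.pressures("applanation"), e_r.value, coefficients[name].value),
                    rtol=1e-12,
                )

    def test_explicit_baseline_anchors_series(self, trips_by_id, coefficients):
        ex = transform_series_to_human(
            trips_by_id["SF6_100"],
            coefficients["rabbit_mean"],
            coefficients["friedenwald"],
            baseline_pressure=15.0,
        )
        assert ex.pressures()[0] == pytest.approx(15.0)
        assert ex.baseline_pressure == 15.0


class TestHumanFit:
    def test_identity_transform_reproduces_rabbit_fit(self, rabbit_trips, coefficients):
        e = coefficients["rabbit_mean"]
        for series in rabbit_trips:
            rabbit = fit_iop_altitude(series)
            human = fit_human_series(transform_series_to_human(series, e, e))
            assert human.slope == pytest.approx(rabbit.slope, abs=1e-12)
            assert human.ci95 == pytest.approx(rabbit.ci95, abs=1e-10)

    def test_benchmark_eye_friedenwald_slope(self, trips_by_id, coefficients):
        ex = transform_series_to_human(
            trips_by_id["SF6_100"], coefficients["rabbit_mean"], coefficients["friedenwald"]
        )
        assert fit_human_series(ex).slope == pytest.approx(2.1, abs=0.25)

    def test_ascent_only_fit_matches_direct_recomputation(self, trips_by_id, coefficients):
        ex = transform_series_to_human(
            trips_by_id["SF6_100"], coefficients["rabbit_mean"], coefficients["friedenwald"]
        )
        fit = fit_human_series(ex, ascent_only=True)
        y = ex.pressures()[:5]
        x = ex.altitudes()[:5] / 100.0
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.n == 5
        assert fit.slope == pytest.approx(slope, abs=1e-9)

    def test_saline_control_stays_flat_under_every_coefficient(self, trips_by_id, coefficients):
        for name in HUMAN_ORDER:
            ex = transform_series_to_human(
                trips_by_id["BSS"], coefficients["rabbit_mean"], coefficients[name]
            )
            assert abs(fit_human_series(ex).slope) < 0.3

    def test_slope_monotone_in_target_rigidity(self, trips_by_id, coefficients):
        slopes = [
            fit_human_series(
                transform_series_to_human(
                    trips_by_id["SF6_100"], coefficients["rabbit_mean"], coefficients[name]
                )
            ).slope
            for name in HUMAN_ORDER
        ]
        assert slopes == sorted(slopes)


class TestReportTable:
    def test_cardinality_and_benchmark_rows(self, rabbit_trips, coefficients):
        table = extrapolation_table(
            rabbit_trips,
            coefficients["rabbit_mean"],
            [coefficients[n] for n in HUMAN_ORDER],
            benchmark_eye="SF6_100",
        )
        assert len(table) == 24
        assert (table.significance == "").sum() == 4  # benchmark is its own reference
        assert set(table.coefficient) == set(HUMAN_ORDER)

    def test_nonvitrectomized_and_control_eyes_significant(self, rabbit_trips, coefficients):
        table = extrapolation_table(
            rabbit_trips,
            coefficients["rabbit_mean"],
            [coefficients["friedenwald"]],
            benchmark_eye="SF6_100",
        )
        by_case = table.set_index("case").significance
        assert by_case["PNEUM"] == "Sig"
        assert by_case["BSS"] == "Sig"

    def test_missing_benchmark_rejected(self, rabbit_trips, coefficients):
        with pytest.raises(ValueError, match="NOPE"):
            extrapolation_table(
                rabbit_trips, coefficients["rabbit_mean"], [coefficients["friedenwald"]], "NOPE"
            )


class TestAdvisory:
    def test_sea_level_to_high_city_example(self):
        res = predict_travel_iop(15, 2.1, (1.7, 2.5), 2260)
        assert res.delta_iop == pytest.approx(47.46)
        assert res.predicted_iop == pytest.approx(62.46)
        assert res.ci95 == pytest.approx((53.42, 71.5))

    def test_no_travel_no_change(self):
        res = predict_travel_iop(15, 2.1, (1.7, 2.5), 0)
        assert res.predicted_iop == 15
        assert res.ci95 == (15, 15)

    def test_round_number_arithmetic(self):
        res = predict_travel_iop(10, 1.0, (0.5, 1.5), 1000)
        assert res.predicted_iop == pytest.approx(20)
        assert res.ci95 == pytest.approx((15, 25))

    @given(
        h=st.floats(min_value=0, max_value=3000),
        slope=st.floats(min_value=-1, max_value=3),
        k=st.floats(min_value=0.1, max_value=3),
    )
    def test_linear_in_altitude_and_slope(self, h, slope, k):
        base = predict_travel_iop(15, slope, (slope, slope), h).delta_iop
        assert predict_travel_iop(15, slope * k, (slope, slope), h).delta_iop == pytest.approx(
            base * k, abs=1e-9
        )
        assert predict_travel_iop(15, slope, (slope, slope), h * k).delta_iop == pytest.approx(
            base * k, abs=1e-9
        )

    def test_descent_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            predict_travel_iop(15, 2.1, (1.7, 2.5), -100)
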