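"""Unit and property tests for volumes, RTV, TGI and responder classification."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import make_arm, make_curve
from pdxefficacy import (
    NotEvaluableError,
    ValidationError,
    classify_response,
    last_common_day,
    median_rtv,
    optimal_tgi,
    orr_table,
    responder_percentage,
    rtv_series,
    tgi_series,
    volume_from_diameters,
)
from pdxefficacy.growth import GrowthCurve, TumorMeasurement


class TestVolumeFromDiameters:
    @pytest.mark.parametrize(
        "a, b, convention, expected",
        [
            (10, 6, "as-printed", 1800.0),
            (10, 6, "conventional", 180.0),
            (2, 2, "as-printed", 8.0),
            (2, 2, "conventional", 4.0),
        ],
    )
    def test_worked_examples(self, a, b, convention, expected):
        assert volume_from_diameters(a, b, convention) == expected

    @pytest.mark.parametrize("a, b", [(6, 10), (0, 0), (-1, -2), (5, 0)])
    def test_invalid_diameters_rejected(self, a, b):
        with pytest.raises(ValidationError):
            volume_from_diameters(a, b)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValidationError):
            volume_from_diameters(10, 6, "cubic")


class TestRtv:
    @pytest.mark.parametrize(
        "volumes, days, expected",
        [
            ([100, 250, 400], [1, 8, 15], [1.0, 2.5, 4.0]),
            ([120, 120, 120], [1, 8, 15], [1.0, 1.0, 1.0]),
            ([80, 40], [1, 8], [1.0, 0.5]),
        ],
    )
    def test_examples(self, volumes, days, expected):
        curve = make_curve(volumes, days)
        assert [r for _, r in rtv_series(curve)] == expected
        assert [d for d, _ in rtv_series(curve)] == days

    def test_missing_day_one_rejected(self):
        with pytest.raises(ValidationError, match="day 1"):
            make_curve([100, 200], days=[8, 15])

    def test_non_increasing_days_rejected(self):
        ms = tuple(TumorMeasurement("m", d, 100.0) for d in (1, 8))
        with pytest.raises(ValidationError):
            GrowthCurve("m", "a", (ms[0], ms[1], ms[1]))

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e6), min_size=1, max_size=12)
    )
    def test_day_one_rtv_is_exactly_one(self, volumes):
        curve = make_curve(volumes)
        assert rtv_series(curve)[0] == (1, 1.0)


class TestMedianRtv:
    @pytest.mark.parametrize(
        "rtvs, expected",
        [([1.0, 2.0, 9.0], 2.0), ([1.0, 3.0], 2.0), ([2.0], 2.0)],
    )
    def test_median_conventions(self, rtvs, expected):
        arm = make_arm("control", [[100.0, 100.0 * r] for r in rtvs])
        assert median_rtv(arm, 8) == expected

    def test_unmeasured_day_not_evaluable(self):
        arm = make_arm("control", [[100.0, 200.0]])
        with pytest.raises(NotEvaluableError):
            median_rtv(arm, 22)


class TestTgi:
    def two_arm(self, treated_rtvs, control_rtvs, day=8):
        treated = make_arm("treated", [[100.0, 100.0 * r] for r in treated_rtvs],
                           days=[1, day])
        control = make_arm("control", [[100.0, 100.0 * r] for r in control_rtvs],
                           days=[1, day])
        return treated, control

    def test_sixty_percent_meaningful(self):
        treated, control = self.two_arm([2.0, 2.0], [5.0, 5.0], day=49)
        (res,) = [r for r in tgi_series(treated, control) if r.day == 49]
        assert res.tgi_percent == pytest.approx(60.0)
        assert res.meaningful

    def test_identical_arms_zero(self):
        treated, control = self.two_arm([3.0, 1.5], [3.0, 1.5])
        res = tgi_series(treated, control)[-1]
        assert res.tgi_percent == pytest.approx(0.0)
        assert not res.meaningful

    def test_regression_case(self):
        treated, control = self.two_arm([0.5, 0.5], [4.0, 4.0])
        res = tgi_series(treated, control)[-1]
        assert res.tgi_percent == pytest.approx(87.5)
        assert res.meaningful

    def test_negative_tgi_when_treated_grows_faster(self):
        treated, control = self.two_arm([4.0, 4.0], [2.0, 2.0])
        assert tgi_series(treated, control)[-1].tgi_percent == pytest.approx(-100.0)

    def test_too_few_evaluable_mice_not_evaluable(self):
        # single-mouse arms never reach the >= 2 evaluable-mice floor
        treated = make_arm("treated", [[100, 200]], days=[1, 8])
        control = make_arm("control", [[100, 300]], days=[1, 8])
        with pytest.raises(NotEvaluableError):
            tgi_series(treated, control)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_common_volume_rescaling(self, scale):
        treated, control = self.two_arm([1.4, 2.2, 3.0], [2.0, 4.0, 8.0])
        base = tgi_series(treated, control)[-1].tgi_percent
        t2 = make_arm("treated", [[100 * scale, 100 * scale * r] for r in [1.4, 2.2, 3.0]])
        c2 = make_arm("control", [[100 * scale, 100 * scale * r] for r in [2.0, 4.0, 8.0]])
        assert tgi_series(t2, c2)[-1].tgi_percent == pytest.approx(base, rel=1e-9)


class TestOptimalTgi:
    def arms_with_tgi_profile(self, control_rtv_by_day, treated_rtv_by_day, days):
        control = make_arm(
            "control", [[100.0] + [100.0 * r for r in control_rtv_by_day]] * 2,
            days=days)
        treated = make_arm(
            "treated", [[100.0] + [100.0 * r for r in treated_rtv_by_day]] * 2,
            days=days)
        return treated, control

    def test_maximum_selected(self):
        # TGI by day: 10%, 60%, 55%
        treated, control = self.arms_with_tgi_profile(
            [2.0, 5.0, 8.0], [1.8, 2.0, 3.6], days=[1, 8, 15, 22])
        best = optimal_tgi(treated, control)
        assert best.day == 15
        assert best.tgi_percent == pytest.approx(60.0)
        assert all(best.tgi_percent >= r.tgi_percent
                   for r in tgi_series(treated, control))

    def test_treated_always_faster_never_meaningful(self):
        # post-baseline TGIs are all negative; day 1 (TGI exactly 0 by
        # construction, every RTV is 1) is then the optimum
        treated, control = self.arms_with_tgi_profile(
            [2.0, 4.0], [2.1, 4.4], days=[1, 8, 15])
        series = tgi_series(treated, control)
        assert [r.tgi_percent for r in series if r.day > 1] == pytest.approx(
            [-5.0, -10.0])
        best = optimal_tgi(treated, control)
        assert best.day == 1 and best.tgi_percent == 0.0
        assert not best.meaningful
        assert all(best.tgi_percent >= r.tgi_percent for r in series)

    def test_tie_resolved_to_earliest_day(self):
        treated, control = self.arms_with_tgi_profile(
            [2.0, 4.0], [1.2, 2.4], days=[1, 21, 28])
        best = optimal_tgi(treated, control)
        assert best.tgi_percent == pytest.approx(40.0)
        assert best.day == 21


class TestClassifyResponse:
    def control_with_median(self, median, day=8):
        return make_arm("control", [[100.0, 100.0 * median]] * 3, days=[1, day])

    def test_responder_example(self):
        mouse = make_curve([100.0, 120.0], mouse_id="t1", arm="treated")
        rec = classify_response(mouse, self.control_with_median(4.0), 8)
        assert rec.rtvv == pytest.approx(0.3)
        assert rec.orr == pytest.approx(-0.7)
        assert rec.responder
        assert not rec.used_last_available

    def test_identity_non_responder(self):
        mouse = make_curve([100.0, 400.0], mouse_id="t1", arm="treated")
        rec = classify_response(mouse, self.control_with_median(4.0), 8)
        assert rec.rtvv == 1.0 and rec.orr == 0.0 and not rec.responder

    def test_strict_boundary_is_non_responder(self):
        mouse = make_curve([100.0, 200.0], mouse_id="t1", arm="treated")
        rec = classify_response(mouse, self.control_with_median(4.0), 8)
        assert rec.orr == -0.5
        assert not rec.responder

    def test_just_below_boundary_is_responder(self):
        mouse = make_curve([100.0, 199.6], mouse_id="t1", arm="treated")
        rec = classify_response(mouse, self.control_with_median(4.0), 8)
        assert rec.responder

    def test_orr_is_rtvv_minus_one_exactly(self):
        for rtv in (0.1, 0.77, 1.3, 2.9):
            mouse = make_curve([100.0, 100.0 * rtv], mouse_id="t", arm="treated")
            rec = classify_response(mouse, self.control_with_median(2.0), 8)
            assert rec.orr == rec.rtvv - 1.0

    def test_sacrificed_mouse_uses_last_rtv_with_flag(self):
        control = make_arm("control", [[100.0, 200.0, 400.0]] * 2, days=[1, 8, 15])
        mouse = make_curve([100.0, 120.0], days=[1, 8], mouse_id="t1",
                           arm="treated", status="sacrificed")
        rec = classify_response(mouse, control, 15)
        assert rec.used_last_available
        assert rec.rtvv == pytest.approx(1.2 / 4.0)

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_responder_flag_monotone_in_mouse_rtv(self, shrink):
        """Decreasing a responder's RTV (control fixed) never un-responds it."""
        control = self.control_with_median(4.0)
        base = classify_response(
            make_curve([100.0, 180.0], mouse_id="t", arm="treated"), control, 8)
        assert base.responder
        smaller = classify_response(
            make_curve([100.0, 180.0 * shrink], mouse_id="t", arm="treated"),
            control, 8)
        assert smaller.responder


class TestOrrTable:
    @pytest.mark.parametrize(
        "n_resp, n_total, expected",
        [(3, 16, 18.8), (0, 5, 0.0), (5, 5, 100.0), (1, 3, 33.3), (1, 8, 12.5)],
    )
    def test_percentage_rounding_half_up(self, n_resp, n_total, expected):
        assert responder_percentage(n_resp, n_total) == expected

    def test_counts_and_evaluation_day(self):
        control = make_arm("control", [[100.0, 400.0]] * 2)
        # RTVVs: 0.25 (responder), 0.5 (boundary non-responder), 1.5
        treated = make_arm("treated", [[100.0, 100.0], [100.0, 200.0],
                                       [100.0, 600.0]])
        (row,) = orr_table([treated], control)
        assert (row.n_responders, row.n_non_responders) == (1, 2)
        assert row.n_mice == treated.n_mice
        assert row.responder_pct == 33.3
        assert row.evaluation_day == last_common_day(treated, control) == 8
        for rec in row.records:
            assert rec.orr == rec.rtvv - 1.0

    def test_empty_percentage_rejected(self):
        with pytest.raises(ValidationError):
            responder_percentage(0, 0)
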