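"""Comprehensive smoking index, pack-years, lagged variants and codings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokemets.exposure import (
    CsiParameters,
    SmokingHistory,
    SmokingStatus,
    apply_sensitivity_lag,
    compute_csi,
    compute_pack_years,
    csi_values,
    make_coding,
)


class TestCsi:
    @pytest.mark.parametrize(
        "status,intensity,duration,tsc,expected",
        [
            ("never", 0, 0, 0, 0.0),
            # frozen from independent high-precision evaluation of the
            # closed form: tsc*=0, dur*=39.5
            ("current", 20, 40, 0, 2.026184822574735),
            # tsc*=9.5, dur*=20
            ("former", 10, 20, 10, 0.7843181950006726),
        ],
    )
    def test_reference_values(self, status, intensity, duration, tsc, expected):
        h = SmokingHistory(status, intensity, duration, tsc)
        assert compute_csi(h) == pytest.approx(expected, abs=1e-9)

    def test_half_life_exact(self):
        """Waiting one half-life (tau=25 y) after quitting halves the CSI."""
        for tsc in (0.5, 2.0, 9.5, 30.0):  # all >= delta
            lo = csi_values(np.array([15.0]), np.array([20.0]), np.array([tsc + 25.0]))[0]
            hi = csi_values(np.array([15.0]), np.array([20.0]), np.array([tsc]))[0]
            assert lo / hi == pytest.approx(0.5, abs=1e-12)

    def test_infinite_duration_limit(self):
        """With tsc=0 the CSI saturates at ln(intensity + 1)."""
        for intensity in (1, 10, 40):
            v = csi_values(np.array([intensity]), np.array([1e6]), np.array([0.0]))[0]
            assert abs(v - np.log(intensity + 1)) < 1e-6

    def test_monotonicity_grids(self):
        rng = np.random.default_rng(42)
        base_i = rng.uniform(1, 60, 200)
        base_d = rng.uniform(2, 60, 200)
        base_t = rng.uniform(0.5, 40, 200)
        f = lambda i, d, t: csi_values(i, d, t)
        assert np.all(f(base_i + 1, base_d, base_t) >= f(base_i, base_d, base_t))
        assert np.all(f(base_i, base_d + 1, base_t) >= f(base_i, base_d, base_t))
        # non-increasing in time since cessation on tsc >= delta
        assert np.all(f(base_i, base_d, base_t + 1) <= f(base_i, base_d, base_t))

    def test_zero_iff_no_exposure(self):
        assert compute_csi(SmokingHistory("never")) == 0.0
        assert compute_csi(SmokingHistory("current", 5, 10, 0)) > 0.0

    def test_current_smoker_scored_with_tsc_zero(self):
        a = compute_csi(SmokingHistory("current", 20, 30, 0.9))
        b = compute_csi(SmokingHistory("current", 20, 30, 0.0))
        assert a == b

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            csi_values(np.array([-1.0]), np.array([10.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            SmokingHistory("current", 10, -5, 0)


class TestHistoryInvariants:
    def test_never_must_be_zeroed(self):
        with pytest.raises(ValueError):
            SmokingHistory("never", intensity=10)

    def test_ever_requires_more_than_one_year(self):
        with pytest.raises(ValueError):
            SmokingHistory("current", 10, 0.5, 0)

    def test_former_requires_cessation_over_one_year(self):
        with pytest.raises(ValueError):
            SmokingHistory("former", 10, 10, 0.2)
        SmokingHistory("former", 10, 10, 1.0)  # boundary accepted

    def test_current_requires_recent_smoking(self):
        with pytest.raises(ValueError):
            SmokingHistory("current", 10, 10, 2.0)

    def test_age_consistency(self):
        h = SmokingHistory("former", 10, 30, 10, start_age=25)
        h.check_age_consistency(70)
        with pytest.raises(ValueError):
            h.check_age_consistency(60)


class TestPackYears:
    @pytest.mark.parametrize(
        "intensity,duration,expected",
        [(20, 30, 30.0), (10, 39, 19.5), (0, 0, 0.0)],
    )
    def test_values(self, intensity, duration, expected):
        status = "never" if intensity == 0 else "current"
        h = SmokingHistory(status, intensity, duration, 0)
        assert compute_pack_years(h) == expected


def _lag_oracle(duration: int, tsc: int, lag: int):
    """Window arithmetic on an annual grid: smoking occupies the years
    [tsc, tsc + duration) before the index date; drop years before
    index - lag and recompute (duration, tsc)."""
    years = [y for y in range(tsc, tsc + duration) if y >= lag]
    if not years:
        return 0, 0
    return len(years), min(years)


class TestSensitivityLag:
    def test_lag_zero_is_identity(self):
        h = SmokingHistory("former", 12, 20, 5)
        assert apply_sensitivity_lag(h, 0) == h

    @pytest.mark.parametrize(
        "status,duration,tsc,lag,exp_dur,exp_tsc",
        [
            ("current", 40, 0, 3, 37, 3),   # counted as stopped 3 y before index
            ("former", 20, 10, 3, 20, 10),  # quitting predates the window
        ],
    )
    def test_examples(self, status, duration, tsc, lag, exp_dur, exp_tsc):
        out = apply_sensitivity_lag(SmokingHistory(status, 10, duration, tsc), lag)
        assert out.duration == exp_dur
        assert out.time_since_cessation == exp_tsc
        assert _lag_oracle(duration, tsc, lag) == (exp_dur, exp_tsc)

    def test_short_smoker_reclassified_never(self):
        out = apply_sensitivity_lag(SmokingHistory("current", 10, 2, 0), 3)
        assert out.status is SmokingStatus.NEVER
        assert out.duration == 0

    def test_agrees_with_annual_grid_oracle(self):
        for duration in range(2, 45, 4):
            for tsc in range(0, 25, 3):
                for lag in range(0, 12, 3):
                    status = "current" if tsc == 0 else "former"
                    h = SmokingHistory(status, 10, duration, tsc)
                    out = apply_sensitivity_lag(h, lag)
                    o_dur, o_tsc = _lag_oracle(duration, tsc, lag)
                    if o_dur <= 1:
                        assert out.status is SmokingStatus.NEVER
                    else:
                        assert out.duration == o_dur
                        assert out.time_since_cessation == o_tsc

    @given(
        intensity=st.integers(1, 60),
        duration=st.integers(4, 50),
        tsc=st.integers(0, 30),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_lag_param_matches_history_transform(self, intensity, duration, tsc):
        """Folding the lag into the CSI parameters equals transforming the
        history first and scoring it with the plain parameters."""
        status = "current" if tsc == 0 else "former"
        h = SmokingHistory(status, intensity, duration, max(tsc, 0))
        lagged = apply_sensitivity_lag(h, 3.0)
        via_history = compute_csi(lagged)
        via_params = compute_csi(h, CsiParameters(sensitivity_lag=3.0))
        assert via_params == pytest.approx(via_history, abs=1e-12)


class TestCoding:
    def test_tertiles_balanced(self):
        values = np.array([0, 0, 1, 2, 3, 4, 5, 6], dtype=float)
        ever = np.array([False, False] + [True] * 6)
        coding = make_coding(values, ever, "csi_tertiles")
        cats = coding.assign(values, ever)
        counts = cats.value_counts()
        assert counts["never"] == 2
        assert [counts[f"tertile_{k}"] for k in (1, 2, 3)] == [2, 2, 2]
        assert int(counts.sum()) == len(values)

    def test_never_always_reference(self):
        values = np.array([9.0, 1.0, 2.0, 3.0, 4.0])
        ever = np.array([False, True, True, True, True])
        coding = make_coding(values, ever, "csi_tertiles")
        assert coding.assign(values, ever)[0] == "never"

    def test_cutpoint_ties_go_low(self):
        values = np.array([1.0, 2.0, 3.0])
        ever = np.array([True, True, True])
        coding = make_coding(values, ever, "duration_tertiles")
        q1 = coding.cutpoints[0]
        cats = coding.assign(np.array([q1]), np.array([True]))
        assert cats[0] == "tertile_1"

    @pytest.mark.parametrize("intensity,label", [(19.0, "10-19"), (20.0, ">=20"), (9.0, "1-9")])
    def test_intensity_bins(self, intensity, label):
        ever = np.ones(4, dtype=bool)
        values = np.array([5.0, 12.0, 25.0, intensity])
        coding = make_coding(values, ever, "intensity_bins")
        assert coding.assign(values, ever)[-1] == label

    def test_category_medians(self):
        values = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ever = np.array([False] + [True] * 6)
        coding = make_coding(values, ever, "csi_tertiles")
        assert coding.category_medians["never"] == 0.0
        assert coding.category_medians["tertile_1"] == pytest.approx(1.5)

    def test_too_few_ever_smokers(self):
        with pytest.raises(ValueError, match="at least 3 ever smokers"):
            make_coding(np.array([1.0, 2.0]), np.array([True, True]), "csi_tertiles")

    def test_status_scheme(self):
        statuses = np.array(["never", "former", "current"], dtype=object)
        ever = np.array([False, True, True])
        coding = make_coding(statuses, ever, "status")
        assert list(coding.assign(statuses, ever)) == ["never", "former", "current"]
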