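import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from careshift import (
    CoPSeries,
    MarkerTrajectory,
    TrialRecord,
    delta_cop,
    detect_contact,
    group_summary,
    mann_whitney,
    seating_velocity_vz,
    simple_regression,
    skill_report,
    t_from_correlation,
)
from careshift.errors import ContactError, ParameterError, PeakError


def _cop(x, y, fs=600.0):
    x = np.asarray(x, dtype=float)
    return CoPSeries(fs=fs, t=np.arange(x.size) / fs, cop_x=x, cop_y=np.asarray(y, float))


def _step_cop(t_step, dx, dy, duration=16.0, fs=600.0):
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    x = np.where(t >= t_step, dx, 0.0)
    y = np.where(t >= t_step, dy, 0.0)
    return CoPSeries(fs=fs, t=t, cop_x=x, cop_y=y)


class TestDetectContact:
    def test_step_displacement_found_at_step(self):
        cop = _step_cop(10.0, 8.0, 0.0)
        t1 = detect_contact(cop, threshold_mm=5.0, hold_s=0.1)
        assert t1 == pytest.approx(10.0, abs=0.11)

    def test_flat_series_is_no_contact(self):
        n = 600 * 12
        cop = _cop(np.zeros(n), np.zeros(n))
        with pytest.raises(ContactError):
            detect_contact(cop)

    def test_simulated_contact_close_to_truth(self):
        from careshift import MotionProfile, simulate_force_plate

        p = MotionProfile(seat_offset=(40.0, -60.0))
        cop = simulate_force_plate(p, noise_sd=0.0)
        t1 = detect_contact(cop)
        assert abs(t1 - p.contact_time) <= 0.1


class TestDeltaCop:
    def test_constant_series_zero_delta(self):
        n = 600 * 12
        cop = _cop(np.full(n, 3.0), np.full(n, -4.0))
        d = delta_cop(cop, t1=2.0)
        assert d.dx == pytest.approx(0.0, abs=1e-12)
        assert d.dy == pytest.approx(0.0, abs=1e-12)

    def test_step_recovered_exactly(self):
        cop = _step_cop(8.0, -30.0, -40.0)
        d = delta_cop(cop, t1=8.0)
        assert d.dx == pytest.approx(-30.0, abs=1e-9)
        assert d.dy == pytest.approx(-40.0, abs=1e-9)
        assert d.t2 == pytest.approx(13.0)

    def test_truncated_recording_rejected(self):
        cop = _step_cop(8.0, -30.0, -40.0, duration=12.0)
        from careshift.errors import AnalysisError

        with pytest.raises(AnalysisError):
            delta_cop(cop, t1=8.0)

    @given(shift_x=st.floats(-100, 100), shift_y=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_equivariance_under_constant_shift(self, shift_x, shift_y):
        cop = _step_cop(8.0, -30.0, -40.0)
        shifted = CoPSeries(
            fs=cop.fs, t=cop.t, cop_x=cop.cop_x + shift_x, cop_y=cop.cop_y + shift_y
        )
        d0 = delta_cop(cop, 8.0)
        d1 = delta_cop(shifted, 8.0)
        assert d1.dx == pytest.approx(d0.dx, abs=1e-9)
        assert d1.dy == pytest.approx(d0.dy, abs=1e-9)


def _marker_with_pulses(amplitudes, centers, fs=120.0, duration=20.0, sigma=0.4):
    t = np.arange(int(duration * fs) + 1) / fs
    v = np.zeros_like(t)
    for a, c in zip(amplitudes, centers):
        v -= a * np.exp(-((t - c) ** 2) / (2 * sigma**2))
    z = 1600.0 + np.cumsum(v) / fs
    return MarkerTrajectory(fs=fs, t=t, z=z)


class TestSeatingVelocity:
    def test_third_peak_in_time_order(self):
        m = _marker_with_pulses([10.0, 20.0, 50.0], [4.0, 8.0, 12.0])
        assert seating_velocity_vz(m) == pytest.approx(50.0, rel=0.02)

    def test_monotone_z_has_no_downward_peaks(self):
        fs = 120.0
        t = np.arange(int(20 * fs)) / fs
        m = MarkerTrajectory(fs=fs, t=t, z=1600.0 + 5.0 * t)
        with pytest.raises(PeakError):
            seating_velocity_vz(m)

    def test_two_peaks_is_an_error_reporting_count(self):
        m = _marker_with_pulses([20.0, 50.0], [6.0, 12.0])
        with pytest.raises(PeakError, match="found 2"):
            seating_velocity_vz(m)

    def test_invariant_to_height_offset(self):
        m = _marker_with_pulses([10.0, 20.0, 50.0], [4.0, 8.0, 12.0])
        shifted = MarkerTrajectory(fs=m.fs, t=m.t, z=m.z + 250.0)
        assert seating_velocity_vz(shifted) == pytest.approx(
            seating_velocity_vz(m), abs=1e-9
        )


class TestSimpleRegression:
    def test_reported_t_for_r046_n42(self):
        """The t statistic implied by r = 0.46 at N = 42 is 3.28 (2 dp)."""
        assert round(t_from_correlation(0.46, 42), 2) == 3.28

    def test_four_point_closed_form_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 1.5, 3.5])
        res = simple_regression(x, y)
        # independent closed-form computation
        r = np.corrcoef(x, y)[0, 1]
        t = r * math.sqrt(2) / math.sqrt(1 - r * r)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.t_value == pytest.approx(t, abs=1e-12)
        from scipy.stats import t as tdist

        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), 2), abs=1e-12)

    def test_collinear_data_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = simple_regression(x, 2 * x)
        assert res.flagged and math.isnan(res.t_value)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ParameterError):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_internal_t_consistency(self, seed):
        """Reported t always equals r sqrt(n-2)/sqrt(1-r^2)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        res = simple_regression(x, y)
        expect = res.r * math.sqrt(n - 2) / math.sqrt(1 - res.r**2)
        assert abs(res.t_value - expect) < 1e-10


def _enumeration_p(a, b):
    """Independent oracle: full enumeration of group splits over midranks."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    obs = abs(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0 - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        hits += abs(u - mu) >= obs - 1e-9
        total += 1
    return hits / total


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_fully_separated_small_groups(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20."""
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n7(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 7)
        b = rng.normal(0.8, 1.0, 7)
        exact = mann_whitney(a, b)
        assert exact.method == "exact"
        from scipy.stats import mannwhitneyu

        p_norm = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert abs(exact.p_value - p_norm) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])

    def test_tied_small_samples_use_enumeration(self):
        res = mann_whitney([1.0, 1.0, 2.0], [1.0, 3.0, 3.0])
        assert res.method == "exact-enumeration"
        assert res.p_value == pytest.approx(
            _enumeration_p([1.0, 1.0, 2.0], [1.0, 3.0, 3.0]), abs=1e-12
        )


class TestGroupSummary:
    def test_five_number_example(self):
        """{1..5}: median 3, Q1 2, Q3 4 under linear-interpolation quantiles."""
        s = group_summary([1.0, 2.0, 3.0, 4.0, 5.0])
        assert (s.median, s.q1, s.q3) == (3.0, 2.0, 4.0)
        assert s.outliers == []
        assert (s.whisker_low, s.whisker_high) == (1.0, 5.0)

    def test_constant_values_zero_width_box(self):
        s = group_summary([7.0] * 6)
        assert s.q1 == s.median == s.q3 == 7.0
        assert s.whisker_low == s.whisker_high == 7.0

    def test_extreme_point_reported_as_outlier(self):
        s = group_summary([1.0, 2.0, 3.0, 4.0, 5.0, 50.0])
        assert 50.0 in s.outliers
        assert s.whisker_high < 50.0


class TestSkillReport:
    def test_roster_counts(self):
        """8 novices x 3 trials and 6 experts x 3 trials give 24 + 18 = 42
        observations from 14 caregivers."""
        records = []
        rng = np.random.default_rng(0)
        for i in range(8):
            for trial in range(3):
                records.append(
                    TrialRecord(
                        participant=f"novice{i}", group="inexperienced", trial=trial + 1,
                        v_z=float(rng.uniform(25, 110)), alpha=float(rng.uniform(0.2, 0.6)),
                    )
                )
        for i in range(6):
            for trial in range(3):
                records.append(
                    TrialRecord(
                        participant=f"expert{i}", group="pt_ot", trial=trial + 1,
                        v_z=float(rng.uniform(8, 45)), alpha=float(rng.uniform(0.1, 0.4)),
                    )
                )
        report = skill_report(records)
        assert report["groups"]["inexperienced"]["n_observations"] == 24
        assert report["groups"]["pt_ot"]["n_observations"] == 18
        assert report["totals"]["n_observations"] == 42
        assert report["totals"]["n_participants"] == 14
        assert "v_z" in report["group_tests"]
        assert report["group_tests"]["v_z"]["p_value"] <= 1.0

    def test_report_is_json_serialisable(self):
        import json

        records = [
            TrialRecord("a", "g1", 1, cog_y_bar=1.0, alpha=0.3, v_z=30.0),
            TrialRecord("b", "g1", 1, cog_y_bar=2.0, alpha=0.4, v_z=50.0),
            TrialRecord("c", "g2", 1, cog_y_bar=3.0, alpha=0.2, v_z=20.0),
            TrialRecord("d", "g2", 1, cog_y_bar=2.5, alpha=0.25, v_z=25.0),
        ]
        json.dumps(skill_report(records))
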