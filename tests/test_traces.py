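"""Tests for growth/activity estimation, pulses, correlation and events."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rpospulse import (
    FrameSeries,
    PopulationSample,
    cross_correlation,
    event_duration_cdf,
    find_activity_peaks,
    growth_rate_series,
    low_growth_events,
    moving_average,
    population_growth_rate,
    promoter_activity_series,
)
from rpospulse.traces import LowGrowthEvent, _local_maxima

DT = 1.0 / 6.0  # 10-min frames, hours


def make_frames(l, M=None, division=None):
    l = np.asarray(l, dtype=float)
    t = np.arange(len(l)) * DT
    if M is None:
        M = np.ones_like(l)
    return FrameSeries(t=t, l=l, M=np.asarray(M, dtype=float),
                       division=division)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(20, 3.7)
        assert np.allclose(moving_average(x, 5), x)

    def test_span_one_is_identity(self, rng):
        x = rng.normal(size=30)
        assert np.array_equal(moving_average(x, 1), x)

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(30, dtype=float) * 0.5 + 2.0
        sm = moving_average(x, 5)
        # symmetric windows centered on a line return the center — and the
        # shrinking endpoint windows are symmetric too, so all points match
        assert np.allclose(sm, x)

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(10), 4)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=7, max_size=40))
    @settings(deadline=None)
    def test_matches_direct_windowed_mean(self, vals):
        x = np.array(vals)
        sm = moving_average(x, 5)
        n = len(x)
        for i in range(n):
            k = min(2, i, n - 1 - i)
            assert sm[i] == pytest.approx(x[i - k:i + k + 1].mean(),
                                          rel=1e-9, abs=1e-9)


class TestGrowthRateSeries:
    def test_constant_length_gives_zero(self):
        gs = growth_rate_series(make_frames(np.full(12, 2.0)))
        assert np.allclose(gs.g, 0.0) and np.allclose(gs.g_corrected, 0.0)

    def test_exponential_forward_difference(self):
        g_true = 0.9
        t = np.arange(20) * DT
        frames = make_frames(1.3 * np.exp(g_true * t))
        gs = growth_rate_series(frames)
        expected = (np.exp(g_true * DT) - 1.0) / DT
        # interior, pre-smoothing values are the exact forward difference
        assert np.allclose(gs.g_corrected[:-1], expected, rtol=1e-9)
        # smoothing of a constant-rate series changes nothing
        assert np.allclose(gs.g, expected, rtol=1e-9)

    def test_negative_value_replaced_by_neighbour_mean(self):
        # raw growth sequence [0.5, -0.2, 0.7] -> middle becomes 0.6
        raw = np.array([0.5, -0.2, 0.7, 0.4, 0.3, 0.2])
        l = np.empty(len(raw) + 1)
        l[0] = 1.0
        for i, g in enumerate(raw):
            l[i + 1] = l[i] * (1 + g * DT)
        gs = growth_rate_series(make_frames(l), smooth=False)
        assert gs.g_corrected[0] == pytest.approx(0.5)
        assert gs.g_corrected[1] == pytest.approx(0.6)
        assert gs.g_corrected[2] == pytest.approx(0.7)
        assert gs.replaced[1] and not gs.replaced[0]

    def test_division_pair_excluded_and_filled(self):
        # growth at 0.6/h, a division (halving) between frames 4 and 5
        g_true = 0.6
        l = [1.0]
        division = [0] * 10
        for i in range(9):
            nxt = l[-1] * (1 + g_true * DT)
            if i == 4:
                nxt /= 2
                division[5] = 1
            l.append(nxt)
        gs = growth_rate_series(make_frames(l, division=division),
                                smooth=False)
        expected = g_true  # discrete-rate construction: recovered exactly
        assert np.allclose(gs.g_corrected[:-1], expected, rtol=1e-9)
        assert gs.replaced[4]  # the pair (4, 5) spanned the division

    def test_all_negative_raises(self):
        l = np.linspace(2.0, 1.0, 8)  # monotonically shrinking
        with pytest.raises(ValueError):
            growth_rate_series(make_frames(l))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            growth_rate_series(make_frames([1.0]))


class TestPromoterActivity:
    def test_zero_fluorescence_zero_activity(self):
        frames = make_frames(np.full(12, 1.5), M=np.zeros(12))
        act = promoter_activity_series(frames)
        assert np.allclose(act.A, 0.0)

    def test_constant_m_constant_l_gives_m_times_p(self):
        m, p = 4.0, 0.1
        frames = make_frames(np.full(15, 2.0), M=np.full(15, m))
        act = promoter_activity_series(frames, p=p)
        assert np.allclose(act.A, m * p)

    def test_length_respects_source(self):
        frames = make_frames(np.full(9, 1.0))
        act = promoter_activity_series(frames)
        assert len(act.A) == len(frames)


class TestFindActivityPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert find_activity_peaks(np.linspace(0, 1, 15)) == []

    def test_triangular_pulse_height_from_unsmoothed_window(self):
        # apex 1.0 flanked by 0.8 within zeros; the 5-frame smooth yields a
        # 3-frame plateau (0.52 at frames 6-8) whose first frame wins, and
        # the 7-frame window max of the raw series is the apex value 1.0
        a = np.zeros(15)
        a[6], a[7], a[8] = 0.8, 1.0, 0.8
        peaks = find_activity_peaks(a)
        assert len(peaks) == 1
        assert peaks[0].frame == 6
        assert peaks[0].height == pytest.approx(1.0)

    def test_two_separated_pulses_equal_heights(self):
        a = np.zeros(40)
        for c in (10, 28):
            a[c - 1], a[c], a[c + 1] = 0.8, 1.0, 0.8
        peaks = find_activity_peaks(a)
        assert len(peaks) == 2
        assert peaks[0].height == peaks[1].height == pytest.approx(1.0)
        assert [p.frame for p in peaks] == [9, 27]  # plateau first frames

    def test_plateau_takes_first_frame(self):
        x = np.array([0, 1, 2, 2, 2, 1, 0], dtype=float)
        assert _local_maxima(x) == [2]

    def test_endpoints_never_peaks(self):
        x = np.array([5, 1, 1, 1, 1, 1, 6], dtype=float)
        assert all(p.frame not in (0, 6) for p in find_activity_peaks(x))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            find_activity_peaks(np.ones(5))


class TestCrossCorrelation:
    def test_self_correlation_is_one_at_lag_zero(self, rng):
        x = rng.normal(size=200)
        c = cross_correlation(x, x, 5)
        assert c.loc[c.lag == 0, "corr"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, rng):
        x = rng.normal(size=200)
        c = cross_correlation(x, -x, 5)
        assert c.loc[c.lag == 0, "corr"].iloc[0] == pytest.approx(-1.0)

    def test_delayed_copy_peaks_at_construction_lag(self, rng):
        # y delayed by k frames: the x(t+dt)y(t) sum peaks at lag -k
        x = rng.normal(size=4000)
        k = 7
        y = np.roll(x, k)
        c = cross_correlation(x, y, 15)
        best = int(c.loc[c["corr"].idxmax(), "lag"])
        assert best == -k

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation(np.ones(20), np.arange(20.0), 3)

    @given(st.integers(0, 2**31 - 1), st.integers(10, 60), st.integers(0, 6))
    @settings(deadline=None, max_examples=30)
    def test_matches_bruteforce_sum(self, seed, n, max_lag):
        # oracle: direct summation of the normalized cross-covariance
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        max_lag = min(max_lag, n - 1)
        c = cross_correlation(x, y, max_lag)
        xd, yd = x - x.mean(), y - y.mean()
        denom = np.sqrt((xd**2).sum() * (yd**2).sum())
        for lag in range(-max_lag, max_lag + 1):
            total = sum(xd[t + lag] * yd[t] for t in range(n)
                        if 0 <= t + lag < n)
            got = c.loc[c.lag == lag, "corr"].iloc[0]
            assert got == pytest.approx(total / denom, rel=1e-9, abs=1e-12)


class TestPopulationGrowthRate:
    def test_single_class_doubling_time(self):
        s = PopulationSample(n=[1.0], c=[0.8])
        g = population_growth_rate(s)
        assert s.t_D == pytest.approx(0.8, abs=1e-10)
        assert g == pytest.approx(np.log(2) / 0.8)

    def test_two_class_mixture_closed_form(self):
        # 50/50 at 0.5 h and 1.0 h: with u = 2^{t_D}, u^2 + u - 4 = 0,
        # so t_D = log2((-1 + sqrt(17)) / 2)
        s = PopulationSample(n=[0.5, 0.5], c=[0.5, 1.0])
        population_growth_rate(s)
        expected = np.log2((-1 + np.sqrt(17)) / 2)
        assert s.t_D == pytest.approx(expected, abs=1e-10)

    def test_scaling_all_cycle_times(self):
        s1 = PopulationSample(n=[0.3, 0.7], c=[0.4, 1.2])
        s2 = PopulationSample(n=[0.3, 0.7], c=[0.4 * 2.5, 1.2 * 2.5])
        population_growth_rate(s1)
        population_growth_rate(s2)
        assert s2.t_D == pytest.approx(2.5 * s1.t_D, rel=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_agrees_with_bisection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 5)
        n = rng.dirichlet(np.ones(k))
        c = rng.uniform(0.2, 3.0, size=k)
        s = PopulationSample(n=n, c=c)
        population_growth_rate(s)
        lo, hi = 0.0, float(c.max()) * (1 + 1e-9)
        for _ in range(200):  # plain bisection, independent of brentq
            mid = 0.5 * (lo + hi)
            if np.sum(n * 2.0 ** (mid / c)) < 2.0:
                lo = mid
            else:
                hi = mid
        assert s.t_D == pytest.approx(0.5 * (lo + hi), abs=1e-10)

    def test_invalid_samples_rejected(self):
        with pytest.raises(ValueError):
            PopulationSample(n=[], c=[])
        with pytest.raises(ValueError):
            PopulationSample(n=[0.6, 0.6], c=[1.0, 2.0])


class TestLowGrowthEvents:
    def test_no_events_when_fast(self):
        g = np.full(12, 1.0)
        assert low_growth_events(g, 0.71, frame_dt=10.0) == []

    def test_hand_counted_run(self):
        g = np.ones(12)
        g[3:8] = 0.5  # frames 3..7 below threshold
        evs = low_growth_events(g, 0.71, frame_dt=10.0)
        assert len(evs) == 1
        ev = evs[0]
        assert (ev.start, ev.end) == (3, 7)
        assert ev.duration == pytest.approx(50.0)  # 5 frames x 10 min
        assert not ev.censored

    def test_whole_trace_below_is_censored(self):
        evs = low_growth_events(np.zeros(8), 0.71, frame_dt=10.0)
        assert len(evs) == 1 and evs[0].censored
        assert evs[0].duration == pytest.approx(80.0)

    def test_boundary_runs_flagged_censored(self):
        g = np.ones(10)
        g[:2] = 0.1
        g[-3:] = 0.1
        evs = low_growth_events(g, 0.71, frame_dt=10.0)
        assert [e.censored for e in evs] == [True, True]


class TestEventDurationCdf:
    def test_single_event_single_step(self):
        df = event_duration_cdf([LowGrowthEvent(0, 2, 30.0)])
        assert df["duration"].tolist() == [30.0]
        assert df["fraction"].tolist() == [1.0]

    def test_hand_counted_complementary_fractions(self):
        evs = [LowGrowthEvent(0, 0, d) for d in (10.0, 20.0, 20.0, 40.0)]
        df = event_duration_cdf(evs)
        assert df["duration"].tolist() == [10.0, 20.0, 40.0]
        assert df["fraction"].tolist() == [1.0, 0.75, 0.25]

    def test_orientation_switch(self):
        evs = [LowGrowthEvent(0, 0, d) for d in (10.0, 20.0)]
        df = event_duration_cdf(evs, complementary=False)
        assert df["fraction"].tolist() == [0.5, 1.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            event_duration_cdf([])
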