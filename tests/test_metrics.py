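"""Event-locked ratio statistics and cross-correlation lag estimation."""

import numpy as np
import pytest

from wormcal.behavior import SwitchEvent
from wormcal.metrics import (
    cross_correlate,
    pairwise_correlation,
    ratio_change_omega,
    ratio_change_reversal,
    summarize_events,
)
from wormcal.synthetic import GeneratorConfig, NeuronConfig, noiseless, simulate_experiment
from wormcal.types import BACKWARD, FORWARD


def _series(values, fps=10.0):
    v = np.asarray(values, float)
    return np.arange(v.size) / fps, v


def _event(t0, bout_s, preceding=10.0):
    return SwitchEvent(t0, FORWARD, BACKWARD, bout_s, True, preceding)


def test_constant_ratio_gives_100_percent():
    t, r = _series(np.full(200, 1.7))
    res = ratio_change_reversal(t, r, _event(10.0, 3.0))
    assert res.accepted
    assert res.change_pct == pytest.approx(100.0)


def test_piecewise_constant_series_gives_hand_computed_windows_and_value():
    """R = 2 before the switch and 1 after; 3-s bout: 1/2 = 50%, with
    windows [-4, -1] and [+1, +3] around t0."""
    t = np.arange(200) / 10.0
    t0 = 10.0
    r = np.where(t < t0, 2.0, 1.0)
    res = ratio_change_reversal(t, r, _event(t0, 3.0))
    assert res.change_pct == pytest.approx(50.0)
    assert res.forward_window == (pytest.approx(6.0), pytest.approx(9.0))
    assert res.event_window == (pytest.approx(11.0), pytest.approx(13.0))


def test_short_bout_is_qc_rejected_without_exception():
    t, r = _series(np.full(200, 1.0))
    res = ratio_change_reversal(t, r, _event(10.0, 1.2))
    assert "bout too short" in res.qc
    assert np.isnan(res.change_pct)


def test_missing_pre_event_coverage_is_qc_rejected():
    t, r = _series(np.full(100, 1.0))
    res = ratio_change_reversal(t, r, _event(2.0, 3.0))
    assert "insufficient pre-event coverage" in res.qc


def test_short_forward_baseline_is_qc_rejected():
    t, r = _series(np.full(300, 1.0))
    res = ratio_change_reversal(t, r, _event(15.0, 3.0, preceding=2.5))
    assert "insufficient forward baseline" in res.qc


def test_invalid_frames_are_excluded_from_window_means():
    t = np.arange(200) / 10.0
    t0 = 10.0
    r = np.where(t < t0, 2.0, 1.0)
    valid = np.ones_like(t, bool)
    # poison some forward-window frames; with the mask the result is unchanged
    poisoned = r.copy()
    poisoned[(t >= 6.0) & (t < 6.5)] = 99.0
    valid_mask = valid.copy()
    valid_mask[(t >= 6.0) & (t < 6.5)] = False
    res = ratio_change_reversal(t, poisoned, _event(t0, 3.0), valid=valid_mask)
    assert res.change_pct == pytest.approx(50.0)


def test_omega_change_examples():
    t, r = _series(np.full(300, 0.8))
    res = ratio_change_omega(t, r, omega_onset_s=20.0, reference_s=18.0)
    assert res.change_pct == pytest.approx(100.0)

    t = np.arange(300) / 10.0
    ref = 18.0
    r = np.where((t >= ref - 5.0) & (t < ref - 4.0), 1.0, 0.4)
    res = ratio_change_omega(t, r, omega_onset_s=20.0, reference_s=ref)
    assert res.change_pct == pytest.approx(40.0)


def test_omega_window_truncation_is_flagged():
    t, r = _series(np.full(100, 1.0))
    res = ratio_change_omega(t, r, omega_onset_s=9.5, reference_s=9.5)
    assert "event window truncated" in res.qc


def test_omega_change_recovers_generator_truth_at_low_noise():
    cfg = GeneratorConfig(duration_s=400, seed=17, omega_prob=1.0, noise_sd=1.0)
    sim = simulate_experiment(cfg, neurons=[NeuronConfig.rme()])
    from wormcal import compute_ratio

    trace = compute_ratio(sim.traces["RMED"])
    truths = [d for d in sim.truth.true_ratio_change_pct["RMED"] if d["kind"] == "omega"]
    assert len(truths) >= 5
    bouts = sim.track.bouts()
    t = sim.track.timestamps
    ests = []
    for k, (i0, i1, st) in enumerate(bouts):
        if st == "omega" and k > 1 and bouts[k - 1][2] == BACKWARD:
            onset = float(t[i0])
            if not any(abs(d["t0"] - onset) < 0.05 for d in truths):
                continue
            res = ratio_change_omega(
                trace.timestamps, trace.ratio, onset,
                reference_s=float(t[bouts[k - 1][0]]), valid=trace.valid)
            if res.accepted:
                ests.append(res.change_pct)
    truth_mean = np.mean([d["change_pct"] for d in truths])
    assert abs(np.mean(ests) - truth_mean) < 5.0


# --- pairwise correlation ----------------------------------------------------


def test_pairwise_correlation_limits_and_hand_value():
    t = np.arange(40) / 10.0
    a = np.sin(t) + 2.0
    assert pairwise_correlation(t, a, a, (0.0, 4.0)) == pytest.approx(1.0)
    assert pairwise_correlation(t, a, -a + 5.0, (0.0, 4.0)) == pytest.approx(-1.0)

    x = np.array([1.0, 2.0, 3.0, 4.0] * 3)
    y = np.array([1.0, 2.0, 2.0, 4.0] * 3)
    tt = np.arange(x.size) / 10.0
    # textbook Pearson on the first four points (pattern repeats)
    xm, ym = x.mean(), y.mean()
    r_hand = np.sum((x - xm) * (y - ym)) / np.sqrt(
        np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2))
    assert pairwise_correlation(tt, x, y, (0.0, 1.2)) == pytest.approx(r_hand)


def test_pairwise_correlation_rejects_degenerate_input():
    t = np.arange(40) / 10.0
    with pytest.raises(ValueError):
        pairwise_correlation(t, np.ones(40), np.arange(40.0), (0.0, 4.0))
    with pytest.raises(ValueError):
        pairwise_correlation(t, np.arange(40.0), np.arange(40.0), (0.0, 0.5))


# --- cross-correlation -------------------------------------------------------


def brute_force_ccf(a, b, max_lag):
    """Definitionally simple biased cross-correlation of z-scored series."""
    n = a.size
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.empty(lags.size)
    for i, lag in enumerate(lags):
        s = 0.0
        for t in range(n):
            if 0 <= t + lag < n:
                s += az[t] * bz[t + lag]
        out[i] = s / n
    return lags, out


def test_identical_series_peak_at_zero_with_unit_value():
    rng = np.random.default_rng(0)
    a = rng.normal(size=300)
    res = cross_correlate(a, a, frame_rate_hz=10.0, max_lag_s=3.0,
                          smooth_window_s=0.0)
    assert res.peak_lag_s == 0.0
    assert res.peak_value == pytest.approx(1.0, abs=1e-6)


def test_delayed_copy_recovers_the_delay_and_matches_brute_force():
    # a mixture of incommensurate tones has a decaying autocorrelation, so
    # the true delay is the unique |ccf| peak (a single sinusoid's
    # anti-phase trough would rival it)
    t = np.arange(400) / 10.0
    base = (np.sin(2 * np.pi * 0.31 * t)
            + 0.7 * np.sin(2 * np.pi * 0.47 * t + 1.0)
            + 0.4 * np.sin(2 * np.pi * 0.9 * t + 2.0))
    for k in (3, 7):
        b = np.roll(base, k)  # b delayed by k frames; base leads
        res = cross_correlate(base, b, frame_rate_hz=10.0, max_lag_s=1.0)
        assert res.peak_lag_s == pytest.approx(k / 10.0)
        lags, ref = brute_force_ccf(
            *(np.asarray(x) for x in _smoothed_pair(base, b)), max_lag=10)
        assert np.max(np.abs(res.ccf - ref)) < 1e-12


def _smoothed_pair(a, b):
    from wormcal.traces import moving_average

    return moving_average(a, 0.27, 10.0), moving_average(b, 0.27, 10.0)


def test_anticorrelated_delayed_signal_gives_negative_peak():
    t = np.arange(400) / 10.0
    a = np.sin(2 * np.pi * 0.3 * t)
    b = -np.roll(a, 4)
    res = cross_correlate(a, b, frame_rate_hz=10.0, max_lag_s=2.0)
    assert res.peak_value < 0
    assert res.peak_lag_s == pytest.approx(0.4)


def test_ccf_matches_brute_force_on_random_series():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = int(rng.integers(80, 160))
        a, b = rng.normal(size=n), rng.normal(size=n)
        res = cross_correlate(a, b, frame_rate_hz=10.0, max_lag_s=2.0)
        lags, ref = brute_force_ccf(*_smoothed_pair(a, b), max_lag=20)
        assert np.max(np.abs(res.ccf - ref)) < 1e-8


def test_ccf_scale_invariance():
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=200), rng.normal(size=200)
    r1 = cross_correlate(a, b, 10.0)
    r2 = cross_correlate(3.7 * a, 0.2 * b, 10.0)
    assert np.allclose(r1.ccf, r2.ccf, atol=1e-12)


def test_zero_variance_input_raises():
    with pytest.raises(ValueError):
        cross_correlate(np.ones(200), np.arange(200.0), 10.0)


def test_lag_recovery_for_generator_pairs():
    """True response lags of 0.2, 0.469 and 0.8 s are recovered to within
    one frame period at 10 fps."""
    for lag in (0.2, 0.469, 0.8):
        cfg = noiseless(GeneratorConfig(duration_s=120, seed=5))
        cfg.noise_sd = 0.5
        a = NeuronConfig.rim(name="A")
        b = NeuronConfig.rim(name="B")
        b.response_lag_s = lag
        sim = simulate_experiment(cfg, neurons=[a, b])
        from wormcal import compute_ratio

        ra = compute_ratio(sim.traces["A"]).ratio
        rb = compute_ratio(sim.traces["B"]).ratio
        res = cross_correlate(ra, rb, frame_rate_hz=cfg.frame_rate_hz)
        assert abs(res.peak_lag_s - lag) <= 0.1 + 1e-9
        assert res.peak_value > 0


def test_rim_rme_pairing_is_anticorrelated_with_rim_leading(wt_sim):
    from wormcal import compute_ratio

    rim = compute_ratio(wt_sim.traces["RIM"]).ratio
    rme = compute_ratio(wt_sim.traces["RMED"]).ratio
    res = cross_correlate(rim, rme, frame_rate_hz=10.0)
    assert res.peak_value < 0
    assert res.peak_lag_s > 0  # RIM leads RME
    assert abs(res.peak_lag_s - 0.469) <= 0.1 + 1e-9


# --- summaries ---------------------------------------------------------------


def _accepted(pct):
    t, r = _series(np.full(200, 1.0))
    res = ratio_change_reversal(t, r, _event(10.0, 3.0))
    res.change_pct = pct
    return res


def test_summarize_single_event():
    s = summarize_events([_accepted(50.0)])
    assert (s.mean, s.sem, s.n) == (50.0, 0.0, 1)


def test_summarize_hand_computed_sem():
    s = summarize_events([_accepted(v) for v in (40.0, 50.0, 60.0)])
    assert s.mean == pytest.approx(50.0)
    assert s.sem == pytest.approx(10.0 / np.sqrt(3))


def test_summarize_all_rejected_events():
    t, r = _series(np.full(200, 1.0))
    rejected = [ratio_change_reversal(t, r, _event(10.0, 1.0)) for _ in range(3)]
    s = summarize_events(rejected)
    assert s.n == 0
    assert s.n_rejected == 3
    assert np.isnan(s.mean)


def test_change_pct_scale_invariance():
    t = np.arange(200) / 10.0
    r = np.where(t < 10.0, 2.0, 1.0)
    a = ratio_change_reversal(t, r, _event(10.0, 3.0))
    b = ratio_change_reversal(t, 13.7 * r, _event(10.0, 3.0))
    assert a.change_pct == pytest.approx(b.change_pct)
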