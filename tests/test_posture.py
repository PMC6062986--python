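"""Midline geometry, bend counting, closure, and turn classification."""

import numpy as np
import pytest

from conftest import make_straight_midline
from wormcal.posture import (
    CLOSED_OMEGA,
    NO_OMEGA,
    SHALLOW_OMEGA,
    TurnEvent,
    classify_turn,
    count_body_bends,
    detect_closure,
    head_bend_angle,
    omega_success_rate,
    resample_midline,
    turning_angle,
)
from wormcal.types import MidlineSeries


# --- resampling --------------------------------------------------------------


def test_straight_segment_resamples_to_unit_spacing():
    pts = np.array([[0.0, 0.0], [5.0, 0.0], [12.0, 0.0]])
    out = resample_midline(pts)
    assert out.shape == (13, 2)
    assert np.allclose(out[:, 0], np.arange(13.0))
    assert np.allclose(out[:, 1], 0.0)


def test_semicircle_resamples_at_equal_arc_spacing():
    theta = np.linspace(0.0, np.pi, 721)
    pts = np.stack([np.cos(theta), np.sin(theta)], axis=1) * 50.0
    out = resample_midline(pts)
    chords = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert np.max(np.abs(chords - chords.mean()) / chords.mean()) < 1e-6


def test_resampling_equally_spaced_points_is_idempotent():
    pts = np.stack([np.arange(13.0) * 2.0, np.zeros(13)], axis=1)
    out = resample_midline(pts)
    assert np.max(np.abs(out - pts)) < 1e-12


def test_resample_preserves_endpoints_and_lies_on_the_curve():
    x = np.linspace(0.0, 100.0, 400)
    pts = np.stack([x, 20.0 * np.sin(x / 18.0)], axis=1)
    out = resample_midline(pts)
    assert np.allclose(out[0], pts[0], atol=1e-12)
    assert np.allclose(out[-1], pts[-1], atol=1e-12)
    # every resampled point sits on the input polyline
    for p in out:
        d_best = np.inf
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            d_best = min(d_best, np.linalg.norm(p - (a + t * ab)))
        assert d_best < 1e-9
    # points divide the input arc into 12 equal pieces
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    arcs = np.interp(out[:, 0], pts[:, 0], cum)  # x is monotone here
    assert np.max(np.abs(np.diff(arcs) - cum[-1] / 12.0)) < 1e-6 * cum[-1]


def test_zero_length_midline_is_rejected():
    with pytest.raises(ValueError):
        resample_midline(np.zeros((5, 2)))


# --- angles ------------------------------------------------------------------


def _m13_with_head(p1, p2, p3):
    rest = np.stack([np.linspace(2.0, 12.0, 10), np.zeros(10)], axis=1)
    return np.vstack([p1, p2, p3, rest])


@pytest.mark.parametrize(
    "p1,p2,p3,expected",
    [
        ((0, 0), (1, 0), (2, 0), 180.0),
        ((0, 0), (1, 0), (1, 1), 90.0),
        ((0, 0), (1, 0), (1.5, np.sqrt(3) / 2), 120.0),
    ],
)
def test_head_bend_angle_analytic_values(p1, p2, p3, expected):
    m = _m13_with_head(np.array(p1, float), np.array(p2, float), np.array(p3, float))
    assert head_bend_angle(m) == pytest.approx(expected, abs=1e-9)


def test_head_bend_angle_undefined_for_coincident_points():
    m = _m13_with_head(np.array([1.0, 0.0]), np.array([1.0, 0.0]),
                       np.array([2.0, 0.0]))
    with pytest.raises(ValueError):
        head_bend_angle(m)


def test_angle_invariance_under_rigid_transforms_and_scaling():
    rng = np.random.default_rng(11)
    m = _m13_with_head(np.array([0.3, 0.1]), np.array([1.0, 0.4]),
                       np.array([1.9, -0.2]))
    base = head_bend_angle(m)
    for _ in range(20):
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        scale = rng.uniform(0.1, 10.0)
        shift = rng.normal(size=2) * 100
        assert head_bend_angle(scale * m @ R.T + shift) == pytest.approx(base, abs=1e-9)
    # reflection leaves the unsigned angle unchanged
    assert head_bend_angle(m * [1.0, -1.0]) == pytest.approx(base, abs=1e-9)


@pytest.mark.parametrize("pre,post,expected", [(0.0, 0.0, 0.0),
                                               (0.0, 180.0, 180.0),
                                               (0.0, 90.0, 90.0)])
def test_turning_angle_between_commanded_headings(pre, post, expected):
    headings = [pre] * 20 + [post] * 20
    series = make_straight_midline(headings)
    # the "turn" happens instantaneously at t = 2 s
    ang = turning_angle(series, (2.0, 2.0), window_s=1.0)
    assert ang == pytest.approx(expected, abs=1e-9)


def test_turning_angle_requires_data_around_the_turn():
    series = make_straight_midline([0.0] * 10)
    with pytest.raises(ValueError):
        turning_angle(series, (0.95, 1.0), window_s=1.0)


# --- bends and closure -------------------------------------------------------


def test_frozen_posture_has_zero_bends():
    series = make_straight_midline([0.0] * 40, speed=0.0)
    assert count_body_bends(series, (0.0, 4.0)) == 0


def test_constructed_reversal_with_three_cycles_counts_three_bends():
    """A backward bout spanning exactly three undulation cycles (5 s at
    0.6 Hz) scores three body bends."""
    from wormcal.synthetic import GeneratorConfig, noiseless, simulate_midline
    from wormcal.types import BACKWARD, FORWARD, BehaviorTrack

    cfg = noiseless(GeneratorConfig(duration_s=25, seed=8))
    fps = cfg.frame_rate_hz
    states = [FORWARD] * int(10 * fps) + [BACKWARD] * int(5 * fps) \
        + [FORWARD] * int(10 * fps)
    track = BehaviorTrack(np.arange(len(states)) / fps,
                          np.array(states, dtype=object))
    series = simulate_midline(track, cfg)
    assert count_body_bends(series, (10.0, 15.0)) == 3


def test_subthreshold_wiggle_counts_zero_bends():
    n = 60
    t = np.arange(n) / 10.0
    s = np.linspace(0.0, 1.0, 15)
    pts = np.empty((n, 15, 2))
    for i in range(n):
        # 3 deg tangent wiggle, far below the 10 deg hysteresis threshold
        psi = np.deg2rad(3.0) * np.sin(2 * np.pi * (s - 0.6 * t[i]))
        u = np.stack([np.cos(psi), np.sin(psi)], axis=1)
        pts[i] = np.vstack([[0, 0], np.cumsum(10.0 * 0.5 * (u[:-1] + u[1:]), axis=0)])
    series = MidlineSeries(t, pts, 140.0)
    assert count_body_bends(series, (0.0, 6.0)) == 0


def _arc_series(total_turn_rad, n_points=41, L=120.0):
    s = np.linspace(0.0, 1.0, n_points)
    psi = total_turn_rad * s
    u = np.stack([np.cos(psi), np.sin(psi)], axis=1)
    ds = L / (n_points - 1)
    pts = np.vstack([[0.0, 0.0], np.cumsum(ds * 0.5 * (u[:-1] + u[1:]), axis=0)])
    return MidlineSeries(np.array([0.0, 0.1]), np.stack([pts, pts]), L)


def test_straight_worm_is_never_closed():
    series = make_straight_midline([0.0, 0.0], speed=0.0)
    dist, closed = detect_closure(series, (0.0, 0.2))
    assert dist == pytest.approx(series.body_length_px)
    assert not closed


def test_near_closed_circle_is_closed():
    series = _arc_series(6.2)  # head-tail gap ~1.6% of body length
    dist, closed = detect_closure(series, (0.0, 0.2))
    assert dist < 0.02 * series.body_length_px
    assert closed


def test_distance_exactly_at_threshold_is_not_closed():
    series = make_straight_midline([0.0, 0.0], speed=0.0)
    # min distance == threshold -> strict inequality says open
    dist, closed = detect_closure(series, (0.0, 0.2), threshold_frac=1.0)
    assert dist == pytest.approx(1.0 * series.body_length_px)
    assert not closed


# --- classification ----------------------------------------------------------


def _turn(angle, bends, closed):
    return TurnEvent(0.0, 5.0, bends, angle, 90.0, 3.0 if closed else 50.0, closed)


@pytest.mark.parametrize(
    "angle,bends,closed,expected",
    [
        (150.0, 4, True, CLOSED_OMEGA),
        (150.0, 2, False, NO_OMEGA),
        (100.0, 5, True, NO_OMEGA),
        (150.0, 4, False, SHALLOW_OMEGA),
        (120.0, 4, True, NO_OMEGA),  # strict: exactly 120 deg is not a turn
    ],
)
def test_turn_classification_rules(angle, bends, closed, expected):
    assert classify_turn(_turn(angle, bends, closed)) == expected


def test_classification_flips_only_across_the_angle_threshold():
    below = classify_turn(_turn(119.9, 4, True))
    above = classify_turn(_turn(120.1, 4, True))
    assert (below, above) == (NO_OMEGA, CLOSED_OMEGA)


def test_success_rate_conventions():
    assert omega_success_rate([CLOSED_OMEGA] * 10) == pytest.approx(1.0)
    cls = [CLOSED_OMEGA] * 84 + [SHALLOW_OMEGA] * 10 + [NO_OMEGA] * 6
    assert omega_success_rate(cls) == pytest.approx(0.84)
    assert omega_success_rate(cls, denominator="omega") == pytest.approx(84 / 94)
    with pytest.raises(ValueError):
        omega_success_rate([])


def test_deep_and_shallow_presets_contrast(wt_sim):
    """Shallow-bend cohorts show larger (straighter) head-bend angles and a
    lower closed-turn fraction than the deep wild-type preset."""
    from wormcal import score_turns
    from wormcal.synthetic import PRESETS, escape_config, simulate_experiment

    results = {}
    for preset, seed0 in (("wt", 500), ("ser2-like", 600)):
        evs = []
        for seed in range(seed0, seed0 + 14):
            gen = escape_config(duration_s=45, seed=seed,
                                **PRESETS[preset]["generator"])
            sim = simulate_experiment(gen, neurons=[])
            evs.extend(score_turns(sim.midline, sim.track))
        evs = [e for e in evs if np.isfinite(e.turning_angle_deg)]
        cls = [e.classification for e in evs]
        results[preset] = (
            float(np.mean([e.head_bend_angle_deg for e in evs])),
            omega_success_rate(cls),
        )
    assert results["wt"][0] < results["ser2-like"][0]
    assert results["wt"][1] > results["ser2-like"][1]
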