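"""Midline posture analysis and omega-turn scoring.

The worm midline is resampled to 13 points defining 12 equal arc-length
segments, with point 1 at the head tip and point 13 at the tail end.  From
these the module measures the head-bend angle (interior angle at point 2
formed by points 1-2-3; 180 deg = straight), counts body bends from the
midbody bend signal, measures the turning angle between pre-reversal and
post-turn headings, detects head-tail closure, and applies the omega-turn
classification: a sharp turn (turning angle > 120 deg) after a reversal
with three or more body bends; "closed" when the head touches the tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import MidlineSeries

OMEGA_TURN_ANGLE_DEG = 120.0
MIN_BODY_BENDS = 3
CLOSURE_FRAC = 0.05

NO_OMEGA = "no_omega"
SHALLOW_OMEGA = "shallow_omega"
CLOSED_OMEGA = "closed_omega"


@dataclass
class TurnEvent:
    """One reversal-plus-turn episode and everything scored from it."""

    rev_start_s: float
    rev_end_s: float
    bend_count: int
    turning_angle_deg: float
    head_bend_angle_deg: float  # interior angle one frame before turn initiation
    min_head_tail_dist_px: float
    closed: bool
    classification: str = ""
    qc: list[str] = field(default_factory=list)

    @property
    def head_bend_magnitude_deg(self) -> float:
        return 180.0 - self.head_bend_angle_deg


def _cumulative_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def arc_position(points: np.ndarray, frac: float) -> np.ndarray:
    """Point at arc-length fraction ``frac`` (0 = head) along a polyline."""
    cum = _cumulative_arc(points)
    total = cum[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    x = np.interp(frac * total, cum, points[:, 0])
    y = np.interp(frac * total, cum, points[:, 1])
    return np.array([x, y])


def resample_midline(points: Sequence | np.ndarray, n_points: int = 13) -> np.ndarray:
    """Resample an ordered head-to-tail polyline at equal arc spacing.

    Returns ``n_points`` points at arc positions k/(n_points-1); the 13-point
    default gives the 12-equal-segments convention (points 1..13).  Endpoints
    are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (N>=3, 2) array of points")
    cum = _cumulative_arc(pts)
    if cum[-1] <= 0:
        raise ValueError("midline collapses to zero length")
    targets = np.linspace(0.0, cum[-1], n_points)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, cum, pts[:, 0])
    out[:, 1] = np.interp(targets, cum, pts[:, 1])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def _angle_at(p_prev: np.ndarray, vertex: np.ndarray, p_next: np.ndarray) -> float:
    u = np.asarray(p_prev, float) - np.asarray(vertex, float)
    v = np.asarray(p_next, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident points: angle undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def head_bend_angle(m13: np.ndarray) -> float:
    """Interior angle at point 2 between rays to points 1 and 3, degrees.

    180 = straight; the bend magnitude is ``180 - angle``.
    """
    m13 = np.asarray(m13, dtype=float)
    return _angle_at(m13[0], m13[1], m13[2])


def _bend_signal(points13: np.ndarray, vertex: int = 6) -> float:
    """Signed midbody bend (degrees) at the given 0-based vertex:
    deviation from straight, signed by the cross product."""
    a, b, c = points13[vertex - 1], points13[vertex], points13[vertex + 1]
    ang = _angle_at(a, b, c)
    u, v = a - b, c - b
    sign = np.sign(u[0] * v[1] - u[1] * v[0])
    return float((180.0 - ang) * (sign if sign != 0 else 1.0))


def _resampled_series(series: MidlineSeries, n_points: int = 13) -> np.ndarray:
    return np.stack([resample_midline(series.points[i], n_points)
                     for i in range(series.n_frames)])


def _span_indices(t: np.ndarray, span: tuple[float, float]) -> np.ndarray:
    return np.where((t >= span[0]) & (t < span[1]))[0]


def turning_angle(
    series: MidlineSeries,
    span: tuple[float, float],
    window_s: float = 1.0,
    pre_window_s: Optional[float] = None,
    post_window_s: Optional[float] = None,
) -> float:
    """Absolute angle (degrees, [0, 180]) between the mean centroid-travel
    heading over ``window_s`` before the reversal onset and the same after
    the turn completes.

    ``span`` is ``(reversal_start_s, turn_end_s)``.  Averaging displacement
    over the window suppresses the lateral wobble of undulation; windows
    of about one undulation period cancel it best.
    """
    t = series.timestamps
    start, end = span
    cents = series.centroids()
    pre = _span_indices(t, (start - (pre_window_s or window_s), start))
    post = _span_indices(t, (end, end + (post_window_s or window_s)))
    if pre.size < 2 or post.size < 2:
        raise ValueError("insufficient data around the turn for heading windows")
    h_pre = cents[pre[-1]] - cents[pre[0]]
    h_post = cents[post[-1]] - cents[post[0]]
    n1, n2 = np.linalg.norm(h_pre), np.linalg.norm(h_post)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero displacement in a heading window")
    c = np.clip(np.dot(h_pre, h_post) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def count_body_bends(
    series: MidlineSeries,
    span: tuple[float, float],
    amplitude_threshold_deg: float = 10.0,
    smooth_window_s: float = 0.27,
    points13: Optional[np.ndarray] = None,
) -> int:
    """Count body bends in a time span as floor(Z/2), Z the number of
    sign alternations of the smoothed midbody bend signal between
    excursions exceeding the amplitude threshold (hysteresis)."""
    from .traces import moving_average

    idx = _span_indices(series.timestamps, span)
    if idx.size < 3:
        return 0
    if points13 is None:
        points13 = np.stack([resample_midline(series.points[i]) for i in idx])
    else:
        points13 = points13[idx]
    sig = np.array([_bend_signal(points13[j]) for j in range(len(idx))])
    fps = series.n_frames / (series.timestamps[-1] - series.timestamps[0] + 1e-12)
    sig = moving_average(sig, window_s=smooth_window_s, frame_rate_hz=fps)
    crossings = 0
    last = 0
    for v in sig:
        if v > amplitude_threshold_deg:
            if last == -1:
                crossings += 1
            last = 1
        elif v < -amplitude_threshold_deg:
            if last == 1:
                crossings += 1
            last = -1
    # first suprathreshold excursion opens the count
    n_excursions = crossings + (1 if last != 0 else 0)
    return int(n_excursions // 2)


def detect_closure(
    series: MidlineSeries,
    span: tuple[float, float],
    threshold_frac: float = CLOSURE_FRAC,
    points13: Optional[np.ndarray] = None,
) -> tuple[float, bool]:
    """Minimum head-to-tail (point 1 to point 13) distance over the span,
    and whether it falls strictly below ``threshold_frac`` of body length."""
    idx = _span_indices(series.timestamps, span)
    if idx.size == 0:
        raise ValueError("empty span")
    if points13 is None:
        pts = np.stack([resample_midline(series.points[i]) for i in idx])
    else:
        pts = points13[idx]
    d = np.linalg.norm(pts[:, 0] - pts[:, -1], axis=1)
    dmin = float(d.min())
    return dmin, bool(dmin < threshold_frac * series.body_length_px)


def classify_turn(
    event: TurnEvent,
    turn_threshold_deg: float = OMEGA_TURN_ANGLE_DEG,
    min_bends: int = MIN_BODY_BENDS,
) -> str:
    """Apply the omega-turn rules: not an omega turn unless the turning
    angle exceeds 120 deg after a reversal with >= 3 body bends; closed if
    the head touched the tail, shallow otherwise."""
    if event.turning_angle_deg is None or event.bend_count is None:
        raise ValueError("event fields must be populated before classification")
    if event.turning_angle_deg <= turn_threshold_deg or event.bend_count < min_bends:
        return NO_OMEGA
    return CLOSED_OMEGA if event.closed else SHALLOW_OMEGA


def omega_success_rate(
    classifications: Sequence[str],
    denominator: str = "all",
) -> float:
    """Fraction of closed omega turns.

    ``denominator='all'`` divides by every scored escape (the convention of
    per-animal scoring of the first turn); ``'omega'`` divides by events
    classified as omega turns (closed or shallow) only.
    """
    cls = list(classifications)
    if denominator == "all":
        denom = len(cls)
    elif denominator == "omega":
        denom = sum(c in (CLOSED_OMEGA, SHALLOW_OMEGA) for c in cls)
    else:
        raise ValueError("denominator must be 'all' or 'omega'")
    if denom == 0:
        raise ValueError("no scored events")
    return sum(c == CLOSED_OMEGA for c in cls) / denom


def score_turn(
    series: MidlineSeries,
    reversal_span: tuple[float, float],
    turn_span: tuple[float, float],
    heading_window_s: float = 2.0,
    bend_threshold_deg: float = 10.0,
    closure_frac: float = CLOSURE_FRAC,
    pre_limit_s: Optional[float] = None,
    post_limit_s: Optional[float] = None,
) -> TurnEvent:
    """Assemble a :class:`TurnEvent` for one reversal + turn episode.

    The head-bend angle is measured on the last frame of the reversal
    phase (the frame immediately before turn initiation).  The default
    2-s heading window spans about one undulation period so the lateral
    wobble of crawling averages out of the headings; ``pre_limit_s`` /
    ``post_limit_s`` clip the heading windows so they never reach into a
    neighboring reversal or turn.
    """
    t = series.timestamps
    qc: list[str] = []
    pts13 = _resampled_series(series)

    rev_idx = _span_indices(t, reversal_span)
    if rev_idx.size == 0:
        raise ValueError("reversal span contains no frames")
    pre_turn_frame = rev_idx[-1]
    hba = head_bend_angle(pts13[pre_turn_frame])

    bends = count_body_bends(series, reversal_span, bend_threshold_deg,
                             points13=pts13)
    pre_w = heading_window_s
    if pre_limit_s is not None:
        pre_w = min(pre_w, reversal_span[0] - pre_limit_s)
    post_w = heading_window_s
    if post_limit_s is not None:
        post_w = min(post_w, post_limit_s - turn_span[1])
    if pre_w < heading_window_s or post_w < heading_window_s:
        qc.append("heading window clipped")
    try:
        if pre_w <= 0.3 or post_w <= 0.3:
            raise ValueError("heading window too short")
        ta = turning_angle(series, (reversal_span[0], turn_span[1]),
                           window_s=heading_window_s,
                           pre_window_s=pre_w, post_window_s=post_w)
    except ValueError:
        ta = float("nan")
        qc.append("turning angle window truncated")
    dmin, closed = detect_closure(series, turn_span, closure_frac, points13=pts13)

    ev = TurnEvent(
        rev_start_s=float(reversal_span[0]),
        rev_end_s=float(reversal_span[1]),
        bend_count=bends,
        turning_angle_deg=float(ta),
        head_bend_angle_deg=float(hba),
        min_head_tail_dist_px=dmin,
        closed=closed,
        qc=qc,
    )
    ev.classification = (classify_turn(ev) if np.isfinite(ta) else NO_OMEGA)
    return ev


def turn_events_frame(events: Sequence[TurnEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rev_start_s": e.rev_start_s,
                "rev_end_s": e.rev_end_s,
                "bend_count": e.bend_count,
                "turning_angle_deg": e.turning_angle_deg,
                "head_bend_angle_deg": e.head_bend_angle_deg,
                "min_head_tail_dist_px": e.min_head_tail_dist_px,
                "closed": int(e.closed),
                "classification": e.classification,
                "qc": ";".join(e.qc),
            }
            for e in events
        ]
    )


def write_turn_events(events: Sequence[TurnEvent], path: str | Path) -> None:
    turn_events_frame(events).to_csv(path, index=False, float_format="%.17g")
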