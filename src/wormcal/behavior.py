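"""Locomotion-state segmentation from midline kinematics.

Replaces by-eye scoring of forward/backward bouts with a reproducible
criterion.  The primary per-frame statistic is the direction of body-wave
propagation: the arc-length shift that maximizes the correlation between
the curvature profiles of the surrounding frames (head-to-tail shift =
forward).  Where the wave is undetectable (straight or degenerate posture)
the fallback is the sign of the centroid velocity projected on the
tail-to-head axis.  Omega-turn frames are recognized after reversals by a
sustained deep head bend with a near-stationary centroid; near-stationary
frames without the bend become pauses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .posture import head_bend_angle, resample_midline
from .types import BACKWARD, FORWARD, OMEGA, PAUSE, BehaviorTrack, MidlineSeries


@dataclass
class SwitchEvent:
    """A label transition; ``t0`` anchors event-locked analysis windows.

    Forward-to-backward switches are ``analyzable`` only when the backward
    bout they start lasts longer than the minimum bout length (reversals
    shorter than 1.5 s are excluded from ratio-change statistics).
    """

    t0: float
    from_state: str
    to_state: str
    following_bout_duration_s: float
    analyzable: bool = True
    preceding_bout_duration_s: float | None = None


def _curvature_profile(points: np.ndarray) -> np.ndarray:
    """Turning-angle-per-segment profile of a resampled midline."""
    d = np.diff(points, axis=0)
    ang = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    return np.diff(ang)


def _shift_correlation(a: np.ndarray, b: np.ndarray,
                       max_shift: int) -> tuple[int, float, float]:
    """Integer shift of ``b`` (positive = toward the tail) maximizing the
    Pearson correlation with ``a`` over the overlap.

    Returns ``(best_shift, best_r, r_at_zero)``; the zero-shift value lets
    callers distinguish a genuinely traveling profile from one that merely
    changes amplitude in place (whose correlation peaks at zero shift).
    """
    best_shift, best_r, r0 = 0, -np.inf, 0.0
    for d in range(-max_shift, max_shift + 1):
        if d >= 0:
            aa, bb = (a[: a.size - d], b[d:]) if d else (a, b)
        else:
            aa, bb = a[-d:], b[:d]
        if aa.size < 8:
            continue
        sa, sb = aa.std(), bb.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((aa - aa.mean()) * (bb - bb.mean())) / (sa * sb))
        if d == 0:
            r0 = r
        if r > best_r + 1e-12:
            best_r, best_shift = r, d
    return best_shift, best_r, r0


def wave_direction(
    series: MidlineSeries,
    delta_frames: int = 2,
    n_profile_points: int = 25,
    max_shift_frac: float = 0.25,
) -> np.ndarray:
    """Signed wave statistic per frame: +1 forward, -1 backward, 0 undecided.

    Frame t compares the curvature profiles of frames t - delta/2 and
    t + delta/2; a positive arc-length shift means the wave travels
    head-to-tail (forward locomotion).  Returns +1 / -1 per frame, 0 for a
    tie (wave present but stationary, e.g. exactly at a turnaround), and
    NaN where no wave is detectable at all.
    """
    n = series.n_frames
    prof = np.stack([
        _curvature_profile(resample_midline(series.points[i], n_profile_points))
        for i in range(n)
    ])
    half = max(delta_frames // 2, 1)
    max_shift = max(int(round(max_shift_frac * prof.shape[1])), 2)
    stat = np.full(n, np.nan)
    for t in range(n):
        i0, i1 = max(t - half, 0), min(t + half, n - 1)
        if i0 == i1:
            continue
        a, b = prof[i0], prof[i1]
        if a.std() < 1e-12 or b.std() < 1e-12:
            continue  # no wave; leave undecided for the fallback
        shift, r, r0 = _shift_correlation(a, b, max_shift)
        # low peak correlation = no coherent profile (wave faded or noise
        # dominated): abstain and let the centroid fallback decide
        if r <= 0.6:
            continue
        # a direction call needs the shifted correlation to clearly beat
        # the zero-shift one; a profile that only changes amplitude in
        # place (e.g. a growing turn bend) is a tie, not a direction
        if shift == 0 or r - r0 < 0.05:
            stat[t] = 0.0
        else:
            stat[t] = np.sign(shift)
    return stat


def _centroid_speed(series: MidlineSeries) -> tuple[np.ndarray, np.ndarray]:
    """Centroid velocity (central difference, px/s) and a robust speed:
    the larger of the two one-sided speeds, so a frame at a motion
    boundary is still counted as moving."""
    c = series.centroids()
    t = series.timestamps
    v = np.gradient(c, t, axis=0)
    step = np.linalg.norm(np.diff(c, axis=0), axis=1) / np.diff(t)
    speed = np.zeros(t.size)
    speed[:-1] = step
    speed[1:] = np.maximum(speed[1:], step)
    # backward-looking speed: movement during the interval into each frame
    speed_in = np.concatenate([[step[0] if step.size else 0.0], step])
    return v, speed, speed_in


def _fallback_direction(series: MidlineSeries) -> np.ndarray:
    """Sign of centroid velocity projected on the tail-to-head axis."""
    v, _, _ = _centroid_speed(series)
    axis = series.points[:, 0, :] - series.points[:, -1, :]
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return np.sign((v * (axis / norm)).sum(axis=1))


def _enforce_min_bout(labels: np.ndarray, min_frames: int) -> np.ndarray:
    """Absorb runs shorter than ``min_frames`` into the preceding run
    (recording edges are left alone)."""
    out = labels.copy()
    n = out.size
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if i > 0 and j < n and (j - i) < min_frames:
            out[i:j] = out[i - 1]
        i = j
    return out


def segment_states(
    series: MidlineSeries,
    delta_frames: int = 2,
    min_bout_frames: int = 3,
    omega_bend_deg: float = 60.0,
    pause_speed_frac: float = 0.02,
) -> BehaviorTrack:
    """Label every frame forward / backward / omega / pause.

    Wave direction (with the centroid-velocity fallback) decides forward
    vs backward; short runs are absorbed by a minimum-bout filter.  After
    each backward run, a sustained (>= 2 frame) episode of head-bend
    magnitude above ``omega_bend_deg`` with a near-stationary centroid is
    an omega turn.  Remaining near-stationary frames become pauses.
    """
    if series.n_points < 13:
        raise ValueError("need at least 13 midline points per frame")
    t = series.timestamps
    if t.size < 2 or (t[-1] - t[0]) < 2.0:
        raise ValueError("need at least 2 s of midline data")
    if np.median(series.arc_lengths()) <= 0:
        raise ValueError("degenerate midline: zero arc length")

    n = series.n_frames
    body_len = float(np.median(series.arc_lengths()))
    stat = wave_direction(series, delta_frames=delta_frames)
    fallback = _fallback_direction(series)
    _, speed, speed_in = _centroid_speed(series)

    pts13 = np.stack([resample_midline(series.points[i]) for i in range(n)])
    bend_mag = np.array([180.0 - head_bend_angle(pts13[i]) for i in range(n)])

    moving = speed >= pause_speed_frac * body_len
    # NaN = no detectable wave -> centroid-velocity fallback (if moving);
    # 0 = wave present but tied -> inherit the previous decided label.
    direction = np.where(np.isnan(stat), np.where(moving, fallback, 0.0), stat)
    signs = np.sign(direction)
    # hysteresis: the running label flips only when the new sign persists
    # (no opposing call, and a second supporting call where available,
    # within the next 3 frames); lone contrary calls are noise
    labels = np.empty(n, dtype=object)
    prev = 0.0
    for i in range(n):
        s = signs[i]
        if s != 0 and s != prev:
            window = signs[i:i + 3]
            support = int(np.sum(window == s))
            opposing = int(np.sum(window == -s))
            needed = 2 if window.size >= 2 else 1
            if opposing == 0 and support >= needed:
                prev = s
        labels[i] = FORWARD if prev >= 0 else BACKWARD
    first = next((i for i in range(n) if signs[i] != 0), None)
    if first is not None and signs[first] < 0:
        labels[:first] = BACKWARD
    labels = _enforce_min_bout(labels, min_bout_frames)

    # omega turns: onset = sustained deep head bend with a stationary
    # centroid right after a reversal; the label extends until locomotion
    # resumes (the head bend relaxes while the body stays curled).
    stationary_in = speed_in < pause_speed_frac * body_len
    candidate = (bend_mag > omega_bend_deg) & stationary_in
    fps = 1.0 / float(np.median(np.diff(t)))
    lookback = max(int(round(1.5 * fps)), 3)  # a turn starts within ~1.5 s
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j < n and candidate[j]:
            j += 1
        follows_reversal = bool(np.any(labels[max(i - lookback, 0):j] == BACKWARD))
        if (j - i) >= 2 and follows_reversal:
            end = j
            while end < n and stationary_in[end]:
                end += 1
            labels[i:end] = OMEGA
            i = end
        else:
            i = j

    # pauses: stationary frames that are not part of a turn
    for i in range(n):
        if labels[i] != OMEGA and not moving[i] and bend_mag[i] <= omega_bend_deg:
            labels[i] = PAUSE

    return BehaviorTrack(t, labels)


def detect_switches(
    track: BehaviorTrack,
    min_backward_s: float = 1.5,
) -> list[SwitchEvent]:
    """One event per label transition.

    Forward-to-backward events are analyzable only if the backward bout
    exceeds ``min_backward_s`` (the bout-length filter for event-locked
    ratio statistics).
    """
    events: list[SwitchEvent] = []
    bouts = track.bouts()
    dt = 1.0 / track.frame_rate_hz
    for k in range(1, len(bouts)):
        i0, i1, state = bouts[k]
        p0, p1, prev_state = bouts[k - 1]
        duration = (i1 - i0) * dt
        analyzable = True
        if prev_state == FORWARD and state == BACKWARD:
            analyzable = duration > min_backward_s
        events.append(
            SwitchEvent(
                t0=float(track.timestamps[i0]),
                from_state=prev_state,
                to_state=state,
                following_bout_duration_s=float(duration),
                analyzable=analyzable,
                preceding_bout_duration_s=float((p1 - p0) * dt),
            )
        )
    return events


def switches_frame(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t0_s": e.t0,
                "from": e.from_state,
                "to": e.to_state,
                "bout_s": e.following_bout_duration_s,
                "analyzable": int(e.analyzable),
                "preceding_bout_s": (
                    np.nan if e.preceding_bout_duration_s is None
                    else e.preceding_bout_duration_s
                ),
            }
            for e in events
        ]
    )


def write_switches(events: Sequence[SwitchEvent], path: str | Path) -> None:
    switches_frame(events).to_csv(path, index=False, float_format="%.17g")


def read_switches(path: str | Path) -> list[SwitchEvent]:
    df = pd.read_csv(path)
    return [
        SwitchEvent(
            row["t0_s"], row["from"], row["to"], row["bout_s"],
            bool(row["analyzable"]),
            None if pd.isna(row.get("preceding_bout_s", np.nan))
            else float(row["preceding_bout_s"]),
        )
        for _, row in df.iterrows()
    ]
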