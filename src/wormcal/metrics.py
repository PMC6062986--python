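"""Event-locked ratio statistics and neuron-pair correlation analysis.

The ratio change across a reversal is ``R_backward / R_forward x 100%``,
where ``R_forward`` is the mean ratio over the 3 s of forward locomotion
from t = -4 s to -1 s before the directional switch (t = 0), ``R_backward``
the mean over the backward bout after the 2 s exclusion interval
(t = -1 s to +1 s, the rising/falling phase of the calcium transient), and
only reversals longer than 1.5 s are analyzed.  The omega-turn analogue
uses 1-s windows: the first second of the turn against the second from
-5 s to -4 s before the reference time.  Neuron-pair coupling is measured
by Pearson correlation around the switch and by the cross-correlation of
the smoothed (0.27 s boxcar), z-scored ratio series; the lag of the
extreme correlation estimates who leads whom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import SwitchEvent
from .traces import moving_average

FORWARD_WINDOW = (-4.0, -1.0)   # s, relative to the directional switch
EXCLUSION = (-1.0, 1.0)          # s, rising/falling phase, excluded
MIN_BACKWARD_S = 1.5
OMEGA_WINDOW_S = 1.0
OMEGA_REFERENCE_OFFSET = (-5.0, -4.0)  # s, relative to the reference time


@dataclass
class RatioChangeResult:
    """One event's ``R_event / R_forward x 100%`` with the windows used."""

    event_id: str
    r_forward: float
    r_event: float
    change_pct: float
    forward_window: tuple[float, float]   # absolute seconds
    event_window: tuple[float, float]
    qc: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.qc


@dataclass
class CrossCorrelationResult:
    """Correlation against lag; positive ``peak_lag_s`` means the first
    series leads the second."""

    lags_s: np.ndarray
    ccf: np.ndarray
    peak_lag_s: float
    peak_value: float


def _masked_mean(t: np.ndarray, x: np.ndarray, valid: Optional[np.ndarray],
                 lo: float, hi: float) -> tuple[float, int]:
    m = (t >= lo) & (t < hi)
    if valid is not None:
        m &= valid
    m &= np.isfinite(x)
    return (float(np.mean(x[m])), int(m.sum())) if m.any() else (np.nan, 0)


def ratio_change_reversal(
    t: np.ndarray,
    ratio: np.ndarray,
    event: SwitchEvent,
    valid: Optional[np.ndarray] = None,
    min_backward_s: float = MIN_BACKWARD_S,
    event_id: Optional[str] = None,
) -> RatioChangeResult:
    """Reversal ratio change for one forward-to-backward switch.

    QC failures (short bout, missing pre-event coverage, empty windows)
    produce a flagged result rather than an exception, so whole recordings
    can be summarized with rejected events counted.
    """
    t = np.asarray(t, float)
    ratio = np.asarray(ratio, float)
    t0 = event.t0
    qc: list[str] = []
    if event.following_bout_duration_s <= min_backward_s:
        qc.append("bout too short")
    if t0 + FORWARD_WINDOW[0] < t[0]:
        qc.append("insufficient pre-event coverage")
    if (event.preceding_bout_duration_s is not None
            and event.preceding_bout_duration_s < -FORWARD_WINDOW[0] - 1e-9):
        # the baseline window would reach into the previous reversal/turn
        qc.append("insufficient forward baseline")
    fwd = (t0 + FORWARD_WINDOW[0], t0 + FORWARD_WINDOW[1])
    bwd = (t0 + EXCLUSION[1], t0 + event.following_bout_duration_s)
    if bwd[1] > t[-1] + (t[1] - t[0]):
        qc.append("event window truncated")
    r_f, n_f = _masked_mean(t, ratio, valid, *fwd)
    r_b, n_b = _masked_mean(t, ratio, valid, *bwd)
    if not qc and (n_f == 0 or n_b == 0):
        qc.append("empty analysis window")
    change = 100.0 * r_b / r_f if not qc else np.nan
    return RatioChangeResult(
        event_id=event_id or f"rev@{t0:.2f}s",
        r_forward=r_f, r_event=r_b, change_pct=change,
        forward_window=fwd, event_window=bwd, qc=qc,
    )


def ratio_change_omega(
    t: np.ndarray,
    ratio: np.ndarray,
    omega_onset_s: float,
    reference_s: Optional[float] = None,
    valid: Optional[np.ndarray] = None,
    forward_baseline_s: Optional[float] = None,
    event_id: Optional[str] = None,
) -> RatioChangeResult:
    """Omega-turn ratio change: the first second of the turn against 1 s of
    forward locomotion from -5 s to -4 s before the reference time.

    For stimulated turns the reference is the photostimulation time; for
    spontaneous turns it defaults to the turn onset's reversal, supplied by
    the caller (or the onset itself when omitted).
    """
    t = np.asarray(t, float)
    ratio = np.asarray(ratio, float)
    ref = omega_onset_s if reference_s is None else reference_s
    qc: list[str] = []
    fwd = (ref + OMEGA_REFERENCE_OFFSET[0], ref + OMEGA_REFERENCE_OFFSET[1])
    omg = (omega_onset_s, omega_onset_s + OMEGA_WINDOW_S)
    if fwd[0] < t[0]:
        qc.append("insufficient pre-event coverage")
    if omg[1] > t[-1] + (t[1] - t[0]):
        qc.append("event window truncated")
    if (forward_baseline_s is not None
            and forward_baseline_s < -OMEGA_REFERENCE_OFFSET[0] - 1e-9):
        qc.append("insufficient forward baseline")
    r_f, n_f = _masked_mean(t, ratio, valid, *fwd)
    r_o, n_o = _masked_mean(t, ratio, valid, *omg)
    if not qc and (n_f == 0 or n_o == 0):
        qc.append("empty analysis window")
    change = 100.0 * r_o / r_f if not qc else np.nan
    return RatioChangeResult(
        event_id=event_id or f"omega@{omega_onset_s:.2f}s",
        r_forward=r_f, r_event=r_o, change_pct=change,
        forward_window=fwd, event_window=omg, qc=qc,
    )


def pairwise_correlation(
    t: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    interval: tuple[float, float],
) -> float:
    """Pearson correlation of two ratio series restricted to an interval
    (by default the +-5 s around a directional switch, chosen upstream)."""
    from scipy import stats

    t = np.asarray(t, float)
    m = (t >= interval[0]) & (t < interval[1])
    m &= np.isfinite(a) & np.isfinite(b)
    if m.sum() < 10:
        raise ValueError("interval must contain at least 10 usable frames")
    aa, bb = np.asarray(a, float)[m], np.asarray(b, float)[m]
    if aa.std() == 0 or bb.std() == 0:
        raise ValueError("zero variance in the interval: correlation undefined")
    return float(stats.pearsonr(aa, bb)[0])


def cross_correlate(
    a: np.ndarray,
    b: np.ndarray,
    frame_rate_hz: float,
    max_lag_s: float = 5.0,
    smooth_window_s: float = 0.27,
) -> CrossCorrelationResult:
    """Cross-correlation of two simultaneously recorded ratio series.

    Both series are boxcar-smoothed (window in seconds), z-scored, and
    correlated at every integer-frame lag in ``[-max_lag_s, +max_lag_s]``
    with the biased (divide-by-N) estimator.  The peak is the lag of
    maximum ``|ccf|`` (ties broken toward zero lag); a positive peak lag
    means the first series leads the second.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("series must share timestamps")
    n = a.size
    max_lag = int(round(max_lag_s * frame_rate_hz))
    if n <= 2 * max_lag:
        raise ValueError("series too short for the requested maximum lag")
    if smooth_window_s > 0:
        a = moving_average(a, smooth_window_s, frame_rate_hz)
        b = moving_average(b, smooth_window_s, frame_rate_hz)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance after smoothing")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()

    lags = np.arange(-max_lag, max_lag + 1)
    ccf = np.empty(lags.size)
    for i, lag in enumerate(lags):
        # positive lag: does a(t) match b(t + lag)?  then a leads by lag
        if lag >= 0:
            ccf[i] = float(np.dot(az[: n - lag], bz[lag:]) / n)
        else:
            ccf[i] = float(np.dot(az[-lag:], bz[: n + lag]) / n)
    order = np.lexsort((np.abs(lags), -np.abs(ccf)))
    best = order[0]
    return CrossCorrelationResult(
        lags_s=lags / frame_rate_hz,
        ccf=ccf,
        peak_lag_s=float(lags[best] / frame_rate_hz),
        peak_value=float(ccf[best]),
    )


@dataclass
class EventSummary:
    mean: float
    sem: float
    n: int
    n_rejected: int
    values: list[float]


def summarize_events(results: Sequence[RatioChangeResult]) -> EventSummary:
    """Mean +- SEM over accepted events; QC-rejected events are counted
    separately and never enter the mean."""
    vals = [r.change_pct for r in results if r.accepted and np.isfinite(r.change_pct)]
    n_rej = len(results) - len(vals)
    if not vals:
        return EventSummary(math.nan, math.nan, 0, n_rej, [])
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return EventSummary(mean, sem, len(vals), n_rej, vals)


def results_frame(results: Sequence[RatioChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "R_forward": r.r_forward,
                "R_event": r.r_event,
                "change_pct": r.change_pct,
                "fwd_start_s": r.forward_window[0],
                "fwd_end_s": r.forward_window[1],
                "event_start_s": r.event_window[0],
                "event_end_s": r.event_window[1],
                "qc": ";".join(r.qc),
            }
            for r in results
        ]
    )


def write_results(results: Sequence[RatioChangeResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, index=False, float_format="%.17g")


def write_ccf(res: CrossCorrelationResult, path: str | Path) -> None:
    pd.DataFrame({"lag_s": res.lags_s, "ccf": res.ccf}).to_csv(
        path, index=False, float_format="%.17g"
    )
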