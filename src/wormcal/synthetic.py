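"""Synthetic freely-moving worm recordings with known ground truth.

The generator emulates the structure of a head-neuron calcium-imaging
experiment in *C. elegans*: a semi-Markov locomotion state sequence
(forward / backward / omega), undulatory midline kinematics built by
tangent-angle integration (so the body is exactly inextensible), neuron
activity that relaxes toward a state-dependent target with a configurable
response lag, two-channel fluorescence with shared multiplicative motion
artifacts, optional photobleaching and additive noise, and optionally a
rendered two-channel image stack with Gaussian soma blobs.

Everything random is drawn from a ``numpy`` generator seeded from
``GeneratorConfig.seed``, with a fixed stream per stage and per neuron, so
outputs are bit-identical across runs for a fixed config.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .types import (
    BACKWARD,
    FORWARD,
    OMEGA,
    BehaviorTrack,
    GroundTruth,
    ImageStack,
    MidlineSeries,
    NeuronTrace,
)

# Per-stage RNG stream keys (spawn keys off the config seed).
_STREAM_STATES = 0
_STREAM_MIDLINE = 1
_STREAM_CALCIUM = 2
_STREAM_RENDER = 3


def _rng(seed: int, stream: int, name: str | None = None) -> np.random.Generator:
    key = (stream,) if name is None else (stream, zlib.crc32(name.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic recording.

    Frame rates mirror the 7-15 fps range of tracking-microscope recordings;
    dwell means give bout statistics of spontaneous crawling (forward bouts
    of several seconds, reversals of a couple of seconds, brief omega
    turns).  Omega-turn shape parameters control how deeply the body curls
    (total tangent turn, radians), how sharply the head bends at turn
    initiation (degrees), and how far the heading rotates across the turn.
    """

    frame_rate_hz: float = 10.0
    duration_s: float = 60.0
    seed: int = 0
    dwell_mean_s: dict = field(
        default_factory=lambda: {FORWARD: 8.0, BACKWARD: 3.0, OMEGA: 2.0}
    )
    backward_min_s: float = 2.0
    omega_min_s: float = 2.0
    omega_prob: float = 0.5
    # kinematics
    wave_amplitude: float = 0.08     # lateral amplitude, fraction of body length
    wavelength: float = 0.9          # fraction of body length
    body_length_px: float = 300.0
    n_midline_points: int = 25
    undulation_hz: dict = field(
        default_factory=lambda: {FORWARD: 0.6, BACKWARD: 0.6}
    )
    speed_blps: float = 0.15         # centroid speed, body lengths / s
    midline_noise_px: float = 0.5
    # omega-turn shape (wild-type defaults; presets override).  At its
    # deepest the turn is a constant-curvature curl of the whole body with
    # total turn Theta, whose head-tail gap is |2 sin(Theta/2) / Theta| of
    # body length; the 5% closure threshold is met for Theta in
    # [5.98, 6.62] rad; the ramp sweeps every depth up to the event's
    # peak, so a turn closes when its peak curl exceeds ~5.98 rad and
    # N(6.20, 0.22) closes ~84% of wild-type turns.
    omega_curl_mean_rad: float = 6.20
    omega_curl_sd_rad: float = 0.22
    omega_head_bend_deg: float = 120.0
    omega_head_bend_sd_deg: float = 10.0
    omega_turn_mean_deg: float = 160.0
    omega_turn_sd_deg: float = 12.0
    omega_pre_bend_s: float = 0.8
    # fluorescence
    noise_sd: float = 3.0            # additive counts per channel per frame
    motion_artifact_amp: float = 0.1
    motion_artifact_hz: float = 0.7
    bleach_tau_s: Optional[float | tuple] = None

    def validate(self) -> None:
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be positive")
        if not (7.0 <= self.frame_rate_hz <= 15.0):
            raise ValueError("frame_rate_hz must lie in the supported 7-15 fps range")
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        if any(v < 0 for v in self.dwell_mean_s.values()):
            raise ValueError("dwell means must be non-negative (0 disables the state)")
        if not (0.0 <= self.omega_prob <= 1.0):
            raise ValueError("omega_prob must lie in [0, 1]")
        if not (0.0 <= self.motion_artifact_amp < 1.0):
            raise ValueError("motion_artifact_amp must lie in [0, 1)")
        if self.n_midline_points < 13:
            raise ValueError("need at least 13 midline points")
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass
class NeuronConfig:
    """Signal model for one neuron.

    ``polarity`` maps locomotion states to the activity target:
    ``forward_high`` (RME-like: active in forward, suppressed in backward
    and omega) or ``backward_high`` (RIM-like).  ``suppression_factor`` is
    the asymptotic ratio of suppressed to active fluorescence ratio; when
    given, ``activity_low`` is derived from it so that the steady-state
    event-locked ratio change equals ``100 * suppression_factor`` %.
    ``response_lag_s`` delays the state signal feeding the activity
    relaxation, modeling a neuron downstream in the circuit.
    """

    name: str = "RMED"
    polarity: str = "forward_high"   # or "backward_high"
    activity_high: float = 0.9
    activity_low: float = 0.13
    suppression_factor: Optional[float] = None
    response_lag_s: float = 0.0
    tau_on_s: float = 0.35
    tau_off_s: float = 0.7
    baseline_green: float = 120.0
    baseline_red: float = 150.0
    gain_alpha: float = 2.0
    soma_arc_position: float = 0.10

    def __post_init__(self) -> None:
        if self.suppression_factor is not None:
            s = self.suppression_factor
            lo = ((1.0 + self.gain_alpha * self.activity_high) * s - 1.0) / self.gain_alpha
            self.activity_low = float(np.clip(lo, 0.0, self.activity_high))
        if not (0.0 <= self.activity_low <= self.activity_high <= 1.0):
            raise ValueError("require 0 <= activity_low <= activity_high <= 1")
        if self.tau_on_s <= 0 or self.tau_off_s <= 0:
            raise ValueError("time constants must be positive")
        if self.baseline_green <= 0 or self.baseline_red <= 0:
            raise ValueError("channel baselines must be positive")
        if self.polarity not in ("forward_high", "backward_high"):
            raise ValueError("polarity must be forward_high or backward_high")

    @classmethod
    def rme(cls, name: str = "RMED", suppression_factor: float = 0.45,
            response_lag_s: float = 0.469, **kw) -> "NeuronConfig":
        """RME-like preset: forward-active, suppressed in reversals/turns,
        responding after the RIM-to-RME lag (469 ms by default)."""
        return cls(name=name, polarity="forward_high",
                   suppression_factor=suppression_factor,
                   response_lag_s=response_lag_s, soma_arc_position=0.10, **kw)

    @classmethod
    def rim(cls, name: str = "RIM", **kw) -> "NeuronConfig":
        """RIM-like preset: active in backward/omega, zero lag."""
        kw.setdefault("suppression_factor", 0.45)
        return cls(name=name, polarity="backward_high",
                   response_lag_s=0.0, soma_arc_position=0.22, **kw)

    @property
    def steady_ratio_change_pct(self) -> float:
        """Asymptotic suppressed/active fluorescence-ratio change, percent."""
        hi = 1.0 + self.gain_alpha * self.activity_high
        lo = 1.0 + self.gain_alpha * self.activity_low
        return 100.0 * lo / hi


# Strain-like presets: only suppression / posture-depth parameters change.
PRESETS: dict[str, dict] = {
    "wt": {"suppression_factor": 0.45, "generator": {}},
    "tbh1-like": {"suppression_factor": 0.45, "generator": {}},
    "tdc1-like": {"suppression_factor": 1.0, "generator": {}},
    "ser2-like": {
        "suppression_factor": 0.80,
        "generator": {
            "omega_head_bend_deg": 50.0,
            "omega_head_bend_sd_deg": 8.0,
            "omega_curl_mean_rad": 6.07,
            "omega_curl_sd_rad": 0.30,
            "omega_turn_mean_deg": 145.0,
            "omega_turn_sd_deg": 15.0,
        },
    },
}


def preset_config(name: str, **overrides) -> tuple[GeneratorConfig, float]:
    """Return ``(GeneratorConfig, rme_suppression_factor)`` for a named preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    cfg = GeneratorConfig(**{**p["generator"], **overrides})
    return cfg, p["suppression_factor"]


def escape_config(**overrides) -> GeneratorConfig:
    """Conditions of a touch-evoked escape assay: long reversals (enough
    undulation cycles to count three or more body bends) always followed
    by an omega turn."""
    kw = dict(
        dwell_mean_s={FORWARD: 8.0, BACKWARD: 7.0, OMEGA: 2.0},
        backward_min_s=6.0,
        omega_prob=1.0,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


# ---------------------------------------------------------------------------
# state sequence


def simulate_state_sequence(config: GeneratorConfig) -> BehaviorTrack:
    """Draw a forward -> backward -> (omega) -> forward bout sequence.

    Dwell times are exponential with per-state means; backward dwells are
    clipped below at ``backward_min_s`` and omega dwells at ``omega_min_s``.
    A state with dwell mean 0 is skipped entirely.  Omega bouts occur only
    immediately after backward bouts, with probability ``omega_prob``.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_STATES)
    n = int(round(config.duration_s * config.frame_rate_hz))
    t = np.arange(n) * config.dt

    bouts: list[tuple[float, str]] = []  # (duration_s, state)
    total = 0.0
    mean_f = config.dwell_mean_s.get(FORWARD, 8.0)
    mean_b = config.dwell_mean_s.get(BACKWARD, 3.0)
    mean_o = config.dwell_mean_s.get(OMEGA, 2.0)
    while total < config.duration_s:
        d_f = rng.exponential(mean_f) if mean_f > 0 else config.duration_s
        bouts.append((d_f, FORWARD))
        total += d_f
        if mean_b <= 0:
            continue
        d_b = max(rng.exponential(mean_b), config.backward_min_s)
        bouts.append((d_b, BACKWARD))
        total += d_b
        if mean_o > 0 and rng.random() < config.omega_prob:
            d_o = max(rng.exponential(mean_o), config.omega_min_s)
            bouts.append((d_o, OMEGA))
            total += d_o

    edges = np.cumsum([0.0] + [d for d, _ in bouts])
    labels = np.empty(n, dtype=object)
    idx = np.searchsorted(edges, t, side="right") - 1
    idx = np.clip(idx, 0, len(bouts) - 1)
    for i in range(n):
        labels[i] = bouts[idx[i]][1]
    return BehaviorTrack(t, labels)


# ---------------------------------------------------------------------------
# midline kinematics


@dataclass
class _OmegaEvent:
    rev_start: int      # first backward frame of the preceding reversal
    start: int          # first omega frame
    end: int            # one past the last omega frame
    bend_start: int     # first frame of the head-bend schedule (in the reversal)
    curl_rad: float
    head_bend_rad: float
    turn_rad: float     # signed heading rotation across the turn
    sign: float


def _omega_schedule(track: BehaviorTrack, config: GeneratorConfig,
                    rng: np.random.Generator) -> list[_OmegaEvent]:
    events = []
    bouts = track.bouts()
    for k, (i0, i1, state) in enumerate(bouts):
        if state != OMEGA:
            continue
        rev_start = i0
        if k > 0 and bouts[k - 1][2] == BACKWARD:
            rev_start = bouts[k - 1][0]
        pre = int(round(config.omega_pre_bend_s * config.frame_rate_hz))
        bend_start = max(i0 - pre, rev_start)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        curl = rng.normal(config.omega_curl_mean_rad, config.omega_curl_sd_rad)
        head = np.deg2rad(
            max(rng.normal(config.omega_head_bend_deg, config.omega_head_bend_sd_deg), 0.0)
        )
        turn = np.deg2rad(abs(rng.normal(config.omega_turn_mean_deg, config.omega_turn_sd_deg)))
        events.append(_OmegaEvent(rev_start, i0, i1, bend_start, curl, head, sign * turn, sign))
    return events


def _omega_envelopes(n: int, events: list["_OmegaEvent"]):
    """Per-frame envelopes of the two omega-turn shape components.

    The concentrated head bend ramps up through the late reversal (the
    sharp bend that initiates the turn), peaks on the frame before turn
    onset, and relaxes over the first 30% of the turn; the whole-body curl
    rises over the first 35%, holds its full depth through mid-turn (where
    the body is a constant-curvature arc and closure is decided), and
    unwinds over the last 35%.  The normal undulation fades as either
    component grows (the turn is its own motor program), returning as the
    body straightens.
    """
    w_head = np.zeros(n)
    w_curl = np.zeros(n)
    which = np.full(n, -1)
    for e_idx, ev in enumerate(events):
        pre = max(ev.start - ev.bend_start, 1)
        for i in range(ev.bend_start, ev.start):
            w_head[i] = np.sin(0.5 * np.pi * (i - ev.bend_start + 1) / pre)
            which[i] = e_idx
        dur = ev.end - ev.start
        for i in range(ev.start, ev.end):
            tau = (i - ev.start + 0.5) / dur
            w_head[i] = np.cos(0.5 * np.pi * min(tau / 0.3, 1.0))
            if tau < 0.35:
                w_curl[i] = np.sin(0.5 * np.pi * tau / 0.35)
            elif tau <= 0.65:
                w_curl[i] = 1.0
            else:
                w_curl[i] = np.cos(0.5 * np.pi * (tau - 0.65) / 0.35)
            which[i] = e_idx
    return w_head, w_curl, which


def simulate_midline(track: BehaviorTrack, config: GeneratorConfig,
                     return_events: bool = False):
    """Generate midline coordinates consistent with the state sequence.

    The body is built per frame by integrating tangent angles over arc
    length, so arc length is exactly the configured body length.  A
    traveling sinusoid propagates head-to-tail during forward frames and
    tail-to-head during backward frames (omega frames keep the forward
    direction); omega turns superimpose a ramped concentrated head bend
    (started late in the preceding reversal) and a distributed body curl
    that brings the head close to the tail, while the heading rotates by
    the event's turning angle.
    """
    config.validate()
    if track.n_frames == 0:
        raise ValueError("behavior track is empty")
    rng = _rng(config.seed, _STREAM_MIDLINE)
    n = track.n_frames
    dt = config.dt
    L = config.body_length_px
    P = config.n_midline_points
    s = np.linspace(0.0, 1.0, P)
    ds = L / (P - 1)
    theta_w = 2.0 * np.pi * config.wave_amplitude / config.wavelength
    k_wave = 2.0 * np.pi / config.wavelength

    f_u = {
        FORWARD: config.undulation_hz.get(FORWARD, 0.6),
        BACKWARD: config.undulation_hz.get(BACKWARD, 0.6),
        OMEGA: config.undulation_hz.get(FORWARD, 0.6),
        "pause": 0.0,
    }
    wave_dir = {FORWARD: 1.0, BACKWARD: -1.0, OMEGA: 1.0, "pause": 0.0}
    move_dir = {FORWARD: 1.0, BACKWARD: -1.0, OMEGA: 0.0, "pause": 0.0}

    events = _omega_schedule(track, config, rng)
    w_head, w_curl, curl_of = _omega_envelopes(n, events)

    # wave phase and heading bookkeeping
    phase = np.zeros(n)
    heading = np.zeros(n)
    heading[0] = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(1, n):
        st = str(track.states[i])
        phase[i] = phase[i - 1] + wave_dir[st] * 2.0 * np.pi * f_u[st] * dt
        dphi = 0.0
        if st == OMEGA:
            ev = next(e for e in events if e.start <= i < e.end)
            dphi = ev.turn_rad / (ev.end - ev.start)
        heading[i] = heading[i - 1] + dphi

    # centroid path
    centroid = np.zeros((n, 2))
    for i in range(1, n):
        st = str(track.states[i])
        step = move_dir[st] * config.speed_blps * L * dt
        centroid[i] = centroid[i - 1] + step * np.array(
            [np.cos(heading[i]), np.sin(heading[i])]
        )

    # per-frame construction by tangent integration
    head_step = np.clip((s - 0.04) / 0.10, 0.0, 1.0)   # concentrated near head
    curl_ramp = s                                       # uniform whole-body curl
    pts = np.empty((n, P, 2))
    for i in range(n):
        wave_scale = max(0.0, 1.0 - max(w_head[i], w_curl[i]))
        psi = heading[i] + np.pi + wave_scale * theta_w * np.sin(k_wave * s - phase[i])
        if curl_of[i] >= 0:
            ev = events[curl_of[i]]
            psi = psi + ev.sign * (
                w_head[i] * ev.head_bend_rad * head_step
                + w_curl[i] * ev.curl_rad * curl_ramp
            )
        u = np.stack([np.cos(psi), np.sin(psi)], axis=1)
        raw = np.vstack([[0.0, 0.0], np.cumsum(0.5 * (u[:-1] + u[1:]) * ds, axis=0)])
        pts[i] = raw - raw.mean(axis=0) + centroid[i]

    if config.midline_noise_px > 0:
        pts = pts + rng.normal(0.0, config.midline_noise_px, size=pts.shape)

    series = MidlineSeries(track.timestamps.copy(), pts, L)
    if return_events:
        return series, events
    return series


# ---------------------------------------------------------------------------
# calcium dynamics and two-channel fluorescence


def _state_target(track: BehaviorTrack, neuron: NeuronConfig) -> np.ndarray:
    high = {FORWARD} if neuron.polarity == "forward_high" else {BACKWARD, OMEGA}
    return np.where(
        np.isin(track.states.astype(str), list(high)),
        neuron.activity_high,
        neuron.activity_low,
    ).astype(float)


def simulate_calcium(
    track: BehaviorTrack,
    neuron: NeuronConfig,
    config: GeneratorConfig,
    midline: Optional[MidlineSeries] = None,
) -> tuple[GroundTruth, NeuronTrace]:
    """Generate a two-channel trace for one neuron plus its ground truth.

    Activity relaxes first-order toward the state target evaluated at
    ``t - response_lag_s`` (``tau_on_s`` rising, ``tau_off_s`` falling).
    The green channel scales as ``baseline * (1 + gain_alpha * a(t))``;
    the red reference is calcium-insensitive.  A multiplicative motion
    artifact is shared between channels (it cancels exactly in the ratio);
    additive Gaussian noise and optional per-channel exponential
    photobleaching complete the model.
    """
    config.validate()
    dt = config.dt
    if neuron.tau_on_s <= dt or neuron.tau_off_s <= dt:
        warnings.warn("calcium time constants at or below one frame period; "
                      "dynamics are under-resolved", stacklevel=2)
    rng = _rng(config.seed, _STREAM_CALCIUM, neuron.name)
    t = track.timestamps
    n = t.size

    target = _state_target(track, neuron)
    lagged = np.interp(t - neuron.response_lag_s, t, target)
    a = np.empty(n)
    a[0] = lagged[0]
    for i in range(1, n):
        tau = neuron.tau_on_s if lagged[i] > a[i - 1] else neuron.tau_off_s
        a[i] = a[i - 1] + dt * (lagged[i] - a[i - 1]) / tau
    a = np.clip(a, 0.0, 1.0)

    bleach_g = bleach_r = np.ones(n)
    if config.bleach_tau_s is not None:
        taus = config.bleach_tau_s
        tau_g, tau_r = (taus if isinstance(taus, (tuple, list)) else (taus, taus))
        bleach_g = np.exp(-t / tau_g)
        bleach_r = np.exp(-t / tau_r)

    artifact = 1.0 + config.motion_artifact_amp * np.sin(
        2.0 * np.pi * config.motion_artifact_hz * t + rng.uniform(0.0, 2.0 * np.pi)
    )

    green_clean = neuron.baseline_green * (1.0 + neuron.gain_alpha * a) * bleach_g
    red_clean = neuron.baseline_red * bleach_r
    green = green_clean * artifact + rng.normal(0.0, config.noise_sd, n)
    red = red_clean * artifact + rng.normal(0.0, config.noise_sd, n)

    clean_ratio = green_clean / red_clean
    truth = GroundTruth(
        activity={neuron.name: a},
        true_states=track,
        true_lag_s={neuron.name: neuron.response_lag_s},
        true_ratio_change_pct={neuron.name: _true_event_changes(track, clean_ratio)},
        clean_ratio={neuron.name: clean_ratio},
    )
    if midline is not None:
        truth.soma_paths[neuron.name] = _soma_path(midline, neuron.soma_arc_position)

    trace = NeuronTrace(t.copy(), green, red, name=neuron.name)
    return truth, trace


def _window_mean(t: np.ndarray, x: np.ndarray, lo: float, hi: float) -> float:
    m = (t >= lo) & (t < hi)
    return float(np.mean(x[m])) if m.any() else np.nan


def _true_event_changes(track: BehaviorTrack, clean_ratio: np.ndarray) -> list[dict]:
    """Noise-free event-locked ratio changes with the analysis windows:
    reversals use R over [t0-4, t0-1] vs [t0+1, bout end]; omega turns use
    1-s windows at turn onset vs [rev_onset-5, rev_onset-4]."""
    t = track.timestamps
    dt = t[1] - t[0]
    out = []
    bouts = track.bouts()

    def _dur(k: int) -> float:
        return (bouts[k][1] - bouts[k][0]) * dt

    for k, (i0, i1, state) in enumerate(bouts):
        if state == BACKWARD and k > 0 and bouts[k - 1][2] == FORWARD:
            t0 = t[i0]
            t_end = t[i1 - 1] + dt
            # needs a clean 4-s forward baseline and an analyzable bout
            if t0 - 4.0 < t[0] or (t_end - t0) <= 1.5 or _dur(k - 1) < 4.0:
                continue
            r_f = _window_mean(t, clean_ratio, t0 - 4.0, t0 - 1.0)
            r_b = _window_mean(t, clean_ratio, t0 + 1.0, t_end)
            if np.isfinite(r_f) and np.isfinite(r_b):
                out.append({"kind": "reversal", "t0": float(t0),
                            "change_pct": 100.0 * r_b / r_f})
        elif state == OMEGA and k > 1 and bouts[k - 1][2] == BACKWARD:
            onset = t[i0]
            rev_onset = t[bouts[k - 1][0]]
            # the 1-s reference must lie inside forward locomotion
            if rev_onset - 5.0 < t[0] or bouts[k - 2][2] != FORWARD or _dur(k - 2) < 5.0:
                continue
            r_o = _window_mean(t, clean_ratio, onset, onset + 1.0)
            r_f = _window_mean(t, clean_ratio, rev_onset - 5.0, rev_onset - 4.0)
            if np.isfinite(r_o) and np.isfinite(r_f):
                out.append({"kind": "omega", "t0": float(onset),
                            "change_pct": 100.0 * r_o / r_f})
    return out


def _soma_path(midline: MidlineSeries, arc_frac: float) -> np.ndarray:
    """Soma position at a fixed arc-length fraction from the head."""
    from .posture import arc_position

    return np.stack([arc_position(midline.points[i], arc_frac)
                     for i in range(midline.n_frames)])


# ---------------------------------------------------------------------------
# rendering


def render_stack(
    midline: MidlineSeries,
    truths: GroundTruth,
    traces: list[NeuronTrace],
    config: GeneratorConfig,
    shape: tuple[int, int] = (128, 128),
    blob_sigma_px: float = 2.5,
    background: float = 10.0,
    fov_jitter_px: float = 1.0,
    noise: str = "gaussian",
) -> ImageStack:
    """Render neurons as Gaussian blobs into a two-channel stack.

    The field of view follows the soma cluster (as a tracking microscope
    would), with smooth residual jitter; per-frame in-frame soma positions
    are stored in ``meta['frame_paths']`` for use as tracking ground truth.
    Blob peak amplitude equals the trace's channel intensity for that
    frame over a constant background.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_RENDER)
    H, W = shape
    n = midline.n_frames
    names = [tr.name for tr in traces]
    for nm in names:
        if nm not in truths.soma_paths:
            raise ValueError(f"no soma path recorded for neuron {nm!r}")
    if names:
        paths = np.stack([truths.soma_paths[nm] for nm in names])  # (N, T, 2)
        # the FOV tracks the soma cluster exactly (as the real-time
        # tracking stage would), leaving only residual jitter in frame
        # coordinates
        fov = paths.mean(axis=0)
    else:
        paths = np.zeros((0, n, 2))
        fov = np.zeros((n, 2))
    if fov_jitter_px > 0:
        jitter = rng.normal(0.0, 1.0, (n, 2)).cumsum(axis=0)
        for d in range(2):
            jitter[:, d] -= jitter[:, d].mean()
            sd = jitter[:, d].std()
            if sd > 0:
                jitter[:, d] *= fov_jitter_px / sd
        fov = fov + jitter

    center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    frame_paths = paths - fov[None, :, :] + center  # (N, T, 2), x-y order

    yy, xx = np.mgrid[0:H, 0:W]
    green = np.full((n, H, W), background, dtype=float)
    red = np.full((n, H, W), background, dtype=float)
    clipped = []
    for i in range(n):
        for j, tr in enumerate(traces):
            x, y = frame_paths[j, i]
            if not (0 <= x < W and 0 <= y < H):
                clipped.append((i, tr.name))
            blob = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * blob_sigma_px**2))
            green[i] += tr.green[i] * blob
            red[i] += tr.red[i] * blob
    if clipped:
        warnings.warn(f"{len(clipped)} soma positions fell outside the frame "
                      "and were clipped", stacklevel=2)

    if noise == "gaussian" and config.noise_sd > 0:
        green += rng.normal(0.0, config.noise_sd, green.shape)
        red += rng.normal(0.0, config.noise_sd, red.shape)
    elif noise == "poisson":
        green = rng.poisson(np.clip(green, 0, None)).astype(float)
        red = rng.poisson(np.clip(red, 0, None)).astype(float)

    meta = {
        "seed": config.seed,
        "blob_sigma_px": blob_sigma_px,
        "background": background,
        "neurons": names,
        "frame_paths": {nm: frame_paths[j].tolist() for j, nm in enumerate(names)},
        "clipped": clipped,
    }
    return ImageStack(
        green=np.clip(np.round(green), 0, 65535).astype(np.uint16),
        red=np.clip(np.round(red), 0, 65535).astype(np.uint16),
        timestamps=midline.timestamps.copy(),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# one-call experiment


@dataclass
class SimulatedExperiment:
    config: GeneratorConfig
    track: BehaviorTrack
    midline: MidlineSeries
    truth: GroundTruth
    traces: dict[str, NeuronTrace]
    stack: Optional[ImageStack] = None


def simulate_experiment(
    config: GeneratorConfig,
    neurons: Optional[list[NeuronConfig]] = None,
    render: bool = False,
    **render_kw,
) -> SimulatedExperiment:
    """Full synthetic recording: states, midline, traces (RME + RIM by
    default), merged ground truth, and optionally a rendered stack."""
    if neurons is None:
        neurons = [NeuronConfig.rme(), NeuronConfig.rim()]
    track = simulate_state_sequence(config)
    midline, events = simulate_midline(track, config, return_events=True)
    truth = GroundTruth(true_states=track)
    traces: dict[str, NeuronTrace] = {}
    for nc in neurons:
        tr_truth, trace = simulate_calcium(track, nc, config, midline=midline)
        truth.activity.update(tr_truth.activity)
        truth.true_lag_s.update(tr_truth.true_lag_s)
        truth.true_ratio_change_pct.update(tr_truth.true_ratio_change_pct)
        truth.clean_ratio.update(tr_truth.clean_ratio)
        truth.soma_paths.update(tr_truth.soma_paths)
        traces[nc.name] = trace
    dt = config.dt
    truth.turn_truth = [
        {
            "rev_start_s": float(track.timestamps[ev.rev_start]),
            "onset_s": float(track.timestamps[ev.start]),
            "end_s": float(track.timestamps[ev.end - 1] + dt),
            "curl_rad": float(ev.curl_rad),
            "head_bend_deg": float(np.rad2deg(ev.head_bend_rad)),
            "turn_deg": float(abs(np.rad2deg(ev.turn_rad))),
            "undulation_cycles": float(
                (ev.start - ev.rev_start) * dt * config.undulation_hz.get(BACKWARD, 0.6)
            ),
        }
        for ev in events
    ]
    stack = None
    if render:
        stack = render_stack(midline, truth, list(traces.values()), config, **render_kw)
    return SimulatedExperiment(config, track, midline, truth, traces, stack)


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of a config with all stochastic corruption switched off."""
    return replace(config, midline_noise_px=0.0, noise_sd=0.0,
                   motion_artifact_amp=0.0)
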