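"""End-to-end orchestration: simulate -> extract -> segment -> analyze ->
score turns -> report.

Every stage writes its intermediate table as CSV in the output directory,
so a report can be regenerated from saved intermediates, and a run with a
fixed seed is byte-identical across invocations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import behavior, metrics, posture, synthetic, traces as tr
from .types import BACKWARD, FORWARD, OMEGA, BehaviorTrack, MidlineSeries, NeuronTrace


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either simulate (``preset`` + ``seed`` + ``duration_s``) or analyze
    existing files (``midline_csv`` and/or ``trace_csvs``).  Thresholds
    are the bout-length filter for reversal analysis, the head-bend
    threshold for omega labeling, and the head-tail closure fraction.
    """

    out_dir: str = "wormcal_out"
    preset: str = "wt"
    seed: int = 0
    duration_s: float = 60.0
    midline_csv: Optional[str] = None
    trace_csvs: list = field(default_factory=list)
    min_backward_s: float = 1.5
    omega_bend_deg: float = 60.0
    closure_frac: float = 0.05
    render: bool = False
    generator_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.min_backward_s <= 0 or self.omega_bend_deg <= 0 or self.closure_frac <= 0:
            raise ValueError("thresholds must be positive")
        if self.preset not in synthetic.PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        for p in [self.midline_csv, *self.trace_csvs]:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _simulate(cfg: RunConfig) -> synthetic.SimulatedExperiment:
    gen, suppression = synthetic.preset_config(
        cfg.preset, seed=cfg.seed, duration_s=cfg.duration_s,
        **cfg.generator_overrides,
    )
    neurons = [
        synthetic.NeuronConfig.rme(suppression_factor=suppression),
        synthetic.NeuronConfig.rim(),
    ]
    return synthetic.simulate_experiment(gen, neurons, render=cfg.render)


def _extract(sim: synthetic.SimulatedExperiment, cfg: RunConfig) -> dict[str, NeuronTrace]:
    out: dict[str, NeuronTrace] = {}
    if cfg.render and sim.stack is not None:
        for name in sim.traces:
            init = np.asarray(sim.stack.meta["frame_paths"][name][0])
            path = tr.track_roi(sim.stack, tuple(init))
            trace = tr.measure_trace(sim.stack, path, name=name)
            out[name] = tr.compute_ratio(trace)
    else:
        for name, trace in sim.traces.items():
            out[name] = tr.compute_ratio(trace)
    return out


def _analyze(
    track: BehaviorTrack,
    extracted: dict[str, NeuronTrace],
    cfg: RunConfig,
) -> dict:
    switches = behavior.detect_switches(track, min_backward_s=cfg.min_backward_s)
    reversal: dict[str, list[metrics.RatioChangeResult]] = {}
    omega: dict[str, list[metrics.RatioChangeResult]] = {}
    bouts = track.bouts()
    dt = 1.0 / track.frame_rate_hz
    for name, trace in extracted.items():
        revs = [
            metrics.ratio_change_reversal(
                trace.timestamps, trace.ratio, ev,
                valid=trace.valid, min_backward_s=cfg.min_backward_s,
            )
            for ev in switches
            if ev.from_state == FORWARD and ev.to_state == BACKWARD
        ]
        omgs = []
        for k, (i0, i1, st) in enumerate(bouts):
            if st == OMEGA and k > 0 and bouts[k - 1][2] == BACKWARD:
                baseline = (
                    (bouts[k - 2][1] - bouts[k - 2][0]) * dt
                    if k > 1 and bouts[k - 2][2] == FORWARD else 0.0
                )
                omgs.append(
                    metrics.ratio_change_omega(
                        trace.timestamps, trace.ratio,
                        omega_onset_s=float(track.timestamps[i0]),
                        reference_s=float(track.timestamps[bouts[k - 1][0]]),
                        valid=trace.valid,
                        forward_baseline_s=baseline,
                    )
                )
        reversal[name] = revs
        omega[name] = omgs

    pair = None
    if {"RIM", "RMED"} <= set(extracted) or len(extracted) >= 2:
        names = sorted(extracted)
        a = next((n for n in names if n.startswith("RIM")), names[0])
        b = next((n for n in names if n.startswith("RME")), names[-1])
        if a != b:
            ta, tb = extracted[a], extracted[b]
            ccf = metrics.cross_correlate(
                np.nan_to_num(ta.ratio, nan=float(np.nanmean(ta.ratio))),
                np.nan_to_num(tb.ratio, nan=float(np.nanmean(tb.ratio))),
                frame_rate_hz=track.frame_rate_hz,
            )
            pair = {"first": a, "second": b, "ccf": ccf}
    return {"switches": switches, "reversal": reversal, "omega": omega, "pair": pair}


def score_turns(
    midline: MidlineSeries,
    track: BehaviorTrack,
    closure_frac: float = 0.05,
) -> list[posture.TurnEvent]:
    """Score every backward-bout-plus-omega episode in a labeled track."""
    events = []
    bouts = track.bouts()
    t = track.timestamps
    dt = 1.0 / track.frame_rate_hz
    for k, (i0, i1, st) in enumerate(bouts):
        if st != OMEGA or k == 0 or bouts[k - 1][2] != BACKWARD:
            continue
        r0, r1, _ = bouts[k - 1]
        # heading windows must stay inside the flanking forward bouts
        pre_limit = float(t[bouts[k - 2][0]]) if k >= 2 else float(t[0])
        post_limit = (float(t[bouts[k + 1][1] - 1] + dt)
                      if k + 1 < len(bouts) else float(t[-1] + dt))
        ev = posture.score_turn(
            midline,
            reversal_span=(float(t[r0]), float(t[r1 - 1] + dt)),
            turn_span=(float(t[i0]), float(t[i1 - 1] + dt)),
            closure_frac=closure_frac,
            pre_limit_s=pre_limit,
            post_limit_s=post_limit,
        )
        events.append(ev)
    return events


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, write outputs under ``cfg.out_dir``, and return
    the summary dictionary."""
    try:
        cfg.validate()
    except ValueError as e:
        raise StageError("config", str(e)) from e
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={cfg.seed}", f"preset={cfg.preset}",
                      f"config={dataclasses.asdict(cfg)}"]

    try:
        sim = _simulate(cfg)
        sim.track.to_csv(out / "true_states.csv")
        sim.midline.to_csv(out / "midline.csv")
        log.append(f"simulate: {sim.track.n_frames} frames, "
                   f"{len(sim.truth.turn_truth)} omega events")
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e

    try:
        extracted = _extract(sim, cfg)
        for name, trace in extracted.items():
            trace.to_csv(out / f"trace_{name}.csv")
        log.append(f"extract: {sorted(extracted)}")
    except Exception as e:  # noqa: BLE001
        raise StageError("extract", str(e)) from e

    try:
        seg = behavior.segment_states(sim.midline, omega_bend_deg=cfg.omega_bend_deg)
        seg.to_csv(out / "behavior.csv")
        switches = behavior.detect_switches(seg, min_backward_s=cfg.min_backward_s)
        behavior.write_switches(switches, out / "switches.csv")
        log.append(f"segment: {len(switches)} switches")
    except Exception as e:  # noqa: BLE001
        raise StageError("segment", str(e)) from e

    try:
        ana = _analyze(seg, extracted, cfg)
        for name, revs in ana["reversal"].items():
            metrics.write_results(revs, out / f"ratio_changes_reversal_{name}.csv")
        for name, omgs in ana["omega"].items():
            metrics.write_results(omgs, out / f"ratio_changes_omega_{name}.csv")
        if ana["pair"]:
            metrics.write_ccf(ana["pair"]["ccf"], out / "ccf_pair.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze", str(e)) from e

    try:
        turns = score_turns(sim.midline, seg, closure_frac=cfg.closure_frac)
        posture.write_turn_events(turns, out / "turn_events.csv")
        log.append(f"score-turns: {len(turns)} events")
    except Exception as e:  # noqa: BLE001
        raise StageError("score-turns", str(e)) from e

    try:
        summary = _report(cfg, ana, turns)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (out / "run.log").write_text("\n".join(log) + "\n")
    except Exception as e:  # noqa: BLE001
        raise StageError("report", str(e)) from e
    return summary


def _report(cfg: RunConfig, ana: dict, turns: list[posture.TurnEvent]) -> dict:
    def _ev_summary(results):
        s = metrics.summarize_events(results)
        return {"mean_pct": _r(s.mean), "sem_pct": _r(s.sem), "n": s.n,
                "n_rejected": s.n_rejected}

    summary: dict = {
        "preset": cfg.preset,
        "seed": cfg.seed,
        "reversal_ratio_change": {k: _ev_summary(v) for k, v in ana["reversal"].items()},
        "omega_ratio_change": {k: _ev_summary(v) for k, v in ana["omega"].items()},
        "n_analyzable_reversals": sum(
            1 for e in ana["switches"]
            if e.from_state == FORWARD and e.to_state == BACKWARD and e.analyzable
        ),
    }
    if ana["pair"]:
        ccf = ana["pair"]["ccf"]
        summary["pair_cross_correlation"] = {
            "first": ana["pair"]["first"],
            "second": ana["pair"]["second"],
            "peak_lag_s": _r(ccf.peak_lag_s),
            "peak_value": _r(ccf.peak_value),
        }
    if turns:
        cls = [t.classification for t in turns]
        summary["turns"] = {
            "n": len(turns),
            "closed": cls.count(posture.CLOSED_OMEGA),
            "shallow": cls.count(posture.SHALLOW_OMEGA),
            "no_omega": cls.count(posture.NO_OMEGA),
            "closed_fraction": _r(posture.omega_success_rate(cls)),
            "mean_head_bend_angle_deg": _r(
                float(np.mean([t.head_bend_angle_deg for t in turns]))
            ),
        }
    return summary


def report_from_dir(out_dir: str | Path, cfg: RunConfig) -> dict:
    """Regenerate the summary from the saved intermediate CSVs (the
    pipeline is checkpointable: this equals the end-to-end summary)."""
    out = Path(out_dir)
    seg = BehaviorTrack.from_csv(out / "behavior.csv")
    extracted = {
        p.stem.removeprefix("trace_"): NeuronTrace.from_csv(p)
        for p in sorted(out.glob("trace_*.csv"))
    }
    midline = MidlineSeries.from_csv(out / "midline.csv")
    ana = _analyze(seg, extracted, cfg)
    turns = score_turns(midline, seg, closure_frac=cfg.closure_frac)
    return _report(cfg, ana, turns)


def _r(x: float, nd: int = 6) -> float:
    return float(np.round(x, nd)) if np.isfinite(x) else float("nan")
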