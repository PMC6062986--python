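"""Shared containers for behavior-coupled calcium imaging data.

The pipeline passes four kinds of objects between stages: per-frame
locomotion labels (:class:`BehaviorTrack`), worm midline coordinates
(:class:`MidlineSeries`), two-channel fluorescence traces
(:class:`NeuronTrace`), and rendered two-channel image stacks
(:class:`ImageStack`).  :class:`GroundTruth` carries the generator's
hidden state so that every estimator in the package can be checked
against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

FORWARD = "forward"
BACKWARD = "backward"
OMEGA = "omega"
PAUSE = "pause"
STATES = (FORWARD, BACKWARD, OMEGA, PAUSE)


@dataclass
class Switch:
    """A single label transition at time ``t0`` (seconds)."""

    t0: float
    from_state: str
    to_state: str


@dataclass
class BehaviorTrack:
    """Per-frame locomotion labels plus the list of directional switches.

    ``switches`` is always derivable from ``states``; it is stored so the
    two representations can be cross-checked (they must agree exactly).
    """

    timestamps: np.ndarray
    states: np.ndarray  # dtype object/str, one of STATES per frame
    switches: list[Switch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.states = np.asarray(self.states, dtype=object)
        if self.timestamps.shape != self.states.shape:
            raise ValueError("timestamps and states must have equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        if not self.switches:
            self.switches = self.switches_from_states()

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    @property
    def frame_rate_hz(self) -> float:
        dt = np.diff(self.timestamps)
        return 1.0 / float(np.median(dt))

    def switches_from_states(self) -> list[Switch]:
        """Reconstruct the switch list from the per-frame labels."""
        out: list[Switch] = []
        s = self.states
        for i in range(1, s.size):
            if s[i] != s[i - 1]:
                out.append(Switch(float(self.timestamps[i]), str(s[i - 1]), str(s[i])))
        return out

    def bouts(self) -> list[tuple[int, int, str]]:
        """Maximal runs of a single label as ``(start_idx, end_idx_exclusive, state)``."""
        out = []
        s = self.states
        if s.size == 0:
            return out
        start = 0
        for i in range(1, s.size):
            if s[i] != s[i - 1]:
                out.append((start, i, str(s[start])))
                start = i
        out.append((start, s.size, str(s[start])))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.timestamps,
                "state": [str(x) for x in self.states],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehaviorTrack":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["state"].to_numpy(dtype=object))


@dataclass
class MidlineSeries:
    """Ordered head-to-tail midline coordinates per frame.

    ``points`` has shape ``(T, P, 2)`` with the head at index 0.  The worm
    is treated as inextensible: per-frame arc length should stay within
    10% of ``body_length_px``.
    """

    timestamps: np.ndarray
    points: np.ndarray
    body_length_px: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must have shape (T, P, 2)")
        if self.points.shape[0] != self.timestamps.size:
            raise ValueError("one frame of points per timestamp required")
        if self.points.shape[1] < 13:
            raise ValueError("midline needs at least 13 points per frame")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("midline coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def arc_lengths(self) -> np.ndarray:
        seg = np.diff(self.points, axis=1)
        return np.linalg.norm(seg, axis=2).sum(axis=1)

    def centroids(self) -> np.ndarray:
        return self.points.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        T, P, _ = self.points.shape
        cols = {"frame": np.arange(T), "time_s": self.timestamps}
        for j in range(P):
            cols[f"x{j}"] = self.points[:, j, 0]
            cols[f"y{j}"] = self.points[:, j, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, body_length_px: Optional[float] = None) -> "MidlineSeries":
        df = pd.read_csv(path)
        xs = sorted([c for c in df.columns if c.startswith("x")], key=lambda c: int(c[1:]))
        ys = sorted([c for c in df.columns if c.startswith("y")], key=lambda c: int(c[1:]))
        pts = np.stack([df[xs].to_numpy(), df[ys].to_numpy()], axis=2)
        series = cls(df["time_s"].to_numpy(), pts, body_length_px or 0.0)
        if body_length_px is None:
            series.body_length_px = float(np.median(series.arc_lengths()))
        return series

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "timestamps": self.timestamps.tolist(),
            "points": self.points.tolist(),
            "body_length_px": self.body_length_px,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "MidlineSeries":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["timestamps"]), np.asarray(d["points"]),
                   float(d["body_length_px"]))


@dataclass
class NeuronTrace:
    """Two-channel (indicator green, reference red) intensity time series.

    ``ratio`` is the semi-ratiometric series R = green/red; ``valid`` marks
    frames where the reference channel was large enough for R to be
    meaningful.
    """

    timestamps: np.ndarray
    green: np.ndarray
    red: np.ndarray
    name: str = "neuron"
    ratio: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        n = self.timestamps.size
        if self.green.size != n or self.red.size != n:
            raise ValueError("green/red must match timestamps in length")
        if self.ratio is not None:
            self.ratio = np.asarray(self.ratio, dtype=float)
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.timestamps,
                "green": self.green,
                "red": self.red,
            }
        )
        if self.ratio is not None:
            df["ratio"] = self.ratio
        if self.valid is not None:
            df["valid"] = self.valid.astype(int)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, name: Optional[str] = None) -> "NeuronTrace":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["green"].to_numpy(),
            df["red"].to_numpy(),
            name=name or Path(path).stem,
            ratio=df["ratio"].to_numpy() if "ratio" in df else None,
            valid=df["valid"].to_numpy(dtype=bool) if "valid" in df else None,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "timestamps": self.timestamps.tolist(),
            "green": self.green.tolist(),
            "red": self.red.tolist(),
        }
        if self.ratio is not None:
            payload["ratio"] = [None if not np.isfinite(r) else r for r in self.ratio]
        if self.valid is not None:
            payload["valid"] = self.valid.astype(int).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NeuronTrace":
        d = json.loads(Path(path).read_text())
        ratio = d.get("ratio")
        return cls(
            np.asarray(d["timestamps"]), np.asarray(d["green"]), np.asarray(d["red"]),
            name=d.get("name", Path(path).stem),
            ratio=None if ratio is None else np.array(
                [np.nan if r is None else r for r in ratio]),
            valid=None if "valid" not in d else np.asarray(d["valid"], bool),
        )


@dataclass
class ImageStack:
    """Two-channel unsigned 16-bit image stack, green and red, (T, H, W) each."""

    green: np.ndarray
    red: np.ndarray
    timestamps: np.ndarray
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red channels must share a shape")
        if self.green.ndim != 3:
            raise ValueError("channels must be (T, H, W) arrays")
        if self.green.shape[0] != self.timestamps.size:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape[1], self.green.shape[2]

    def write(self, path: str | Path) -> None:
        """Write a multi-page TIFF (green page then red page per timepoint)
        with a JSON sidecar holding timestamps and metadata."""
        import tifffile

        path = Path(path)
        T, H, W = self.green.shape
        pages = np.empty((2 * T, H, W), dtype=np.uint16)
        pages[0::2] = self.green
        pages[1::2] = self.red
        tifffile.imwrite(path, pages)
        sidecar = {
            "timestamps": self.timestamps.tolist(),
            "pixel_size_um": self.pixel_size_um,
            "channel_order": ["green", "red"],
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "ImageStack":
        import tifffile

        path = Path(path)
        pages = tifffile.imread(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            green=pages[0::2],
            red=pages[1::2],
            timestamps=np.asarray(sidecar["timestamps"], dtype=float),
            pixel_size_um=float(sidecar.get("pixel_size_um", 1.0)),
            meta=sidecar.get("meta", {}),
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    activity
        per-neuron activation a(t) in [0, 1] driving the indicator channel.
    true_states
        the behavior track the kinematics and calcium were generated from.
    true_lag_s
        per-neuron lag between the state signal and the neuron's response.
    true_ratio_change_pct
        per-neuron list of event dicts with the noise-free event-locked
        ratio change (same windows the analysis uses).
    soma_paths
        per-neuron per-frame (x, y) soma position on the midline.
    """

    activity: dict[str, np.ndarray] = field(default_factory=dict)
    true_states: Optional[BehaviorTrack] = None
    true_lag_s: dict[str, float] = field(default_factory=dict)
    true_ratio_change_pct: dict[str, list[dict]] = field(default_factory=dict)
    soma_paths: dict[str, np.ndarray] = field(default_factory=dict)
    clean_ratio: dict[str, np.ndarray] = field(default_factory=dict)
    turn_truth: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "activity": {k: v.tolist() for k, v in self.activity.items()},
            "true_lag_s": self.true_lag_s,
            "true_ratio_change_pct": self.true_ratio_change_pct,
            "soma_paths": {k: v.tolist() for k, v in self.soma_paths.items()},
            "clean_ratio": {k: v.tolist() for k, v in self.clean_ratio.items()},
            "turn_truth": self.turn_truth,
            "states": [str(s) for s in self.true_states.states] if self.true_states else None,
            "timestamps": self.true_states.timestamps.tolist() if self.true_states else None,
        }
        Path(path).write_text(json.dumps(payload))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
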