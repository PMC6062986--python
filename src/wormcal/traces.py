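"""ROI tracking and two-channel trace extraction.

Neuron somas are tracked frame-to-frame on the calcium-insensitive red
reference channel (an intensity-weighted centroid inside a search window
around the previous position), intensities are measured as
background-subtracted disk means, and the semi-ratiometric series
R = green/red is formed so that shared motion and focus artifacts cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ImageStack, NeuronTrace


class TrackingLostError(RuntimeError):
    """Raised when the tracked ROI loses its target for too many frames."""


@dataclass
class RoiPath:
    """Per-frame ROI center, fixed radius, and a quality score
    (peak-to-background ratio inside the search window)."""

    centers: np.ndarray  # (T, 2) x, y in pixels
    radius: float
    quality: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be (T, 2)")

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]


def _window(img: np.ndarray, cx: float, cy: float, half: int):
    H, W = img.shape
    x0, x1 = int(round(cx)) - half, int(round(cx)) + half + 1
    y0, y1 = int(round(cy)) - half, int(round(cy)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, W)
    y0c, y1c = max(y0, 0), min(y1, H)
    if x0c >= x1c or y0c >= y1c:
        return None, 0, 0
    return img[y0c:y1c, x0c:x1c], x0c, y0c


def track_roi(
    stack: ImageStack,
    init_center: tuple[float, float],
    search_radius: float | None = None,
    roi_radius: float = 6.0,
    quality_threshold: float = 2.0,
    max_lost_frames: int = 3,
) -> RoiPath:
    """Track a soma on the red channel through a stack.

    Each frame's center is the intensity-weighted centroid of the
    (window-median-subtracted) red signal within the search window around
    the previous center; the search window defaults to 3x the ROI radius.
    Quality is the window peak over its median background; if it stays
    below ``quality_threshold`` for more than ``max_lost_frames``
    consecutive frames a :class:`TrackingLostError` names the frame.
    """
    if roi_radius <= 0:
        raise ValueError("roi_radius must be positive")
    if search_radius is None:
        search_radius = 3.0 * roi_radius
    H, W = stack.shape
    cx, cy = init_center
    if not (0 <= cx < W and 0 <= cy < H):
        raise ValueError("init_center outside image bounds")

    half = int(np.ceil(search_radius))
    n = stack.n_frames
    centers = np.empty((n, 2))
    quality = np.empty(n)
    lost_run = 0
    for i in range(n):
        img = stack.red[i].astype(float)
        win, x0, y0 = _window(img, cx, cy, half)
        if win is None:
            raise TrackingLostError(f"search window left the image at frame {i}")
        bg = np.median(win)
        q = float(win.max() / max(bg, 1e-9))
        quality[i] = q
        # centroid on pixels clearly above the noise floor, else the
        # aggregate of positive noise drags the centroid to the window center
        sigma = 1.4826 * np.median(np.abs(win - bg))
        sig = np.clip(win - bg - 3.0 * sigma, 0.0, None)
        tot = sig.sum()
        if q < quality_threshold or tot <= 0:
            lost_run += 1
            if lost_run > max_lost_frames:
                raise TrackingLostError(
                    f"tracking lost: quality below {quality_threshold} for "
                    f"{lost_run} consecutive frames ending at frame {i}"
                )
            centers[i] = (cx, cy)  # hold position while signal is weak
            continue
        lost_run = 0
        ys, xs = np.mgrid[0:win.shape[0], 0:win.shape[1]]
        cx = x0 + float((sig * xs).sum() / tot)
        cy = y0 + float((sig * ys).sum() / tot)
        centers[i] = (cx, cy)
    return RoiPath(centers, roi_radius, quality)


def measure_trace(
    stack: ImageStack,
    path: RoiPath,
    background: str = "annulus",
    percentile: float = 10.0,
    name: str = "neuron",
) -> NeuronTrace:
    """Mean disk intensity per channel minus local background.

    ``background='annulus'`` subtracts the median of an annulus between
    1.5x and 2.5x the ROI radius (robust to neighboring somas);
    ``'percentile'`` subtracts a global per-frame intensity percentile.
    """
    if path.n_frames != stack.n_frames:
        raise ValueError("path must cover every frame of the stack")
    H, W = stack.shape
    yy, xx = np.mgrid[0:H, 0:W]
    r = path.radius
    green = np.empty(stack.n_frames)
    red = np.empty(stack.n_frames)
    for i in range(stack.n_frames):
        cx, cy = path.centers[i]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        disk = d2 <= r**2
        if not disk.any():
            raise ValueError(f"ROI disk fully outside the image at frame {i}")
        for chan, out in ((stack.green[i], green), (stack.red[i], red)):
            img = chan.astype(float)
            if background == "annulus":
                ann = (d2 > (1.5 * r) ** 2) & (d2 <= (2.5 * r) ** 2)
                bg = np.median(img[ann]) if ann.any() else 0.0
            elif background == "percentile":
                bg = np.percentile(img, percentile)
            elif background == "none":
                bg = 0.0
            else:
                raise ValueError(f"unknown background method {background!r}")
            out[i] = img[disk].mean() - bg
    return NeuronTrace(stack.timestamps.copy(), green, red, name=name)


def compute_ratio(trace: NeuronTrace, eps_frac: float = 0.01) -> NeuronTrace:
    """Attach the ratio series R = green/red to a trace.

    Frames where the background-subtracted red channel is at or below
    ``max(1e-6, eps_frac * median(red))`` are flagged invalid instead of
    producing unstable or infinite ratios.
    """
    red = trace.red
    eps = max(1e-6, eps_frac * float(np.median(red[red > 0])) if (red > 0).any() else 1e-6)
    valid = red > eps
    if not valid.any():
        raise ValueError("no frame has a usable reference-channel value")
    ratio = np.full(trace.n_frames, np.nan)
    ratio[valid] = trace.green[valid] / red[valid]
    trace.ratio = ratio
    trace.valid = valid
    return trace


def moving_average(
    series: np.ndarray,
    window_s: float = 0.27,
    frame_rate_hz: float = 10.0,
) -> np.ndarray:
    """Centered boxcar smoothing with the window given in seconds.

    The window length is ``window_s * frame_rate_hz`` rounded to the
    nearest odd frame count (0.27 s at 10 fps -> 3 frames).  At the edges
    the window shrinks symmetrically, so no data are fabricated and the
    output length equals the input length.
    """
    x = np.asarray(series, dtype=float)
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = int(round(window_s * frame_rate_hz))
    if w < 1:
        warnings.warn("smoothing window shorter than one frame; returning input",
                      stacklevel=2)
        return x.copy()
    if w % 2 == 0:
        w += 1 if (window_s * frame_rate_hz) >= w else -1
    if w <= 1:
        return x.copy()
    k = w // 2
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(n)
    for i in range(n):
        h = min(k, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out
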