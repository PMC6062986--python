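import numpy as np
import pytest

from wormcal.synthetic import (
    GeneratorConfig,
    NeuronConfig,
    noiseless,
    simulate_experiment,
)
from wormcal.types import MidlineSeries


@pytest.fixture(scope="session")
def wt_sim():
    """60 s wild-type recording at default noise with RME + RIM traces."""
    return simulate_experiment(GeneratorConfig(duration_s=60.0, seed=3))


@pytest.fixture(scope="session")
def clean_fb_sim():
    """Noiseless forward/backward-only kinematics (no omega turns)."""
    cfg = noiseless(GeneratorConfig(duration_s=60.0, seed=3, omega_prob=0.0))
    return simulate_experiment(cfg, neurons=[])


@pytest.fixture(scope="session")
def rendered_sim():
    """60 s single-neuron recording rendered to a 128x128 image stack."""
    cfg = GeneratorConfig(duration_s=60.0, seed=21)
    return simulate_experiment(cfg, neurons=[NeuronConfig.rme()], render=True)


def make_straight_midline(headings_deg, speed=30.0, n_points=15, fps=10.0,
                          length=120.0, start=(0.0, 0.0)):
    """A rigid straight worm translating along a per-frame heading.

    Useful for turning-angle fixtures: the centroid displacement direction
    equals the commanded heading exactly.
    """
    headings = np.deg2rad(np.asarray(headings_deg, float))
    n = headings.size
    pos = np.zeros((n, 2))
    for i in range(1, n):
        step = speed / fps
        pos[i] = pos[i - 1] + step * np.array([np.cos(headings[i]), np.sin(headings[i])])
    pos += np.asarray(start, float)
    s = np.linspace(0.0, 1.0, n_points)
    pts = np.empty((n, n_points, 2))
    for i in range(n):
        u = np.array([np.cos(headings[i]), np.sin(headings[i])])
        # head leads: body extends backward from the head position
        pts[i] = pos[i] - np.outer(s * length, u)
    return MidlineSeries(np.arange(n) / fps, pts, length)
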