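"""Who leads whom: cross-correlation between a RIM-like and an RME-like cell.

The two neurons are simulated with opposite state preferences (RIM-like
active in reversals, RME-like in forward runs) and the RME response lagging
by 469 ms.  The cross-correlation of the smoothed, z-scored ratio series
recovers both facts.
"""

from wormcal import GeneratorConfig, compute_ratio, simulate_experiment
from wormcal.metrics import cross_correlate, pairwise_correlation

cfg = GeneratorConfig(duration_s=240.0, seed=6, noise_sd=1.0)
sim = simulate_experiment(cfg)  # default neurons: RMED (lag 469 ms) + RIM

rim = compute_ratio(sim.traces["RIM"])
rme = compute_ratio(sim.traces["RMED"])
res = cross_correlate(rim.ratio, rme.ratio, frame_rate_hz=cfg.frame_rate_hz)

print(f"peak correlation: {res.peak_value:+.3f} at lag {res.peak_lag_s*1000:+.0f} ms")
# A negative peak = anti-correlated activity; a positive lag = the first
# series (RIM) leads the second (RME), as expected if RIM drives RME
# suppression.  The true generator lag is 469 ms; the estimate is quantized
# to the 100 ms frame grid.

switch = next(s for s in sim.track.switches
              if s.from_state == "forward" and s.to_state == "backward"
              and s.t0 > 6.0)
r = pairwise_correlation(rim.timestamps, rim.ratio, rme.ratio,
                         (switch.t0 - 5.0, switch.t0 + 5.0))
print(f"Pearson r in +-5 s around the switch at t={switch.t0:.1f}s: {r:+.2f}")
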