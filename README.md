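# wormcal

Behavior-coupled ratiometric calcium-imaging analysis for freely moving
*Caenorhabditis elegans*.

Head motor neurons such as the GABAergic RME cells and the tyraminergic RIM
pair change their calcium levels with the worm's locomotion program: RME is
active during forward crawling and suppressed during reversals and omega
turns, while RIM shows the opposite pattern and leads RME by a fraction of a
second. Quantifying this coupling from freely moving recordings requires
several analysis stages that are usually stitched together ad hoc: soma
tracking and two-channel trace extraction, behavioral state segmentation
from the worm's midline, event-locked averaging of the fluorescence ratio,
cross-correlation lag estimation between neurons, and posture-based scoring
of omega turns. `wormcal` implements that pipeline as a tested library for
experimenters analyzing tracking-microscope recordings (7–15 fps, a green
calcium indicator such as G-CaMP7 plus a calcium-insensitive red reference
such as DsRed) — and ships a synthetic-data generator with full ground
truth, so every stage can be validated without touching a microscope.

## The quantities it computes

- **Semi-ratiometric trace** `R(t) = G(t)/R_ref(t)`: dividing the indicator
  channel by the reference cancels shared motion and focus artifacts.
- **Reversal ratio change** `R_backward / R_forward × 100%`, where
  `R_forward` is the mean of `R` over `t = −4…−1 s` before the directional
  switch (`t = 0`), `t = −1…1 s` is excluded as the transient rise/fall,
  and `R_backward` is the mean over the rest of the backward bout; only
  reversals longer than 1.5 s (with a clean forward baseline) are analyzed.
  The omega-turn analogue uses the first 1 s of the turn against a 1-s
  forward window at `−5…−4 s` before the reference time.
- **Neuron-pair coupling**: Pearson correlation around the switch, and the
  cross-correlation function of the smoothed (0.27 s boxcar), z-scored
  ratio series; the lag of the extreme `|ccf|` says who leads whom.
- **Behavioral states** forward / backward / omega / pause from midline
  kinematics: the sign of the body-wave propagation direction (curvature
  profile shift), a centroid-velocity fallback, and a head-bend +
  stationarity rule for omega turns.
- **Omega-turn scores** on the 13-point midline (12 equal segments, head =
  point 1): head-bend angle at points 1-2-3 one frame before turn
  initiation, body-bend count during the reversal, turning angle between
  pre- and post-turn headings, head–tail closure. A turn is an omega turn
  if the turning angle exceeds 120° after a reversal with ≥ 3 body bends;
  it is *closed* if the head touches the tail (gap < 5% of body length).
- **Group statistics**: Student's *t* (pooled), one-way ANOVA with Tukey's
  HSD, pairwise χ² on proportions with Holm or Bonferroni correction.

## A worked example

```python
from wormcal import (GeneratorConfig, NeuronConfig, simulate_experiment,
                     compute_ratio, detect_switches)
from wormcal.metrics import ratio_change_reversal, summarize_events

cfg = GeneratorConfig(duration_s=300.0, seed=11)      # 10 fps, wild type
sim = simulate_experiment(cfg, neurons=[NeuronConfig.rme(suppression_factor=0.45)])

trace = compute_ratio(sim.traces["RMED"])             # R = green/red
events = [e for e in detect_switches(sim.track)
          if e.from_state == "forward" and e.to_state == "backward"]
res = [ratio_change_reversal(trace.timestamps, trace.ratio, e, valid=trace.valid)
       for e in events]
s = summarize_events(res)
print(f"mean ratio change: {s.mean:.1f}% +- {s.sem:.1f}% (n={s.n})")
```

prints

```
mean ratio change: 53.7% +- 1.4% (n=16)
```

meaning the RME-like neuron's fluorescence ratio during backward crawling
averaged ~54% of its forward baseline over 16 accepted reversals — strong
event-locked suppression (the generator's noise-free value for this run is
52.9%, so the estimate is accurate to well under a percentage point).
The `examples/` directory holds one short script per capability:
simulation, event-locked analysis, cross-correlation lags, behavioral
segmentation, omega-turn scoring, the image-stack round trip, and the full
pipeline; each prints the numbers it computes and what they mean.

A thin CLI mirrors the pipeline:

```sh
wormcal run --preset wt --seed 0 --out-dir out/   # end-to-end, all CSVs + summary.json
wormcal simulate / extract / segment / analyze / score-turns / report
```

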