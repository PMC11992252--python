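# placecode

Analysis of hippocampal place coding from chronic two-photon calcium imaging
in a virtual linear corridor — built for experiments that track the same CA1
neurons across weeks (for example around an induced microstroke) and ask how
spatial memory, place-cell stability and population structure change.

The package covers the full path from ΔF/F traces and behaviour to
population-level statistics:

- **Behaviour** — lick histograms over 120 position bins and the spatial
  information of licking, `SI = Σ p_i (λ_i/λ̄) log2(λ_i/λ̄)` (bits), plus
  performance relative to the healthy baseline and Recovery / No-Recovery
  outcome groups (75% threshold).
- **Spatial maps** — ΔF/F detrending `(F − F0)/(B0 + F0)` with rolling
  mode-percentile baselines, velocity-filtered 5 cm binning (< 5 cm/s
  excluded) and Gaussian smoothing (σ = 5 cm).
- **Place cells** — field screening at 25% of the max-to-baseline range and
  three criteria (width ≥ 15 cm; in/out mean ratio ≥ 6×; significant
  transients — runs ≥ 0.5 s above 3σ — covering ≥ 20% of in-field time),
  with a 50-frame chunk-shuffle bootstrap p_pf ≤ 0.05.
- **Stability** — Fisher-averaged split-half correlations within sessions,
  3-day-pair map correlations across sessions, and the stable/unstable
  split at the network's pre-injection median.
- **Class transitions** — ΔP = P(a→b) observed minus a shuffled-class null.
- **Bayesian decoder** — Gaussian naive Bayes over 5 cm bins,
  `x̂(t) = argmax_x occ(x) Π_i p_i(x,t)/max_x p_i(x,t)`, with per-neuron SD
  flooring, top-100 stability selection, leave-one-out and cross-session
  evaluation, and empirical chance levels (1/80 = 1.25%).
- **Population structure** — population vector correlation curves
  (y-intercept, initial slope, relative peak prominence), pairwise trace
  and map correlations, 95th-percentile synchronous pools, cosine
  similarity of correlation structure across days, and place-field /
  reward-zone geometry.
- **ROI tracking** — patchwise subpixel FOV alignment (phase
  cross-correlation) and mutual-nearest-neighbour centroid matching.
- **Synthetic generator** — multi-session experiments with known
  stable / unstable / non-coding populations, expert or naive licking,
  GCaMP-like transients and a parameterised stroke-like perturbation, so
  every stage is testable against ground truth.

## Worked example

Decode position from 120 simulated place cells
(`examples/03_bayesian_decoding.py`):

```text
leave-one-out accuracy:    32.6%
leave-one-out sensitivity: 90.4%
empirical chance accuracy: 1.23%  (analytic 1.25%)
```

Accuracy is the fraction of frames whose exact 5 cm bin is predicted —
here 26× the 1/80 chance level, which the bin-identity shuffle reproduces
empirically. Sensitivity is the fraction of reward-zone frames predicted
inside a reward zone; it exceeds accuracy because confusing one reward zone
for another (the zones share wall patterns) still counts.

Each script in `examples/` exercises one capability end to end: behaviour
scoring, place-cell recovery against ground truth, decoding, population
stability and remapping, ROI tracking, and the full pipeline
(`placecode.run_pipeline` / `placecode pipeline run` on the CLI). The
`placecode simulate` command writes synthetic sessions as HDF5 plus a
ground-truth CSV.

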