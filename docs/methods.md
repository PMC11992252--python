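# Methods

`placecode` analyses chronic two-photon calcium imaging of hippocampal CA1
populations recorded while a head-fixed mouse runs a 400 cm virtual linear
corridor with four 40 cm reward zones (RZs, centred at 30, 137, 243 and
350 cm) at a 30 Hz frame rate. This note documents the models and procedures
each module implements, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made where the
design was open.

## Coordinate conventions

Positions are in cm; spatial bins are 0-based and half-open,
`[k·5, (k+1)·5)` cm, giving 80 bins; the behavioural lick histogram uses a
finer 120-bin grid. Frames are 0-based; trials are half-open frame
intervals. Frames between trials (screen blackout) carry no valid position
and are excluded from every analysis. Sessions are dated relative to the
injection day; day ≤ 0 is the healthy phase (the last baseline session is
imaged on the injection day, before the injection), days 1–7 the early
post-injection phase, and later days the late phase.

## Behavioural performance

Licks are binned into 120 position bins; λ_i is the fraction of trials with
at least one lick in bin i and t_i the occupancy time. Spatial information

    SI = Σ_i p_i (λ_i/λ̄) log2(λ_i/λ̄),  p_i = t_i/Σt,  λ̄ = Σ_i p_i λ_i

is 0 for spatially uniform licking and log2(N) when licking collapses into
one of N equally occupied bins. Conventions: bins with t_i = 0 drop out of
all sums (they are unobserved, and the measure is occupancy-weighted); a
session without licks gets SI = 0 with a warning rather than an error,
because impaired animals produce such sessions and the pipeline must carry
them. No velocity filter is applied to behavioural occupancy — the animal
licks mostly while slowed or stopped, and filtering would discard exactly
the frames the metric is about; the velocity filter applies to neural maps
only.

Post-injection sessions are scored as percent of the mouse's mean healthy
SI. Outcome groups use a 75% threshold with the tie going to the impaired
label: at or below 75% in both post phases → No-Recovery; only early →
Recovery; never → pooled with shams (pooling can be vetoed by a histology
flag the pipeline itself cannot compute).

## ΔF/F and spatial activity maps

Traces are detrended as ΔF/F = (F − F0)/(B0 + F0) with rolling baselines at
the percentile of the distribution mode, estimated per 1000-frame window
(stride 500). The mode is located with a Gaussian KDE under Silverman's
bandwidth and its percentile rank within the window computed; the median
across windows is the trace's baseline percentile. The per-window mode
estimate has a sampling sd of roughly 7 percentile points on Gaussian data,
so the median over many windows is the quantity to trust, not any single
window. A constant trace maps to the 50th percentile by convention.

Maps: frames with running velocity < 5 cm/s are excluded (exactly 5 cm/s is
kept); per trial, the mean ΔF/F of remaining frames per 5 cm bin; the
session map averages trials, ignoring bins a trial never covered. Smoothing
uses a Gaussian kernel, σ = 5 cm (1 bin), with reflective boundaries — the
corridor ends are walls, and mirroring conserves map mass. Missing bins are
linearly interpolated from visited neighbours before smoothing and
re-flagged afterwards, so empty bins never smear zeros into visited ones.
Per-trial maps and the trial-mean map are smoothed independently: stability
and the decoder consume per-trial maps, detection the trial-mean map.

## Place-cell detection

Candidate fields are runs of bins strictly above
`baseline + 0.25·(max − baseline)` on the smoothed trial-mean map, with the
baseline the mean of the lowest quartile of bin values. A field passes when
(1) it is ≥ 15 cm (3 bins) wide, (2) its mean ΔF/F is ≥ 6× the mean outside
the field — when the outside mean is ≤ 0 the ratio is undefined and the
criterion reads as "inside mean positive" — and (3) significant transients
cover ≥ 20% of the velocity-filtered frames the animal spent inside the
field. Significant transients are runs of ≥ 0.5 s above 3σ, with σ taken
from the FWHM of the ΔF/F value distribution (KDE peak; FWHM/2.355). The
FWHM estimator ignores the right tail that sparse transients add, which is
precisely why it is preferred over the sample sd here.

Significance: the trace is cut into 50-frame chunks (a final partial chunk
kept as its own piece, preserving all data), chunk order is permuted, and
the full detection pipeline re-runs against the unchanged behaviour; p_pf is
the fraction of shuffles yielding a passing field, and a cell is a place
cell iff a passing field exists with p_pf ≤ 0.05. σ is estimated once per
trace — chunk permutation does not change the value distribution. Cells
whose real map has no passing field are never place cells regardless of
p_pf, so the shuffle loop is skipped for them; this is an optimisation with
identical results. Detection is invariant to positive rescaling of a trace:
σ, the candidate threshold and both field means scale together.

## Stability and functional classes

Within-session stability correlates the trial-half and odd/even split maps
and Fisher-averages the two coefficients (values clipped to ±(1−1e−6)
before atanh; results reported back on the r scale). Cross-session
stability Fisher-averages map correlations over all session pairs exactly 3
days apart inside a phase. The network baseline is the median pre-injection
stability score across all neurons; place cells strictly above it are
stable, at or below it unstable ("higher" is read strictly, so a tie is
unstable), non-place-cells are non-coding. An optional gate additionally
requires healthy-phase stable cells to have held a field at the same
position across the healthy sessions; the median split is the default.

## Class transitions

P(a→b) between two time points is the fraction of cells in class a at t1
found in class b at t2, over cells present at both; chance comes from
permuting the t2 labels across cells (permuting t1 instead is equivalent
for this statistic). ΔP = P_true − mean over 1000 permutations, with the
permutation sd retained for z-scoring; ΔP rows sum to zero by construction.
Cells absent in either epoch are excluded pairwise.

## Bayesian decoder

Tuning curves are the cross-trial mean μ_i(x) and SD σ_i(x) of the smoothed
per-trial training maps; per-bin SDs below the neuron's average SD are
floored to that average (a quiet bin would otherwise dominate the product),
with a global floor of 1e−6 ΔF/F. The occupancy prior occ(x) is the
velocity-filtered training frame count, normalised. Models keep the 100
neurons with the highest within-session stability among those present in
both training and decoding data. At decode time S_i(t) is the mean ΔF/F
over t ± 0.5 s (window truncated at record edges); each neuron contributes
a Gaussian likelihood normalised by its own maximum over bins, and

    x̂(t) = argmax_x occ(x) Π_i p_i(x,t)/max_x p_i(x,t),

computed entirely in log space (a 100-factor product underflows in linear
space), with argmax ties broken to the lowest bin. All frames are decoded,
including those the velocity filter excludes from map building. Accuracy is
the exact-bin hit rate; sensitivity the fraction of true-RZ frames whose
prediction also lands in an RZ (any RZ).

Chance levels shuffle the bin identity of the training maps: one
permutation per shuffle, applied consistently to every neuron's μ, σ and to
occ, preserving the joint tuning structure while destroying the position
mapping. Because the likelihood depends on the bin only through
(μ_i(x), σ_i(x), occ(x)) — and the per-neuron max-normalisation is constant
in x, cancelling in the argmax — permuting those arrays equals permuting
the columns of the unshuffled per-frame log-score matrix. The
implementation therefore computes that matrix once and reduces each of the
500 shuffles to a column gather; this is algebraically identical to
refitting. For any frame, a uniform random permutation maps the true bin
onto the predicted one with probability exactly 1/80, so the shuffle mean
is an unbiased estimate of 1.25% whatever the occupancy.

## Population structure

PVC(x,y) is the cosine of the across-neuron activity vectors of two
sessions at positions x and y; the curve averages entries at each offset
Δx = |x−y| from 0 to 275 cm (56 values). The y-intercept is curve(0); the
initial slope is the maximum absolute consecutive-offset difference within
0–100 cm, scaled to correlation change per 100 cm (the scale factor is
configurable, since slope units are a reporting convention). Relative peak
prominence is (peak − mean of flanking valleys)/peak per local maximum;
with four regularly spaced reward zones the curve peaks near the ~105 cm
zone spacing. PVC is invariant to positive rescaling of either session's
maps and to neuron permutation; maps are used as-is (trial-mean ΔF/F can be
slightly negative).

Pairwise structure: Pearson correlations of ΔF/F traces over whole-session
frames (synchrony in time) or of spatial maps over bins (spatial
synchronicity). The synchronous pool holds pairs strictly above the 95th
percentile (midpoint interpolation, upper triangle only); composition is
reported both as the fraction of each class-pair type inside the pool
(whose chance level is 5% under independent labels — the default reading)
and as each type's share of the pool. Cross-day persistence of correlation
structure is the cosine similarity of strict upper triangles, missing
entries dropped pairwise. Phase-averaged pairwise correlations are matched
per cell pair across phase pairs and summarised by Pearson r, p and the
least-squares slope; distributions with p > 0.05 are flagged excluded.
Field-to-RZ geometry labels field centres in / close / far with a 25 cm
"close" threshold (half an RZ width beyond the edge; configurable, since no
canonical value exists).

## ROI tracking

FOV mean images are split 2×2; each patch's subpixel translation is
estimated by FFT phase cross-correlation (upsampling factor 20) after mean
removal and Hann windowing (which suppresses the bias from cells truncated
at patch edges), then interpolated bilinearly between patch centres with
edge extension — extrapolating linearly beyond the centres would amplify
per-patch noise. A featureless patch inherits the mean of the others.
Matching displaces session-A centroids by the field and accepts
mutual-nearest-neighbour pairs within 12 px (≈ 20 µm at 830 µm / 512 px);
the mutual-NN gate is an automatic stand-in for manual curation and is a
deliberate dialect, not a fidelity claim.

## Synthetic generator

The generator emulates: monotone trial-wise running with lognormal speed
fluctuation and slowing inside/ahead of RZs; expert licking concentrated in
RZs and a 10 cm anticipatory approach window (~75–85% of licks in-zone)
versus naive licking uniform in space; populations of stable place cells
(fixed Gaussian tuning, truncated at the walls — the track is linear, no
wraparound), unstable place cells (field centre redrawn every session), and
non-coding cells; Poisson transient events at
`baseline + peak·exp(−(x−c)²/2w²)` convolved with a GCaMP6f-like kernel
(1-frame rise, 0.7 s decay, ~1 ΔF/F amplitude) plus Gaussian noise (default
sd 0.1 ΔF/F); and a stroke-like perturbation: at onset each neuron switches
class with a turnover probability, rates scale down, stable cells remap
with probability 1 − stability_scale, and an optional half-life relaxes all
three toward baseline. Defaults: 20% stable, 20% unstable, 60% non-coding;
field widths 8–14 cm; peak rates 0.8–1.6 events/s; baseline 0.02 events/s;
20 trials/session. These are the conditions under which the recovery
properties (≥90% stable-PC detection, ≤10% false positives) are asserted.

Not emulated: biophysical calcium dynamics, spike inference, neuropil
contamination, slow photobleaching beyond an optional gain drift, and
behaviourally correlated noise. Passing tests therefore demonstrate the
correctness and calibration of the analysis code under the stated
statistical structure, not performance on raw microscope output.

All randomness flows through one seeded generator per experiment with
deterministically derived per-session substreams; identical seeds reproduce
identical sessions byte-for-byte.

## Problem sizes and runtime choices

The test suite and the acceptance script run desk-scale problems chosen to
keep Monte-Carlo error well inside the asserted tolerances: 40–120 neurons
per session, 10–20 trials, 100–200 bootstrap shuffles per cell where the
full analysis uses 1000 (p_pf resolution 0.005–0.01 is ample for an α of
0.05 on clearly separated populations), 500 decoder-chance shuffles and
1000-rep pool simulations as stated. All counts are configuration values;
`RunConfig` defaults to the published 1000/500 counts.

## Known limitations

- The plug-in SI estimator is biased upward on sparse histograms: with few
  trials, binomial noise in λ_i mimics spatial structure, so a uniformly
  licking agent scores well above 0 bits. Expert/naive separation is clean
  at the default 20 trials per session and degrades below ~15; relative
  (percent-of-baseline) performance inherits this bias symmetrically.
- The KDE mode percentile is a consistent but noisy estimator; traces
  shorter than ~10 windows give a coarse median.
- `rpp` requires ≥ 5 curve points and treats curve endpoints as valleys
  when no interior minimum flanks a peak.
- The automatic ROI-matching gate cannot reproduce human curation choices;
  its error rate is characterised only on rendered blob fixtures.
- The pooled-sham rule's histology condition enters only as an override
  flag; the package does not count microspheres.
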