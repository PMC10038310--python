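# Methods

## Detection model

All behavioral and neuronal inactivity detection follows one recipe applied
to a per-frame series (tracked speed, frame-subtraction motion value, or
ratiometric activity):

1. **Smoothing.** Each point is replaced by the value, at its own position,
   of a degree-1 local regression over the nearest `smooth_window` time
   points, weighted by the tricube kernel w = (1 − (d/dmax)³)³ of the index
   distance (the lowess convention). Windows are counted in *points*, not
   seconds, so the same preset means different temporal scales at different
   frame rates; at the standard 0.1 Hz a 30-point window spans 5 min. At the
   series edges the neighborhood keeps its size but becomes asymmetric; the
   nearest-k block for point *i* starts at `clip(i − (k−1)//2, 0, n−k)`.
   A plain moving average over the same neighborhood is available behind
   `method="moving"`; lowess is the default because a degree-1 fit
   reproduces linear trends exactly and tracks steps with less lag.
   Invalid frames get zero weight in every fit but still receive an
   interpolated output value; a window with fewer than two positive-weight
   valid points falls back to the weighted mean.

2. **Normalization.** The smoothed series is scaled to [0, 1] over the
   animal's *own* valid frames: (v − min)/(max − min). Detection thresholds
   are therefore fractions of each animal's dynamic range, and differences
   in absolute units between setups or animals drop out. A constant series
   degenerates to all zeros with a warning.

3. **Thresholding.** Maximal runs of consecutive valid frames *strictly*
   below the preset threshold (strictly above for `direction="above"`)
   lasting at least `min_duration` seconds become bouts. Ties at the
   threshold end a run; no merging across single-frame excursions is
   performed; invalid frames break runs, because a bout must not span
   unobserved frames. Intervals are 0-based half-open in frames, so
   second↔frame conversion is lossless.

Presets: `calcium_20x` 30 pts / 10 % / 180 s, `calcium_10x` 30 / 5 % /
240 s, `dic_20x` 30 / 15 % / 180 s, `neuronal` 30 / 20 % / 180 s. Presets
layer as built-ins < YAML config file < explicit overrides.

**RIM inactivity** is peak-based instead: the ratiometric activity is
smoothed over 5 points, local maxima with topographic prominence ≥ 0.2 are
located (prominence = peak height minus the higher of the two lowest points
separating it from higher terrain or the series ends; plateaus report their
left-most index), and maximal peak-free stretches of ≥ 300 s become
`rim_inactivity` bouts. RIM is wake-active, so inactivity is the absence of
events, not a level.

### Step response and its consequences

The 30-point lowess window has a measurable group delay: on a noiseless
square wave with the `calcium_20x` preset the detected bout starts exactly
8 frames after, and ends 8 frames before, the true edges, and bouts shorter
than ≈ 34 frames (≈ 5.7 min at 0.1 Hz) are never detected because the
smoothed series cannot reach the 10 % threshold inside them. Two design
choices follow:

- Detected occupancy systematically *undercounts* true occupancy by roughly
  (16 frames × detected bouts + time in sub-detectable bouts)/total. This
  bias is a property of the published detection rule, not of this
  implementation; it cancels in between-strain comparisons.
- Bout-onset alignment is most meaningful on the **smoothed** series the
  detector thresholds. Relative time 0 is the detected onset, which lags
  the physical onset by the group delay, so the *raw* speed is already at
  sleep level ~1 min before time 0, while the smoothed speed crosses
  downward exactly at the detected onset. `align_to_onsets` itself is
  quantity-agnostic; the acceptance checks align the smoothed speed.

### Alignment eligibility

A bout enters the onset-aligned ensemble only when the `pre` seconds before
its onset (default 180 s) lie fully inside the trace, contain no frame of
any other detected bout, and contain only valid frames — the worm must have
been observably mobile throughout the window. The snippet
[onset − pre, onset + post) must also fit inside the trace. The ensemble
exposes per-bout means over the pre and post windows for paired
(signed-rank) comparisons.

## Signal extraction

ROI tracking segments pixels strictly above an intensity threshold into
8-connected components; the neuron is the largest component (ties broken by
mean brightness, then by lowest centroid coordinates — a deterministic
convention). The background is the annulus obtained by dilating the
component by `dilation_margin` pixels (default 2) and removing the
component, i.e. the extracted region is slightly larger than the neuron so
the local background can be estimated; signal = ROI mean − annulus mean,
kept (and flagged) when negative rather than clipped. The pan-neuronal
variant treats all supra-threshold pixels as one combined ROI and reports
its background-subtracted *mean*, so the signal does not scale with the
number of lit neurons. Frame-subtraction mobility is the mean *absolute*
frame difference: a signed mean would cancel to ≈ 0 and carry no motion
information. Speeds are Euclidean frame-to-frame steps × pixel size / dt;
`speed[0]` and `motion[0]` are backfilled from index 1 so series keep trace
length, and frames adjacent to invalid positions are invalid.

## Survival statistics

Survival (or post-refeeding recovery, selected by the `endpoint` column) is
fit with the decreasing three-parameter logistic
S(t) = A / (1 + exp(k·(t − t50))) by least squares on the per-day
fractions, with multistart initialization (A₀ = max fraction, t50₀ = first
day below A₀/2, k₀ ∈ {0.1, 0.5, 1.0}) and bounds A ∈ (0, 1.05],
k ∈ (0, 10]. An all-equal fraction series is flagged non-converged.

Strain comparisons use Fisher's exact test on the 2×2 alive/dead table at
the first observed day the reference strain's empirical fraction reaches
the target (50 % by default); a strain without an observation on that day
contributes its nearest earlier day, recorded in the output. The two-sided
p-value uses point-probability ordering — the sum over all tables with the
same margins whose probability does not exceed the observed table's — and
is computed by exact integer enumeration (all tables in a margin family
share the denominator, so tie comparisons are decided on integer
numerators). Families of comparisons are corrected per analysis family with
the Benjamini–Hochberg step-up at q = 0.05.

The Wilcoxon signed-rank test drops zero differences (Wilcoxon's original
convention) and is exact — full 2ⁿ sign-pattern enumeration over
tie-averaged ranks, p = 2·min(P(W ≤ w), P(W ≥ w)) capped at 1 — for up to
12 effective pairs, switching to the tie-corrected normal approximation
(no continuity correction) above. Welch's t-test uses the
Welch–Satterthwaite degrees of freedom; two degenerate zero-variance cases
return p = 1 (equal means) or p = 0 with a warning (unequal means). The
linear regressions of inactivity fraction on quiescence fraction are plain
OLS; R² is defined as 0 for constant y and snapped to 1 when residuals
vanish below 1e-12.

## Synthetic data

The generator reproduces the statistical structure of microchamber
recordings, not neuron biophysics:

- **States:** an alternating renewal process with exponential wake dwells
  (rate `sleep_bout_rate`, per hour) and exponential sleep dwells (mean
  `mean_bout_duration`, seconds). The initial state is drawn from the
  stationary occupancy ρ/(1+ρ), ρ = rate × mean duration, which together
  with memoryless dwells makes the process exactly stationary.
- **Speed:** per-frame |Normal(wake mean, wake SD)|, multiplied by
  `sleep_speed_scale` during sleep, plus Gaussian measurement noise.
- **RIS calcium:** a constant baseline (100 AU × `ris_baseline_scale`) plus
  transient kernels (30-s linear rise, 60-s exponential decay, amplitude in
  units of the strain's baseline) placed at sleep-bout onsets in coupled
  mode, or as an independent Poisson stream in uncoupled mode. The
  strong-activation phenotype is uncoupled with rate 0: an elevated,
  transient-free baseline.
- **mKate2:** constant 100 AU with 2 % multiplicative noise and a linear
  5 %-per-12-h bleach; the GCaMP/mKate2 ratio cancels the common factors.
- **RIM:** baseline 1 plus short triangular events at Poisson times with
  state-dependent rates (wake ≫ sleep).
- **Positions:** a speed-proportional random walk reflected inside a
  110-µm chamber.
- **Randomness:** per-channel streams are split from the single seed, so
  changing one channel's noise never perturbs another channel's draws;
  every generator is a pure function of (parameters, seed).

Defaults describe a 12-h, 0.1-Hz wild-type recording: bout rate 1.2/h and
mean bout duration 1000 s (stationary occupancy 0.25) — bout durations of
order 15 min, long relative to the detector's 5-min smoothing scale, as in
arrested-L1 recordings; wake speed 2.0 ± 0.3 µm/s, sleep speed scale 0.1,
and measurement noise 5 % of the channel scale, giving a wake/sleep
separation of ≈ 5.7× the per-frame noise SD. The six-strain panel spans
the RIS dose-response ordering (strong inactivation → strong activation);
the only magnitude anchored to a reported value is the strong-activation
baseline fold-change of 1.55× wild type — all other panel numbers are
generator conventions.

What the generator does **not** emulate: tracking dropouts and refocusing
artifacts, non-exponential dwell times, posture-dependent speed artifacts,
bleaching of GCaMP, developmental drift across days. Passing recovery
tests therefore demonstrates correctness of the detection arithmetic under
the stated statistical assumptions, not robustness to every artifact of
real recordings.

Survival cohorts are Binomial(n, S(day)) draws from the logistic curve;
image stacks render a Gaussian blob (σ = 1.5 px) over flat background with
Gaussian pixel noise and return the true centroids for oracle comparisons.

## Numerical and interface conventions

- Frame intervals are 0-based half-open everywhere; times in seconds
  internally; survival days are integers.
- Lost-tracking frames are *invalid*, never zero-filled — zeros would fake
  immobility and corrupt the per-animal normalization.
- Trace tables are CSV written with `%.17g` and read with round-trip float
  parsing, so write→read is bit-for-bit the identity.
- The report pipeline derives every per-animal seed from the single
  top-level seed via seed-sequence spawning and records it; identical
  config + seed reproduces byte-identical report files.
- Problem sizes in the test-suite recovery checks (100 simulated animals
  for occupancy recovery, 50 per strain for panel ordering, 200 binomial
  cohorts for t50 recovery) are the package's chosen study sizes; the
  acceptance script uses 60/20/100 for its summary JSON.

## Known limitations

- The smoothing-induced onset lag and occupancy undercount described above
  are inherent to the published detection rule and are reported, not
  corrected.
- The empirical 50 %-day convention (first observed crossing) depends on
  the sampling grid of counting days; the logistic-inversion mode is
  available where a grid-free estimate is needed.
- The exact signed-rank enumeration is O(2ⁿ) and capped at n = 12 by
  default; beyond that the normal approximation is used.
- `extract_roi` assumes one animal per chamber (the brightest component is
  the neuron); it performs no multi-worm segmentation.
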