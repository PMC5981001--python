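# Methods

## Task model and conventions

The task geometry is two circles of radius 13 mm, vertically aligned
204 mm apart, on a 509 × 286 mm screen. Coordinates are in mm with the
origin at the screen bottom-left and y increasing upward, so the end
(goal) circle has the larger y. Timestamps are seconds relative to
session start; a path's duration is `t_last − t_first` of its own
samples, excluding inter-path pauses. A path is *valid* iff its first
sample lies within 21 mm (inclusive — "within" is read as ≤) of the
start center and its last sample within 21 mm of the end center.
Sampling may be irregular; nothing downstream assumes a fixed rate.
Data recorded in device pixels are converted on ingestion with a
per-axis pixels-per-mm calibration from the geometry config.

## Path representation

1. Consecutive duplicate samples are dropped (touchscreens emit
   repeats; interpolation needs strictly increasing arc length).
2. Cumulative arc length s(t) is the running sum of segment norms.
3. The path is linearly interpolated at 200 points at arc lengths
   k·L/199, k = 0…199. The first/last output points are the exact
   source endpoints. Resampling depends only on sample *positions*:
   any strictly increasing relabeling of timestamps yields bit-identical
   coordinates, which is what makes the metric blind to drawing speed.

Numerical note: re-resampling an already-resampled path as a polyline is
not an exact fixed point — each pass cuts corners by
O((L/n)²·curvature), accumulating to ~1e-5·L on smooth drawn paths. The
property test bounds this drift at 1e-4·L; it is far below any
behavioural signal but worth knowing when chaining resampling passes.

## Features and the mirror-min distance

The feature vector has 480 values:
`[hx(200), hy(200), h'x(20), h'y(20), h''x(20), h''y(20)]`.
First differences are `h'(k) = h(k) − h(k−1)` with `h'(0) = 0`
(zero-padding keeps 200 values per component so they bin evenly into
20 bins of 10 arc units; whether the original analysis padded,
truncated, or wrapped is unknowable from the published description —
padding is the one reading that makes the stated bin count exact).
Second differences are the same operator applied to h'. "Bins of 10
distance units" are 10 consecutive resampled indices, which *are*
uniform distance units after arc-length resampling. Derivative blocks
carry an exposed `derivative_weight` (default 1.0 — raw resampled
units, no reweighting) for sensitivity analysis.

The distance between paths i and j is
`min(‖v_i − v_j‖_p, ‖v_i − v'_j‖_p)` where v' is the feature vector of
the path reflected about the vertical line through the circle centers
(hx → 2·axis − hx; derivative x-components flip sign). p ∈ {1, 2, 3},
default 2. Reflection is a norm-preserving involution, so the
mirror-min is symmetric, but it can violate the triangle inequality —
the distance matrix is treated as a dissimilarity, never as a metric
space. A `pointwise_sum` variant (sum over corresponding points of
per-point Euclidean distances) is provided for comparison with the
looser "sum of distances between corresponding points" reading.

Uniqueness `u_i = min_{j≠i} d_ij` is always taken over the pooled
corpus of all valid option-generation paths in the loaded cohort(s) —
cross-participant, cross-session — never within-participant. The
achieved nearest neighbour is recorded for audit. Invalid paths stay in
the per-path table with their validity flag and reason; they are
excluded from features, uniqueness pools and summaries.

## Tremor smoothing

Optional (off by default): a centered moving average over a 250 ms
window (time-based, ±125 ms, truncated at the ends), applied to raw
samples *before* resampling — the order matters because tremor inflates
arc length. A boxcar spanning one full period has a frequency-response
zero at 4 Hz, so parkinsonian-band tremor is removed while the drawn
shape (curvature radii ≫ the ~20 mm the window spans at normal drawing
speed) is essentially untouched. The window is time-based rather than
sample-count-based because sampling may be irregular; centering is an
assumption (the alternative trailing window delays the path by 125 ms
but is otherwise equivalent for shape purposes).

## MDS and exploration area

Per participant and session, the valid paths' dissimilarity matrix is
embedded in 2-D by minimizing normalized metric stress
`Σ_{i<j}(d_ij − δ_ij)² / Σ_{i<j} d_ij²` via iterative majorization
(SMACOF; Guttman transform with unit weights). Initialization is
classical (Torgerson) scaling plus 3 seeded random restarts; the best
solution is kept. Raw stress is non-increasing across majorization
steps by construction and the per-iteration history is retained and
asserted in tests. Convergence: stress improvement < 1e-8 or 512
iterations (both configurable). The embedding is deterministic given
(matrix, seed). Exact coordinate agreement with any other MDS
implementation is *not* a goal — MDS solutions are only defined up to
isometry — which is why exploration is quantified by the convex-hull
area of the embedded points (rotation/reflection/translation
invariant; checked under random isometries). Sessions with < 3 valid
paths get hull area 0 with a logged warning; no normalization by path
count is applied. Hull computation uses the standard Qhull routine with
degenerate (collinear / < 3 distinct points) configurations mapped to 0.

## Statistics

- Correlations: scipy Pearson/Spearman, two-sided p.
- Partial correlation: residualize both variables on the controls by
  OLS (ranks first for Spearman), correlate residuals, df = n − 2 − k.
  Variables fully explained by the controls get partial r = 0 by
  definition rather than numerical noise.
- Comparing two correlations that share a variable: Fisher-transformed
  z with Steiger's dependent-overlapping-correlations correction (the
  shared-variable design makes the naive independent-samples Fisher
  test anticonservative; that naive variant is available behind
  `dependent=False` for sensitivity).
- Paired condition comparisons: two-sided paired t; measures are
  log-transformed when a Shapiro pre-check (α = 0.05) fails on the
  pooled positive values (policy configurable: never/always/auto).
  Zero-variance differences are reported exactly and flagged.
- Mixed model: `uniqueness ~ duration + condition + apathy +
  condition×apathy` with a random intercept per participant
  (statsmodels MixedLM, REML). This is the smallest random-effects
  structure supporting the within-subject crossover; random slopes are
  deliberately omitted by default. Apathy is mean-centered inside the
  fit so the condition main effect is the condition contrast at fixed
  duration and average apathy — the "uniqueness for a given fluency"
  quantity. An optional duration×condition term is exposed.
- Motivation model: OLS of motivation on fluency, mean uniqueness and
  hull area jointly (a Gaussian GLM), unstandardized predictors.
- Bayes factors are not computed.

## Synthetic agents

Each agent has a dispersion σ (mm), drawing speed (mm/s), a uniqueness
cost (s per mm of per-path dispersion draw), optional tremor
(amplitude, frequency), and per-condition effect knobs. A path is a
natural cubic spline through 5 waypoints on the start–end chord; the 3
interior waypoints get lateral offsets ~ Normal(0, σ²) with the bulge
side set by a fair coin (mirror pairs arise naturally). Timestamps are
spread uniformly over the path duration
`L/speed + cost·mean|offsets|`, so more dispersed paths take longer;
paths are drawn sequentially with a 1.5 s (+ uniform jitter ≤ 1 s) gap
until the next path would exceed the 240 s budget. Fluency therefore
falls as dispersion rises and the uniqueness–fluency trade-off emerges
mechanically rather than being painted in.

Population defaults, chosen once as the simulated study conditions:
speed lognormal around 80 mm/s (σ_log = 0.25; a ~210–260 mm path then
takes ~2.5–4 s, giving 20–50 paths per 240 s session, the right order
for this task), per-agent σ uniform on 5–55 mm (from nearly straight to
screen-filling curves), uniqueness cost 0.1 s/mm, sampling 60 Hz
uniform (irregular sampling available as a stress flag). Motivation is
constructed as 0.6·z(speed) − 0.6·z(σ) + noise, apathy as its negative
plus noise — motivated agents are fast, prolific and conventional,
matching the qualitative pattern the statistics must detect. The
dopamine-like condition ("ON"/"drug") applies speed ×1.35, σ ×0.7 and a
+0.25 uniqueness boost: the boost widens paths *without* charging the
time cost, raising uniqueness at fixed duration — three orthogonal
knobs so the pipeline's ability to separate the trade-off from the
residual drug effect is testable by construction. Session order is
counterbalanced across agents. Control tasks: ten near-straight lines
(motor execution); straight lines to targets at the 204 mm chord
distance at random angles within ±90° (externally cued, 90 s); or to
self-picked targets among 24 equally spaced arc locations (option
selection, 90 s).

What the generator does *not* emulate: real motor control
(minimum-jerk profiles, speed–curvature power laws, endpoint noise),
learning or fatigue across the session, deliberate path planning, or
path-crossing strategies. Passing tests therefore demonstrate that the
pipeline recovers known generative structure — not that human data
would show the same effect sizes; the generator's effects are
intentionally strong enough to make test outcomes stable under seeded
randomness.

## Determinism and problem sizes

A single master seed determines agent parameters, path draws and MDS
restarts; identical configs produce byte-identical CSVs (floats are
written with 10 significant digits, the documented round-trip
precision). The test suite and the acceptance script run the full chain
at a 96-agent healthy cohort, a 500-path norm-robustness corpus, a
35-agent ON/OFF crossover, 100 replicates of a 12-agent crossover for
effect-direction stability, and a 6-agent tremor control; these sizes
give stable statistics at desk-scale runtimes.

## Known limitations

- The mirror reflection axis must be vertical (as in the standard task
  layout); rotated geometries raise an unsupported-geometry error.
- Mirror-min dissimilarities are not metrics; MDS stress on them is
  interpreted as misfit, not as embedding error in a metric space.
- Uniqueness depends on the pool: scores from differently sized pools
  are not comparable (enlarging a pool can only lower scores).
- The derivative blocks enter the norm in raw resampled units; their
  relative weight against the 400 position values is a modelling choice
  exposed as `derivative_weight`, not an empirically fitted constant.
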