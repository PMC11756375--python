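# Methods

This document describes the measurement model, the algorithms, the synthetic
ground-truth generator, the numerical choices, and the known limitations of
`junctrack`.

## 1. Measurement model

The object of study is the shrinkage and growth of cell–cell interfaces
(junctions) during convergent-extension-like tissue flow, where
dorso-ventrally oriented ("vertical") interfaces contract to a fourfold
vertex and resolve into new antero-posteriorly oriented ("horizontal")
interfaces — a t1 topological transition.

Each interface in a segmented, tracked movie is reduced to a per-frame
record:

- **length** `l` (µm): the geodesic length of the shared boundary between the
  two cells, from the pixel count of the boundary ridge scaled by pixel size
  (diagonal steps weighted √2).
- **orientation** `θ` (degrees): the angle of the end-to-end chord of the
  interface relative to the horizontal image axis, folded into `(−90°, 90°]`
  (an undirected line, so θ and θ+180° are the same orientation). After
  calibration, θ is measured from the estimated tissue axis instead of the
  image axis.
- **myosin intensity** `m` (z-score units): mean of the per-frame z-scored
  myosin channel over the interface region of interest (§6).

Rates are centred at 30-s differencing by default:
`r_L = Δl/Δt` (µm/min) and `r_θ = Δθ/Δt` (°/min), with the angular
difference taken on the folded circle (shortest signed arc modulo 180°).
Each rate sample is attributed to the **end** of its differencing interval,
which matters for onset estimation (§4).

The central kinematic picture is a pair of orientation laws:

```
dl/dt = −v · cos 2θ          dθ/dt = −ω · sin 2θ
```

so vertical interfaces (θ ≈ 0 after calibration, by convention) contract
fastest, horizontal ones grow, and interfaces rotate toward the nearest
attractor of the angle flow. The analysis recovers these laws empirically by
binning measured rates against orientation; the laws above are also the laws
used by the synthetic generator, which is what makes closed-loop validation
possible.

## 2. Segmentation and tracking

- **Segmentation**: seeded watershed on the smoothed membrane channel.
  Seeds are connected components of the below-Otsu (dark, cell-interior)
  region of the Gaussian-smoothed frame; the watershed floods the smoothed
  image from those seeds. Cells touching the image border can be excluded
  downstream.
- **Cell tracking**: greedy maximal-overlap linking between consecutive
  frames (each label in frame *t*+1 inherits the identity of the frame-*t*
  label with the largest pixel overlap, ties broken by size). Movies whose
  labels are already persistent (e.g. generator output) can skip relinking.
- **Interface extraction**: for every 4- or 8-adjacent pair of cell labels,
  the ridge pixels equidistant between the two cells form the interface;
  a track is the time series of one unordered cell pair. Tracks tolerate a
  configurable number of missing frames (`max_gap`, default 1) before being
  terminated; the birth/end cause (appeared from a vertex, contracted to a
  vertex, left the field, movie boundary) is recorded on the track table and
  consumed by the t1 detector.

## 3. Interface kinematics

`compute_rates` adds `r_L` and `r_θ` columns (30-s differencing by default,
optionally smoothed with a centred moving average before differencing).
`rate_vs_angle` bins the samples by folded orientation (10° bins by default)
and reports per-bin mean, SD and count for both rates; the rate heat map is
the 2-D version binned by orientation and time.

## 4. Calibration: tissue axis δ and flow onset t0

Image axes are arbitrary; the biology defines the axis. `calibrate`
estimates:

- **Axis offset δ**: the orientation law `r_L = −v·cos 2(θ−δ)` implies
  `E[r_L · cos 2(θ−δ)]` is extremal at the true δ. Because
  `mean(r_L·cos 2(θ−δ)) = C·cos 2δ + S·sin 2δ` with
  `C = mean(r_L·cos 2θ)`, `S = mean(r_L·sin 2θ)`, two data moments give the
  whole projection curve in closed form; δ is taken as the minimiser
  (maximal contraction of interfaces aligned with the axis) on a 0.25° grid
  over `(−90°, 90°]`, with a local ±15° window score retained for
  diagnostics.
- **Onset t0**: a polarity score per time bin,
  `P(t) = mean r_L(|θ|>60°) − mean r_L(|θ|<30°)`, computed from end-of-
  interval-attributed rate samples, is fit with a least-squares two-segment
  (step) model. The step time is accepted as t0 only if the fitted jump
  exceeds a multiple (default 3) of its Welch-style standard error; tissues
  with no anisotropic phase return `t0 = None`. A residual-based acceptance
  test was rejected during development because P(t) is pulse-shaped (it
  spikes at onset and then decays), which inflates two-segment residuals
  even for unambiguous onsets.

`apply_calibration` rewrites θ relative to δ and time relative to t0.

## 5. Rotation analysis

- **Angular MSD**: tracks are grouped by mean |θ| over their first 5 min
  (15° bins by default; a 90° bin width pools everything), and the mean
  squared angular displacement `⟨Δθ²⟩(τ)` is computed per lag on the folded
  circle. The exponent γ is the log–log slope over lags of 1–8 min:
  γ ≈ 2 for deterministic (ballistic) rotation, γ ≈ 1 for an angular random
  walk.
- **Rate–angle curves and zero crossings**: the binned `r_θ(θ)` curve is
  scanned for sign changes with linear interpolation; for the orientation
  laws above the crossings sit at θ = 0 (attractor) and θ = ±90°
  (repeller).
- **Phase portrait**: the joint `(θ, l)` flow field assembled from the
  binned rates, with streamline integration for visualisation.

## 6. Oscillation phase and the ratchet

Cell areas oscillate; interface shortening is gated by the phase of the
neighbouring cell's oscillation.

- **Phase extraction**: the area trace is detrended (subtracting a long
  moving average of one estimated period), the dominant period is taken from
  the Hanning-windowed periodogram, and the phase is the analytic-signal
  angle (Hilbert transform) mapped so that **ϕ = 180° at the area maximum,
  ϕ = 270° at the fastest area decrease, and ϕ = 90° at the fastest
  increase** — i.e. the oscillation is modelled as `A(ϕ) = b − c·cos ϕ`.
  Traces shorter than 1.5 estimated periods are rejected as
  indistinguishable from a trend.
- **Ratchet curves**: each detected cycle of a neighbour cell contributes a
  length-change profile ΔL(ϕ) interpolated onto a common grid of **40 phase
  points spaced 9° apart starting at ϕ = 0**, anchored so that
  **ΔL(0) = 0 exactly** (each cycle is referenced to its own start). The
  population ratchet is the per-gridpoint mean with confidence band; net
  shortening per cycle is ΔL(351°).

## 7. Myosin intensity

The interface ROI is every pixel within a Euclidean distance of 4 px
(default) of the interface ridge, computed by distance transform, clipped to
a corridor between the interface endpoints (with a margin) so that the ROI
does not bleed around the vertices onto neighbouring interfaces. A single
isolated ridge pixel therefore yields the 49 lattice points with
x² + y² ≤ 16. Each intensity frame is z-scored (`(I − mean)/SD`) before
averaging over the ROI, which makes `m(t)` exactly invariant under per-frame
affine intensity transforms — uniform photobleaching and detector
gain/offset drift cancel by construction. Aggregates: the myosin–orientation–
time heat map and event-aligned averages around t1 vertices.

## 8. t1 accounting

- **Detection**: a *contraction* is a track whose end cause is "contracted"
  (length collapsed below the vertex scale); an *appearance* is a track born
  "appeared-from-vertex". A contraction of pair {a, b} is linked to an
  appearance of pair {c, d} when {c, d} are common neighbours of {a, b}
  around the vertex and the appearance follows within a 3-min window;
  nearest-in-time wins. For linked events the vertex time `t_vertex` is the
  midpoint between last sight of the old interface and first sight of the
  new one; unlinked events carry their own bounding time.
- **Counting**: per-cell transition counts, grouped by how long the cell is
  continuously visible (the longest continuous run of frames), with border
  cells excludable.
- **Starting angles**: for each linked t1, the orientation of the
  contracting interface at flow onset t0 (tracks not visible at t0 are
  excluded) against `t_vertex` — later transitions start at larger |angle|.
- **Survival**: count of initially vertical interfaces (|θ| < 30° at t0)
  still present as a function of time.

## 9. Synthetic ground truth

Two generators provide closed-loop validation; their **defaults are the
study conditions** and are never tuned to make an analysis succeed.

**Interface-track generator** (`generate_interface_tracks`): ensembles of
independent interfaces integrated with explicit Euler (Δt = 30 s) under
`dl/dt = −v·cos 2θ · gate(ϕ)` and `dθ/dt = −ω·sin 2θ` with v = 2 µm/min,
ω = 3 °/min; the oscillation gate is `1 − bias·sin ϕ` (period 120 s,
amplitude 0.1, bias 0.5) and the observed length adds
`amplitude·l₀·(1 − cos ϕ)/2`. Observation noise: Gaussian angle noise
(SD 2°/step) and proportional length noise (SD 5%). Initial lengths are
uniform on 2–6 µm, orientations uniform. Ground truth (noiseless states,
true rates, true phase) is returned alongside.

**Tissue-movie generator** (`generate_tissue_movie`): a jittered-grid
Voronoi mesh (12×12 cells by default) whose vertices move under the tissue
flow after onset t0 = 5 min (v = 0.5 µm/min, ω = 2.5 °/min, optionally
rotated by a programmed axis offset δ), with per-cell area oscillations,
optional scripted t1 events (contract at a given time, hold a fourfold
vertex, resolve into the perpendicular pair) and automatic t1s when edges
collapse. Frames (15-s interval, 0.15 µm/px) are rasterised into a label
movie plus membrane and myosin channels; myosin intensity on an interface
follows its contraction state and an exponential bleach (10-min scale) that
the z-scored measurement must cancel. Generation is bit-identical for a
fixed seed.

## 10. Numerical choices

- Orientation arithmetic is always on the folded circle
  ((−90°, 90°], shortest signed arc mod 180°); phase arithmetic mod 360°.
- Integration: explicit Euler at the observation cadence; rates by finite
  differences at the same cadence, never by differentiating smoothed
  splines.
- δ search: closed-form two-moment projection, 0.25° grid.
- MSD exponent: unweighted log–log least squares over 1–8 min lags.
- Group statistics: Weibull (type-6) plotting-position percentiles for box
  summaries; Welch/pooled t, Kolmogorov–Smirnov, one-way ANOVA with
  Tukey–Kramer, and Kruskal–Wallis with tie-corrected Dunn tests under
  Šidák adjustment.
- Determinism: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); reruns are bit-identical.

## 11. Known limitations

- **δ recovery is limited by the realised mesh, not the estimator.** A
  12×12 Voronoi tissue has a quenched random anisotropy axis a few degrees
  away from the programmed δ; an oracle fit on noiseless ground-truth
  kinematics shows the same few-degree scatter. Expect |δ error| up to
  ~3° at this tissue size.
- **Binned r_θ curves are noise-limited.** With per-step angle noise of 2°
  and 30-s differencing, each rate sample carries ≈5.7 °/min of noise;
  near-vertical orientation bins are depleted as interfaces contract, so
  per-bin standard errors of ~0.25 °/min persist regardless of movie
  duration. Curve-level comparisons (signs, zero crossings at the ±5–6°
  level, amplitudes at the ~20% level) are reliable; per-bin agreement at
  the 10% level is only achievable at reduced noise.
- The onset estimator assumes a single step-like transition from isotropy
  to polarised flow; gradual ramps bias t0 late.
- The segmentation is tuned for clean membrane markers; heavy speckle or
  out-of-focus frames degrade the interface ridge and thus length
  estimates.
- The t1 linker requires the new interface to appear within 3 min and the
  quartet topology to be observed; occlusions at the vertex leave events
  unlinked (they are still counted).
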