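# Methods

## The ring model

The marginal zone is idealised as a one-cell-thick ring of `n_cells = 100`
cells with periodic boundary conditions; after the anterior-half cut it
becomes an open segment with reflecting (no-flux) ends, on the reasoning
that gap-junctional transmission cannot cross a wound. Each cell carries
three continuous variables and one latch:

| symbol | meaning | units |
|---|---|---|
| `B_i` | BMP4, streak inhibitor | conc. |
| `V_i` | cVG1/GDF3, streak inducer | conc. |
| `C_i` | calcium activity (amplitude × local firing fraction) | activity |
| `A_i` | streak identity, latched when `B_i ≤ β_C` | binary |

Dynamics:

```
dB_i/dt = k_B P(C_i; α) − (γ₀ + γ_C C_i + γ_V V_i) B_i
dC_i/dt = k_C A_i + D/Δx² (C_{i+1} + C_{i−1} − 2 C_i) − λ C_i
dV_i/dt = k_V Q(B_i; β_V) − μ V_i
```

`P` is an increasing and `Q` a decreasing threshold function; in
`heaviside` mode they are steps with the boundary on (`H(0) = 1`), in
`hill` mode the Hill forms `C⁴/(α⁴ + C⁴)` and `β_V⁴/(β_V⁴ + B⁴)` with
coefficient 4. The latch is one-way: once `B_i` touches `β_C`, `A_i = 1`
forever. Time is in hours, space in cell lengths; `t = 0` is the cut, so
intact-phase times are negative.

The initial condition is the unique linear-in-arc-distance BMP4 gradient
through the pinned values `B = 1.1` at the two cells flanking the
posterior pole and `B = 2.2` at the two flanking the anterior pole (cell
centres sit at half-integer arc distances from the pole, which lies on the
midpoint between cells 99 and 0); `C`, `V`, `A` start at zero.

Mechanism, in words: posterior cells start below `β_V`, so cVG1 rises
there and accelerates BMP4 decay; the posterior-most cells cross `β_C`
first and commit. Committed cells source calcium activity, which spreads
almost instantaneously on the scale of the other rates (`D` large) and
turns BMP4 production back on everywhere above the tiny threshold `α`,
arresting further commitment — production rescues every cell whose
activity-dependent decay is not overwhelming, which is everyone except the
streak itself (`γ_C C` large there). The result is one narrow streak arc
straddling the posterior pole and a stable activity gradient that
maintains the BMP4 gradient. Cutting out the posterior arc removes every
source: activity collapses at rate `λ`, production shuts off once `C < α`,
BMP4 decays ring-wide, and the slightly oblique cut (arc shifted by
`obliquity_offset` cells) gives the posterior-leaning edge a small head
start to `β_C`. Its commitment re-ignites activity, which crosses the
fragment fast enough to rescue the opposite edge before it, too, commits.

### Reference parameter set

The shipped defaults are a calibrated reference set, not published values
(users reproducing specific printed timings should override them through
the YAML config):

```
k_B = 0.6    α = 3e-4    γ₀ = 0.08   γ_C = 0.25   γ_V = 0.6
k_C = 12     D = 4800    λ = 2       k_V = 1      μ = 2
β_C = 0.4    β_V = 1.3   Δx = 1      Δt = 1e-4 h
```

They were chosen, by simulation, to satisfy simultaneously: (a) at the end
of the intact phase the gradient still has `B > β_V` anteriorly and
`B < β_V` posteriorly; (b) the intact ring commits exactly one contiguous
posterior arc; (c) the anterior-half scenario shows transient bilateral
cVG1 induction resolving to a single streak on the posterior-leaning edge
for every obliquity offset in {±1, ±2, ±3}, in both Heaviside and Hill
modes. The binding constraint is (c) with |offset| = 1 in Hill mode, where
the asymmetry between the edges is smallest: the rescue wave must cross
~80 cells within the commitment lag between the edges, which requires `D`
near the explicit-scheme stability bound (`Δt ≤ Δx²/2D`; 4800 leaves a
4 % margin at Δt = 10⁻⁴), a production threshold `α` small enough that the
far edge feels a 1–2-cell source across the fragment, and `λ` large
enough that post-cut activity still clears in a few hours. With this set
the timeline is slower than the published one (commitment ~8.9 h post-cut
rather than ~3 h); the default `post_cut_duration = 14 h` is a recording
window chosen to outlast the losing edge's cVG1 transient, not a
biological claim.

### Numerics

Forward Euler at `Δt = 10⁻⁴ h` (first order; the convergence check
measures the order on the smooth Hill variant, since step-function
switching makes pointwise order ill-defined at crossing times). Any
negative concentration produced by undershoot is clamped to zero and
counted (`SimulationRecord.clamped_negatives`; zero under the reference
set). Non-finite values abort with the offending time. The discrete
Laplacian conserves total activity exactly on the ring and under no-flux
ends, which the tests assert to 10⁻¹⁰ relative. Snapshots are recorded
every `record_interval = 0.05 h`; commitment events are recorded at the
exact step where the latch flips, so event times are Δt-accurate.

## Trace analysis

`compute_dff` scales to 100 × (F − F0)/F0 with F0 the temporal mean —
invariant to multiplicative rescaling of the raw intensities.

`als_baseline` is asymmetric least squares: minimise
`Σ w_i (y_i − z_i)² + 10^smooth Σ (Δ²z)²` with `w = 0.001` above the
current baseline and `0.999` below, re-weighting for up to 10 iterations
or until fewer than 2 % of weights change. `smooth = 4` maps the
"smoothing factor" to the exponent of the roughness penalty; at this
stiffness the baseline tracks constants, ramps and slow monotone
(bleaching-like) drift essentially exactly while ignoring sparse positive
transients (heights preserved to 5 % in the tests), but it cannot follow
oscillatory drift with period comparable to the record (a known
limitation; lower `smooth` if that matters). With such extreme asymmetry
the fitted baseline sits on the *lower noise envelope*, roughly 1.3 σ
below the mean — the detector therefore re-centres on the median before
measuring heights.

`detect_spikes` keeps the classical structure — smooth, take local maxima
in a `local_points = 5` frame window (ties to the earlier frame), filter
by height — but with detection engineering needed for reliable calls at
amplitude/noise = 5:

- candidates are collected at two smoothing scales, the coarse
  `smooth_window = 20` average and a fine `local_points`-frame average,
  because a 60 s boxcar cannot separate transients 30 s apart;
- each scale is gated at `noise_floor_sigma = 3.5` × a noise estimate from
  the median absolute deviation of first differences (transients are slow
  relative to frame noise, so they barely inflate it), scaled by `1/√window`;
- candidates are localised on the fine-smoothed trace, then snapped to the
  unsmoothed maximum within ±2 frames — a wide unsmoothed argmax would let
  tail noise capture the peak;
- acceptance is greedy, tallest first, with two suppression rules: an
  exclusion radius of ~`smooth_window/3` frames for shoulders of the same
  transient, and a predicted-tail veto — a later candidate within 4
  predicted FWHMs of an accepted call must exceed twice that call's
  extrapolated half-life decay plus the noise floor. The predicted scale is
  stretched 1.3× for sharp-rise/slow-decay shapes (right half-width > 1.5 ×
  left), whose measured FWHM understates the tail;
- amplitude and FWHM are measured on the unsmoothed, median-centred trace;
  FWHM by linear interpolation at half height, mirroring the measured side
  if the trace ends before the other crossing; finally the 10 %-of-maximum
  height filter is applied.

On synthetic traces this yields recall and precision ≥ 0.95 at
amplitude/noise = 5 with inter-spike intervals ≥ 2 × FWHM (both transient
shapes), exact recovery noise-free, and FWHM within one 3 s frame. Known
limitation: under strong *oscillatory* drift plus ALS the precision
degrades (~0.9) because residual drift curvature survives baseline
removal.

`trace_stats` reports `1000 · n / duration` mHz and the mean call
amplitude (absent when there are no calls).

## Track analysis

`link_events` is LAP-style particle linking: per consecutive frame pair, a
minimum-cost assignment on squared distances with a hard 90 µm gate,
using the standard birth/death augmentation (alternative cost 1.05 ×
gate²) so unmatched events are allowed. Track fragments whose end and
start are ≤ 90 µm apart with a frame difference of exactly 2 (one dropped
frame) are merged by a second assignment (gap closing). A leftover
singleton within 90 µm of a linked source in the previous frame is
recorded as a *branch*: a separate track whose `parent_id` names the
source track, so splitting is represented while every event still belongs
to exactly one track. Linking depends only on pairwise distances, hence is
invariant to rigid motions of the coordinates.

Durations are last-minus-first event time and require ≥ 2 events. Net
displacement angles use `atan2` on the coordinates as given (flip y at the
I/O boundary for image-convention data) and are binned half-open into
quadrants Q1 [0°, 90°) … Q4 [270°, 360°); zero-displacement tracks are
reported as unclassified rather than forced into a bin.

`sector_histogram` divides the masked annulus (or arc — the angular extent
is detected from the mask, and an arc is split over its own span) into
equal angular sectors s1…s4 about the mask centroid, histograms each
sector's pixels, fits `area · LogNormal(x; μ, σ)` by least squares on the
histogram, and reports the pixel count above the threshold (default 6)
and the fitted mode `exp(μ − σ²)`. Fit failures are reported per sector,
not raised. Parameter recovery is within 5 % at ≥ 10⁴ pixels per sector.

`count_active_cells` assigns events to non-overlapping region masks and
single-linkage-clusters each region's event positions at one blob diameter
(13 µm), counting clusters — cells, not firings.

## Synthetic data

The generators emulate the recording conditions the analyses target:
200 frames at 3 s (10 min), ~5 mHz per-cell firing, 15 s FWHM transients,
and an annular marginal zone (inner radius 1500 µm, outer 1620 µm —
~120 µm wide — with 12 µm cell spacing, a 180° arc by default, matching an
anterior fragment). All randomness comes from one integer seed
(`numpy` `default_rng`); identical configs give bitwise-identical output.

Traces: Poisson spike trains (optional refractory `min_isi_s`, default
none), log-normal amplitudes with configurable mean 50 and sd 10 (positive
and right-skewed, consistent with log-normal intensity histograms; a
normal left tail would generate spikes no detector could see), transient
shapes `expdecay` (1-frame rise, decay τ = FWHM/ln 2; the default, typical
of calcium indicators) or `gaussian` (symmetric, for tests of symmetric
measures), additive Gaussian noise (default σ = 5), and optional
bleaching-style exponential baseline drift. Spike times stop two frames
before the record end so every true transient is sampled.

Event fields: each frame, each annulus cell initiates a track with
probability ramping linearly along the arc between the two
`track_init_rate` endpoints (default 0.004 → 0.0004 per cell-frame,
activity highest at the arc start "edge"); tracks hop to a uniformly
random neighbour within `track_step_um = 30` every frame and live a
geometric number of events (mean 5, minimum 2). `make_sparse_track_field`
instead confines each track to its own arc slot with enough margin that
inter-track distances always exceed 120 µm — a scenario the 90 µm linker
must solve exactly, used for the round-trip guarantee.

`render_movie` draws each event as a Gaussian blob scaled by intensity on
a Gaussian background and also returns the temporal average;
`make_annulus_mask` / `make_lognormal_image` provide mask and
known-parameter intensity fixtures for the sector analysis.

What passing these tests does *not* show about real data: no photophysics
(bleaching interacts with ΔF/F0, shot noise is not Gaussian), no cell
movement (real linking contends with motion, handled upstream by motion
correction), no overlapping sources (real traces come from a source
extraction step), and real track/amplitude distributions are unknown —
the lifetime and amplitude defaults are explicit placeholders.

## Interpretation choices worth knowing

- The baseline "threshold 0.02" is taken as the re-weighting convergence
  criterion (it sits among the baseline settings); the peak "threshold
  height = 10 %" is referenced to the per-trace maximum.
- Gap closing "within 2 frames" means a frame difference of exactly 2;
  consecutive-frame pairs are the linker's job.
- The pooled-frequency check pools spike lists through `trace_stats`
  (Poisson sampling arithmetic); detector unbiasedness is asserted
  separately against the realized ground-truth count under the
  ISI ≥ 2 × FWHM condition, since closer doublets are unresolvable by
  design at these settings.
- The transmission-speed helper reports both the exact half-circumference
  (π·240/2 ≈ 377 cells) and the round figure (380) from which the
  1.27 cells/min bound is conventionally quoted (380/300 min).
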