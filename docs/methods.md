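# Methods

This note documents the models, estimators and numerical choices
behind `pulseattractor`, in the spirit of a statistical package's
methods appendix: what is computed, under which assumptions, and what
the synthetic validation does and does not demonstrate.

## 1. Delay embedding and the u/(v,w) split

An approximately periodic scalar signal x(t), uniformly sampled at fs,
is embedded with delay coordinates (x(t), x(t−τ), x(t−2τ)). The delay
is fixed at τ = T/3, one third of the estimated average cycle length:
with this choice an exactly T-periodic signal maps onto a closed curve
in the plane orthogonal to (1,1,1), and advancing time by T/3 rotates
that plane by 120°, producing the three-fold-symmetric triangular
attractor every downstream feature assumes. Embedding dimension is
fixed at 3; no automatic delay selection (e.g. mutual information) is
attempted — τ is tied to the physiology (one cardiac cycle) rather
than to decorrelation arguments.

The orthonormal rotation

    u = (x+y+z)/√3,  v = (x+y−2z)/√6,  w = (x−y)/√2

splits the trajectory into a baseline coordinate u (any additive
constant c moves u by c√3 and leaves (v,w) untouched — this is exact,
not approximate) and the morphology plane (v,w). Norm preservation
means (v,w) keep the signal's physical units, so attractor size is
commensurable with pulse amplitude. Off-grid delayed values use linear
interpolation: exact on locally linear segments, with error bounded by
the local curvature times (1/fs)².

Baseline wander of frequency f and amplitude a is *attenuated*, not
annihilated, in (v,w): the residual is a near-sinusoidal displacement
of magnitude ≈ √2·τ·a·2πf along a fixed direction. For respiration-
scale wander (f ≤ 0.05/T) this is ≲ 15% of a instantaneously, but it
oscillates with zero mean at a rate incommensurate with the pulse, so
window-averaged statistics are barely affected (see the Size
paragraph below).

## 2. Cycle-length estimation

T is estimated per window from the normalized autocorrelation of the
mean-removed, Hann-tapered window, scanned over a configurable lag
range [T_min, T_max] (defaults: human 0.2–2 s, i.e. 30–300 bpm; mouse
preset 75–200 ms, i.e. 300–800 bpm). Implementation choices, each of
which was found necessary for sub-millisecond accuracy:

- **Hann taper, taper-normalized.** A plain (biased or unbiased)
  finite-window autocorrelation carries two artefacts: a linear
  overlap taper that tilts the peak, and an incomplete-cycle edge
  ripple. Either one shifts the 3-point sub-sample refinement by a
  sizeable fraction of a sample — enough to move a 674 bpm estimate
  to 675. Tapering the data with a Hann window and dividing by the
  taper's own autocorrelation removes both (sinusoid test error
  < 1e-5 s at fs = 250 Hz).
- **Harmonic guard.** Candidate lags are local maxima; the accepted
  fundamental is the *smallest* candidate scoring at least 0.8 of the
  in-range global maximum, so a strong second harmonic cannot halve
  the reported period. The 0.8 threshold is configurable
  (`harmonic_guard`).
- **Multi-period refinement.** The peak near m·T has the same absolute
  lag error as the fundamental peak, so refining the largest usable
  multiple (m·lag ≤ 0.6·window, m ≤ 8, peak value ≥ 0.5 of the
  fundamental's) and dividing by m shrinks the period error roughly
  m-fold. With per-beat period jitter the long-lag peaks broaden and
  weaken; the value threshold makes the estimator fall back to the
  fundamental automatically.
- Sub-sample positions come from a quadratic fit through a peak and
  its two neighbours, clipped to ±0.5 samples.

Failure (no local maximum in range, or a constant window) raises an
error which the tracking layer converts into a flagged output row.

Heart rate is 60/T; user-facing output rounds to integer bpm, full
precision is kept internally.

## 3. Synthetic pulse model

The generator produces beat i on [t_i, t_i + T_i): a half-cosine rise
from the baseline `offset` to `offset + A_i` over α_i·T_i, then the
power-law decay `offset + A_i(1−s)^κ` with s the normalized downstroke
phase. κ = 1 is a straight downstroke; κ > 1 is concave, the
morphology seen when peripheral resistance and compliance fall. Per-
beat (T_i, A_i, α_i) are i.i.d. Gaussian perturbations (relative sd
σ_T, σ_A, σ_α) truncated at ±4 sd and clamped to physical ranges;
sinusoidal wander, linear drift and white measurement noise are added
on top. Realized per-beat parameters are stored in
`signal.meta["beats"]` so estimators can be tested against exact
ground truth. Everything is deterministic given the seed.

The functional form (half-cosine rise, power-law fall) is a modelling
choice: it maps one parameter (κ) monotonically onto downstroke
concavity and one (σ_α) onto upstroke-timing variability while keeping
the total period fixed. The model has **no dicrotic notch** and no
reflected-wave physics (no Windkessel or transmission-line modelling);
beats join continuously at the baseline. Consequences for validation:
passing tests demonstrate the geometry of the method (invariances,
monotone responses, calibration) on clean triangular attractors, not
performance on real arterial data, whose notched, asymmetric beats
produce blunter, denser attractors. Artifact handling, likewise, is
only exercised with synthetic masks.

## 4. Feature definitions and calibration

All features are computed from the (v,w) cloud of one window
(≥ 100 points for densities and size, ≥ 300 for arm statistics).

**Density.** A normalized n×n histogram (default n = 128) on the
square [−B, B]². B defaults to 1.05× the window's largest radial
distance; for cross-window density comparisons a fixed B must be
supplied (`fixed_extent`) — auto-scaling makes each window's grid
individually optimal but mutually incomparable, and the chosen B is
therefore recorded in all output metadata. **Symmetrization** averages
the density with its 120°/240° rotations (bilinear resampling about
the grid origin, clipped and renormalized); for an exactly periodic
signal the attractor is a fixed point of this map.

**Size.** S = c₀ × (interior trimmed mean of radial distances, ranks
10–90%). Radial distances are invariant under the three-fold point
replication, so the statistic is taken on radii directly. The interior
mean was chosen over an outer quantile deliberately: an outer quantile
(e.g. q95) rides on the corner points and inflates by ~15% under
full-amplitude slow wander, whereas the first-order wander term cancels
in an interior average (measured residual < 1%). Rank-based (not
value-based) trimming keeps S *exactly* homogeneous — S(k·x) = k·S(x)
— even on exactly periodic signals whose radii contain large tied
blocks. The calibration constant c₀ = 1.9370498952 is frozen once,
defined so that the ideal calibration pulse (T = 1 s, half-cosine
upstroke over 20% of the beat, straight downstroke, no variability,
500 Hz, 30 s) of amplitude A reports S = A; a test recomputes it from
scratch to guard regressions.

**Rotation.** θ = arg(Σ ρ·e^{3iφ})/3 over density cells, minus a
frozen reference angle (−29.9861265°, the same calibration pulse's raw
angle), wrapped to (−60°, 60°]. The order-3 moment is the natural
orientation statistic for a three-fold-symmetric shape: it is exactly
equivariant (rotating the cloud by β adds β mod 120°) and needs no
template fitting. Positive = counter-clockwise; increasing downstroke
concavity rotates the attractor clockwise (θ decreases). A moment
magnitude below 1e−6 (rotationally symmetric density) is an error.

**Arm widths and edge uniformity.** Points are de-rotated by θ and
partitioned into three 120° sectors centred on the calibration
triangle's side-midpoint directions (30°, 150°, 270° in the canonical
frame; the sector containing the +v axis is arm 1, arms 2–3 follow
counter-clockwise). Per sector, a total-least-squares line (principal
axis of the 2-D scatter) is fitted; the width is the RMS perpendicular
distance, and edge uniformity is the CV of point counts in 20
equal-length bins spanning the 5th–95th percentile extent along the
line. Sectors with < 30 points report NaN. Arm labels are geometric,
not physiological: which arm responds to which waveform manipulation
is established empirically by simulation sweeps (next section),
because
left/right vocabulary depends on plotting convention.

**Periodicity.** Mean available arm width divided by S. Zero for a
perfectly repeating pulse; dimensionless, hence comparable across
subjects and amplifier gains.

**u statistics.** u/√3 averaged (equals the trajectory-mean signal
level) and its least-squares slope in units/s.

## 5. What the simulation sweeps establish

- Size vs amplitude: exactly linear; calibration recovers A within 2%
  at two amplitudes.
- κ ∈ {1 … 3}: strictly monotone clockwise rotation.
- σ_α ∈ {0 … 0.08}: one arm's width grows monotonically and dominates
  (> 1.5× the growth of either other arm); that arm is thereby
  identified as the "upstroke arm". Note a structural fact of the
  τ = T/3 embedding: variability localized in one waveform segment
  displaces three perimeter regions along fixed directions of which
  exactly one is tangent to its local side — so *two* arms always
  respond to any localized variability, one dominantly. Claims that
  exactly one arm moves should be read as "one arm moves most".
- σ_A > 0 raises the periodicity score relative to a jitter-free twin.
- Resampling the same trace at double rate doubles HR and leaves size,
  rotation and widths within 2% (heart-rate independence).

## 6. Tracking, windows, degenerate inputs

Records are split at artifact-mask boundaries; each unmasked segment
is windowed independently (windows never straddle a mask), with
per-segment window count floor((duration − length)/step) + 1. Window
length must cover ≥ 3·T_max — three cycles is the minimum for a
usable autocorrelation. T is re-estimated per window, so slow heart
rate drift is tracked rather than smeared. Windows where estimation
or feature extraction fails are emitted with a diagnostic flag
(`no_cycle`, `too_few_points`, `degenerate`) and NaN features — never
dropped, so row counts remain predictable. Defaults (human: 10 s
window, 5 s step; mouse: 2 s / 1 s) are configurable; optimal window
lengths per species are an open question and these are pragmatic
choices covering ≥ 10 beats.

Degenerate cases: an all-constant cloud has S = 0 (periodicity is then
undefined and reported NaN via the failure path); points exactly on
the grid's upper edge belong to the last bin; quantile ties in the
size statistic are resolved by rank, as above.

## 7. Problem sizes used in validation

The test suite and acceptance checks run on synthetic records of
2–60 s at 250–1000 Hz (≤ 60 000 samples), chosen to keep the full
suite fast while leaving ≥ 10 beats per analysis window and ≥ 2 500
points per attractor; the stationarity check uses a 120 bpm train so
each 10 s window holds 20 beats. All sweeps use 5 parameter levels
with independent seeds per level.

## 8. Known limitations

- Features are only meaningful for approximately periodic signals; the
  pipeline flags but does not attempt to salvage aperiodic windows.
- The attractor geometry assumes τ = T/3; strongly arrhythmic signals
  violate the three-fold symmetry and make rotation/arm features hard
  to interpret (size and periodicity degrade gracefully).
- Densities from different windows are comparable only with a caller-
  fixed extent.
- The synthetic model's idealized beats (no dicrotic notch, no
  reflected waves) mean quantitative feature values on real arterial
  data will differ from the synthetic calibration in detail, though
  the invariances (offset, amplitude scaling, heart rate) are
  structural and carry over.
- Arm widths conflate beat-to-beat variability with any structural
  curvature of a side; for strongly concave downstrokes (κ ≫ 1) the
  sides are curved and the TLS width has a shape-dependent floor.
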