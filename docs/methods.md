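# Methods

## Sensor geometry and the proximity model

The seat array is a grid of square conductive-fabric electrodes (20 mm
side) on the wheelchair seat, 5 rows × 4 columns = 20 channels by default,
spaced at an 80 mm pitch and centred on the seat origin (x positive
rightward, y positive forward, lengths in mm).  The inter-electrode pitch
is not a property of the physics — it is stored explicitly in
`SensorLayout` and configurable, and nothing downstream assumes a value.
Channels are numbered row-major from the rear-left corner, 1-based; the
analysis layer takes channel indices from configuration so any alternative
numbering is recoverable.  The default velocity-channel pair {8, 13} is
point-symmetric about the seat centre under this numbering (mean position
exactly (0, 0)), which makes its average waveform a centred proxy for the
body's arrival.

Each electrode is treated as one plate of a parallel-plate capacitor,
C = ε₀ κ S / L, with ε₀ = 8.854 × 10⁻¹² F/mm (the constant as used by the
measurement chain, with L in mm and S in mm²), κ the relative permittivity
of the clothing layer (default 3, dimensionless), S the electrode area
(default 400 mm²) and L the body–electrode gap, clamped below at
`l_min_mm` (default 2.5 mm, the fully compressed clothing gap).  Fringing
fields, wiring parasitics and fabric mechanics are out of scope; the
parasitic response of an electrode in open space appears only as the
transduction baseline.

## Seating-position index (CoG)

`compute_cog` evaluates the count-weighted centroid per sample.  It is
homogeneous of degree zero in the counts (robust to any overall gain),
confined to the layout's convex hull whenever the total count is positive,
and equivariant under translating the layout.  Samples with zero total
count have no centroid; they are flagged and poison any evaluation window
they fall in rather than being interpolated, so the index cannot be
silently biased.

Completion detection takes the global maximum of CoG_y (first sample on
ties — the earliest completion is the conservative, deterministic choice)
and declares seating complete 5 s later.  No smoothing is applied before
the maximum search by default; an odd-width moving average is available in
configuration for noisy hardware data, in which case the maximum is taken
on the smoothed series.  The index is the arithmetic mean (configurable:
median) of the CoG over the 10 s ending at completion.  A window that
would extend before the recording start is an error, never silently
shortened.

## Seating-velocity coefficient (α)

The two central-region channels are averaged; the fit window is the 1 s of
data ending at the maximum first difference of that waveform —
round(fs · 1 s) samples, i.e. exactly 62 at the native 62 Hz, so the rule
generalises by duration rather than by count at other rates.  The first
difference is taken by default on a 5-sample moving-average copy (raw mode
available): single-sample count noise otherwise creates spurious maxima.
The moving average normalises by the actual kernel overlap at the series
edges; zero-padding there would manufacture large fake derivatives.  Ties
at the maximum resolve to the first occurrence.

The window is fitted with c(t) = e^{α(t−β)} + γ by nonlinear least
squares in the reparameterisation (α, ln A′, γ) with A′ the amplitude at
the window start: A e^{αt} = A′ e^{α(t−t₀)} keeps the exponential well
scaled for any time origin, and β is recovered as t₀ − ln A′/α.
Initialisation: γ₀ from the window minimum and (α₀, A′₀) from a log-linear
regression of c − γ₀ + 1 on t; up to 5 seeded, jittered restarts on
failure.  α is bounded to (0, 100] s⁻¹; a fit that converges onto a bound
is flagged and not accepted — a bound-hitting α means the window does not
look like an exponential rise (a step, or pure noise), not that the
recipient moved at the bound.  Identifiability properties (an additive
count offset moves only γ̂; a time shift moves only β̂) hold to solver
tolerance and are enforced by tests, as is agreement of the solver optimum
with a dense grid-search oracle.

## Reference-device indices

Seat contact t₁ is not directly observable from the force plate, so it is
detected as the first time the CoP deviation magnitude from the pre-trial
baseline (mean over the first 1 s) exceeds a threshold (default 5 mm) and
holds for 0.1 s; threshold and hold are configurable and recorded.  The
deviation magnitude is used rather than a single component because no
component is privileged a priori.  ΔCoP is the mean CoP over the half-open
window (t₂, t₂ + 0.5 s], t₂ = t₁ + 5 s — 300 samples at 600 Hz — minus the
baseline mean; it is invariant to adding any constant vector to the whole
stream.

v_z is taken from dz/dt by central differences: downward-velocity peaks
with prominence and height of at least 5 mm/s, separated by at least
0.5 s, are ranked in time order and v_z is the magnitude of the third
(stand-up adjustment, lateral move, seating descent).  Fewer than three
peaks is a structured error reporting the count found.  The extraction is
invariant to any constant height offset.

## Group statistics

Simple regression is ordinary least squares with the Pearson correlation's
t test, t = r√(n−2)/√(1−r²), two-sided p from the t distribution with n−2
degrees of freedom; constant predictors are rejected and perfectly
collinear responses flagged rather than reported with a meaningless t.

The Mann-Whitney comparison is two-sided and records which method produced
its p-value: the exact null distribution when there are no ties and
n_a·n_b ≤ 400; full enumeration of group splits over midranks for small
tied samples (so two identical samples give p = 1 exactly); and the tie-
and continuity-corrected normal approximation otherwise.  Box summaries
use linear-interpolation quartiles (the common default — quartile values
depend on this rule, so it is recorded in the output) and Tukey 1.5 × IQR
whiskers with remaining points listed as outliers.

p-values are reported in full precision; downstream significance
statements are comparisons made by the reader, not by the library.

## The simulator

The simulator emulates a sit-down transfer in three phases with a known
ground truth (`TrialTruth`) attached to every trial.

* **Gap:** L(t) is `start_height` (200 mm) before `approach_start` (5 s),
  descends linearly at `descent_velocity` (default 50 mm/s, the
  recommended comfortable lowering speed for patient lifts) until only the
  clothing layer (5 mm) remains — that instant is the contact time — then
  compresses exponentially toward `l_min` (2.5 mm) with time constant
  0.3 s.  This produces the rapid-rise-then-plateau count waveform the
  exponential fit targets.  The minimum gap is deliberately not far below
  the clothing thickness: with a much smaller `l_min` the compression
  phase would own the maximum count derivative regardless of descent
  speed, and the fit window would no longer land on the descent.
* **Footprint:** the buttock footprint (300 × 300 mm) sweeps in over the
  front edge of the seat (entry centre +300 mm) while the body is still
  high, finishing the sweep at 100 mm height, lands 15 mm forward of the
  final `seat_offset` and settles back with a 0.6 s time constant.  The
  sweep plus overshoot give CoG_y its characteristic rise-then-settle
  shape with an interior maximum for any seat offset — without them,
  rearward offsets would have their CoG_y maximum at the pre-approach
  baseline and the completion rule would degenerate.  The settle constant
  is deliberately slower than the compression constant so the post-contact
  CoG_y tail is decreasing and the maximum is well defined.  Per-channel
  weights are the electrode's overlap with the footprint whose boundary is
  Gaussian-softened (40 mm): body pressure tapers at the edges, and on a
  20 mm-electrode / 80 mm-pitch grid a hard-edged rectangle would make the
  centroid piecewise-constant in the offset.
* **Transduction:** counts = clip(round(baseline + gain · w · C(L) +
  noise), 0, saturation) with baseline 200 counts (parasitic response —
  uncovered channels carry it too, which keeps the pre-approach CoG near
  zero without any baseline subtraction), gain 10¹¹ counts/F (≈ 625 counts
  per fully covered electrode at the compressed gap), Gaussian noise of
  sd 2 counts, hard saturation at 20 000.  The real chain only guarantees
  a monotone capacitance-to-count map, so the simplest affine model is
  used.  The count scale is arbitrary; every analysis that should be
  scale-free (the CoG) is, and only γ of the exponential fit is
  scale-sensitive.
* **Force plate (600 Hz):** baseline before contact, then a damped
  oscillation (rate 2 s⁻¹, 1.2 Hz) toward a displacement equal to
  `cop_gain · seat_offset`, stable well before contact + 5 s, plus
  Gaussian noise (0.3 mm).  The designed ΔCoP is part of the trial truth.
* **Head marker (120 Hz):** z(t) is the analytic integral of three
  Gaussian downward-velocity pulses — two fixed-size excursions (20 and
  30 mm/s; the stand-up and lateral-move speeds do not scale with the
  seating descent) and the seating descent centred at contact with peak
  exactly v_z.  Exactly three excursions means the third-peak rule is
  exercised non-trivially.

All randomness flows from a single per-trial seed; identical inputs give
bit-identical streams.  Trials auto-size to contact + 8 s, enough for the
completion rule and the force-plate stable state.

### What the simulator does and does not show

The generator reproduces the *structure* of real trials — multi-rate
streams, baseline/rise/plateau counts, CoP relaxation, three-phase head
motion — with clean, parameterised ground truth.  It does not model
whole-body biomechanics, caregiver kinematics, asymmetric pressure
distributions, electrode-to-electrode gain variation, or drift.  Passing
round-trip tests therefore demonstrates that the analysis pipeline
recovers what the streams encode, not that the hardware encodes it; the
regression and group-difference magnitudes on synthetic studies
(e.g. r ≈ 0.98 between α and v_z) are cleaner than hardware data would
give, because simulated α and v_z derive from the same underlying descent.

## Numerical and calibration choices

* Timestamps are stored explicitly and checked uniform to 10⁻⁶ s; the
  three streams are never resampled — each index is computed on its native
  stream.
* Writers format floats as `%.17g` and readers parse with round-trip
  precision, so read(write(x)) is bit-exact.
* The Monte-Carlo check of the exponential fit under noise uses true
  (α, β, γ) = (0.5, 1, 100) with the 1-s window placed at t ∈ [12, 13],
  where the exponential term rises by ≈ 160 counts across the window —
  comparable to the count rise the rule actually fits.  Earlier window
  placements make the arc nearly linear at amplitudes below the noise and
  test identifiability rather than the estimator.
* Property tests of the simulated α–velocity relation average 10 seeds per
  velocity at the default noise level; the offset-grid tests run
  noiseless.  Both complete in seconds, so no scaling-down of the stated
  designs was needed.

## Known limitations

* The completion rule assumes seating moves CoG_y through a maximum; a
  recipient sliding forward *after* settling would register a later
  completion.
* α depends on the transduction scale through the fit window's amplitude;
  only comparisons within one hardware configuration are meaningful.
* Contact detection needs a nonzero CoP displacement; a perfectly centred
  landing on an ideal plate is undetectable from the force plate alone
  (the simulator's centred trials are used with the known contact time
  instead).
* The tie-aware exact Mann-Whitney path enumerates group splits and is
  limited to small samples (≤ 50 000 splits); larger tied samples fall
  back to the corrected normal approximation, as recorded in the output.
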