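# Methods

## Task geometry and conventions

The coordinate frame is x to the subject's right, y forward, z up.  The
azimuth of a point seen from the start marker is `atan2(x, y)` in degrees —
0° straight ahead, positive to the right, matching the table protractor of
the emulated task.  Quaternions are scalar-first `(w, x, y, z)`,
right-handed, world-from-body; the head's forward axis is body +y.  Time is
stored as a sample index plus the sampling rate (100 Hz by default), so
grid-uniformity checks never accumulate floating-point drift.  Interfaces
use metres, seconds and degrees.

Targets lie at azimuths −35°, −20°, 0°, +20°, +35° at 0.60 m.  Conditions:
A (250 ms target sound), B (2000 ms), C (250 ms + veridical auditory hand
avatar), D (250 ms + avatar shifted 18.5° left).  The conflicting-avatar
transform is a world-frame azimuthal shift of the rendered hand direction;
whether the original apparatus applied it in world or head-centred
coordinates is not documented, so the world-frame choice is explicit and
the head-centred conversion (`head_relative_azimuth`) is available.

## Filtering and differentiation

Positions are smoothed with a zero-phase Gaussian low-pass filter.  A
"cut-off frequency" needs a gain convention; the kernel scale is fixed by
the −3 dB point: `sigma = sqrt(ln 2) / (2 pi fc)` seconds, so the gain at
`fc` = 5 Hz is 1/√2.  The kernel is truncated at ±4σ, normalised to unit
sum (DC gain exactly 1), with reflection padding at the edges.  Derivatives
are central differences (one-sided at the series edges); v3D, a3D and j3D
are Euclidean norms of the successive derivative vectors.  j3D is computed
and exported but drives no downstream statistic.

## Movement segmentation

Segmentation is two-stage:

1. **Primary (displacement) stage** — the first contiguous run of samples
   whose horizontal distance from the start marker exceeds 2 cm, truncated
   at the *last* sample attaining the maximum displacement.  This isolates
   the outbound gesture and discards the return to the tactile marker.  The
   2 cm value is a repo choice: it clears marker jitter while catching the
   movement well before the velocity refinement.
2. **Velocity refinement** — within the candidate window the peak-velocity
   point (PVP) is the argmax of v3D; onset is the last sample at or before
   the PVP with `v3D ≤ 0.03 · v_peak`, offset the first such sample at or
   after it.  The walk starts at the PVP and moves outward so that noise
   bumps far from the movement cannot capture a bound, and it may leave the
   displacement window (the displacement stage only locates the gesture).
   If the threshold is never reached before a series edge, the edge is used
   and flagged.

For a noise-free minimum-jerk reach the 3% crossing solves
`30 τ²(1−τ)² = 0.03 · 1.875`, i.e. τ = 0.045359; the detected bounds land
within one sample of the root-found values across amplitudes 0.2–0.6 m and
durations 0.5–2 s.  Note that the 5 Hz filter spreads speed into the
profile tails and moves the measured crossing 1–2 samples earlier, so
closed-form checks are run on unfiltered noise-free profiles.

**Acceleration peaks** are strict local maxima of a3D within the movement
bounds with prominence at least 5% of the in-bounds maximum (suppressing
numerical ripple); plateaus count at their first sample, and a peak exactly
at the PVP counts as "after", which makes before + after = total exact.
The same rule is reused for the head's angular acceleration.

## Heading

Heading is the azimuth of the head's forward axis projected on the
horizontal plane (pitch and roll are ignored), unwrapped, then filtered
with the same Gaussian filter.  A forward axis within 5° of vertical is
rejected as degenerate.  Head ROM (max − min yaw) is computed over the
whole trial window, not only within the hand bounds, because head orienting
typically starts before hand onset; restricting it would truncate the
phenomenon.  The window is an argument, so the hand-bounds variant is one
call away.  The head peak-velocity position is located over the trial
window but expressed relative to the hand bounds and clipped to [0, 1], so
a head that peaks before hand onset reports 0.

## Pointing errors and exclusions

The pointed direction is the azimuth of the filtered hand position at the
movement offset, the in-silico equivalent of reading the protractor.
Endpoints within 5 cm of the marker raise an unstable-angle error — a
numerical guard distinct from the 10 cm subject-level exclusion.  The
signed error is pointed − target (negative = left of target).

Subject-level exclusion rules, applied after per-trial analysis:

1. **slow_indirect** — mean movement duration > 2 × the cohort mean *and*
   > 2.0 s (the longer stimulus duration).  The cohort mean is computed
   once over all subjects before any removal, making the rule
   order-independent.
2. **no_target_dependence** — pointed-vs-target regression slope < 0.1, or
   ≥ 90% of endpoints within 5° of ±90°.  The source description of this
   rule is qualitative; both sub-criteria and thresholds are exposed in
   `ExclusionThresholds`.
3. **short_trajectory** — median path length < 0.10 m.

A subject tripping several rules is attributed to the first in this order.

## Statistics

Features are averaged per subject × condition × target into a balanced
design table (flagged trials dropped; subjects with missing cells dropped
with a warning, since classical repeated-measures ANOVA requires balance —
no imputation).  The two-way repeated-measures ANOVA (condition × target
within subjects) is computed by pingouin; reported degrees of freedom are
uncorrected (no sphericity correction is applied; a Greenhouse–Geisser
column exists in the engine but is not used).  With all cells equal every
sum of squares vanishes and the engine returns 0/0; the wrapper maps this
null case to F = 0, p = 1.  Post-hoc comparisons are Bonferroni-adjusted
over all pairwise levels of the tested factor.  Order (group) and HRTF
ownership enter as between-subject factors through a mixed ANOVA
(`mixed_anova`, one between factor at a time).  The test suite checks the
engine against an independent textbook sums-of-squares decomposition on
small balanced tables (agreement to 1e−8).

## Synthetic generator

The generator emulates the statistical structure the analysis assumes —
it exists so that every pipeline stage is testable without recordings.

* **Transport**: straight minimum-jerk reach (default 0.45 m, 1.1 s with
  8% lognormal duration jitter) from the marker to an endpoint at azimuth
  `gain_c · θ_target + bias_c + ε`, `ε ~ N(0, noise_sd_c)`; then a hold
  (1.0 s) and a minimum-jerk return.  The multiplicative gain reproduces
  eccentricity-dependent overshoot ("perceived auditory space wider than
  real"), the constant bias the leftward shift of straight-ahead pointing.
* **Submovements**: Poisson-many out-and-back minimum-jerk excursions
  (net displacement zero) along the reach direction ±30°, onsets uniform in
  [0.50, 0.80] of the reach for deceleration-phase corrections plus a small
  early-correction rate in [0.12, 0.35]; amplitudes `N(0, 11 mm)`,
  durations 0.25–0.35 s.  Random-direction displacements were rejected:
  components orthogonal to the main deceleration add in quadrature inside
  the a3D norm and leave almost no peak signature, and onsets later than
  ~0.8 of the reach get cut off when the excursion's turnaround dips v3D
  under the 3% offset threshold.
* **Head**: one minimum-jerk yaw excursion of amplitude
  `head_gain_c · θ_target + N(0, head_base_sd_c)` starting
  `N(head_lead_s, head_lead_sd_s)` before hand onset (defaults 0.10 ±
  0.15 s) and lasting 0.7 of the reach duration, easing back to 0 during
  the return.  The lead makes the head's peak velocity fall early in the
  hand movement, as orienting reactions do.
* **Noise**: isotropic Gaussian marker noise (0.25 mm at the calibrated
  default — within optical mocap precision; the raw field default is
  0.5 mm) and 0.1° yaw noise.

The pseudo-random target order (32 trials per condition; every target at
least 6 times) is drawn from a dedicated `order_seed` fixed across
subjects, mirroring the protocol's "same pseudo-random order for each
subject"; the trajectory-noise seed varies per subject.  Generation is a
pure function of (config, params, seed): same seed ⇒ byte-identical
session files.

### Calibration

`default_calibration()` fixes the per-condition parameters so that the
*pipeline's output* on a large generated cohort approximates the
study-level condition means: ≈26° mean absolute error in A, a −9.8°
straight-ahead bias in B, head ROM means ≈ 5.3/21.9/7.4/5.2° for A/B/C/D,
acceleration peaks ≈ 1.52 before / 2.84 after the PVP with condition
totals ≈ 4.85 (B) vs 4.20.  Calibration is approximate by construction —
the reference values are means over a human cohort and no fitting loop is
shipped; on a 50-subject synthetic cohort all reference means are
reproduced within ~7% (the suite's calibration check allows 15%).

What the generator does *not* emulate: between-subject variability beyond
the noise terms, arm biomechanics and posture, velocity/path asymmetries
between left and right hemispace, reaction times, closed-loop responses to
the avatar shift (the emulated study found no accuracy effect of the
shift), and any acoustics (HRTFs appear only as metadata).  Passing tests
therefore validate the *measurement pipeline* — segmentation, features,
statistics — not claims about human behaviour.

## Problem sizes and determinism

The test suite generates cohorts of up to 50 subjects × 128 trials
(~4 s of movement per trial at 100 Hz), which keeps every check well under
a minute while leaving standard errors on cohort means near 1%.  All
randomness flows from explicit seeds; hypothesis property tests run
derandomised.

## Known limitations

* The original "semi-automatic" segmentation implies manual vetoes that
  cannot be reconstructed; the automated displacement + 3% rule stands in.
* Head acceleration peaks are counted on angular (yaw) acceleration; the
  original analysis may have used 3-D positional acceleration of the head
  rigid body.
* The exclusion rule for target independence is an operationalisation of a
  qualitative description; its thresholds are config-exposed rather than
  canonical.
* At 0.5 mm marker noise the filtered-noise ripple can add up to two
  acceleration peaks per side of the PVP; robustness to one peak holds at
  the calibrated 0.25 mm level.
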