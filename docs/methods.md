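# Methods

## Machine model and conventions

The simulated machine is an ideal two-axis gimbal with a fixed pivot: an
outer frame rotating about the laboratory x-axis (angle α) carries an
inner frame rotating about the outer frame's y-axis (angle β).  The
laboratory frame is z-up with gravity `(0, 0, −g)`, g = 9.80665 m/s².
Rotation composition is `R = Rx(α)·Ry(β)` (inner → lab), so the gravity
direction in the sample frame is

    u = Rᵀ(0,0,−1) = (sin β cos α, −sin α, −cos β cos α).

No axis convention is canonical for these machines; any consistent choice
is equivalent up to a global rotation, which every statistic used here is
invariant to.  The convention above is used in every module and at the CSV
interfaces.  Angles are unwrapped reals (planners accumulate turns),
radians and seconds internally; degrees appear only in the CLI.

The pivot is treated as stationary: a benchtop machine rotates but does
not translate, so the sample position is `r_c(t) = R(t)·r_pc` with `r_pc`
the mount offset in inner-frame coordinates.  The general decomposition
`r_c = r_p + r_pc` is retained in the data model, with `r_p ≡ 0`.

**Assumptions.** Rigid body, ideal actuators (the planned kinematics are
executed exactly), no fluid dynamics inside flasks, no external forces
beyond gravity and the kinematic apparent force (`F_a = m·a`,
`F_g = m·g`, with `m = ρ·V_c`).  Shear, buoyancy and magnetic effects are
out of scope.

## Point kinematics

The body angular velocity is assembled analytically from the stored axis
rates, `ω = (α̇ cos β, β̇, α̇ sin β)` in inner-frame coordinates, and its
derivative from the stored rates *and* accelerations — not by numerical
differencing — so the acceleration of an off-centre point,

    a_lab = R·(ω×(ω×r_pc) + ω̇×r_pc),

carries no sampling error.  A finite-difference cross-check (3-point
central second difference of the lab-frame position, O(dt²)) is exposed
separately; the test suite verifies second-order convergence between the
two routes (log–log slope 2 when dt is halved).  The 3-point stencil is
deliberate: it has the textbook O(dt²) error that the convergence check
asserts, whereas a 5-point stencil would converge at fourth order and hit
the rounding floor almost immediately.

## Residual gravity

`residual_gravity` reports the running mean of u(t) scaled by g; its
magnitude in units of g equals the mean resultant length of the direction
sample by construction (an exact identity, also used as the brute-force
cross-check in tests).  It starts at 1 and lies in [0, 1].

## Uniformity statistics and the 3.633 threshold

With pairwise angles Θij over i < j,

    A_n = n/2 − (2/nπ) Σ Θij,   G_n = n/2 − (4/nπ) Σ sin Θij.

Two normalizations of the uniformity factor are implemented:

* `sum` (default): `F* = A_n + G_n`.  Under the iid-uniform null its mean
  is exactly 1 (E Θ = π/2, E sin Θ = π/4) and its Monte-Carlo 95th
  percentile is ≈ 1.68, essentially independent of n ≥ 100.
* `classical`: `F* = 2·A_n + G_n`, identical to the classical Giné
  statistic `F_n = 4·A_Ajne + G_n` with `A_Ajne = n/4 − (1/nπ) Σ Θij`.
  Its calibrated null 99th percentile is 3.62 ± 0.02 (n = 100…400,
  30,000 replicates) — matching the threshold 3.633 quoted as the
  "optimal" uniformity factor in the random-positioning-machine
  literature.  We therefore read that literature value as the asymptotic
  upper 1% critical point of the classical statistic, and
  `calibrate_null` is the instrument that anchors whichever normalization
  is in use.  Headline comparisons against literature scores (3.6 for
  optimized designs, ≈ 190 for random control) are made on the classical
  scale.

Numerical care: Gram-matrix diagonals are forced to an exact unit dot
product before `arccos` (u·u evaluates to 1−O(ε) and arccos amplifies
that to O(√ε)); off-diagonal dots are clamped to [−1, 1].  Pair sums are
computed block-wise, bounding memory at ~16 MB for n = 10⁴.

Because the statistic assumes iid samples while a motion path is serially
correlated, paths are decimated before scoring (default: keep ~1000
points).  Correlation inflates F\*; the planner's scores are quoted on the
decimated path, as is customary for these machines.

## The optimized planner

The published descriptions of optimized microgravity trajectories state
goals (uniform coverage, minimal uniformity factor, zero/partial gravity,
jerk-limited smoothness) but not an algorithm.  The planner implemented
here is the package's own design:

1. **Waypoints.** Zero-gravity mode: a spherical Fibonacci lattice
   (default 64 points), re-rotated by a seeded random rotation on each
   full pass so successive passes do not repeat endpoints.  Partial mode:
   von Mises–Fisher draws about −z with κ solved from
   `coth κ − 1/κ = target_g`, so the waypoint set itself has the target
   mean resultant length.
2. **Ordering (compensation on).** Waypoints are visited greedily: the
   candidate minimizing the predicted distance between the accumulated
   direction sum and the target ray `n·(0,0,−target_g)` is chosen, using
   a closed-form segment-time estimate and the geodesic mean of the
   transit arc as the prediction.
3. **Joins.** Each move is a rest-to-rest seven-phase S-curve per axis
   (closed-form phase times, exact endpoints), the faster axis resting
   while the slower finishes.  Rate, acceleration and jerk limits hold at
   every sample by construction; rest-to-rest joins keep the limits valid
   across segment boundaries.
4. **Trim (compensation on).** The final ~2% of the run cancels the
   remaining imbalance deterministically: short transits toward the
   deficit direction, then a balanced fill of dwells at that direction and
   its exact antipode (reached by outer-axis half turns; the two half
   turns traverse opposite halves of a great circle so their own sums
   cancel to first order).  The dwell split solves the projected deficit
   to within a sample, leaving a residual of a few samples' worth — this
   is what takes long runs into the 10⁻³–10⁻⁴ g range.

Typical results at the default limits (60 °/s, 60 °/s², 120 °/s³):
residual gravity ≈ 8×10⁻⁴ g after 600 s at dt = 0.01 s, ≈ 1×10⁻⁴ g after
10⁴ s at dt = 0.05 s; decimated F\* (classical) ≈ 0.8–1.6, far below the
3.63 threshold.  A deterministic low-discrepancy design is *more* even
than iid uniform sampling, so scores well below literature values for
randomized controllers are expected.

The conventional random controller draws piecewise-constant rate targets
uniformly within the rate limit with dwell times uniform in [1, 10] s
(unstated in the literature; chosen to reproduce the familiar polar
clustering) and tracks them with a jerk-limited velocity ramp.  Its
stationary direction measure is the latitude–longitude measure of a
doubly rotating frame, which concentrates at the inner-axis poles — the
caps |u_y| > 0.9 hold ≈ 2.6× their uniform share, and F\* at 10⁴ samples
is ≈ 200–270.

## Synthetic data and what the tests show

All inputs are generated in-package: iid uniform directions (normalized
Gaussians), von Mises–Fisher samples (stable inversion sampler), the
90°-turn random walk, and the planners themselves.  These fixtures
emulate the *geometry* of direction paths, not real-machine artifacts:
motor tracking error, backlash, frame flexing, or sensor noise.  Passing
tests therefore certify the planning and scoring mathematics, and the
machine-independent statistics; they do not certify a physical device.

## Numerical choices and degenerate inputs

* S-curve: degenerate `q0 = q1` returns a single constant sample; profile
  sampling clamps at the analytic end time so endpoints are exact.
* Inverse kinematics: of the two (α, β) solution branches the one nearest
  the current pose (Chebyshev distance after 2π-unwrapping) is chosen; at
  gimbal lock (|u_y| = 1) the redundant β keeps its current value.
* Random-walk frame is re-orthonormalized every step; the bare
  rotate/turn recursion is exponentially unstable over hundreds of steps.
* Random rate targets use a 1% margin inside the rate limit because the
  discretized jerk-limited tracker can overshoot by O(jerk·dt²).
* Residual-gravity identities hold exactly only when integer rotation
  periods contain an integer number of samples; the clinostat invariant
  is checked under that sampling.
* CSV floats use shortest round-trip formatting and are re-read with
  pandas' `round_trip` parser, making write→read bit-exact and seeded
  pipelines byte-reproducible.

## Problem sizes

Defaults (and the sizes used by tests and `scripts/acceptance.py`) are
dt = 0.01 s for ≤ 600 s horizons and dt = 0.05 s for the 10⁴ s horizon;
calibration uses n = 100 with 10⁴ replicates (seconds of runtime);
random-control scoring uses 10⁴ decimated samples from a 2000 s run.
These sizes put every Monte-Carlo error well below the margins being
tested while keeping any single computation in the seconds-to-a-minute
range.

## Known limitations

* The greedy ordering is myopic; a global (e.g. assignment-based)
  ordering could cancel the running mean faster in the first minute.
* Partial-gravity mode controls the *magnitude* of the mean vector and
  its direction (−z); it does not shape higher moments of the direction
  distribution.
* Equality of treatment is verified on symmetric synthetic mount layouts;
  real flask racks have their own geometry.
* The uniformity statistic is scored on decimated, still weakly
  correlated samples; its null calibration assumes iid draws.  The
  decimation default (~1000 points) is a compromise, not a decorrelation
  proof.
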