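# Methods

## Physical model

Each swimmer is a Najafi–Golestanian (N-G) three-sphere swimmer: three
rigid spheres of radius `R` on a common axis, joined by two extensible
arms of negligible thickness that toggle between a contracted length of
`6R` and an extended length of `10R`. Two identical swimmers share the
axis; spheres 1–3 form the back swimmer, spheres 4–6 the front swimmer,
and the gap `d = x4 − x3` is the closest distance between them. All
lengths are reported in units of `R`, and the dynamic viscosity is scaled
to 1; in Stokes flow the displacement over a prescribed shape path is
independent of the actuation rate and viscosity, so these scalings lose
no generality.

At zero Reynolds number, inertia is absent and sphere velocities respond
instantaneously to forces through the far-field (Oseen) mobility. Along a
common axis the tensor reduces to scalars:

- self-mobility `H_ii = 1/(6πμR)` (Stokes drag),
- cross-mobility `H_ij = 1/(4πμ|x_i − x_j|)` — the axial component of the
  Oseen tensor, where the `(I + r̂r̂)` factor equals 2.

Given the four arm-length rates (at most one actuating arm per swimmer),
the instantaneous state closes into a 6×6 linear system: `V = H F`, the
four rate constraints `V_{k+1} − V_k = L̇`, and one zero-net-force
condition per swimmer (each swimmer is autonomous, so the fluid exerts no
net force on it). The system is torque-free by axisymmetry. The Oseen
approximation is used at every separation the environment permits, with a
warning below a gap of 5 (the far-field assumption `R/d ≪ 1` degrades
there); no higher-order (Rotne–Prager, lubrication) corrections are
applied.

### Actuation and integration

One actuation step toggles at most one arm per swimmer between its two
rest lengths. The actuating arm lengths ramp linearly in a shape
parameter `s ∈ [0, 1]`, with simultaneous actuations sharing the ramp and
completing together (the relative timing within a step is a convention;
synchronous linear ramps are the simplest reproducible choice). Positions
are integrated along the shape path with classical RK4 over `substeps`
sub-intervals (default 128). Because the rate constraints are linear, the
arm lengths follow the prescribed ramps to machine precision and only the
rigid translation carries integration error: per-step displacements change
by less than 1e−9 when refining from 128 substeps, and the net
displacement of a full stroke cycle is converged to ~1e−10 already at 16
substeps. The reduced-scale training runs therefore use 16 substeps; all
accuracy-sensitive benchmarks use the default 128.

If spheres come within contact range (centre separation ≤ 2, i.e.
overlapping spheres of radius 1) during a step, the integrator aborts:
the library raises a geometry error, while the learning environment
converts the event into an episode termination with the hard penalty
(physically a collision; formally the gap has crossed its lower bound).

### Canonical stroke and its direction

The canonical stroke cycle from the fully extended configuration is:
contract rear arm → contract front arm → extend rear arm → extend front
arm. Numerically this cycle displaces a lone swimmer by +0.17209 per
4-step cycle (0.04302 per step) in the +x direction, i.e. toward the
front; a leading-order perturbation estimate of the same quantity
(expanding the centroid drift to first order in the Oseen coupling) gives
+0.156, confirming the sign and magnitude. Reversing the cycle exactly
negates the displacement (kinematic reversibility), and any reciprocal
sequence (toggle–untoggle) displaces nothing — the scallop theorem.

### Phase mismatch convention

For the pair benchmarks both swimmers run the canonical cycle and the
front swimmer's cycle phase is offset by `delay ∈ {0,1,2,3}` steps within
the 4-periodic stroke. A cyclic offset has two equivalent descriptions
(shifting one way by `k` equals shifting the other way by `4−k`); the
package fixes the orientation so that `delay = 1` is the cooperative
synchronized gait — the same gait the trained policies discover — and
documents results in that convention. Under it the sweep gives, at a
calibrated minimum gap of 6: delay 0 ≈ +14%, delay 1 ≈ +30% (best),
delays 2 and 3 ≈ −14% relative to the lone-swimmer speed.

### Calibration of the initial gap

To compare mismatches fairly, each pair case starts from the gap that
makes the steady-cycle minimum of `d` equal 6. The initial gap is found
by bisection: simulate 10 transient cycles, measure the minimum of `d`
over the next full cycle, and exploit that this minimum is monotone
increasing in the initial gap (verified over the bracket [3, 40]). The
residual cycle-to-cycle change of the minimum is reported as a drift
diagnostic; for all four mismatches it is below 1e−6 per cycle, so no
secular drift correction is needed. Steady speed is the least-squares
slope of the pair-average displacement `⟨D⟩ = (D_B + D_F)/2` over the
last 20 of 50 cycles; the first 10 cycles are treated as transient. The
measured speeds are insensitive to widening either window.

## Decision process

- **State.** Four arm bits (16 discrete configurations) plus the
  continuous gap `d`. Networks receive the bits as 0/1 features and `d`
  rescaled by the upper bound 70, a 5-vector.
- **Actions.** Each swimmer toggles its rear arm, toggles its front arm,
  or holds; the double hold is excluded, leaving 3²−1 = 8 joint actions.
- **Reward.** With end-of-step gap `d`: the summed centroid displacements
  `D_F + D_B` while `70 > d ≥ 6`; a soft penalty −0.3 in the buffer zone
  `6 > d > 5` (replacing, not added to, the displacement term); −1 with
  termination when `d ≤ 5` or `d ≥ 70`. Displacements are signed along
  +x, the propulsion direction of the canonical stroke. Mid-step crossings
  of the bounds are ignored (substeps are short); only the end-of-step gap
  is classified.
- **Episodes.** Capped at 16,384 steps (treated as truncation, so the
  value bootstraps across the cap, which is a time limit rather than a
  physical ending). Initial configuration uniform over the 16; initial gap
  uniform on [10, 40] — inside the safe band with room to approach (the
  exact training distribution is a free choice; results are insensitive to
  it because initial conditions are randomized every episode).

## Learner

Clipped proximal policy optimization with generalized advantage
estimation, implemented directly on NumPy arrays: separate actor and
critic multilayer perceptrons (hidden sizes 128-128-64 each, tanh
activations, orthogonal initialization with a 0.01-gain policy head), Adam
at learning rate 1e−4, rollouts of 16,384 steps, 10 epochs of shuffled
256-sample minibatches per update, clip range 0.2, discount γ = 0.9997
(effective horizon ≈ 3,300 steps, comfortably below the episode cap), no
target-KL stop. Quantities the published configuration leaves open are
set to common practice and exposed in configuration: GAE λ = 0.95,
entropy coefficient 0, value coefficient 0.5, global gradient-norm clip
0.5, and advantages normalized once per update. The analytic gradients of
both objectives are verified against central finite differences in the
test suite.

Advantage estimation distinguishes the two episode endings: terminations
(bound violations) zero the bootstrap value, while truncations (time
limit) bootstrap from the value of the state actually reached, which the
rollout collector records separately since the buffer's next slot holds
the post-reset state.

Every 2×10⁵ environment steps (and once before training) the policy is
snapshot and scored by the mean undiscounted return of 5 fixed-seed
stochastic evaluation episodes in a fresh environment; the best-scoring
snapshot is the selected model (early stopping by selection rather than
by halting). Checkpoints are NumPy `.npz` archives with a JSON metadata
record (version tag, step count, score) and round-trip exactly.

## Stage analysis

Trained policies show an approach stage (back swimmer strokes, front
mostly waits, `d` shrinks) followed by a synchronization stage (both
swimmers phase-locked, `d` oscillating with the 4-step gait period). The
detector scans for the earliest step from which the per-step pattern of
(configuration, sign of Δd) repeats with period 4 for 5 consecutive gait
cycles. The sign of Δd uses a dead-band of 1e−6; stochastic rollouts may
use a tolerance of a few mismatching steps per window (default 2 for
stochastic inputs, 0 for deterministic). The change of `d` during the
first recorded step is unobservable (no prior gap is stored) and is
backfilled from the same phase one period later.

## Problem sizes and what the tests show

The phase sweep runs at its study scale (50 cycles, calibration to
|min d − 6| < 1e−4) in seconds. The learning check runs at a reduced
scale chosen for a single-CPU test suite: 5×10⁵ environment steps with
2,048-step episodes and 3 seeds, asserting only that evaluation scores
improve over the untrained policy in at least 2 of 3 seeds and that a
synchronized gait is detected — not the full-scale (≈5.4×10⁶-step)
training trajectory, which the same code reproduces unasserted. Because
unreported optimizer details (λ, entropy/value coefficients, activation,
initialization) had to be chosen, trained-policy behaviors should be read
qualitatively; the prescribed-gait benchmarks, by contrast, are fully
deterministic physics and are asserted tightly.

The simulator generates all data internally; no external measurements are
involved. What passing tests do not show: behavior off the common axis,
at separations where the far-field mobility is invalid (gaps ≲ 5), or for
more than two swimmers.

## Known limitations

- The Oseen coupling is leading-order; near the lower gap bound the true
  hydrodynamics would include finite-size corrections the model omits
  (matching the modeling choice of the study this package reproduces).
- The collision-termination convention (mid-step contact → hard penalty)
  is exercised only in rare corners of state space reachable from the
  buffer zone.
- The NumPy learner is single-threaded and processes one environment; it
  trains the full-scale configuration overnight on one CPU but is not
  tuned for larger experiments.
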