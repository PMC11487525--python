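# Methods

## The model

The package studies an ODE-form echo-state network ("reservoir computer").
Before training it is a driven, non-autonomous system — the *open loop*:

    dr/dt = gamma * ( -r + tanh( M r + sigma * W_in u(t) ) ),     r(0) = 0,

with reservoir state `r(t) ∈ R^N`, a fixed sparse random adjacency
`M ∈ R^{N×N}`, a fixed random input matrix `W_in ∈ R^{N×2}` with exactly one
nonzero per row (each neuron hears one input coordinate), decay rate `gamma`
and input strength `sigma`.  Training never touches `M` or `W_in`; only a
linear readout over quadratic features is fitted:

    psi(r) = W_out q(r),        q(r) = [r ; r^2]   (elementwise square).

Substituting the readout for the drive gives the autonomous *closed loop*:

    dr/dt = gamma * ( -r + tanh( M r + sigma * W_in W_out q(r) ) ).

Because tanh is bounded, each component obeys dr_i/dt < 0 whenever r_i > 1
(and symmetrically below −1), so the box `[−1, 1]^N` is globally attracting
for *any* readout: the closed loop can deform, bifurcate, or wander, but it
cannot diverge.  This constraint is what ultimately forces a new attractor
into existence when the trained ones destabilize, and it is asserted as an
invariant in the tests.

The appended squares in `q` matter: a linear-only readout makes the
closed-loop flow odd (`f(−r) = −f(r)`), so every attractor would coexist
with its mirror image.  The squares break the symmetry; the test suite
demonstrates both the exact mirror symmetry of the linear variant and its
absence in the quadratic one.

## Training

Each orbit's signal drives the open loop from `r(0) = 0`.  States before
`t_listen` (the listening stage) are discarded; by that time the state is
determined by the input history alone (the echo-state property — verified by
running the listening stage twice from different initial states and checking
agreement to 1e−6).  States from `t_listen` to `t_train` are collected as
feature columns `X = [q(r(t))]` with targets `Y = [u(t)]`, both orbits
concatenated, and the readout solves the ridge problem

    W_out = Y X^T (X X^T + beta I)^{-1}

via a Cholesky factorization of the symmetric positive-definite Gram matrix
(never an explicit inverse).  The end-of-training states `r^(A)(t_train)`,
`r^(B)(t_train)` are stored: they are the canonical closed-loop initial
conditions for reconstructing each orbit.

## The seeing-double task

The driving signals are two circles of radius `b = 5` sampled at
`tau = 0.01`: orbit A counter-clockwise about `(+x_cen, 0)` and its y-axis
mirror image, orbit B, clockwise about `(−x_cen, 0)`.  Decreasing `x_cen`
moves the circles together — disjoint for `x_cen > 5`, touching at
`x_cen = 5`, overlapping below — so the reservoir must disambiguate
identical input points by their history.  The trained system is
*multifunctional* when the closed loop, started from each end-of-training
state, reproduces the corresponding circle: mean radial deviation from the
correct center below 5% of `b` and the correct rotation sense, both measured
after discarding the first half of the test window.  One reconstructed
orbit is *partial*; neither is *failed* (which includes the switching
regime).

## Continuation in the spectral radius

`M` is drawn once per seed as a Bernoulli(P)-masked uniform[−1,1] matrix and
rescaled — never redrawn — to each target spectral radius `rho`, so `rho` is
the only quantity changing along a sweep.  The full protocol decreases `rho`
from 0.7 to 0.1 in steps of 0.001, retrains at every step with identical
input sequences, re-integrates each tracked attractor from its final state
at the previous step for a `t_track = 200` window, and records the local
maxima `x_m` of the projected x variable after discarding the first half of
the window.  When a branch's orbit is lost, the sweep keeps following
whatever the carried state approaches (the surviving orbit, a fixed point,
or the switching attractor).  Because the branches are genuinely
multistable, a carried state can hop basins at a step — with coarse steps
this happens earlier; the per-`rho` labels record exactly what was reached.
Branch labels are classified from the post-transient projection: a
late-time displacement below `1e−3·b` over the last quarter window is a
fixed point; zero relay transitions with the mean x sign matching an
orbit's center is that orbit; at least two transitions each way is
switching; anything else is "other".  A branch is considered off its orbit
after two consecutive off-label windows (debouncing long transients).

## Transition detection and switching statistics

The monitored scalar is the projected x coordinate.  Transitions between
the metastable states near the two orbits are detected with a non-ideal
relay: thresholds `alpha = −2 < beta = 2`; the detector enters the low
state only when x drops below `alpha` and the high state only when it rises
above `beta`; in-band samples never change the state, and exact threshold
hits do not trigger (a measure-zero, deterministic tie-break).  The state
near the `+x_cen` orbit (A) is the high state.  Transition times are taken
at sample resolution (no sub-`tau` interpolation; the error is at most
`tau = 0.01`, negligible against minimum residences of a few time units).

Residence times are the durations of completed stays (open-ended first and
last stays excluded).  Their probability density is computed on 100
geometrically spaced bins between the sample minimum and maximum,
normalized so that the density integrates to one.  Each completed stay is
also tagged with the number of revolutions the trajectory makes about the
resident orbit's center (winding angle / 2π, rounded, since threshold
crossings cut into loops), which stratifies the exponential branches of the
residence distribution by loop count.  Escape times are the first relay
departure from the initialization's own state, measured from the start of
the closed-loop run at `r^(A)(t_train)`.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| N | 100 | neurons | small enough for desk-scale sweeps, large enough for echo-state behavior at P = 0.04 |
| P | 0.04 | — | per-element Bernoulli connection probability |
| gamma | 10 | 1/time | reservoir timescale ~10× faster than the orbit period 2π |
| sigma | 0.1 | — | keeps sigma·W_in·u inside tanh's responsive range for \|u\| ≤ 13.5 |
| tau | 0.01 | time | RK4 step; also the signal sampling step |
| t_listen / t_train | 50 / 550 | time | long washout; ~50,000 regression columns ≫ 2N |
| beta (ridge) | 1e−4 | — | mild shrinkage; Gram matrix comfortably positive definite |
| b, x_cen | 5; {8, 6.5, 5, 3.5, 2} | signal units | the task geometry, from well separated to strongly overlapping |
| rho sweep | 0.7 → 0.1, step 0.001 | — | full continuation grid |
| alpha, beta (relay) | −2, 2 | signal units | symmetric hysteresis band between the orbit centers |

Every parameter is configurable; configurations are validated (unknown
keys rejected, cross-field invariants checked) before any computation, and
echoed with a hash into every output sidecar.

## Numerical choices

* Fixed-step classical RK4 at `tau = 0.01`; the driving signal is analytic,
  so the middle stages use exact values at `t + tau/2` rather than
  interpolation.  Fourth-order convergence is verified on a linear decay
  benchmark (fitted order 4.0 ± 0.2).
* The integration kernels are JIT-compiled (numba) over a CSR view of the
  sparse adjacency and the one-nonzero-per-row input matrix; no fastmath,
  no parallelism — identical inputs give bit-identical trajectories, and
  the kernels are checked against a plain-NumPy RK4 built on the reference
  right-hand side.
* `rho = 0` returns the zero matrix (the limit of the rescaling); a
  nilpotent base draw (spectral radius 0) is an error instructing the
  caller to redraw.
* The ridge solve must match the explicit normal-equations formula to
  1e−10 on small problems.  Note that at full scale the Gram conditioning
  (~1e9 at beta = 1e−4) amplifies summation-order roundoff, so readouts
  trained with the two orbit blocks concatenated in either order agree to
  ~1e−6, not machine precision.
* A closed-loop divergence guard aborts if any |r_i| exceeds 10 — a level
  that is unreachable for the tanh dynamics and can only indicate a bug.

## What the synthetic generator does and does not emulate

All inputs are generated internally: the analytic circular orbits and the
seeded random matrices.  The generator reproduces the study's conditions
exactly (noise-free signals, ideal circles, a single fixed realization per
seed).  It does not emulate measurement noise, non-stationary drives,
unequal radii or frequencies, or same-direction orbit pairs; passing tests
therefore certify the method's behavior under the stated idealized
conditions, not robustness to noisy or mismatched data.

## Problem sizes used in the tests

The test suite and acceptance script run the pipeline at its study
conditions (N = 100, P = 0.04, gamma = 10, sigma = 0.1, tau = 0.01) with
shortened windows chosen as the package's desk-scale defaults for
verification: `t_listen = 10`, `t_train = 110` (10,001 regression columns
per orbit, still ≫ 2N = 200), tracking windows of t = 100–200, verdict
horizons of t = 100–500, switching counts measured over t = 2000 windows,
and a continuation step of 0.01 for the full multi-`x_cen` study.  The
full-resolution protocol (step 0.001, t_track = 200, 10,000 collected
switchings) is available through the same functions and CLI by changing
the configuration.

## Known limitations

* Specific bifurcation values (where an orbit destabilizes, where switching
  begins and ends) are properties of the random realization; different
  seeds shift them, as the tests' seed-scanning structure reflects.
* The multifunctionality verdict operationalizes "indistinguishable
  long-term dynamics" as radial error + rotation sense; it does not compare
  Poincaré sections or spectra.
* Attractor labels come from finite windows; extremely slow transients can
  be misclassified at a single step (mitigated, not eliminated, by the
  debounce rule).
* No saddle localization, Lyapunov spectra, or formal classification of
  the switching as chaotic itinerancy versus heteroclinic cycling is
  attempted.
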