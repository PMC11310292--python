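# Methods

This note documents the models, the numerical choices and the limits of
what the test suite demonstrates. Equations are in README.md; here we
concentrate on assumptions, parameters and design decisions.

## Model assumptions

The basic model treats the tumor micro-environment as well mixed: fat
produces estrogen at a constant per-volume rate, estrogen washes out
first-order, and tumor growth is logistic with a Michaelis–Menten
dependence on local estrogen. Diet enters exclusively through the
initial conditions — fat volume and the estrogen level it sustains —
never through the rate constants. Over the 15-day experiment fat has no
growth source, so it can only decline (slowly, through tumor
consumption).

The extended model adds the minimal resistance structure: two
subpopulations, with death of sensitive cells and their conversion to
resistance gated by steep Hill switches at estrogen thresholds `a2` and
`a3`. Resistant cells are estrogen-independent and grow more slowly than
sensitive cells at full estrogen (cost of resistance); they never revert.
Fat follows its own logistic growth here, so a treatment that lowers
estrogen cannot starve the tumor by shrinking fat. There is no drug
compartment: an aromatase inhibitor acts instantaneously as a
multiplicative reduction `p = 1-u` of estrogen production. Delay
effects, pharmacokinetics, immune interactions and more than two
phenotypes are out of scope.

## Parameters

| name | meaning | units | default |
|------|---------|-------|---------|
| k1 | max sensitive/tumor growth rate | 1/day | 0.55 (calibrated) |
| a1 | half-max estrogen for growth | pg/g | 43 (calibrated) |
| m1 | inverse tumor carrying capacity | 1/mm³ | 1/2000 |
| r | estrogen production per fat | pg/g/mm³/day | 20 |
| mu | estrogen washout | 1/day | 5.94 (= ln2/2.8 h) |
| alpha | fat consumption by tumor | 1/day/mm³ | 1.7e-6 (calibrated) |
| eta | competition of R on S | – | 1 |
| c | max death rate | 1/day | 1 |
| l | Hill coefficient | – | 10 |
| a2, a3 | death / adaptation thresholds | pg/g | scenario presets |
| k3 | resistant growth rate | 1/day | k1/2 or k1/4 (preset) |
| k2 | fat growth rate | 1/day | 0.05 |
| m2 | inverse fat carrying capacity | 1/mm³ | 0.002711 |
| u_a, u_b | dose bounds | – | 0, 0.99 |
| t_f | study horizon | day | 25 |

`mu` follows from the measured 2.8 h estrogen half-life in tumor tissue;
`m1` is set just above the humane-endpoint volume of a 15 mm spherical
tumor (π/6·15³ ≈ 1767 mm³); `r` is picked from the interval
(17.82, 24.75) that keeps steady-state estrogen `r·F0/mu` within the
measured 150–1500 pg/g for both arms; `u_b < 1` encodes that even maximal
aromatase inhibition leaves some residual local estrogen production.

## Synthetic experiment

`datagen.generate_experiment` emulates the two-diet design: per arm, six
independently measured tumors at days 10/13/15 and one fat-volume
measurement at day 15. Default noise is proportional Gaussian with a
15% coefficient of variation (truncated at zero), chosen as a realistic
magnitude for caliper-derived tumor volumes; the recorded `sd` column
carries the generating standard deviation so the weighted least-squares
objective is chi-square-scaled at the truth. Initial estrogen defaults
to the fat-sustained steady state `r·F0/mu` (the ~3.4 estrogen-to-fat
ratio), which is also what calibration assumes — the generator and the
fitter are consistent by construction.

What the generator does *not* emulate: within-mouse correlation of the
bilateral injections (replicates are fully independent), longitudinal
correlation across days (each draw is independent), heteroscedasticity
beyond proportionality, and the histology-based derivation of fat volume
from adipocyte counts. Passing recovery tests therefore show that the
*estimation machinery* is correct under the stated error model, not that
the real experiment carries this much information.

A consequence worth stating plainly: under this design the fat
consumption rate `alpha` is practically non-identifiable at realistic
noise. Its only signal is the decline of fat by day 15, about 0.1 mm³
of 50 (CD) and 1.8 mm³ of 360 (HFD), i.e. 30–70× below the 15%
measurement noise on the single fat point per arm. Fits on noise-free
data recover `alpha` (and `k1`, `a1`) to much better than 1%, but on
noisy data the `alpha` profile is flat toward zero ("lower-open") and
its estimates scatter over decades, while `k1` and `a1` remain
identifiable with median errors well under 15%. The identifiability
tests assert exactly this behavior for the growth parameters and the
examples display the `alpha` caveat rather than hiding it.

## Numerics

* **Simulation.** `simulate.integrate` uses LSODA with rtol 1e-8 /
  atol 1e-10; the steep Hill switches (l = 10) make the treated system
  locally stiff. Integration is segmented at every control
  discontinuity so square-wave schedules are never smoothed across a
  jump. Hill terms are evaluated through `1/(1+exp(l·log(E/a)))`, which
  cannot overflow; state vectors are clipped at zero inside the RHS
  because adaptive solvers probe marginally negative values.
* **Treatment start.** The detectable-size condition is implemented as
  the first *upward* crossing of `S+ηR` through `1/(4m1)` (500 mm³ at the
  default `m1`), located by linear interpolation between grid points. A
  tumor growing from 1 mm³ is below threshold from day 0, so the literal
  "first time below" reading would fire immediately; that variant
  remains selectable (`direction="down"`) but the upward crossing is the
  default, consistent with treatment beginning after substantial growth
  and earlier for the faster-growing HFD arm.
* **Calibration.** Free parameters are optimized in log10 space with
  box bounds 1e-7–1e4 by trust-region least squares, multistart from a
  Latin-hypercube sample (default 25 starts; the tests use 4–8, which
  suffices because the profiled landscape is unimodal once `m1`, `mu`,
  `r` are fixed). A solver failure returns a large finite penalty so
  optimizers back out. Residual weights are the recorded per-record sd,
  falling back to the replicate spread per (arm, variable, day), then to
  unit weight. Profiles scan 21 log-spaced points over ±1.5 decades,
  re-optimizing the other parameters warm-started from the optimum, and
  extend adaptively until the 3.84 (chi-square, 1 dof, 95%) threshold is
  crossed or a bound is hit.
* **Optimal control.** The sweep discretizes the control on a uniform
  grid (default 0.05 day) with piecewise-linear interpolation inside ODE
  steps. Forward and backward solves use fixed-step classical
  Runge-Kutta with two substeps per node — the standard FBS
  discretization — which agrees with the adaptive stiff solver to below
  1e-4 relative at this step, and keeps the line search cheap. The
  greedy step search evaluates J on
  s ∈ {0.01, 0.05, 0.1, …, 0.9, 0.95, 0.99}; the small-s candidates act
  as a near-no-move fallback so accepted costs are non-increasing in
  practice. Convergence requires the L1 relative change of control,
  state and adjoint to drop below 1e-5 (cap 200 iterations; on very
  coarse grids the iteration can stall just above the tolerance, in
  which case the best-cost iterate is returned and flagged). The
  terminal adjoint is zero, which forces the optimal dose to the lower
  bound at `t_f`. A direct-transcription solver (L-BFGS-B over the
  discretized control) provides an independent cross-check; on a 26-node
  grid the two costs agree to ~0.01%.
* **Adjoint system.** The costate equations are derived from the
  Hamiltonian by differentiation; the derivative of the Hill switch is
  evaluated in the overflow-safe form `(l/E)·h·(1-h)` with the limit 0
  at `E = 0`. The implementation is validated against central
  finite-difference gradients of the discrete cost (agreement ~1e-4 to
  1e-3 relative at interior grid nodes). During this validation the
  sensitive-to-resistant conversion term's sign in the first costate
  equation was pinned down numerically: the conversion flux enters the
  resistant equation with a plus sign, so after negation it must appear
  with a minus sign in the costate bracket — the finite-difference check
  fails by order 100% with the opposite sign.
* **Outcome classification.** "Eradicated" means a final burden below
  the 1 mm³ implanted size; "resistant-regrowth" requires a resistant
  fraction above 50% *and* a burden rising over the last 2 days (the
  lookback bridges one on/off cycle of an alternating schedule);
  "contained" compares the final burden to the burden at treatment
  start. All thresholds are keyword arguments.

## Problem sizes in tests and the acceptance script

The positivity/boundedness property suite uses 100 random draws per
model over 15-day windows. The noisy-recovery study uses 20 replicate
experiments (10 in the acceptance script) with 5 multistarts each. The
solver cross-check runs on a 26-node control grid; scenario runs use the
0.05-day grid over the full 25-day horizon. These sizes were chosen so
the complete suite exercises every claim at full fidelity while running
in minutes.

## Known limitations

* The composite-burden bound `S+ηR ≤ max(S0+ηR0, 1/m1)` holds for
  η ≤ 1 (and more generally while `(η-1)·h_{a3} ≤ h_{a2}`): conversion
  moves mass from S to R, which counts η-fold in the composite. The
  study's η = 1 is safely inside this regime; the property tests draw η
  accordingly.
* FBS convergence is only guaranteed on short horizons; the 25-day
  window with treatment starting at day 12–14 converges reliably, but
  much longer windows may require damping or fail to be unique.
* The `alpha` non-identifiability described above means treatment-model
  predictions are insensitive to `alpha` over several decades — a
  feature of the experimental design, not of the code.
* Scenario conclusions are qualitative classifications of simulated
  trajectories under assumed treatment parameters (`c`, `l`, `a2`, `a3`,
  `k3` are not calibrated to any treatment data).
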