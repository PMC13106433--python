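# Methods

## Model

`adaptnet` simulates a recurrent rate network with two adaptation
mechanisms:

    tau_d dx_i/dt = -x_i + u_i + sum_j w_ij b_j r_j
    r_i   = phi(x_i - a0_i - c sum_k a_ik)
    tau_k da_ik/dt = -a_ik + r_i
    db_i/dt = (1 - b_i)/tau_rec - b_i r_i / tau_rel

`x_i` is a dendritic potential, `r_i in [0, 1]` a normalized firing rate,
`a_ik` the spike-frequency-adaptation (SFA) state at timescale `tau_k`, and
`b_i in [0, 1]` the fraction of releasable vesicles (short-term synaptic
depression, STD, in the resource-depletion form: release consumes `b` in
proportion to the rate with time constant `tau_rel`; recovery refills it
with `tau_rec`). SFA is subtractive (an adaptive bias current); STD is
multiplicative (column scaling of `W`). Units are seconds throughout;
Lyapunov exponents are 1/s internally and are reported nondimensionally as
`lambda_1 * tau_d` by the experiment layer, so printed values are
independent of the time unit.

The activation `phi` is a hard sigmoid with quadratic corners of half-width
`w` (default 0.1): zero below `-w`, `(h+w)^2/(4w)` on `[-w, w]`, identity
on `[w, 1-w]`, the mirrored quadratic on `[1-w, 1+w]`, one above. It is
C^1 with a piecewise-linear derivative; its nonnegative range means every
neuron's output respects its population's synaptic sign (Dale's law holds
at the output even though Gaussian weights can individually cross zero).

Assumptions: deterministic dynamics (no intrinsic noise); fixed structural
weights (no plasticity during a run); adaptation restricted to excitatory
neurons by default (inhibitory neurons keep `a = 0`, `b = 1` frozen);
fixed-step RK4 integration so the Lyapunov bookkeeping aligns exactly with
integration steps. Disabled mechanisms are frozen exactly, so the
no-adaptation configuration is bit-for-bit the classic leaky rate network.

## Linearization

The effective connectivity is the `x`-block of the Jacobian,

    J_eff = (1/tau_d) (-I + W B Phi'(h)),   h = x - a0 - c sum_k a_k,

implemented with `Phi'` as a column scaling exactly as written. The full
Jacobian over the active coordinates (`x`; `a`, `b` for adapting neurons
with the mechanism enabled) is assembled analytically; because no closed
reference exists for it, its sole correctness authority is a
finite-difference oracle test (central differences of the model flow at
random states, five mechanism configurations, relative error < 1e-5; the
achieved agreement is ~1e-10).

## Lyapunov estimation

The largest Lyapunov exponent is estimated with the classical
two-trajectory Benettin scheme: a shadow trajectory starts at distance
`delta0 = 1e-6` along a random unit direction supported on the active
coordinates, both trajectories receive the identical stimulus, and every
`renorm_interval = 0.1 s` the log expansion `ln(d/delta0)` is recorded and
the shadow is pulled back to `delta0` along the current separation. The
finite-time exponent is the time average of log expansions; the local
exponent `lambda1_local(t)` averages a trailing 1 s window. Epoch means
exclude the first 2 s after each epoch boundary (onset transients). The
estimate is insensitive to `delta0` over [1e-8, 1e-5] (tested), and on
linear systems and the Lorenz benchmark it reproduces known exponents
(abscissa to 1e-2; 0.906 +/- 0.02).

Restricting the perturbation to active coordinates matters: frozen
coordinates have zero derivative, so a perturbation component there would
neither grow nor decay and would bias the exponent toward zero.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| N, d | 300, 1/3 | network size and connection density of the study ensemble |
| sigma | 0.3 | weight SD; bulk radius `sigma*sqrt(Nd)` = 3, so the linearized no-adaptation network has many unstable modes |
| mu_E | 0.18 | mean excitatory weight (0.6 sigma) |
| mu_I_mag | 0.24 | mean inhibitory magnitude, fixed at (4/3) mu_E (modest inhibitory dominance) |
| f_E | 0.4-0.6 | excitatory fraction, swept across networks (E:I from 2:3 to 3:2) |
| tau_d | 0.1 s | dendritic time constant |
| tau_k | 0.3, 3, 30 s | K = 3 log-spaced SFA timescales, spanning tens of ms to tens of s |
| c | 0.5 | SFA gain; total subtractive capacity c*K = 1.5 |
| a0 | 0.05 | baseline shift; rests neurons slightly below the activation corner |
| tau_rec, tau_rel | 2.25 s, 0.1 s | STD recovery/release; steady-state depletion `b* = 1/(1 + 22.5 r)` |
| w_corner | 0.1 | activation corner half-width |
| amp_max | 0.5 | stimulus amplitudes ~ Uniform(0, amp_max), per E neuron |
| epochs | 20/20/20 s | baseline / stimulus-on / post |
| dt | 0.01 s | RK4 step (guard: dt <= min(tau_d, tau_rel)/5) |

The weight scale, baseline shift and STD constants are not dictated by any
published value; they were calibrated once, on small pilot sweeps, so that
the model sits in the regime the stability-regulation experiment is about:
quiescence is stable but shallow (resting gain 0.25 at `h = -a0` leaves
the no-adaptation network just below its instability threshold), so random
excitatory steps recruit the high-gain region and induce chaos in networks
lacking adaptation, while depression is strong enough to absorb that gain
increase. After calibration all values were frozen; the acceptance script
and tests run them unmodified. All are exposed through `ModelParams`,
`NetworkSpec` and the YAML run configuration.

## The sweep experiment

`run_sweep` pairs each of 25 networks (f_E linearly spaced over
[0.4, 0.6], fresh seeded Dale matrix) with one fresh random-amplitude
excitatory step stimulus, runs all four adaptation conditions (none,
SFA-only, STD-only, SFA+STD) on the identical (W, stimulus, initial state,
perturbation direction), and records the within-network change in
epoch-averaged local exponent (stimulation minus baseline,
nondimensionalized by tau_d). Per condition it reports the median change, a
seeded bootstrap 95% CI of the median, and a two-tailed Wilcoxon
signed-rank test (zeros dropped, midranks for ties, exact null enumeration
for n <= 25 via a dynamic program over doubled midranks, normal
approximation with tie correction above; the exact branch is verified
against literal 2^n enumeration and scipy).

Typical medians at the defaults (recomputed by `scripts/acceptance.py`):
no adaptation ~ +0.38, SFA-only ~ +0.20, STD-only ~ +0.01, SFA+STD ~ 0.00.

## What the generator emulates, and limits of the tests

The synthetic ensembles capture the statistical skeleton of cortical
connectivity that stability theory operates on — sparsity, sign-segregated
populations with unequal means, inhibitory dominance — but none of its
finer structure: no distance dependence, no clustering or reciprocal-motif
excess, no synaptic delays, no intrinsic noise, and rate (not spiking)
dynamics. Passing tests therefore show that the *mechanisms* behave as
derived (depression bounds, adaptation kinetics, Jacobian structure,
exponent estimation), and that the stability-regulation effect holds in
this model family — not that real cortex operates at these parameters.

A known limitation of the quiescent-baseline regime: when a condition's
dynamics are fully quenched (STD-only and SFA+STD at baseline and, usually,
during stimulation), the measured exponent equals the slowest linear
relaxation mode of the quenched system (~ -1/tau_rec or -1/tau_K), a
deterministic quantity. Stimulation can only leave that floor unchanged or
raise it, so the paired differences for STD-only are one-sided at
magnitudes (~1e-3..0.07) far below the exponent's scientific resolution,
and a signed-rank test on them can reach significance even though the
median change (~+0.01) is negligible. Interpreting the STD conditions
should rest on the magnitude of the median change, not the p-value. A
basally active variant (spontaneous low-rate chaos under depression) would
give the differences genuine two-sided spread, but in this model family
such regimes also make the no-adaptation network basally chaotic, where
excitatory steps *stabilize* it through saturation rather than
destabilizing it.

## Numerical choices

- RK4, fixed step, dt = 0.01 s; observed convergence order >= 3.5 on
  smooth segments (the activation is only C^1 at four breakpoints, crossed
  on a measure-zero set of step boundaries).
- Divergence guard `|x|_inf > 1e6` aborts with the blow-up time; a
  collapsed (exactly zero) Benettin separation raises a dedicated error.
- Eigenvalues are sorted lexicographically by (Re, Im) so spectra of
  related matrices can be matched elementwise; outliers are eigenvalues
  with modulus > (1 + tol) R with tol = 0.05 by default (finite-N edge
  fluctuations scale like N^(-1/2); checks at N = 200 use a wider 20%
  guard).
- Row balancing rescales each row's inhibitory entries by the single
  factor forcing a zero row sum; it errors if a row has excitatory input
  but no inhibitory weight to rescale, and is idempotent to 1e-12.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical configuration and seed reproduce matrices, stimuli and
  trajectories bitwise.
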