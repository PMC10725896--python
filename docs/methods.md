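# Methods

## Model

The package implements the discrete Izhikevich neuron, a two-variable map
for the membrane potential `x` (mV) and the recovery variable `y`:

```
x' = 0.04 x^2 + 5 x + 140 - y + I          y' = sigma (eta x - y)
x >= x_peak (30 mV)  =>  x <- psi,  y <- y + nu
```

`sigma` sets the recovery time scale, `eta` the recovery sensitivity,
`psi` the post-spike reset voltage and `nu` the post-spike recovery
increment; `I` is the injected current.  Two right-hand-side *variants*
circulate for the fractional formulation and both are supported:

* **direct** — the expressions above;
* **difference** — the same minus `(x, y)`, i.e. the first difference of
  the map.  The commensurate scheme is conventionally stated in this form
  and it is that scheme's default; the incommensurate and variable-order
  schemes are stated in (and default to) the direct form.  All defaults
  are overridable, and every trajectory records its variant.

The fractional dynamics replace the unit-lag update by a Caputo-like delta
difference of order `beta` in (0, 1].  With starting point 0 the explicit
solution is a discrete convolution against the kernel weights
`w_k(beta) = Gamma(k+beta)/(Gamma(beta) Gamma(k+1))`: `w_0 = 1` always,
all weights equal 1 at `beta = 1` (no memory), and for `beta < 1` they
decay algebraically, producing the long memory trace responsible for
bursting, chattering and spike-frequency adaptation.  In the
*incommensurate* scheme each variable carries its own order; in the
*variable-order* scheme the order is a function `beta(r)` of the step
index, attached to the **source** term: the weight that history index `j`
contributes to any later step uses `beta(j)`.

## Numerical scheme

The integrator advances the convolution incrementally,

```
z(n) = z(n-1) + F(z(n-1)) + sum_{j<n-1} [w_{n-1-j} - w_{n-2-j}] F(z(j)),
```

with the weight increments maintained by the exact recurrence
`dw = w (beta-1)/(k+1)`.  This is algebraically identical to the explicit
sum, costs O(n) per step (O(n^2) per run; a 6000-step single-neuron run
takes well under a second), and has one decisive property: at `beta = 1`
every increment is *exactly* zero in floating point, so the scheme
collapses bit for bit to direct iteration of the one-step map — through
spike resets and chaotic stretches alike.  The test suite exploits this
for its order-1 reduction checks and cross-checks all three schemes
against literal double-loop transcriptions of the explicit sums at
1e-12 relative tolerance.

Memory sums are accumulated with numpy dot products (pairwise summation),
ascending lag.  Kernel weights are never formed from Gamma quotients
(overflow past arguments of ~170); the falling factorial is evaluated via
log-Gamma with explicit sign tracking.

**Resets versus memory.**  The published formulation is silent on how the
hard reset interacts with the memory sum.  Default (`overwrite`): the
stored state at a spiking step is the post-reset state, all future kernel
sums evaluate the vector field at stored states, and the reset jump enters
the recursion through the incremental update (equivalently, it shifts the
anchor term of the explicit sum).  This is the unique reading under which
the order-1 scheme equals the classical map including resets.  The
alternative `memory-restart` mode clears the history at each spike and
re-anchors at the reset state.

**Divergence is data.**  Trajectories whose potential reaches the
divergence cap (default 1e8) are truncated, the breach step recorded as
`n0`.  Low orders genuinely diverge after a finite number of steps in the
chaotic regimes; this is a reported observable, not an error.

**Memory truncation.**  `SimConfig.memory = L` keeps only the most recent
L kernel lags.  Truncation is exact for `L >= steps`; its error grows as
the window shrinks (verified on a linear fractional relaxation, where the
discarded tail contributes coherently — on chaotic runs the error
saturates at the attractor diameter and no monotone statement holds).

## Local analysis

Fixed points come from the nullcline system `y = slope * x`,
`0.04 x^2 + (5 - slope) x + 140 + I = 0`; both quadratic roots are
returned and complex roots are first-class results.  `recovery_slope` is
an explicit argument (defaulting to `eta`) because the published worked
examples consistently use slope 0.2 with the recovery nullcline
regardless of the quoted `eta`.  The Jacobian at an equilibrium is
`[[0.08 x* + 5, -1], [sigma eta, -sigma]]` (direct variant).  Asymptotic
stability of a linear fractional system of order `beta` is decided per
eigenvalue `s` by

```
|s| < (2 cos(|arg s - pi| / (2 - beta)))^beta   and   |arg s| > beta pi / 2,
```

which at `beta = 1` is exactly the shifted disk `|s + 1| < 1` (verified on
a 1e4-point grid).  `beta_crit = (2/pi) min |arg s|` is reported as the
argument-condition threshold.  The saddle-node current solves the
zero-discriminant condition `(5 - slope)^2 = 0.16 (140 + I)` (I = 4 at
slope 0.2).  The trace-zero (Hopf-type) analysis solves `h = 0` for the
critical voltage (x* = -60 for sigma = 0.2), maps it to the critical
current on the chosen branch (I = -104 with eta = 2) and evaluates the
characteristic polynomial (conjugate pair +/- 0.6i) and the transversality
derivative there.  Some numeric endpoints quoted alongside these formulas
in the source literature (a +/-0.6731i pair, thresholds at I = -103/-105,
the second parameter set's worked eigenvalues) do not follow from the
formulas and are deliberately not reproduced.

**Parameter reconciliation.**  The bursting preset is quoted as
`(sigma, eta, psi, nu) = (0.2, 2, -55, 4)`, yet every worked fixed-point
and eigenvalue number requires `(0.02, 0.2)`.  Preset `B1` therefore maps
to the effective values (logged at INFO on resolution) and the quoted set
is kept as `B1_printed`; the trace-zero algebra conversely matches
`(0.2, 2)` and uses it.  The ensemble-modification preset is stored with
`psi = -65` (a reset *above* the 30 mV cutoff would spike forever; the
printed +65 is taken as a sign typo).

## Lyapunov exponent

The maximal exponent uses the tangent-map method: the perturbation `dz`
is propagated through the same incremental memory recursion as the state,
with the variant's Jacobian evaluated along the trajectory, and is
renormalized to unit norm every `renorm_interval` (default 10) steps —
the whole tangent history is rescaled, which is exact for a linear
recursion.  `zeta_max` is the average log growth per step.  At order 1
and constant Jacobian this reduces to the classical renormalization
method (`zeta = log lambda` for the map `z -> lambda z`, recovered to
1e-6).  Resets leave the tangent untouched by default (the reset map has
no meaningful Jacobian); a `tangent_reset` mode renormalizes it after
each spike instead.  Because the difference-variant scheme does not rest
at the direct-form equilibria, sign checks against the local analysis are
run in the direct variant, where an attracting node (I = 3, order 0.9)
indeed yields `zeta_max < 0`.

## Bifurcation sweeps

Uniform grids (default increment 0.005) over the injected current or any
order; at each point the matching simulator runs, the first 60% of steps
are discarded as transient and at most 400 post-transient potential values
are stored (both plotting-scale defaults, configurable; the discard
policy of the original figures is not stated).  Diverging points carry
empty samples plus their `n0`.

## Spike statistics and pattern labels

Spikes are the integrator's reset events (for reset-free or external
traces: upward threshold crossings at 30 mV).  The qualitative labels are
operationalized: no spikes -> `quiescent`; fewer than three -> `sparse`;
ISI coefficient of variation below 0.15 -> `tonic_spiking`; otherwise
spikes are grouped into bursts wherever the ISI is at most mean(ISI)/5,
and two or more groups of at least three spikes give `bursting`
(`chattering` when the mean burst length reaches six); anything else is
`irregular`.  The mean — not the median — sets the grouping scale: in a
strongly bursting train most intervals are the short intra-burst ones, so
the median is itself short and can never separate bursts.  All thresholds
are exposed parameters; the labels are heuristics for exploration, not
claims about cortical taxonomy.

## Control

**Stabilization.**  The feedback law
`u = x/2 - 0.04 x^2 + y - 5 x - 140 - I` cancels the quadratic, the
constants and the recovery coupling of the first-difference x-dynamics at
machine precision.  The algebra of the substitution leaves `-x/2`, i.e.
the strictly stable lower-triangular matrix
`[[-1/2, 0], [sigma eta, -(sigma+1)]]` (*derived* target); the simplified
target this controller is usually quoted with, `x' = x/2 - y`
(*printed* target, `[[1/2, -1], [sigma eta, -(sigma+1)]]`), does not
follow from that algebra and carries a positive real eigenvalue, hence
fails the stability region test at every order.  Both targets can be
simulated and both matrices — plus a third, trace-zero matrix that has
circulated for this controller and follows from neither — are reported
side by side.  Under the derived target the closed loop contracts
geometrically at order 1 (sup-norm below 1e-3 within ~16 steps) but only
algebraically (~n^-beta) at fractional orders, where the norm is still of
order 1e-2 after 2000 steps from the standard initial state: slow
heavy-tailed convergence is intrinsic to fractional linear systems, not a
solver artifact.  The stabilized run omits the spike reset by default
(the target is the origin).

**Synchronization.**  A slave copy is driven by the x-channel law that
cancels the nonlinear difference terms and adds error feedback with gain
`ell1`, plus plain feedback `-ell2 upsilon2` on the recovery channel (no
law is published for that channel; this is the minimal choice).  The
closed-loop error `upsilon = slave - master` then obeys the linear
fractional system `[[-(1+ell1), 0], [sigma eta, -(1+sigma+ell2)]]`, whose
eigenvalues are the diagonal entries; the defaults `ell1 = 0.2`,
`ell2 = 0.6 - sigma` make them exactly {-1.2, -1.6}.  Gain admissibility
is the stability region test itself — for the negative real eigenvalue
this reads `|1 + ell1| < 2^beta`, which also makes sense of a garbled
published gain bound.  Master and slave are co-simulated under one memory
scheme with resets on: once the error is small both neurons cross the
cutoff together and the reset maps both potentials to `psi`, zeroing the
voltage error, so resets assist convergence.  The master half of the
co-simulation is bitwise identical to an uncontrolled run.  Convergence
is operationalized as error sup-norm below 1e-3 within 2000 steps from
the published initial offset `upsilon1(0) = -0.01` at I = 4; this holds
across the tested 3 x 3 grid of orders {0.8, 0.9, 1.0} and gains
{0.1, 0.2, 0.4}.

## Ensembles

`build_network` reproduces the classical randomized cortical ensemble:
1000 neurons by default, 80% excitatory / 20% inhibitory, per-neuron
parameters drawn from the standard distributions (excitatory:
`(0.02, 0.2, -65 + 15 r^2, 8 - 6 r^2)`; inhibitory:
`(0.02 + 0.08 r, 0.25 - 0.05 r, -65, 2)`, r uniform per neuron),
all-to-all weights uniform (0, 0.5) from excitatory and (-1, 0) from
inhibitory sources, and independent gaussian thalamic drive per step
(scale 5 / 2).  Every constant is overridable.  Coupling uses the
previous step's spikes (synchronous update).  The fractional ensemble
integrator shares one order stream across neurons (per-neuron orders were
not specified for the published runs; shared is the default reading) and
at order 1 agrees event-for-event with an independently coded memoryless
classical update.  Divergent neurons are clamped at the cap and flagged;
the run continues.  Full memory costs O(steps^2) per run; a 100-neuron,
1000-step variable-order run takes about a tenth of a second, the full
1000 x 6000 configuration a few minutes and ~100 MB of history.

The synchrony index of a raster is the variance of the
population-averaged spike indicator over the mean single-neuron indicator
variance, clipped to [0, 1] (1 for lockstep firing, ~1/N for independent
neurons).

## What the synthetic fixtures do and do not show

Test fixtures (constant-ISI and patterned spike trains, Bernoulli rasters,
engineered linear systems, a ten-neuron ensemble) are pure functions of
name and seed.  They validate bookkeeping, classification boundaries and
closed-form limits; they do not emulate biological variability —
heterogeneous conductances, synaptic dynamics, realistic noise spectra —
so green tests certify the numerics and contracts of the schemes, not the
physiological fidelity of any particular regime.

## Problem sizes and determinism

Default test scales are desk-sized by design: single-neuron runs of
50-3000 steps, ensembles of 10-100 neurons for up to 1000 steps, sweeps
of a few hundred grid points; the full published scales (6000 steps,
1000 neurons, 401-point sweeps) are reachable through the same interfaces
and the CLI.  All randomness flows from explicit integer seeds through
`numpy` `SeedSequence` streams split per component (network build,
thalamic noise, fixtures); identical configuration and seed give
byte-identical outputs, and result files embed their configuration in a
JSON sidecar.

## Known limitations

Orders above 1 (beyond clipping), nabla/Riemann-Liouville operators and
Mittag-Leffler kernels are out of scope.  The Lyapunov implementation
estimates only the maximal exponent.  No continuation or normal-form
machinery beyond the two quadratic roots.  Plotting is left to the user
(results are tidy CSV).  Fractional closed-loop convergence rates are
algebraic; see the control section before expecting tolerance-level
stabilization in finitely many steps at low orders.
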