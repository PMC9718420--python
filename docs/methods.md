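# Model and methods

## The circuit and its dynamics

The core object is a feedforward inhibitory motif: a single postsynaptic
excitatory neuron receives input from `N_E` presynaptic excitatory neurons
(rate `rho_E`, plastic weight `w_EE`) and `N_I` inhibitory neurons (rate
`nu_I`, plastic weight `w_EI`); the inhibitory neurons are driven by the same
presynaptic population through a fixed weight `w_IE` plus an external drive
`rho_I`.  Rates follow threshold-linear dynamics

    tau_FR_E * dnu_E/dt = -nu_E + [N_E rho_E w_EE - N_I nu_I w_EI + rho_add]_+
    tau_FR_I * dnu_I/dt = -nu_I + [N_E rho_E w_IE + rho_I]_+

All quantities are population means; with `N_E = N_I = 1` this is the
mean-field collapse used throughout the single-neuron experiments.  The
counts stay explicit so dominance sweeps over synapse numbers are possible.

Three plasticity rules are implemented, all gated by a postsynaptic LTD/LTP
threshold `c_post` (the rate at which plasticity flips from depression to
potentiation):

    excitatory (Hebbian):   tau_w_E dw_EE/dt = rho_E nu_E (nu_E - c_post_E)
    inhibitory, linear:     tau_w_I dw_EI/dt = nu_I (nu_E - c_post_I)
    inhibitory, nonlinear:  tau_w_I dw_EI/dt = nu_I nu_E (nu_E - c_post_I)

The nonlinear inhibitory rule is the mechanism of interest: it carries the
same factor `nu_E (nu_E - c_post)` as the excitatory rule, so for matched
thresholds both weights potentiate and depress together, and neither changes
when the postsynaptic neuron is silent.

## Closed-form theory

With matched thresholds and rates at quasi-steady state, the nullclines of
the two nonlinear rules coincide in a **line attractor**

    w_EI = (N_E rho_E)/(N_I nu_I) w_EE - c_post/(N_I nu_I),

valid for `w_EE >= c_post/(N_E rho_E)`.  Linearising the coupled weight
system on the line gives a rank-one Jacobian with eigenvalues `{Tr(J*), 0}`
and `Tr(J*) = (N_E rho_E^2/tau_w_E - N_I nu_I^2/tau_w_I) c_post`; the
attractor is stable exactly when inhibition dominates,

    N_I nu_I^2 / tau_w_I  >  N_E rho_E^2 / tau_w_E.

`analysis.jacobian_numeric` cross-checks the algebra with a central-difference
Jacobian (step 1e-6; attractor membership checked to 1e-6 in weight units,
eigenvalue agreement to 1e-6 relative in the tests).  On the attractor the
E/I weight ratio is `R = R_inf + c_post/(N_E rho_E w_EI)` with
`R_inf = N_I nu_I/(N_E rho_E)`; `R_inf` equals the attractor slope read as
`dw_EE/dw_EI` (the reciprocal of the `PhaseLines.slope` attribute, which
stores the line as `w_EI(w_EE)`), and for large presynaptic rates it falls to
`(N_I/N_E)(rho_I/rho_E + w_IE)`, bounded below by the fixed E-to-I weight.
For the *linear* inhibitory rule the attractor coexists with a separatrix
`w_EI = (N_E rho_E)/(N_I nu_I) w_EE - nu_I tau_w_E/(N_E rho_E^2 tau_w_I)`;
initial weights below it diverge.

## Time units and integration

Parameter-table values are used verbatim in one consistent arbitrary
simulation time unit.  The rate dynamics are orders of magnitude faster than
plasticity, so single-neuron experiments integrate the rates in the
instantaneous limit (rates at steady state each step) and the weights with
explicit Euler:

- `dt = 0.1` for the single-neuron feedforward runs near the attractor
  (contraction factor `|1 + Tr(J*) dt|` ~ 0.3 for the standard parameters).
  Far from the attractor this step overshoots into the silent region, so
  runs started from excitation-dominated initial weights use `dt = 0.01`.
- `dt = 1e-3` for the stiffer subsystems (sliding thresholds, brief-induction
  ensembles, the recurrent network), and an adaptive
  `dt = min(0.05, 0.5/(lhs+rhs))` in the random stability sweep so strongly
  stable draws stay inside the Euler stability region.

Update order per step: evaluate drive → update rates → compute weight
derivatives from the updated rates → update weights and (if enabled)
thresholds.  Gaussian drive noise is drawn i.i.d. per Euler step without
sqrt(dt) scaling: the noise is defined per step, not as a diffusion.
Divergence is classified by a guard at 1e6 weight units plus NaN detection;
run-ins are considered converged when `max|dw| < 1e-8` per unit time.

## Sliding thresholds (metaplasticity)

When `dynamic_thresholds` is on, the two thresholds move in opposite
directions in proportion to the induced plasticity:

    tau_c dc_post_E/dt = +dw_EE/dt,    tau_c dc_post_I/dt = -dw_EI/dt.

Two conditions are required for the matched state `c_post_E = c_post_I =
nu_E` to be attracting, and both shape the defaults:

1. **Threshold adaptation must be slower than the weight-mediated rate
   feedback.**  The inhibitory threshold update is locally positive feedback
   (`dc_post_I/dt ∝ -(nu_E - c_post_I)` drives `c_post_I` *away* from the
   rate); it is rescued only because the inhibitory weight pulls `nu_E`
   after `c_post_I`, which it can do only if the thresholds do not outrun
   it.  The default is `tau_c = 2.0` time units.  With a fast threshold
   (e.g. `tau_c` of order 1e-3) both thresholds crash to zero and the
   circuit silences — verified numerically during development.
2. **The inhibitory rate must exceed the presynaptic excitatory rate**
   (`nu_I > rho_E`).  On the slow manifold the threshold gap obeys
   `d|c_E - c_I|/dt ∝ (rho_E - nu_I) |c_E - c_I|`, so the gap shrinks only
   for `nu_I > rho_E`.  The threshold-matching experiments therefore default
   to `rho_I = 2` (`nu_I = 3` against `rho_E = 2`).

With these defaults, initial threshold pairs (0.7, 1.3) and (1.3, 0.7) match
to within 1e-3 in a few time units, each settling at a different common
value and hence a different stable firing rate.  The mechanism fails if a
weight hits the zero floor (plasticity stops, thresholds drift); the tests
assert the weights stay above the floor.

## Multi-input circuits and disinhibition

Ten input patterns of four presynaptic neurons each fire at 4 Hz against a
1 Hz background, one pattern per 100-ms window (0.1 time units), in random
order.  Two inhibitory classes control plasticity: ten *specific* pools (two
neurons each) driven only by their own input's neurons (`w_spec_IE = 0.2`),
and one *unspecific* pool driven by all inputs (`w_unsp_IE = 0.02`).  All
feedforward E-to-E and I-to-E weights are plastic under the nonlinear rule;
rates are instantaneous (`dt = 0.01`).

Disinhibition applies an external drive of -2 to one inhibitory class for
60 time units; the specific-class release is ramped linearly over 100 time
units to avoid silencing the neuron (the unspecific release is
instantaneous).  Specific disinhibition removes the input-specific
counterweight to Hebbian potentiation, so inputs compete and a receptive
field forms (selectivity index typically > 0.8); unspecific disinhibition
leaves the specific pools to cancel any input-specific gain and selectivity
stays near zero.  Without disinhibition the rate sits at the target
`c_post = 1` and plasticity is off.

### Recurrent network

Thirty such feedforward circuits are recurrently connected with plastic
E-to-E weights (excitatory rule with the presynaptic recurrent neuron's rate
in place of the input rate).  Design choices where the wiring is genuinely
open:

- The two inhibitory classes are shared across circuits and pool the pattern
  neurons of all thirty feedforward circuits, with per-synapse E-to-I
  weights an order of magnitude weaker (0.002 / 0.001).  This is the only
  wiring under which those weights produce inhibitory rates of order 1, and
  with it the inhibitory-dominance condition holds at the rates the network
  actually visits.
- Recurrent connectivity is sparse: connection probability 0.25 with weights
  drawn from U[0, 0.18].  A dense U[0, 0.18] matrix has spectral radius
  ~2.6, so the threshold-linear rate dynamics would be linearly unstable
  before plasticity could act; sparse connectivity (a standard cortical
  E-to-E density) keeps the initial recurrent gain below one, after which
  inhibitory plasticity maintains stability.  Rates integrate with
  `tau_FR = 0.01`, `dt = 1e-3`.
- Pattern sequences are partially shared: each circuit sees the globally
  shared pattern with probability `pattern_correlation = 0.5` per window,
  otherwise an independent draw.  Full sharing leaves the circuits
  symmetric and every neuron acquires the same one or two preferred inputs;
  independent sequences destroy the co-activity that wires same-preference
  neurons together.  At 0.5 the runs reliably produce 7-10 distinct
  receptive-field groups with within-group recurrent weights ~2.5x the
  across-group mean and strongly within-group bidirectional connections.

Reported connectivity applies a display threshold of 0.03; the
bidirectionality score is the mean of `min(w_ij, w_ji)` over ordered pairs
within versus across preference groups.

## What the synthetic inputs do and do not emulate

The pattern generator produces idealised, piecewise-constant, noiseless
rate patterns with equal presentation probability, and the drive module
provides per-step Gaussian noise and slow sinusoids.  Real sensory input has
temporal correlations, rate fluctuations within patterns, and overlapping
tuning, none of which are modelled; passing tests show that the plasticity
mechanism stabilises weights and gates learning under the stated idealised
conditions, not that it does so for natural stimulus statistics.  Likewise
the perturbation experiments change the input rate instantaneously and
permanently — a model of direct input-pathway stimulation rather than of
gradual sensory deprivation.

## Problem sizes used by the test suite and acceptance script

Closed-form targets are desk evaluations.  Simulated targets use: the
standard feedforward run to convergence (~20-30 Euler steps at `dt = 0.1`);
the perturbation protocol (run-in plus re-convergence, ~50 steps); the
stability sweep (50 parameter draws, a few thousand steps each); the
threshold-matching runs (20 time units at `dt = 1e-3`); ten seeds of the
multi-input protocol with shortened disinhibition (20 time units) and ramp
(30 time units) phases for the specific/unspecific contrast; and one
full-length 30-neuron recurrent run (170 time units at `dt = 1e-3`).
Shortened phases leave the qualitative contrasts unchanged; the full-length
protocol remains the default configuration.

## Known limitations

- The threshold-matching mechanism is non-local (one threshold pair per
  neuron, fed by total weight change), so it cannot coexist with input
  competition; dynamic thresholds and receptive-field formation are
  therefore exercised separately.
- Under varying *presynaptic* input the weights drift slowly (the attractor
  slope itself moves); the model offers no mechanism to arrest this drift,
  and the drift summary quantifies rather than removes it.
- The feedback-motif inhibitory equation
  `tau dnu_I/dt = -nu_I + [N_E rho_E w_FF + w_FB nu_E + rho_I]_+` is the
  minimal reading of the feedback wiring and is marked inferred; its
  stability map is classified empirically by the divergence guard.
- Explicit Euler with the coarse default step reproduces the printed
  dynamics but is not a high-accuracy integrator; halving `dt` changes
  terminal quantities by less than the test tolerances, which is the
  accuracy standard applied throughout.
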