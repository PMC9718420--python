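# inhplast

Rate-based modelling of interacting excitatory and **nonlinear inhibitory
synaptic plasticity** in threshold-linear circuits.

Hebbian plasticity of excitatory-to-excitatory synapses is unstable on its
own: potentiation raises the postsynaptic rate, which drives further
potentiation.  This package implements and analyses an inhibitory plasticity
rule for inhibitory-to-excitatory synapses that depends *nonlinearly* on the
postsynaptic rate,

    tau_w_E dw_EE/dt = rho_E  nu_E (nu_E - c_post)        (excitatory)
    tau_w_I dw_EI/dt = nu_I   nu_E (nu_E - c_post)        (inhibitory, nonlinear)

so that inhibitory weights potentiate and depress *together with* the
excitatory ones and freeze when the neuron is silent.  When inhibition
dominates (`N_I nu_I^2/tau_w_I > N_E rho_E^2/tau_w_E`), the coupled weight
dynamics converge onto a **line attractor**

    w_EI = (N_E rho_E)/(N_I nu_I) w_EE - c_post/(N_I nu_I)

on which the postsynaptic rate equals the LTD/LTP threshold `c_post` and the
E/I weight ratio approaches `R_inf = N_I nu_I / (N_E rho_E)`.  The package
provides:

- `inhplast.model` — threshold-linear rate dynamics of the feedforward
  inhibitory motif (steady states, Euler/instantaneous integration, drive
  waveforms: steps, per-step Gaussian noise, sinusoids);
- `inhplast.plasticity` — the excitatory rule, linear and nonlinear
  inhibitory rules, and sliding LTD/LTP thresholds (metaplasticity);
- `inhplast.analysis` — closed-form line attractor, zero-rate boundary,
  linear-rule separatrix, stability condition, Jacobian eigenvalues (with a
  finite-difference cross-check) and E/I-ratio reports;
- `inhplast.experiments` — convergence runs, input-perturbation protocol,
  E/I-ratio induction ensembles, varying-drive drift summaries, and the
  feedback-motif stability map;
- `inhplast.circuits` — multi-input circuits with input-specific and
  unspecific inhibition, disinhibition-gated receptive-field formation, and
  a 30-neuron recurrent network that forms assemblies of similarly tuned
  neurons;
- a CLI (`inhplast`) and YAML configuration with resolved-config snapshots
  for reproducible runs.

See `docs/methods.md` for the model, its assumptions, parameter defaults and
numerical choices.

## Worked example

```python
import inhplast as ip

params = ip.FeedforwardParams()        # rho_E=2, rho_I=0.5, w_IE=0.5 -> nu_I=1.5
rule   = ip.PlasticityParams(inhibitory_rule="nonlinear")

# closed-form theory
line = ip.line_attractor(params, c_post=1.0)
cond = ip.stability_condition(params, rule, c_post=1.0)
print(f"attractor slope {line.slope:.4f}, abscissa {line.abscissa_intercept}")
print(f"inhibition dominance {cond.lhs} > {cond.rhs}: stable={cond.stable}, "
      f"eigenvalues {cond.eigenvalues}")

# simulation from initial weights [1.5, 0.5]
traj = ip.run_feedforward(params, rule, rule.initial_weights(1.5, 0.5),
                          T=200.0, stop_when_converged=True)
print(f"terminal rate {traj.final_rates.nu_E:.6f} Hz at "
      f"w_EE={traj.final.w_EE:.4f}, w_EI={traj.final.w_EI:.4f}")
```

prints

```
attractor slope 1.3333, abscissa 0.5
inhibition dominance 11.25 > 4.0: stable=True, eigenvalues (-7.25, 0.0)
terminal rate 1.000000 Hz at w_EE=1.8448, w_EI=1.7931
```

The simulated weights land on the analytic attractor
(`1.3333 * 1.8448 - 0.6667 = 1.7931`) and the firing rate sits exactly at
the 1 Hz LTD/LTP threshold: plasticity has switched itself off.

From the shell:

```sh
inhplast simulate --seed 1 --out-dir out/          # trajectory.csv + summary.json
inhplast phase --out-dir out/                      # attractor/boundary + vector field
inhplast perturb --rho-base 2 --rho-disr 2.5 --out-dir out/
inhplast receptive-field --disinhibit specific --out-dir out/
inhplast recurrent --seed 0 --out-dir out/
```

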