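# fpreduce

Low-dimensional spike-rate models derived from networks of adaptive
exponential integrate-and-fire (aEIF) neurons.

Large populations of spiking neurons are expensive to simulate and hard
to analyze, yet their collective activity is often low-dimensional.  In
the mean-field limit, a sparsely coupled aEIF population driven by
fluctuating input is described by a Fokker–Planck (FP) equation for the
membrane-voltage density p(V, t) with an absorbing boundary at the spike
voltage V_s, reinjection at the reset V_r and a slow population-averaged
adaptation current ⟨w⟩:

    ∂_t p + ∂_V q_p = 0,
    q_p = ( [I_L(V) + I_exp(V)]/C + μ_tot(t) ) p − (σ_tot²(t)/2) ∂_V p,
    r(t) = q_p(V_s, t),

with total input moments μ_tot = μ_ext + JK r_d − ⟨w⟩/C and
σ_tot² = σ_ext² + J²K r_d (diffusion approximation of the recurrent
pulses, delayed rate r_d).  `fpreduce` implements this hierarchy end to
end and reduces it to four ordinary differential equation models for the
population rate r(t):

- **spec₁** — dr̃/dt = λ₁(r̃ − r∞), r = Re r̃, driven by the dominant
  eigenvalue λ₁(μ_tot, σ_tot) of the FP operator;
- **spec₂** — β₂r̈ + β₁ṙ + β₀r = r∞ − r − β_c, with coefficients built
  from the two dominant eigenvalues and spectral projection scalars;
- **LN_exp** — exponential linear filters for the input mean and
  standard deviation followed by the static nonlinearity r∞(μ_eff, σ_eff);
- **LN_dos** — a damped-oscillator mean filter variant capturing rate
  over- and undershoots.

All model coefficients are functions of two numbers only — the momentary
mean and standard deviation of the total input — and are precomputed once
on a (μ, σ) grid per EIF parameter set.  Changing the input statistics,
the coupling (K, J, delays) or the adaptation parameters (a, b, τ_w, E_w)
requires no recomputation.

The package is intended for computational neuroscientists who want
derived (not fitted) population-rate models that retain a quantitative
link to single-neuron parameters: for network-state analyses, for
mean-field building blocks in multi-population brain models, and as a
reference implementation of the underlying numerics.

## What is inside

| module | contents |
| --- | --- |
| `fpreduce.params` / `signals` | parameter containers, units, OU input processes, Gaussian smoothing |
| `fpreduce.network` | ground-truth Monte-Carlo simulator of N coupled aEIF neurons (numba) |
| `fpreduce.fv` | implicit Scharfetter–Gummel finite-volume FP solver |
| `fpreduce.stationary` | steady-state density, r∞, ⟨V⟩∞ and derivatives |
| `fpreduce.spectral` | shooting/Magnus eigenvalue solver for the FP operator and its adjoint |
| `fpreduce.cascade` | frequency-domain linear rate responses and filter fits |
| `fpreduce.tables` | (μ, σ) quantity precomputation, HDF5 persistence, bilinear lookup |
| `fpreduce.models` | time integration of spec₁, spec₂, LN_exp, LN_dos |
| `fpreduce.metrics` / `bench` | Pearson/RMS accuracy measures and the benchmark harness |
| `fpreduce.cli` | `fpreduce precompute / simulate-network / run-fp / run-model / compare` |

## Worked example

Benchmark the reduced models against a spiking network driven by a
fluctuating mean input (Ornstein–Uhlenbeck, correlation time 50 ms,
strength 0.54 mV/ms, smoothed with a 1-ms Gaussian kernel; constant
σ_ext = 2 mV·ms^(-1/2)):

```python
from fpreduce import (NeuronParams, CouplingParams, OUParams,
                      precompute_quantities, GridSpec)
from fpreduce.bench import make_inputs, compare_models

neuron = NeuronParams()                      # cortical pyramidal aEIF
table = precompute_quantities(
    neuron,
    GridSpec(mu_min=-1.0, mu_max=4.0, d_mu=0.25,
             sigma_min=1.5, sigma_max=2.5, d_sigma=0.25),
    dV_stationary=0.02, dV_spectral=0.02, dV_cascade=0.1, n_freq=32)

inputs = make_inputs(OUParams(mean=1.5, theta=0.54, tau_ou=50.0),
                     None, sigma_ext_sq=4.0, T=10000.0, dt=0.05, seed=7)
report = compare_models(neuron, CouplingParams(K=0, delay_kind="none"),
                        inputs, table,
                        models=("fp", "lnexp", "lndos", "spec1", "spec2"),
                        N=2000, seed=1)
print(f"network rate: {1e3 * report.rate_mean_net:.1f} "
      f"+- {1e3 * report.rate_std_net:.1f} Hz "
      f"(input-output rho = {report.rho_input_output:.3f})")
for name, m in report.per_model.items():
    print(f"{name:6s} rho = {m.rho:.3f}   d_RMS = {1e3 * m.d_rms:.2f} Hz")
```

Output (a few minutes on one core, dominated by the table and the
2000-neuron network):

```
network rate: 14.5 +- 13.2 Hz (input-output rho = 0.852)
fp     rho = 0.979   d_RMS = 2.70 Hz
lnexp  rho = 0.976   d_RMS = 2.90 Hz
lndos  rho = 0.974   d_RMS = 2.98 Hz
spec1  rho = 0.963   d_RMS = 3.68 Hz
spec2  rho = 0.963   d_RMS = 3.77 Hz
```

Reading this: the network's 1-ms binned rate fluctuates between
quiescence and bursts (mean 14.5 Hz, std 13.2 Hz).  The Fokker–Planck
solution is the mean-field ceiling (ρ = 0.979 — the rest is finite-size
noise of the 2000-neuron estimate); the cascade models track it almost
perfectly, the one-eigenvalue spec₁ model trails, and every model far
exceeds the raw input–output correlation 0.852.

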