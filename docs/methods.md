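# Methods

## Scope and model hierarchy

`fpreduce` implements a four-level hierarchy of descriptions of the same
object — a large, homogeneous population of adaptive exponential
integrate-and-fire (aEIF) neurons receiving fluctuating input and sparse
recurrent pulse coupling:

1. **Network** (`network`): N coupled stochastic differential equations,
   integrated with Euler–Maruyama.  This is the ground truth.
2. **Fokker–Planck (FP) mean field** (`fv`): in the limit N → ∞ under the
   diffusion approximation, the membrane-voltage density p(V, t) obeys a
   drift–diffusion PDE with an absorbing boundary at the spike voltage
   V_s, reinjection at the reset V_r, a reflecting lower bound V_lb, and
   a population-averaged adaptation current ⟨w⟩ (adiabatic
   approximation: the slow adaptation variable is replaced by its
   population mean).
3. **Spectral reductions** (`spectral`, `models`): projecting the FP
   dynamics onto the slowest eigenmodes of the FP operator L(μ, σ) gives
   spec₁ (one eigenvalue, a complex scalar ODE; valid for vanishing input
   variations) and spec₂ (two eigenvalues, a real second-order ODE; valid
   for slow input variations).
4. **Linear–nonlinear cascades** (`cascade`, `models`): the rate response
   of the FP model to weak input modulations defines linear filters for
   the input mean and standard deviation; approximating them by an
   exponential (LN_exp) or a damped oscillator (LN_dos), followed by the
   steady-state nonlinearity r∞(μ, σ), gives the two cascade models.

Every (μ, σ)-dependent quantity — r∞, ⟨V⟩∞, their derivatives, the
dominant eigenvalues λ₁, λ₂, the spectral coupling scalars, the filter
parameters — depends only on the detached EIF membrane (C, g_L, E_L, Δ_T,
V_T, V_s, V_r, V_lb, T_ref).  They are precomputed once on a rectangular
(μ, σ) grid (`tables`) and bilinearly interpolated during time
integration; changing input, coupling or adaptation parameters never
invalidates a table.

## Units

Time in ms, voltage in mV, capacitance in pF, conductance in nS, current
in pA, rates in kHz.  Input moments are expressed per capacitance: the
mean drive μ in mV/ms and the noise intensity σ² in mV²/ms, so σ itself
carries mV·ms^(−1/2).  Noise intensities below σ = 0.5 mV·ms^(−1/2) are
rejected: both the diffusion approximation and the numerics of the
stationary/spectral problems degrade there.

## Default parameters

The default `NeuronParams` describe a regular-spiking cortical pyramidal
neuron: C = 200 pF, g_L = 10 nS, E_L = −65 mV, Δ_T = 1.5 mV, V_T = −50 mV,
V_s = −40 mV, V_r = −70 mV, T_ref = 0, a = 4 nS, b = 40 pA, E_w = −80 mV,
τ_w = 200 ms, V_lb = −200 mV.  Default discretizations: network and FP
step Δt = 0.05 ms, reduced-model step Δt = 0.01 ms (Heun), FP voltage
spacing ΔV = 0.028 mV, spectral/quantity voltage spacing ΔV = 0.01 mV,
quantity-grid spacings Δμ = 0.025 mV/ms and Δσ = 0.1 mV·ms^(−1/2), rate
bin ΔT = 1 ms.  Tests and the bundled analysis scripts use coarser grids
(ΔV up to 0.25 mV, Δμ = 0.25 mV/ms); the shooting eigenvalue solver is
converged to ~6 significant digits already at ΔV = 0.04 mV, and the
benchmark results below are insensitive to these choices at the percent
level.

## Numerical methods

### Network simulator

Fixed in-degree K with partners drawn uniformly without replacement;
per-connection delays sampled once (exponential with mean τ_d, identical
d, or none) and rounded to the nearest step (error ≤ Δt/2), delivered
through a per-neuron ring buffer.  V_i(0) ~ Normal(V_r − δV, (δV/2)²)
with δV = V_T − V_r; w_i(0) = 0.  The exponential spike-initiation
current is evaluated with its argument capped at 20 to avoid overflow in
the step before threshold detection.  Runs are reproducible given a seed;
per-step Gaussian noise is drawn as one vector per time step.  Spike
times are recorded with midpoint convention (the spike occurred during
the step), making the raster's histogram identical to the kernel's
internal bin counts.  Voltage jumps arriving at a refractory neuron are
discarded (the voltage is clamped); with the default T_ref = 0 this never
occurs.

### Finite-volume FP solver

Scharfetter–Gummel exponentially fitted fluxes on equidistant cells, with
the robust `expm1` form and a series branch for Peclet numbers |z| <
1e−8.  Time stepping is backward Euler in p with the operator frozen at
the start of each step (one tridiagonal solve per step, Thomas
algorithm).  The emitted rate is the absorbing ghost-cell flux with the
same frozen coefficients.  Reinjection is delayed by n_ref =
max(1, ceil(T_ref/Δt)) steps — a minimal one-step refractory period that
keeps the system tridiagonal; the discrete probability bookkeeping
(density mass plus the reinjection pipeline) is then conserved to solver
round-off (< 1e−10) at every step.  This one-step delay makes the
long-time rate differ from the direct stationary solve by a factor
1/(1 + r∞Δt), about 0.2% at 46 Hz and Δt = 0.05 ms, which is the dominant
part of the 0.5% agreement tolerance used in the tests.

### Stationary problem

Solved directly as a bordered sparse linear system: per-cell flux balance
with the reinjected rate as an explicit unknown, closed by the
normalization Σp ΔV + r T_ref = 1 (for T_ref > 0 the refractory mass
enters only the normalization).  Derivatives on the (μ, σ) grid use
central differences (one-sided at edges); σ²-derivatives follow from the
chain rule ∂σ² = ∂σ/(2σ).  Time marching of the PDE is retained as a test
oracle, not used for precomputation.  The optional spike-shape variant
adds the refractory mass at the linear-downswing average (V_r + V_s)/2 to
the mean voltage.

### Spectral solver

The eigenproblem of L is recast as complex root finding on the
backward-integrated eigenflux: q(V_lb; λ) = 0.  Each voltage step applies
the analytic exponential of the 2×2 coefficient matrix evaluated at the
interval midpoint (one-term Magnus scheme; a series branch handles nearly
coincident local exponents).  The backward sweep rescales (q, φ) jointly
when magnitudes exceed 1e120, which linearity permits.  Root refinement
uses a complex secant iteration — q(V_lb; λ) is analytic in λ, so this
converges in a handful of sweeps — with Powell's hybrid method on
(Re λ, Im λ) as fallback.  Initial approximations come from (i) a dense
real-λ scan at hyperpolarized mean input, where the entire spectrum is
real, and (ii) for general nodes, a sparse shift-invert
eigendecomposition of the Scharfetter–Gummel operator matrix on a coarse
grid (ΔV = 0.1 mV), refined by the shooting solver on the fine grid.
Seeding from the operator matrix (rather than continuing individual real
roots in μ) is what keeps the solver robust where two real roots merge
into a complex-conjugate pair; along a table column the previous node's
eigenvalues still serve as first-choice seeds, with reseeding on loss of
roots.

λ₁ is the nonzero eigenvalue of smallest |Re|; λ₂ minimizes |Re| among
the rest subject to λ₁ + λ₂ ∈ R, so the pair is real or complex
conjugate and all spec₂ coefficients are real.  Near-ties (within 1e−6)
prefer the branch continuous with the neighboring grid node.  The
selection jumps along a curve in the (μ, σ) plane where the dominant
branch switches between the real "diffusive" family (significant below
the reset, dominant for noise-dominated input) and the "regular" family
(real pairs merging into complex conjugates as the mean drive grows);
those nodes are flagged in the table, and no smoothing is applied across
them.

Adjoint eigenfunctions ψ are integrated forward from V_lb with the
deterministic normalization ψ(V_lb) = 1, ψ′(V_lb) = 0; the boundary
residual ψ(V_s) − ψ(V_r)e^{−λT_ref} is the acceptance check of λ.
Biorthonormalization scales φ (not ψ) so ⟨ψ, φ⟩ = 1 under the
non-conjugated inner product with trapezoidal quadrature.  Keeping ψ at
its fixed-init normalization makes the ψ-branch smooth in (μ, σ); the
coupling coefficients c_n^x = ⟨∂_x ψ_n, φ₀⟩ are computed by central
differences of ψ over small offsets in μ and σ², re-solving λ_n at the
offset points by local continuation so the branch identity is preserved.
The products f·c entering the spec₂ coefficients are invariant under the
residual joint rescale freedom, and c_n itself is normalization-
convention independent because ⟨ψ_n, φ₀⟩ = 0; the dual identity
c_n = −⟨ψ_n, ∂_x p∞⟩ is verified in the tests to 0.5%.  Only the two
dominant modes are used: products for deeper modes suffer catastrophic
cancellation in ⟨ψ_n, φ_n⟩ and are not computed.

A nonzero refractory period is supported in the eigenproblem through the
factor e^{−λT_ref} in the reinjection condition; this is exact only under
the frozen-moments assumption and is therefore used for spec₁ quantities
only (spec₂ requires T_ref = 0).

### Linear rate response and filter fits

For each modulation frequency f, one complex sparse linear solve of the
linearized finite-volume operator about the stationary solution yields
R̂(f); the parameter-derivative sources use central differences of the
operator assembly (step 1e−3).  Using the same discretization family as
the stationary problem makes the f → 0 limit consistent with the
stationary derivative by construction; the module additionally solves an
extra near-zero frequency (1e−6 kHz) whose real part serves as the DC
normalizer — identical to ∂r∞/∂x but well conditioned where the rate is
exponentially small.  The frequency grid is 64 (tests: 32–48) log-spaced
points in [1e−3, 1] kHz.

Filter fits: τ_μ from a least-squares Lorentzian fit of D̂_μ =
R̂_μ/(∂μ r∞) over f ∈ [0, 1] kHz on complex residuals (phase carries the
decay information), weighted by the local frequency spacing so the
discrete sum approximates the continuous misfit; the alternative
asymptotic estimate τ_μ = Δ_T ∂μ r∞/r∞ matches the exact high-frequency
limit R̂_μ → r∞/(i2πfΔ_T) and is exposed as a mode.  The two estimates
agree only in order of magnitude where the filter carries a slow
diffusive component (e.g. a factor 1.8 at μ = 0.5, σ = 3.5); the
least-squares value is the table default.  The damped-oscillator filter
B e^{−t/τ}cos(ωt) has B = (1 + τ²ω²)/τ fixed by DC normalization; τ and ω
minimize the complex mismatch at the two frequencies where |Re D̂| and
|Im D̂| peak (peak positions refined by local quadratic interpolation in
log f; both matching conditions weighted equally; a peak at the grid edge
falls back to ω = 0, which reduces the filter exactly to the
exponential).  Its filter-application ODE is μ̈_f + (2/τ)μ̇_f +
(1/τ² + ω²)μ_f = B(μ_syn/τ + μ̇_syn) — the transfer function of the
normalized filter; the stiffness coefficient 1/τ² + ω² is forced by the
unit DC gain and by the exact ω = 0 reduction.  τ_σ uses the same
Lorentzian fit when ∂σ r∞ > 0 and degenerates to a delta filter
(τ_σ = 0) otherwise, which occurs for large mean and small noise where
the true σ-filter has a negative high-frequency tail.

### Reduced-model integration

Heun (explicit trapezoid) by default at Δt = 0.01 ms; explicit Euler
available (the second-order models need clearly smaller steps under Euler
to avoid ringing artifacts).  Filter time constants are floored at Δt so
near-delta filters relax within one step without overshoot.  spec₂
clamps r and ṙ to zero whenever r < 0 and continues; spec₁ clips only
its output (and the rate fed to adaptation/delay), leaving the complex
state untouched to preserve its linear dynamics.  External-moment
derivatives (μ̇, μ̈, σ̇², σ̈²) are central differences of the
Gaussian-smoothed input signals at the model step; the smoothing width
σ_t ≥ 1 ms is required for spec₂ and LN_dos.  For LN_dos, μ̇_syn uses the
exact identity JK(r − r_d)/τ_d for exponential delays, the ring-buffer
difference quotient of the delayed rate for identical delays (using the
instantaneous rate's derivative instead visibly suppresses the
delayed-inhibition limit cycle), and the input derivative alone when
uncoupled.  The spec₂ coefficient set is implemented for exponential
delays (the delay terms vanish when uncoupled); coupled runs with other
delay kinds raise an unsupported-configuration error.  Initial
conditions: r (or r̃) starts at r∞ of the initial moments, μ_f, σ_f at
the initial synaptic moments, ⟨w⟩ at 0; a Kolmogorov–Smirnov utility can
match (μ_f(0), σ_f(0)) to an empirical voltage distribution.

## What the synthetic inputs emulate

Benchmark inputs are Ornstein–Uhlenbeck processes for μ_ext(t) (and
optionally σ_ext²(t)) smoothed with a Gaussian kernel of width σ_t = 1 ms
— a stand-in for the slowly wandering aggregate drive from presynaptic
populations, covering oscillation timescales via τ_ou (50 ms moderate,
5 ms rapid) and excursion strength via ϑ_μ (0.54 mV/ms in the standard
cells).  The OU update uses the exact discretization, so stationarity
holds at any step; realizations of σ_ext² below the admissible floor are
rejected when frequent (> 1%) and clamped (with a warning) when rare.
These inputs share the Gaussian-process character and the timescales of
cortical population input but none of its non-Gaussian, correlated or
oscillatory-structured features; passing benchmarks therefore demonstrate
fidelity of the *reduction* (reduced model vs. spiking network under
identical drive), not realism of the drive itself.

## Benchmark protocol and problem sizes

One smoothed OU realization is shared by the network and every model; the
1-ms binned rates are compared by Pearson correlation ρ and RMS distance
after discarding the first second (initial conditions are unmatched).
The package's standard benchmark cells are (μ̄, σ_ext) ∈ {(1.5, 2.0),
(3.0, 1.5)} × τ_ou ∈ {50, 5} ms with ϑ_μ = 0.54 mV/ms, run at N = 10,000
neurons for 20 s in the analysis script and N = 5,000 for 15 s in the
test suite.  At these population sizes the finite-size noise in the 1-ms
bins (≈1–2 Hz) caps the attainable correlation; the FP solver, which is
the exact mean-field reference, reaches ρ ≈ 0.98 under these conditions
and upper-bounds every reduced model, with the observed ordering
FP > LN_exp ≈ LN_dos > spec₂ > spec₁.

The quasi-static check drives all models with a τ_ou = 500 ms, ϑ_μ =
0.3 mV/ms input around μ̄ = 2.5 mV/ms at σ_ext = 2.0 — an operating point
chosen in the active, mean-driven regime: near-quiescent excursions would
probe the models' zero-rate clamping rather than the quasi-static limit.
All four reduced models and the FP solver then agree pairwise within 3%
RMS relative to the mean rate.

Oscillation regimes use the recurrent parameter sets (K = 1000): strong
excitation J = 0.03 mV with adaptation a = 3 nS, b = 30 pA and
exponential delays τ_d = 3 ms; and delayed inhibition J = −0.0357 mV with
identical delays d = 10 ms and no adaptation.  Stability is asserted as
amplitude stationarity over the final half of a 2-s run.  With the
inhibitory feedback, replacing the identical delay by an exponential one
of equal mean damps the cycle — the exponential delay's mass at zero lag
weakens the feedback phase — so the identical-delay form is the one
tested.

## Known limitations

- Single population only; no conductance-based synapses, colored input
  noise, heterogeneous neuron parameters or finite-size stochastic
  corrections.
- spec₂ carries only the two dominant eigenmodes; its coefficients jump
  along the diffusive/regular branch-switch curve (flagged, not
  smoothed), and its low-frequency phase deviates from the full-spectrum
  response (the truncation keeps the DC gain exact but not the full
  O(iω) coefficient), consistent with its reduced accuracy for rapid
  input changes.
- Coupled spec₂ supports exponential delays only; spec₂ requires
  T_ref = 0.
- Bilinear table interpolation adds O(Δμ²) error with derivative kinks at
  cell edges; production spacings keep mid-cell rate errors below 1%.
- The minimal one-step refractory period of the FP solver biases the rate
  by a factor 1/(1 + rΔt) (≲0.3% at default settings).
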