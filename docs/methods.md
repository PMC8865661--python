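# Methods

## Model

A single stochastic neuron receives `d` input spike trains and emits an
output spike train. The synaptic weights `w_t ∈ R^d` are hidden and drift as
independent Ornstein–Uhlenbeck (OU) processes

    dw_t = τ_ou⁻¹ (μ_ou − w_t) dt + sqrt(2 σ_ou² τ_ou⁻¹) dV_t,

with per-coordinate mean `μ_ou`, equilibrium variance `σ_ou²` and relaxation
timescale `τ_ou`. Input spikes are low-pass filtered by the causal kernel
`ε(t) = exp(−t/τ_m) Θ(t)` into presynaptic traces `x^ε_t`; the membrane
potential is the Markovian approximation `u_t = w_tᵀ x^ε_t` and output
spikes follow an inhomogeneous Poisson process with exponential gain
`g(u) = g₀ exp(β u)`. The determinism parameter `β` sets how informative an
output spike is about the weights; `β = 0` makes the output a homogeneous
Poisson process. An optional bias weight (coordinate 0) has a constant unit
input and models excitability; its prior timescale `τ_ou,bias` is of the
order of the membrane timescale, far faster than ordinary weights.

## The Synaptic Filter

The learner tracks the posterior over the hidden weights given the observed
input/output spikes. The exact filtering distribution is intractable; the
Synaptic Filter is a continuous-time Gaussian assumed-density filter
`N(μ_t, Σ_t)` with updates

    dμ = β Σ x^ε (dY_t − γ dt) + τ_ou⁻¹ (μ_ou − μ) dt
    dΣ = [ −β² γ (Σ x^ε)(Σ x^ε)ᵀ + relax(Σ_ou − Σ) ] dt

where `dY_t` is the output spike increment (a unit jump at spike bins) and

    γ = g₀ exp( β μᵀx^ε + ½ β² x^εᵀ Σ x^ε )

is the posterior expected firing rate, in closed form for the exponential
gain. The covariance update is independent of the observations — a
structural parallel to the Kalman filter. The mean update is a three-factor
rule: presynaptic trace × (observed − expected output) × covariance.

`relax` acts entry-wise at rate `1/τ_i + 1/τ_j`, which reduces to the
homogeneous `2/τ_ou` when all timescales are equal and lets a fast bias
coordinate coexist with slow weights; bias–weight covariances then decay on
the order of `τ_m`, which the protocol experiments rely on. This
heterogeneous-timescale relaxation is the package's generalisation of the
scalar-timescale update and is required for the bias experiments.

Three covariance structures are provided: **Full** (one `d×d` block),
**Block** (independent blocks of size `b`, default 8; the first block
absorbs both the remainder and the bias) and **Diagonal** (variances only).
Cross-block covariances are identically zero by construction. The baseline
learner is the stochastic-gradient point estimate
`dw = η β x^ε β (dY − g dt)` with `g = g₀ exp(β wᵀx^ε)`. The printed
double-β prefactor is the default (it makes `η` comparable to a posterior
variance and dimension-scaling consistent with the filter); the bare
log-likelihood gradient (single β) is available via `double_beta=False`.

### Numerical integration

All ODE/SDE integration is explicit Euler(–Maruyama) on a fixed grid; spikes
are per-bin Bernoulli with probability `min(rate·dt, 1)` (clipping beyond
0.1 % of bins triggers a warning to shrink `dt`). Within a bin, the order of
operations is fixed for bit-reproducibility: advance hidden weights, draw
input spikes, decay-then-increment traces (bias pinned to 1), compute the
membrane potential, draw the output spike, then update the learners.
Covariance blocks are re-symmetrised every step (guards floating-point
drift; the analytical update is symmetric). If any posterior variance
becomes non-positive the step raises an error advising a smaller `dt`; the
preconditioning protocol contracts variances sharply, which is why the
heterosynaptic experiments integrate at `dt = 1e-5 s` while plain STDP uses
`1e-4 s` and the tracking benchmarks `1e-3 s`.

### Negative weight correlations

With non-negative inputs and a diagonal initial covariance, the off-diagonal
update at the zero crossing is `−γ Σ_ii x_i Σ_jj x_j ≤ 0`, so for two
synapses the weight correlation can never become positive: this
explaining-away structure is what produces heterosynaptic plasticity. The
guarantee is two-dimensional; at `d > 2` a near-zero off-diagonal can be
pushed slightly positive through third-party correlations (`(Σx)_i` changing
sign), which we observe in stress tests at strong update rates. Diagnostics
(`validate_belief`) report symmetry defect, minimum variance and the largest
off-diagonal entry; the strict negativity test is run with two synapses.

## Simulated experiments

### Tracking benchmark (normalised MSE)

A tutor session is generated; every learner consumes the identical (trace,
output spike) stream — matched seeds per grid point make rule comparisons
paired. Performance is `MSE = d⁻¹ ⟨(w_t − μ_t)ᵀ(w_t − μ_t)⟩_t / σ_ou²`, so
"no learning" scores 1. Time is counted in epochs (multiples of `τ_ou`);
burn-in epochs are discarded. The benchmark also records per-epoch errors,
whose spread yields the standard error used by the statistical checks.

Desk-scale defaults: `τ_ou = 20 s`, `dt = 1e-3 s`, `g₀ = 20 Hz`,
`ρ = 40 Hz`, 8 burn-in epochs, 8–16 averaging epochs, `d ≤ 256`. These keep
a full dimension sweep within minutes on one core while leaving the
qualitative structure (prior limit at `β = 0`, saturation at high `d`,
filter ≥ gradient-rule ordering) intact; the larger published-style settings
(`τ_ou = 200–400 s`, 256 epochs, `dt` down to `1e-5 s`) remain reachable
through configuration but are not exercised by the test suite. In dimension
sweeps `β ∝ d^(−1/2)` (value quoted at `d = 16`) keeps the output-rate
statistics comparable across `d`. With few averaging epochs the MSE estimate
at large `d` fluctuates around its saturation value 1; monotonicity checks
therefore compare neighbouring grid points through their combined epoch-wise
standard errors rather than as raw inequalities.

### STDP protocol

Hyperparameters for the plasticity experiments: `g₀ = 1 Hz`, `β = 1`,
`τ_m = 25 ms`, `τ_ou = 1e4 s` (synapses effectively frozen priors),
`τ_ou,bias = τ_m`, `μ_ou,bias = 1`, bias prior variance 2 (STDP) or 1
(heterosynaptic runs), initial condition `μ = 1`, `Σ = I`. The bias prior
variance setting is applied to the bias coordinate only (ordinary weights
keep variance 1); a config override exists. The filter is first relaxed for
`T_wait = 6 τ_m` with no spikes (bias trace pinned at 1) so the bias reaches
its equilibrium. Each delay restarts from this cached state — trials are
independent. One presynaptic and one postsynaptic spike are delivered with
timing difference `delay = t_post − t_pre` (positive = causal); the weight
is read immediately before the first spike and again `|delay| + 2 T_wait`
after it, so every trial settles for the same time after its last spike.
The default delay grid is 200 points over ±125 ms (±5 τ_m).

Without the bias the acausal (post-before-pre) side is timing-independent;
with the bias, a postsynaptic spike transiently raises the inferred
excitability and hence the expected rate, producing timing-dependent
depression whose empirical timescale — the 1/e point of the
baseline-subtracted acausal lobe, with the far-acausal level as the zero
reference — grows monotonically with `τ_ou,bias`. The causal lobe decays
with the trace kernel; at `β = 1` its peak is compressed a further ~20 % by
the elevated expected rate after the presynaptic spike, so log-linear fits
of the lobe use its mid-range. The posterior variance decreases at every
delay (spikes are informative), most strongly at coincidence.

### Preconditioning and heterosynaptic plasticity

Three weights (bias + two synapses). Preconditioning (PC) delivers one
presynaptic spike pair (5 ms apart) synchronously to both synapses with no
output spikes, then waits `T_wait`. The shared silence is evidence against
both weights jointly; the posterior mean drops and the synapse–synapse
covariance turns negative. The STDP pair is then applied to synapse 1 only;
weight changes are read at both synapses and the hetero-vs-homo points are
fitted with an ordinary least-squares line (slope, offset).

The logic table is structural: the Diagonal filter cannot represent
correlations and never shows heterosynaptic plasticity; the Full filter
without PC has nothing in its off-diagonals and behaves likewise; only Full
+ PC moves the unstimulated synapse, with sign opposite to the stimulated
one. The slope magnitude, by contrast, is a continuous function of how much
anticorrelation PC induces: with a single spike pair the post-PC correlation
ratio `Σ₁₂/Σ₁₁` and the fitted slope are ≈ −0.5; a second pair drives the
slope towards −0.75, and more pairs saturate towards −1. The number of PC
pairs is a protocol parameter (`ProtocolSpec.n_pc_pairs`, default one pair).
A cross-check against an exact oracle (the static no-spike posterior is
`prior × exp(−∫g dt)`, integrable by plain Monte Carlo) shows the true
posterior anticorrelation after a single pair is substantially weaker than
the filter's: the assumed-density filter's continuous Gaussian projection
systematically deepens anticorrelation in this strong-evidence regime. Both numbers are far from zero, so the
qualitative prediction — anticorrelated homo- and heterosynaptic plasticity
— is robust to these details, while the slope's absolute value is not.

### Particle-filter oracle

A bootstrap particle filter on the same generative model validates the
Gaussian filter at low dimension: OU propagation, per-bin point-process
log-likelihood `y log(g dt) − g dt`, systematic resampling when the
effective sample size falls below half the ensemble. Particle filters
degenerate with dimension; the oracle refuses `d > 3`. The agreement
tolerance is anchored to the oracle's own Monte-Carlo error: two independent
10⁴-particle runs on the same session set the self-consistency divergence,
and the filter must match the oracle within three times that plus a small
absolute floor (0.02 on the mean, 0.03 on the variance, in units of the
prior scale). The floor covers the filter's genuine projection bias, which
is of the same order as the Monte-Carlo band in typical sessions.

## Synthetic data: what it does and does not emulate

All data are generated by the tutor model itself: homogeneous Poisson
inputs, block-sparse inputs (one block of `b = 8` channels active for
`τ_block = 1 s` at a time, cycling deterministically by default, seeded
shuffle optional), or fully scripted protocol spikes. The generator
reproduces exactly the assumptions the filter is derived under — OU weight
drift, exponential-kernel traces, Markovian membrane, exponential gain —
which is the point: benchmarks measure filtering quality, not model
mismatch. Consequently, passing tests say nothing about biological neurons
with refractoriness, adaptation, conductance synapses, leaky-integrator
membranes (`u^LIF`), Dale's-law weight signs, or non-exponential gains; none
of these are simulated.

## Known limitations

* The filter's covariance cost is `O(d²)` per step (Full variant); the
  Block variant is the practical choice at large `d`.
* Off-diagonal negativity is guaranteed only for two synapses (see above).
* The particle oracle is restricted to `d ≤ 3` and itself carries
  Monte-Carlo error; it bounds, not certifies, the filter's accuracy.
* The heterosynaptic slope magnitude depends on protocol intensity (number
  of PC pairs) and on the assumed-density approximation itself; only its
  sign and the logic table are parameter-robust predictions.
* Euler integration requires `dt` well below `τ_m` and, during strong
  variance contraction, small enough that variances stay positive; the
  code raises rather than silently clipping.
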