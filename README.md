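# synfilter

**Bayesian synaptic plasticity as filtering.** A spiking neuron's synaptic
weights are modelled as hidden Ornstein–Uhlenbeck processes observed only
through input and output spike trains; learning is then a filtering problem:
track the posterior distribution over the weights as spikes arrive. This
package implements the *Synaptic Filter* — a continuous-time Gaussian
assumed-density filter over the weights — together with the generative
(tutor) model, a gradient-rule baseline, a particle-filter oracle, and the
simulated plasticity experiments that make the model's biological
predictions concrete: spike-timing dependent plasticity (STDP) of the weight
mean *and* variance, and heterosynaptic plasticity through explaining-away.

It is written for computational neuroscientists who want to run or extend
these experiments, and for anyone who needs an online Bayesian learner for
point-process (spiking) observations with drifting parameters.

## Model

Hidden weights, traces, membrane and spiking:

    dw_t = τ_ou⁻¹(μ_ou − w_t) dt + √(2σ_ou² τ_ou⁻¹) dV_t      (OU prior)
    x^ε  = x * ε,  ε(t) = e^(−t/τ_m) Θ(t)                      (presynaptic trace)
    u_t  = w_tᵀ x^ε_t,   y_t ~ PoissonProcess(g₀ e^(β u_t))    (observation)

The Synaptic Filter maintains `N(μ_t, Σ_t)` with

    dμ = β Σ x^ε (dY − γ dt) + τ_ou⁻¹(μ_ou − μ) dt
    dΣ = [ −β²γ (Σ x^ε)(Σ x^ε)ᵀ + relax·(Σ_ou − Σ) ] dt
    γ  = g₀ exp(β μᵀx^ε + ½ β² x^εᵀ Σ x^ε)

— a three-factor learning rule whose "learning rate" is the posterior
covariance, with an observation-*independent* covariance update (a Kalman
parallel). Full, Block and Diagonal covariance structures are provided, plus
the gradient point-estimate baseline `dw = ηβ x^ε β(dY − g dt)`.
See `docs/methods.md` for assumptions, parameters and numerical choices.

## Worked example

Filters follow the scikit-learn estimator protocol: `X` is the matrix of
presynaptic traces (time × synapses), `y` the binary output-spike train.

```python
import numpy as np
from synfilter import (InputSpec, NeuronParams, OUPrior, SynapticFilter,
                       GradientFilter, simulate_session, mse)

prior = OUPrior.homogeneous(4, sigma2=1.0, tau=10.0)      # 4 drifting weights
neuron = NeuronParams(g0=20.0, beta=0.3, tau_m=0.025)
session = simulate_session(prior, InputSpec(d=4, rate=40.0), neuron,
                           T=60.0, dt=1e-3, seed=0)

sf = SynapticFilter("full", prior=prior, neuron=neuron, dt=1e-3)
sf.fit(session.x_trace, session.y_spikes)
gr = GradientFilter(eta=0.5, neuron=neuron, dt=1e-3)
gr.fit(session.x_trace, session.y_spikes)

burn = 10_000
print(f"filter   MSE: {mse(session.w, sf.mu_trajectory_, burn):.3f}")
print(f"gradient MSE: {mse(session.w, gr.w_trajectory_, burn):.3f}")
print(f"posterior mean (last bin): {np.round(sf.mu_, 3)}")
print(f"posterior sd   (last bin): {np.round(np.sqrt(np.diag(sf.cov_)), 3)}")
print(f"hidden weights (last bin): {np.round(session.w[-1], 3)}")
```

Output:

```
filter   MSE: 0.290
gradient MSE: 0.378
posterior mean (last bin): [ 0.511 -0.804 -0.402  1.406]
posterior sd   (last bin): [0.529 0.527 0.499 0.482]
hidden weights (last bin): [ 0.526 -0.821 -0.404  1.267]
```

The MSE is the time-averaged per-synapse squared tracking error, normalised
so that "no learning" scores 1: the filter tracks the drifting weights with
about 29 % of the prior uncertainty remaining and beats the gradient rule at
a well-chosen fixed learning rate (0.378). The final posterior mean sits
within one posterior standard deviation of the hidden weights.

Experiment drivers live in `synfilter.protocols` (`run_mse_benchmark`,
`sweep_learning_rate`, `run_stdp`, `run_hetero`, `validate_adf`) and behind
the CLI:

```bash
synfilter stdp --variant full --outdir results/
synfilter hetero --preconditioned --outdir results/
synfilter benchmark-mse --param beta --grid 0,0.05,0.1 --rules full,diagonal
```

Every run writes a tidy CSV plus a JSON sidecar holding the full
configuration, its hash and the seed, and is bit-reproducible from that
sidecar.

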