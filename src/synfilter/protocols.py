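"""Experiment drivers: tracking benchmarks and plasticity protocols.

Three families of simulated experiments:

* **MSE tracking benchmark** — a tutor session is generated and every learner
  consumes the identical (trace, output-spike) stream; performance is the
  normalised mean-square error ``d^-1 <(w_t - mu_t)^T (w_t - mu_t)>_t``
  between hidden and estimated weights, averaged after a burn-in.  Time is
  counted in *epochs* (multiples of the OU timescale tau_ou).
* **STDP protocol** — a single scripted pre/post spike pair per timing delay,
  applied to an equilibrated filter; the change of the posterior mean and
  variance of the stimulated synapse is recorded as a function of the delay.
  A fast bias coordinate (excitability) generates the timing-dependent LTD
  lobe; without it the acausal side is flat.
* **Heterosynaptic experiment** — two synapses plus bias; an optional
  preconditioning stage (synchronous presynaptic spike pairs, no output
  spikes) induces negative weight correlations, after which the STDP pair is
  delivered to synapse 1 only and plasticity is read out at both synapses.
  The hetero-vs-homo relationship is summarised by a least-squares line.

All protocol runs are deterministic (scripted spikes, deterministic ODEs);
the benchmark is reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SynFilterError
from .filters import GaussianBelief, sf_step_, _MAX_EXPONENT
from .generative import InputSpec, NeuronParams, OUPrior, session_stream

__all__ = [
    "MSEResult",
    "ProtocolSpec",
    "STDPCurve",
    "HeteroResult",
    "mse",
    "run_mse_benchmark",
    "sweep_learning_rate",
    "run_stdp",
    "extract_ltd_timescale",
    "run_hetero",
    "fit_slope",
    "validate_adf",
]


# ---------------------------------------------------------------------------
# summary statistics


def mse(w_trajectory, mu_trajectory, burn_in: int = 0) -> float:
    """Normalised tracking error ``d^-1 <(w - mu)^T (w - mu)>_t`` after burn-in."""
    w = np.atleast_2d(np.asarray(w_trajectory, dtype=float))
    m = np.atleast_2d(np.asarray(mu_trajectory, dtype=float))
    if w.shape != m.shape:
        raise ValueError(f"misaligned trajectories: {w.shape} vs {m.shape}")
    if not 0 <= burn_in < w.shape[0]:
        raise ValueError("burn_in must be < trajectory length")
    diff = w[burn_in:] - m[burn_in:]
    return float(np.mean(diff * diff))


def fit_slope(x, y) -> tuple[float, float]:
    """Ordinary least-squares line through (x, y); returns (slope, offset)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values identical")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------------------
# result containers


@dataclass
class MSEResult:
    """Normalised tracking error per grid point and learning rule."""

    param: str
    grid: np.ndarray
    mse: dict[str, np.ndarray]
    n_epochs: int
    burn_in_epochs: int
    mse_epochs: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def stderr(self, rule: str) -> np.ndarray:
        """Standard error of the MSE per grid point from epoch-wise spread."""
        e = self.mse_epochs[rule]
        return e.std(axis=1, ddof=1) / np.sqrt(e.shape[1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rule, vals in self.mse.items():
            for g, v in zip(self.grid, vals):
                rows.append({self.param: g, "rule": rule, "mse": v})
        return pd.DataFrame(rows)


@dataclass
class ProtocolSpec:
    """Scripted spike timing for the plasticity protocols.

    ``delay_grid`` holds post-minus-pre timing differences (s); positive is
    causal (pre before post).  ``t_wait`` is the equilibration time before
    the protocol and sets the settling window after it; defaults to
    ``6 * tau_m`` when None.
    """

    delay_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-0.125, 0.125, 200)
    )
    t_wait: float | None = None
    pc_delay: float = 5e-3           # gap of the preconditioning spike pair
    n_pc_pairs: int = 1              # number of synchronous spike pairs in PC
    pre_spike_times: dict[int, list] | None = None
    post_spike_times: list | None = None

    def __post_init__(self) -> None:
        self.delay_grid = np.asarray(self.delay_grid, dtype=float)
        if not np.allclose(self.delay_grid, -self.delay_grid[::-1], atol=1e-12):
            raise ValueError("delay grid must be symmetric around 0")


@dataclass
class STDPCurve:
    """Weight-mean and weight-variance change versus spike-timing delay."""

    delays: np.ndarray
    delta_mu: np.ndarray
    delta_var: np.ndarray
    channel: str = "homo"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delay": self.delays,
                "delta_mu": self.delta_mu,
                "delta_var": self.delta_var,
                "channel": self.channel,
            }
        )


@dataclass
class HeteroResult:
    """Homo- and heterosynaptic STDP curves plus their least-squares relation."""

    homo_curve: STDPCurve
    hetero_curve: STDPCurve
    slope: float
    offset: float
    preconditioned: bool
    variant: str
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.homo_curve.to_frame(), self.hetero_curve.to_frame()],
            ignore_index=True,
        )


# ---------------------------------------------------------------------------
# tracking benchmark (streaming: tutor and learners advance in one loop)


class _SFLearner:
    __slots__ = ("belief", "prior", "neuron", "dt")

    def __init__(self, belief, prior, neuron, dt):
        self.belief, self.prior, self.neuron, self.dt = belief, prior, neuron, dt

    def update(self, x, y):
        sf_step_(self.belief, x, y, self.dt, self.prior, self.neuron)

    @property
    def estimate(self):
        return self.belief.mu


class _GradLearner:
    __slots__ = ("w", "pref", "g0", "beta", "dt")

    def __init__(self, d, eta, neuron, dt, double_beta=True):
        self.w = np.zeros(d)
        self.pref = eta * neuron.beta * (neuron.beta if double_beta else 1.0)
        self.g0, self.beta, self.dt = neuron.g0, neuron.beta, dt

    def update(self, x, y):
        expo = self.beta * float(self.w @ x)
        if expo > _MAX_EXPONENT:
            raise SynFilterError("gradient rule diverged (rate overflow)")
        g = self.g0 * math.exp(expo)
        self.w = self.w + self.pref * x * (y - g * self.dt)

    @property
    def estimate(self):
        return self.w


def _tracking_point(
    *,
    d: int,
    rho: float,
    beta: float,
    g0: float,
    tau_m: float,
    sigma2: float,
    tau_ou: float,
    dt: float,
    n_epochs: int,
    burn_in_epochs: int,
    rules,
    block_size: int,
    eta: float,
    input_mode: str,
    tau_block: float,
    double_beta: bool,
    seed,
) -> dict[str, float]:
    """Run one tutor session and every learner on the shared stream."""
    prior = OUPrior.homogeneous(d, 0.0, sigma2, tau_ou)
    spec = InputSpec(d=d, rate=rho, mode=input_mode, block_size=block_size,
                     tau_block=tau_block)
    neuron = NeuronParams(g0=g0, beta=beta, tau_m=tau_m)
    T = (n_epochs + burn_in_epochs) * tau_ou
    n_steps = int(round(T / dt))
    burn = int(round(burn_in_epochs * tau_ou / dt))

    learners: dict[str, object] = {}
    for rule in rules:
        if rule == "gradient":
            learners[rule] = _GradLearner(d, eta, neuron, dt, double_beta)
        else:
            belief = GaussianBelief.from_prior(prior, rule, block_size)
            learners[rule] = _SFLearner(belief, prior, neuron, dt)

    epoch_len = int(round(tau_ou / dt))
    sq_epoch = {r: np.zeros(n_epochs) for r in rules}
    for k, (w, _, trace, _, y) in enumerate(
        session_stream(prior, spec, neuron, T, dt, seed)
    ):
        for r, learner in learners.items():
            learner.update(trace, y)
            if k >= burn:
                diff = w - learner.estimate
                e = min((k - burn) // epoch_len, n_epochs - 1)
                sq_epoch[r][e] += float(diff @ diff)
    # normalise by the prior equilibrium variance so that "no learning" = 1
    norm = epoch_len * d * sigma2
    per_epoch = {r: sq_epoch[r] / norm for r in rules}
    n_avg = n_steps - burn
    overall = {r: sq_epoch[r].sum() / (n_avg * d * sigma2) for r in rules}
    return overall, per_epoch


def run_mse_benchmark(
    param: str,
    grid,
    rules=("full",),
    *,
    d: int = 16,
    rho: float = 40.0,
    beta: float = 0.1,
    eta: float = 1.0,
    g0: float = 20.0,
    tau_m: float = 0.025,
    sigma2: float = 1.0,
    tau_ou: float = 20.0,
    dt: float = 1e-3,
    n_epochs: int = 16,
    burn_in_epochs: int = 8,
    block_size: int = 8,
    input_mode: str = "homogeneous",
    tau_block: float = 1.0,
    double_beta: bool = True,
    beta_ref_d: int = 16,
    seed: int = 0,
) -> MSEResult:
    """Sweep one parameter and report the normalised MSE per learning rule.

    ``param`` is one of ``beta``, ``rho``, ``d`` or ``eta``.  In a dimension
    sweep ``beta`` is interpreted as the value at ``beta_ref_d`` inputs and
    scaled proportional to ``d^(-1/2)`` so the output-rate statistics stay
    comparable across dimensions.  At every grid point all rules consume the
    identical session stream (matched seeds); a rule that diverges or whose
    variance collapses is recorded as NaN with a diagnostic.
    """
    if param not in ("beta", "rho", "d", "eta"):
        raise ValueError(f"unknown sweep parameter {param!r}")
    grid = np.asarray(grid, dtype=float)
    base = dict(
        d=d, rho=rho, beta=beta, g0=g0, tau_m=tau_m, sigma2=sigma2,
        tau_ou=tau_ou, dt=dt, n_epochs=n_epochs,
        burn_in_epochs=burn_in_epochs, rules=tuple(rules),
        block_size=block_size, eta=eta, input_mode=input_mode,
        tau_block=tau_block, double_beta=double_beta,
    )
    out = {r: np.full(grid.size, np.nan) for r in rules}
    out_epochs = {r: np.full((grid.size, n_epochs), np.nan) for r in rules}
    diagnostics: list[str] = []
    for i, g in enumerate(grid):
        kw = dict(base)
        if param == "d":
            kw["d"] = int(round(g))
            kw["beta"] = beta * np.sqrt(beta_ref_d / g)
        else:
            kw[param] = float(g)
        # matched stream per grid point, stable across rule sets
        kw["seed"] = np.random.SeedSequence([int(seed), i])
        try:
            point, per_epoch = _tracking_point(**kw)
        except SynFilterError as exc:
            diagnostics.append(f"{param}={g:g}: {exc}")
            continue
        for r in rules:
            out[r][i] = point[r]
            out_epochs[r][i] = per_epoch[r]
    return MSEResult(
        param=param, grid=grid, mse=out, n_epochs=n_epochs,
        burn_in_epochs=burn_in_epochs, mse_epochs=out_epochs,
        diagnostics=diagnostics,
        meta={k: v for k, v in base.items() if k != "rules"} | {"seed": seed},
    )


def sweep_learning_rate(eta_grid, **kwargs) -> MSEResult:
    """Gradient-rule MSE over a learning-rate grid plus the matched filter.

    Every eta point and the Full Synaptic Filter reference consume the same
    session stream.  The result carries rules ``gradient`` (per eta) and
    ``full`` (constant reference row).
    """
    eta_grid = np.asarray(eta_grid, dtype=float)
    if eta_grid.size < 5 or eta_grid.max() / eta_grid.min() < 100:
        raise ValueError("eta grid must have >= 5 points spanning >= 2 decades")
    seed = kwargs.pop("seed", 0)
    res = run_mse_benchmark(
        "eta", eta_grid, rules=("gradient",), seed=seed, **kwargs
    )
    # reference filter on the identical stream (same per-point child seed)
    ref = run_mse_benchmark(
        "eta", eta_grid[:1], rules=("full",), seed=seed, **kwargs
    )
    res.mse["full"] = np.full(eta_grid.size, ref.mse["full"][0])
    res.mse_epochs["full"] = np.tile(ref.mse_epochs["full"][0],
                                     (eta_grid.size, 1))
    res.meta["full_reference"] = float(ref.mse["full"][0])
    return res


# ---------------------------------------------------------------------------
# plasticity protocols (deterministic, scripted spikes)


def _protocol_prior(
    variant: str,
    n_synapses: int,
    *,
    tau_ou: float,
    tau_ou_bias: float,
    sigma2_w: float,
    sigma2_bias: float,
    mu_bias: float,
) -> tuple[OUPrior, bool]:
    """Prior for the protocol experiments; returns (prior, has_bias)."""
    if variant == "single":
        return OUPrior.homogeneous(n_synapses, 0.0, sigma2_w, tau_ou), False
    if variant in ("diagonal", "full"):
        prior = OUPrior.with_bias(
            n_synapses, mu_bias=mu_bias, sigma2_bias=sigma2_bias,
            tau_bias=tau_ou_bias, mu_w=0.0, sigma2_w=sigma2_w, tau_w=tau_ou,
        )
        return prior, True
    raise ValueError(f"unknown model variant {variant!r}")


def _relax(belief, prior, neuron, dt, duration, has_bias) -> None:
    """Evolve the belief with no input/output spikes (bias trace pinned to 1)."""
    x = np.zeros(belief.d)
    if has_bias:
        x[0] = 1.0
    for _ in range(int(round(duration / dt))):
        sf_step_(belief, x, 0, dt, prior, neuron)


def _pair_response(
    belief: GaussianBelief,
    delay: float,
    *,
    prior: OUPrior,
    neuron: NeuronParams,
    dt: float,
    t_wait: float,
    has_bias: bool,
    stim_channels: tuple[int, ...],
    readout_channels: tuple[int, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Deliver one pre/post pair at the given delay; return (dmu, dvar).

    delay = t_post - t_pre; the first spike lands at t=0 and the run lasts
    |delay| + 2 t_wait so the settle time after the last spike is identical
    for every delay.  ``belief`` is consumed (mutated).
    """
    t_pre = max(0.0, -delay)
    t_post = max(0.0, delay)
    pre_bin = int(round(t_pre / dt))
    post_bin = int(round(t_post / dt))
    n_steps = int(round((abs(delay) + 2.0 * t_wait) / dt))
    readout = list(readout_channels)
    mu_before = belief.mu[readout].copy()
    var_before = belief.diagonal()[readout]

    x = np.zeros(belief.d)
    if has_bias:
        x[0] = 1.0
    decay = np.exp(-dt / neuron.tau_m)
    for k in range(n_steps):
        x = x * decay
        if has_bias:
            x[0] = 1.0
        if k == pre_bin:
            for ch in stim_channels:
                x[ch] += 1.0
        spike = 1 if k == post_bin else 0
        sf_step_(belief, x, spike, dt, prior, neuron)
    dmu = belief.mu[readout] - mu_before
    dvar = belief.diagonal()[readout] - var_before
    return dmu, dvar


def run_stdp(
    model_variant: str = "full",
    spec: ProtocolSpec | None = None,
    *,
    g0: float = 1.0,
    beta: float = 1.0,
    tau_m: float = 0.025,
    tau_ou: float = 1e4,
    tau_ou_bias: float = 0.025,
    sigma2_w: float = 1.0,
    sigma2_bias: float = 2.0,
    mu_bias: float = 1.0,
    dt: float = 1e-4,
) -> STDPCurve:
    """Simulated STDP experiment: one pre/post spike pair per delay.

    ``model_variant``: ``single`` (one synapse, no bias), ``diagonal`` or
    ``full`` (bias + one synapse, with or without bias-weight covariance).
    Each delay restarts from the same equilibrated belief (mean and variance
    of the bias at their fixed point after ``t_wait = 6 tau_m`` of silence).
    Initial condition: all means 1, identity covariance.
    """
    spec = spec or ProtocolSpec()
    t_wait = spec.t_wait if spec.t_wait is not None else 6.0 * tau_m
    prior, has_bias = _protocol_prior(
        model_variant, 1, tau_ou=tau_ou, tau_ou_bias=tau_ou_bias,
        sigma2_w=sigma2_w, sigma2_bias=sigma2_bias, mu_bias=mu_bias,
    )
    neuron = NeuronParams(g0=g0, beta=beta, tau_m=tau_m)
    d = prior.d
    cov_variant = "diagonal" if model_variant == "diagonal" else "full"
    base = GaussianBelief.from_prior(
        prior, cov_variant, mu0=np.ones(d), sigma2_0=np.ones(d)
    )
    _relax(base, prior, neuron, dt, t_wait, has_bias)

    syn = 1 if has_bias else 0
    delays = spec.delay_grid
    dmu = np.empty(delays.size)
    dvar = np.empty(delays.size)
    for i, delay in enumerate(delays):
        belief = base.copy()
        m, v = _pair_response(
            belief, float(delay), prior=prior, neuron=neuron, dt=dt,
            t_wait=t_wait, has_bias=has_bias,
            stim_channels=(syn,), readout_channels=(syn,),
        )
        dmu[i], dvar[i] = m[0], v[0]
    return STDPCurve(
        delays=delays.copy(), delta_mu=dmu, delta_var=dvar, channel="homo",
        meta={
            "model_variant": model_variant, "g0": g0, "beta": beta,
            "tau_m": tau_m, "tau_ou": tau_ou, "tau_ou_bias": tau_ou_bias,
            "sigma2_bias": sigma2_bias, "dt": dt, "t_wait": t_wait,
        },
    )


def extract_ltd_timescale(curve: STDPCurve) -> float:
    """Empirical LTD timescale: post-pre delay of 1/e decay of the LTD lobe.

    The acausal depression consists of a timing-independent component (the
    far-acausal level, which plays the role of the zero reference) plus a
    timing-dependent lobe that is deepest just before coincidence.  The
    timescale is the |delay| at which the baseline-subtracted depression has
    decayed to 1/e of its amplitude at zero-minus, linearly interpolated on
    the delay grid (the amplitude itself is extrapolated to the 0- limit).
    """
    neg = curve.delays < 0
    if not np.any(neg):
        raise ValueError("curve has no acausal (post-before-pre) delays")
    # order from 0- towards -inf
    order = np.argsort(-curve.delays[neg])
    d_neg = curve.delays[neg][order]
    m_neg = curve.delta_mu[neg][order]
    # far-acausal baseline from the outermost 10% of the grid
    n_tail = max(1, d_neg.size // 10)
    rel = m_neg - m_neg[-n_tail:].mean()
    if d_neg.size >= 2 and rel[1] < 0:
        amp = rel[0] - d_neg[0] * (rel[1] - rel[0]) / (d_neg[1] - d_neg[0])
    else:
        amp = rel[0]
    if amp >= 0:
        raise ValueError(
            "no depression lobe at zero-minus delay (bias-free model?)"
        )
    target = amp / np.e
    above = rel >= target   # magnitude decayed below amp/e
    if not np.any(above):
        raise ValueError("LTD lobe does not decay to 1/e within the delay grid")
    j = int(np.argmax(above))
    if j == 0:
        return float(-d_neg[0])
    # linear interpolation between grid points j-1 (below target) and j
    f = (target - rel[j - 1]) / (rel[j] - rel[j - 1])
    return float(-(d_neg[j - 1] + f * (d_neg[j] - d_neg[j - 1])))


def run_hetero(
    preconditioned: bool = True,
    variant: str = "full",
    spec: ProtocolSpec | None = None,
    *,
    g0: float = 1.0,
    beta: float = 1.0,
    tau_m: float = 0.025,
    tau_ou: float = 1e4,
    tau_ou_bias: float = 0.025,
    sigma2_w: float = 1.0,
    sigma2_bias: float = 1.0,
    mu_bias: float = 1.0,
    dt: float = 1e-5,
) -> HeteroResult:
    """Preconditioning + STDP on one of two synapses; read out both.

    3-dimensional filter (bias + two synapses).  Preconditioning delivers a
    presynaptic spike pair (``spec.pc_delay`` apart) synchronously to both
    synapses with no output spikes, which leaves the synapse-synapse
    covariance negative; the subsequent STDP pair on synapse 1 then moves
    synapse 2 through that covariance (explaining-away).  The hetero-vs-homo
    weight changes across the delay grid are fitted with a least-squares
    line (slope, offset).
    """
    if variant not in ("full", "diagonal"):
        raise ValueError(f"variant must be 'full' or 'diagonal', got {variant!r}")
    spec = spec or ProtocolSpec()
    t_wait = spec.t_wait if spec.t_wait is not None else 6.0 * tau_m
    prior, has_bias = _protocol_prior(
        variant, 2, tau_ou=tau_ou, tau_ou_bias=tau_ou_bias,
        sigma2_w=sigma2_w, sigma2_bias=sigma2_bias, mu_bias=mu_bias,
    )
    neuron = NeuronParams(g0=g0, beta=beta, tau_m=tau_m)
    d = prior.d
    belief = GaussianBelief.from_prior(
        prior, variant, mu0=np.ones(d), sigma2_0=np.ones(d)
    )
    _relax(belief, prior, neuron, dt, t_wait, has_bias)

    if preconditioned:
        # synchronous presynaptic spike pair(s) on both synapses, no output
        x = np.zeros(d)
        x[0] = 1.0
        decay = np.exp(-dt / tau_m)
        n_pc_spikes = 2 * spec.n_pc_pairs
        pc_bins = {
            int(round(i * spec.pc_delay / dt)) for i in range(n_pc_spikes)
        }
        n_pc = int(round(((n_pc_spikes - 1) * spec.pc_delay + t_wait) / dt))
        for k in range(n_pc):
            x = x * decay
            x[0] = 1.0
            if k in pc_bins:
                x[1] += 1.0
                x[2] += 1.0
            sf_step_(belief, x, 0, dt, prior, neuron)

    delays = spec.delay_grid
    dmu = np.empty((delays.size, 2))
    dvar = np.empty((delays.size, 2))
    for i, delay in enumerate(delays):
        b = belief.copy()
        m, v = _pair_response(
            b, float(delay), prior=prior, neuron=neuron, dt=dt,
            t_wait=t_wait, has_bias=has_bias,
            stim_channels=(1,), readout_channels=(1, 2),
        )
        dmu[i], dvar[i] = m, v
    meta = {
        "variant": variant, "preconditioned": preconditioned, "g0": g0,
        "beta": beta, "tau_m": tau_m, "tau_ou": tau_ou,
        "tau_ou_bias": tau_ou_bias, "sigma2_bias": sigma2_bias, "dt": dt,
        "t_wait": t_wait, "pc_delay": spec.pc_delay,
    }
    homo = STDPCurve(delays.copy(), dmu[:, 0], dvar[:, 0], "homo", meta)
    hetero = STDPCurve(delays.copy(), dmu[:, 1], dvar[:, 1], "hetero", meta)
    slope, offset = fit_slope(homo.delta_mu, hetero.delta_mu)
    return HeteroResult(
        homo_curve=homo, hetero_curve=hetero, slope=slope, offset=offset,
        preconditioned=preconditioned, variant=variant, meta=meta,
    )


# ---------------------------------------------------------------------------
# filter validation against the particle oracle


def validate_adf(
    *,
    d: int = 1,
    T: float = 5.0,
    dt: float = 1e-3,
    rho: float = 20.0,
    g0: float = 20.0,
    beta: float = 0.5,
    tau_ou: float = 2.0,
    n_particles: int = 10_000,
    seed: int = 0,
) -> dict:
    """Run the Gaussian filter and the particle oracle on one session.

    Returns the moment-divergence report of
    :func:`synfilter.particle.compare_moments` plus the particle filter's
    self-consistency divergence (two independent ensembles on the same
    session), which bounds the Monte-Carlo error of the oracle itself.
    """
    from .generative import simulate_session
    from .particle import ParticleFilterOracle, compare_moments
    from .filters import SynapticFilter

    prior = OUPrior.homogeneous(d, 0.0, 1.0, tau_ou)
    spec = InputSpec(d=d, rate=rho)
    neuron = NeuronParams(g0=g0, beta=beta, tau_m=0.025)
    session = simulate_session(prior, spec, neuron, T, dt, seed=seed)

    sf = SynapticFilter("full", prior=prior, neuron=neuron, dt=dt)
    sf.fit(session.x_trace, session.y_spikes)
    pf_a = ParticleFilterOracle(n_particles, prior, neuron, dt, random_state=seed + 1)
    pf_a.fit(session.x_trace, session.y_spikes)
    pf_b = ParticleFilterOracle(n_particles, prior, neuron, dt, random_state=seed + 2)
    pf_b.fit(session.x_trace, session.y_spikes)

    report = compare_moments(
        pf_a.mean_trajectory_, pf_a.var_trajectory_,
        sf.mu_trajectory_, sf.var_trajectory_,
    )
    self_report = compare_moments(
        pf_a.mean_trajectory_, pf_a.var_trajectory_,
        pf_b.mean_trajectory_, pf_b.var_trajectory_,
    )
    report["pf_self_max_mean_divergence"] = self_report["max_mean_divergence"]
    report["pf_self_max_var_divergence"] = self_report["max_var_divergence"]
    report["t"] = np.arange(session.n_steps) * dt
    report["config"] = {
        "d": d, "T": T, "dt": dt, "rho": rho, "g0": g0, "beta": beta,
        "tau_ou": tau_ou, "n_particles": n_particles, "seed": seed,
    }
    return report
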