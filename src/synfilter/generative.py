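"""Generative (tutor) model for spike-based learning.

A single stochastic neuron receives ``d`` input spike trains.  Its synaptic
weights are *hidden* and drift as independent Ornstein-Uhlenbeck (OU)
processes; the membrane potential is the inner product of the weights with the
presynaptic traces (input spikes low-pass filtered by a causal exponential
kernel of timescale ``tau_m``); output spikes are drawn from an inhomogeneous
Poisson process with exponential gain ``g(u) = g0 * exp(beta * u)``.

A learner (see :mod:`synfilter.filters`) only sees the input and output spike
trains and has to track the hidden weights.  Everything here is synthetic and
fully reproducible from a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DivergenceError

__all__ = [
    "OUPrior",
    "InputSpec",
    "NeuronParams",
    "TutorSession",
    "ou_step",
    "generate_inputs",
    "update_trace",
    "gain",
    "simulate_session",
    "session_stream",
]

# exp() overflows double precision just above 709
_MAX_EXPONENT = 700.0


@dataclass
class OUPrior:
    """Per-coordinate OU prior over the hidden weights.

    Each weight w_i reverts to ``mu[i]`` with timescale ``tau[i]`` (seconds)
    and has equilibrium variance ``sigma2[i]``.  Coordinate 0 may be a bias
    (constant-unit input) with its own, typically much faster, timescale.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if not (self.mu.shape == self.sigma2.shape == self.tau.shape):
            raise ValueError(
                "mu, sigma2 and tau must share one length, got "
                f"{self.mu.shape}, {self.sigma2.shape}, {self.tau.shape}"
            )
        if np.any(self.sigma2 <= 0):
            raise ValueError("all equilibrium variances sigma2 must be > 0")
        if np.any(self.tau <= 0):
            raise ValueError("all relaxation timescales tau must be > 0")

    @property
    def d(self) -> int:
        return self.mu.size

    @classmethod
    def homogeneous(
        cls, d: int, mu: float = 0.0, sigma2: float = 1.0, tau: float = 20.0
    ) -> "OUPrior":
        """Identical OU parameters for every coordinate."""
        return cls(np.full(d, mu), np.full(d, sigma2), np.full(d, tau))

    @classmethod
    def with_bias(
        cls,
        n_synapses: int,
        *,
        mu_bias: float = 1.0,
        sigma2_bias: float = 2.0,
        tau_bias: float = 0.025,
        mu_w: float = 0.0,
        sigma2_w: float = 1.0,
        tau_w: float = 1e4,
    ) -> "OUPrior":
        """Bias coordinate (index 0) plus ``n_synapses`` slow weights.

        The bias models neuronal excitability: it has unit input, reverts to
        ``mu_bias`` on the fast timescale ``tau_bias`` (of the order of the
        membrane timescale), while ordinary weights drift far more slowly.
        """
        mu = np.r_[mu_bias, np.full(n_synapses, mu_w)]
        sigma2 = np.r_[sigma2_bias, np.full(n_synapses, sigma2_w)]
        tau = np.r_[tau_bias, np.full(n_synapses, tau_w)]
        return cls(mu, sigma2, tau)


@dataclass
class InputSpec:
    """How the input spike trains are generated.

    modes
    -----
    homogeneous
        every (non-bias) channel fires independently at ``rate`` Hz.
    block_sparse
        channels are split into blocks of ``block_size``; exactly one block
        is active at a time (for ``tau_block`` seconds) and only its channels
        fire at ``rate`` Hz.  Emulates correlated inputs on one dendritic
        branch.
    scripted
        exact user-provided spike times per channel (used by the plasticity
        protocols).
    """

    d: int
    rate: float = 40.0
    mode: str = "homogeneous"
    block_size: int = 8
    tau_block: float = 1.0
    has_bias: bool = False
    shuffle_blocks: bool = False
    scripted_times: dict[int, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "block_sparse", "scripted"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.mode != "scripted" and self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.mode == "block_sparse":
            n = self.n_driven
            if n % self.block_size != 0:
                raise ValueError(
                    f"{n} driven channels not divisible by block_size="
                    f"{self.block_size}"
                )

    @property
    def n_driven(self) -> int:
        """Number of channels that can emit spikes (bias never spikes)."""
        return self.d - 1 if self.has_bias else self.d


@dataclass
class NeuronParams:
    """Spike-response neuron with exponential gain.

    ``g0``: baseline rate (Hz); ``beta``: determinism, i.e. how strongly the
    membrane modulates the rate (beta=0 makes output spikes uninformative);
    ``tau_m``: membrane / presynaptic-trace time constant (s).
    """

    g0: float = 20.0
    beta: float = 0.1
    tau_m: float = 0.025

    def __post_init__(self) -> None:
        if self.g0 <= 0:
            raise ValueError("g0 must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")


@dataclass
class TutorSession:
    """A fully materialised simulation of the tutor network."""

    dt: float
    T: float
    w: np.ndarray          # (n_steps, d) hidden weights
    x_spikes: np.ndarray   # (n_steps, d) binary input raster
    x_trace: np.ndarray    # (n_steps, d) presynaptic traces
    u: np.ndarray          # (n_steps,) membrane potential
    y_spikes: np.ndarray   # (n_steps,) binary output spikes
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.w.shape[0]

    @property
    def d(self) -> int:
        return self.w.shape[1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per time step, channel-indexed columns."""
        data: dict[str, np.ndarray] = {"t": self.t}
        for i in range(self.d):
            data[f"w_{i}"] = self.w[:, i]
            data[f"x_spike_{i}"] = self.x_spikes[:, i]
            data[f"x_trace_{i}"] = self.x_trace[:, i]
        data["u"] = self.u
        data["y_spike"] = self.y_spikes
        return pd.DataFrame(data)

    def save(self, path: str | Path) -> None:
        """Write ``<path>.csv`` plus a ``<path>.json`` config sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path.with_suffix(".csv"), index=False)
        sidecar = {"seed": self.seed, "dt": self.dt, "T": self.T, **self.config}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# elementary operations


def ou_step(
    w: np.ndarray, prior: OUPrior, dt: float, noise: np.ndarray
) -> np.ndarray:
    """One Euler-Maruyama step of the OU weight diffusion.

    ``w + dt/tau * (mu - w) + sqrt(2 sigma2 dt / tau) * noise`` with
    per-coordinate ``tau`` and ``sigma2``; ``noise`` is standard normal.
    """
    w = np.asarray(w, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if w.shape != (prior.d,) or noise.shape != (prior.d,):
        raise ValueError(
            f"w {w.shape} and noise {noise.shape} must both have length {prior.d}"
        )
    drift = (prior.mu - w) * (dt / prior.tau)
    diffusion = np.sqrt(2.0 * prior.sigma2 * dt / prior.tau) * noise
    return w + drift + diffusion


def generate_inputs(
    spec: InputSpec,
    T: float,
    dt: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Generate a binary input-spike raster of shape ``(n_steps, d)``.

    The bias channel (index 0 when ``spec.has_bias``) never spikes; its
    *trace* is pinned to one by :func:`update_trace`.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_steps = int(round(T / dt))
    raster = np.zeros((n_steps, spec.d), dtype=np.uint8)
    driven = np.arange(1, spec.d) if spec.has_bias else np.arange(spec.d)

    if spec.mode == "scripted":
        if spec.scripted_times is None:
            raise ValueError("scripted mode requires scripted_times")
        for ch, times in spec.scripted_times.items():
            times = np.asarray(list(times), dtype=float)
            if times.size and (times.min() < 0 or times.max() > T):
                raise ValueError(f"scripted spike time outside [0, {T}] on channel {ch}")
            if spec.has_bias and ch == 0:
                raise ValueError("the bias channel cannot receive scripted spikes")
            bins = np.minimum((times / dt).astype(int), n_steps - 1)
            raster[bins, ch] = 1
        return raster

    p = spec.rate * dt
    if p > 1.0:
        warnings.warn(
            f"rate*dt = {p:.3g} > 1: spike probability clipped to 1; "
            "use a smaller dt",
            stacklevel=2,
        )
        p = 1.0

    if spec.mode == "homogeneous":
        if p > 0 and driven.size:
            raster[:, driven] = rng.random((n_steps, driven.size)) < p
        return raster

    # block_sparse: exactly one block of channels active at a time
    n_blocks = spec.n_driven // spec.block_size
    steps_per_block = max(int(round(spec.tau_block / dt)), 1)
    order = np.arange(n_blocks)
    if spec.shuffle_blocks:
        order = rng.permutation(n_blocks)
    for k in range(0, n_steps, steps_per_block):
        block = order[(k // steps_per_block) % n_blocks]
        cols = driven[block * spec.block_size : (block + 1) * spec.block_size]
        stop = min(k + steps_per_block, n_steps)
        if p > 0:
            raster[k:stop, cols] = rng.random((stop - k, cols.size)) < p
    return raster


def update_trace(
    trace: np.ndarray,
    spikes_this_bin: np.ndarray,
    tau_m: float,
    dt: float,
    has_bias: bool = False,
) -> np.ndarray:
    """Advance the presynaptic traces by one bin: decay, then add spikes.

    The trace is the spike train convolved with the causal kernel
    ``exp(-t/tau_m)``; each spike contributes a unit jump.  With ``has_bias``
    the first channel is pinned to one.
    """
    if dt >= tau_m:
        raise ValueError("dt must be < tau_m to resolve the trace kernel")
    out = np.asarray(trace, dtype=float) * np.exp(-dt / tau_m)
    out = out + spikes_this_bin
    if has_bias:
        out[0] = 1.0
    return out


def gain(u: float | np.ndarray, params: NeuronParams) -> float | np.ndarray:
    """Instantaneous firing rate ``g0 * exp(beta * u)`` in Hz."""
    expo = params.beta * np.asarray(u, dtype=float)
    if np.any(expo > _MAX_EXPONENT):
        raise DivergenceError(
            f"gain exponent beta*u = {np.max(expo):.3g} overflows: "
            "runaway membrane potential"
        )
    return params.g0 * np.exp(expo)


# ---------------------------------------------------------------------------
# full sessions


def session_stream(
    prior: OUPrior,
    spec: InputSpec,
    params: NeuronParams,
    T: float,
    dt: float,
    seed: int | np.random.SeedSequence | None = None,
    w0: np.ndarray | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray, float, int]]:
    """Yield ``(w, x_spikes, x_trace, u, y)`` per time bin without storing.

    Per-bin order of operations (fixed for reproducibility): advance the
    hidden weights, draw input spikes, decay-then-add the traces, compute the
    membrane potential, draw the output spike as Bernoulli(min(g(u) dt, 1)).
    The first bin uses the initial weights (stationary prior draw by default)
    without an OU step.
    """
    if prior.d != spec.d:
        raise ValueError(f"prior dimension {prior.d} != input dimension {spec.d}")
    if dt >= params.tau_m:
        raise ValueError("dt must be < tau_m")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_steps = int(round(T / dt))
    raster = generate_inputs(spec, T, dt, rng)

    if w0 is None:
        w = prior.mu + np.sqrt(prior.sigma2) * rng.standard_normal(prior.d)
    else:
        w = np.asarray(w0, dtype=float).copy()
    trace = np.zeros(prior.d)
    if spec.has_bias:
        trace[0] = 1.0
    decay = np.exp(-dt / params.tau_m)
    n_clipped = 0
    for k in range(n_steps):
        if k > 0:
            w = ou_step(w, prior, dt, rng.standard_normal(prior.d))
        spikes = raster[k]
        trace = trace * decay + spikes
        if spec.has_bias:
            trace[0] = 1.0
        u = float(w @ trace)
        p_spike = gain(u, params) * dt
        if p_spike > 1.0:
            n_clipped += 1
            p_spike = 1.0
        y = int(rng.random() < p_spike)
        yield w, spikes, trace, u, y
    if n_clipped > 0.001 * n_steps:
        warnings.warn(
            f"g(u)*dt exceeded 1 in {n_clipped}/{n_steps} bins; "
            "the time step is too coarse for this firing rate",
            stacklevel=2,
        )


def simulate_session(
    prior: OUPrior,
    spec: InputSpec,
    params: NeuronParams,
    T: float,
    dt: float,
    seed: int | None = None,
    w0: np.ndarray | None = None,
) -> TutorSession:
    """Simulate and materialise a full tutor session (see ``session_stream``)."""
    n_steps = int(round(T / dt))
    d = spec.d
    w = np.empty((n_steps, d))
    x_spikes = np.empty((n_steps, d), dtype=np.uint8)
    x_trace = np.empty((n_steps, d))
    u = np.empty(n_steps)
    y = np.empty(n_steps, dtype=np.uint8)
    stream = session_stream(prior, spec, params, T, dt, seed, w0=w0)
    for k, (wk, sk, tk, uk, yk) in enumerate(stream):
        w[k] = wk
        x_spikes[k] = sk
        x_trace[k] = tk
        u[k] = uk
        y[k] = yk
    config = {
        "prior": {"mu": prior.mu.tolist(), "sigma2": prior.sigma2.tolist(),
                  "tau": prior.tau.tolist()},
        "input": {"d": spec.d, "rate": spec.rate, "mode": spec.mode,
                  "block_size": spec.block_size, "tau_block": spec.tau_block,
                  "has_bias": spec.has_bias},
        "neuron": {"g0": params.g0, "beta": params.beta, "tau_m": params.tau_m},
    }
    return TutorSession(dt=dt, T=T, w=w, x_spikes=x_spikes, x_trace=x_trace,
                        u=u, y_spikes=y, seed=seed, config=config)
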