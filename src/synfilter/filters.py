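"""The Synaptic Filter: Gaussian assumed-density filtering of synaptic weights.

The learner maintains a Gaussian belief N(mu_t, Sigma_t) over the hidden
weights of the generative model (:mod:`synfilter.generative`) and updates it
online from the presynaptic traces x^eps and the output spike train y:

    dmu    = beta * Sigma x^eps * (y dt - gamma dt)  +  (mu_ou - mu)/tau dt
    dSigma = [- beta^2 gamma (Sigma x^eps)(Sigma x^eps)^T
              + relax * (Sigma_ou - Sigma)] dt

where gamma = g0 * exp(beta mu.x + beta^2/2 x.Sigma x) is the posterior
expected firing rate, available in closed form for the exponential gain.  At
a spike bin, y dt contributes a unit jump (the spike train is a sum of Dirac
deltas).  The covariance update does not depend on the observed spikes — a
structural similarity with the Kalman filter.  ``relax`` acts entry-wise with
rate 1/tau_i + 1/tau_j, which reduces to the homogeneous 2/tau_ou and lets a
fast bias coordinate coexist with slow weights.

Three covariance structures are supported: *full* (one d x d block),
*block* (independent blocks of size b), and *diagonal* (variances only).
Cross-block covariances are identically zero by construction.

A plain stochastic-gradient point estimate of the weights (the classical
three-factor rule without the covariance modulation) is provided as the
baseline learner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DivergenceError, VarianceCollapseError
from .generative import NeuronParams, OUPrior, _MAX_EXPONENT

__all__ = [
    "GaussianBelief",
    "GradientState",
    "expected_rate",
    "sf_step",
    "gradient_step",
    "validate_belief",
    "make_partition",
    "SynapticFilter",
    "GradientFilter",
]


def make_partition(d: int, variant: str, block_size: int = 8) -> list[slice]:
    """Contiguous index blocks for the covariance structure.

    ``full`` -> one block; ``diagonal`` -> d singletons; ``block`` -> blocks
    of ``block_size`` (the first block absorbs the remainder when d is not a
    multiple, which also keeps a bias at index 0 inside the first block).
    """
    if variant == "full":
        return [slice(0, d)]
    if variant == "diagonal":
        return [slice(i, i + 1) for i in range(d)]
    if variant == "block":
        if block_size < 1:
            raise ValueError("block_size must be >= 1")
        rem = d % block_size
        edges = [0, rem + block_size] if rem else [0, block_size]
        while edges[-1] < d:
            edges.append(edges[-1] + block_size)
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
    raise ValueError(f"unknown variant {variant!r}")


class GaussianBelief:
    """Mean vector plus block-structured covariance.

    For the ``diagonal`` structure only the variances are stored (fast path);
    otherwise one symmetric matrix per block.
    """

    __slots__ = ("mu", "partition", "cov_blocks", "var", "_relax_cache")

    def __init__(
        self,
        mu: np.ndarray,
        partition: Sequence[slice],
        cov_blocks: Sequence[np.ndarray] | None = None,
        var: np.ndarray | None = None,
    ) -> None:
        self.mu = np.asarray(mu, dtype=float).copy()
        self.partition = list(partition)
        if (cov_blocks is None) == (var is None):
            raise ValueError("provide exactly one of cov_blocks or var")
        self.cov_blocks = (
            [np.asarray(c, dtype=float).copy() for c in cov_blocks]
            if cov_blocks is not None
            else None
        )
        self.var = np.asarray(var, dtype=float).copy() if var is not None else None
        self._relax_cache = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_prior(
        cls,
        prior: OUPrior,
        variant: str = "full",
        block_size: int = 8,
        mu0: np.ndarray | None = None,
        sigma2_0: np.ndarray | None = None,
    ) -> "GaussianBelief":
        """Diagonal initialisation at the prior (or at given mu0/sigma2_0)."""
        d = prior.d
        mu = prior.mu if mu0 is None else np.asarray(mu0, dtype=float)
        v = prior.sigma2 if sigma2_0 is None else np.asarray(sigma2_0, dtype=float)
        part = make_partition(d, variant, block_size)
        if variant == "diagonal":
            return cls(mu, part, var=v)
        blocks = [np.diag(v[s]) for s in part]
        return cls(mu, part, cov_blocks=blocks)

    # -- views ------------------------------------------------------------
    @property
    def d(self) -> int:
        return self.mu.size

    @property
    def is_diagonal(self) -> bool:
        return self.var is not None

    def cov(self) -> np.ndarray:
        """Assemble the full (block-diagonal) covariance matrix."""
        if self.is_diagonal:
            return np.diag(self.var)
        out = np.zeros((self.d, self.d))
        for s, c in zip(self.partition, self.cov_blocks):
            out[s, s] = c
        return out

    def diagonal(self) -> np.ndarray:
        if self.is_diagonal:
            return self.var.copy()
        return np.concatenate([np.diag(c) for c in self.cov_blocks])

    def copy(self) -> "GaussianBelief":
        if self.is_diagonal:
            return GaussianBelief(self.mu, self.partition, var=self.var)
        return GaussianBelief(self.mu, self.partition, cov_blocks=self.cov_blocks)


@dataclass
class GradientState:
    """Point-estimate learner state: weights and a scalar learning rate."""

    w: np.ndarray
    eta: float

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if self.eta <= 0:
            raise ValueError("eta must be > 0")


# ---------------------------------------------------------------------------
# core updates


def _quad_and_sx(belief: GaussianBelief, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Return (x^T Sigma x, Sigma x) exploiting the block structure."""
    if belief.is_diagonal:
        sx = belief.var * x
        return float(x @ sx), sx
    sx = np.empty(belief.d)
    quad = 0.0
    for s, c in zip(belief.partition, belief.cov_blocks):
        v = c @ x[s]
        sx[s] = v
        quad += float(x[s] @ v)
    return quad, sx


def expected_rate(
    belief: GaussianBelief, x_trace: np.ndarray, neuron: NeuronParams
) -> float:
    """Posterior expected firing rate gamma (Hz).

    For a Gaussian belief and exponential gain,
    ``gamma = g0 * exp(beta mu.x + 1/2 beta^2 x.Sigma x)`` — the covariance
    term raises the rate relative to the plug-in mean, as a convex gain must.
    """
    x = np.asarray(x_trace, dtype=float)
    if x.shape != (belief.d,):
        raise ValueError(f"x_trace must have length {belief.d}, got {x.shape}")
    quad, _ = _quad_and_sx(belief, x)
    expo = neuron.beta * float(belief.mu @ x) + 0.5 * neuron.beta**2 * quad
    if expo > _MAX_EXPONENT:
        raise DivergenceError(
            f"expected-rate exponent {expo:.3g} overflows: divergent belief"
        )
    return neuron.g0 * float(np.exp(expo))


def sf_step(
    belief: GaussianBelief,
    x_trace: np.ndarray,
    spike: int,
    dt: float,
    prior: OUPrior,
    neuron: NeuronParams,
    symmetrize: bool = True,
) -> GaussianBelief:
    """One Euler step of the Synaptic Filter; returns a new belief."""
    out = belief.copy()
    sf_step_(out, np.asarray(x_trace, dtype=float), int(spike), dt, prior,
             neuron, symmetrize)
    return out


def sf_step_(
    belief: GaussianBelief,
    x: np.ndarray,
    spike: int,
    dt: float,
    prior: OUPrior,
    neuron: NeuronParams,
    symmetrize: bool = True,
) -> None:
    """In-place Synaptic Filter step (hot loop; no input validation).

    The relaxation-rate matrices are cached on the belief at first use, so a
    given belief instance must always be stepped with the same prior.
    """
    beta = neuron.beta
    quad, sx = _quad_and_sx(belief, x)
    expo = beta * float(belief.mu @ x) + 0.5 * beta * beta * quad
    if expo > _MAX_EXPONENT:
        raise DivergenceError(
            f"expected-rate exponent {expo:.3g} overflows: divergent belief"
        )
    gamma = neuron.g0 * np.exp(expo)
    # mean: observation term (unit jump at spike bins) + prior relaxation
    belief.mu += beta * sx * (spike - gamma * dt) + (prior.mu - belief.mu) * (
        dt / prior.tau
    )
    # covariance: rank-one contraction (observation-independent) + relaxation
    coef = beta * beta * gamma * dt
    if belief.is_diagonal:
        belief.var += -coef * sx * sx + 2.0 * (prior.sigma2 - belief.var) * (
            dt / prior.tau
        )
        if np.any(belief.var <= 0):
            raise VarianceCollapseError(
                "posterior variance became non-positive; reduce dt"
            )
        return
    if belief._relax_cache is None:
        inv_tau = 1.0 / prior.tau
        belief._relax_cache = [
            (inv_tau[s][:, None] + inv_tau[s][None, :], np.diag(prior.sigma2[s]))
            for s in belief.partition
        ]
    for s, c, (rates, target) in zip(
        belief.partition, belief.cov_blocks, belief._relax_cache
    ):
        v = sx[s]
        c += -coef * np.outer(v, v) + rates * (target - c) * dt
        if symmetrize:
            c += c.T
            c *= 0.5
        if np.any(np.diag(c) <= 0):
            raise VarianceCollapseError(
                "posterior variance became non-positive; reduce dt"
            )


def gradient_step(
    state: GradientState,
    x_trace: np.ndarray,
    spike: int,
    dt: float,
    neuron: NeuronParams,
    double_beta: bool = True,
) -> GradientState:
    """One Euler step of the gradient point-estimate rule.

    ``dw = eta * beta * x^eps * beta * (y dt - g dt)`` with
    ``g = g0 exp(beta w.x)``.  The default keeps the second beta factor (so
    eta is comparable to a posterior variance and scales with dimension like
    the filter's beta); ``double_beta=False`` gives the bare log-likelihood
    gradient scaled by eta.
    """
    x = np.asarray(x_trace, dtype=float)
    expo = neuron.beta * float(state.w @ x)
    if expo > _MAX_EXPONENT:
        raise DivergenceError(
            f"gradient-rule rate exponent {expo:.3g} overflows"
        )
    g = neuron.g0 * np.exp(expo)
    pref = state.eta * neuron.beta * (neuron.beta if double_beta else 1.0)
    w = state.w + pref * x * (spike - g * dt)
    return GradientState(w=w, eta=state.eta)


def validate_belief(belief: GaussianBelief) -> dict[str, float]:
    """Pure diagnostics: symmetry defect, minimum variance, off-diagonal sign.

    ``max_offdiag`` should stay <= 0 when filtering non-negative inputs from a
    diagonal initialisation (explaining-away makes weight correlations
    negative).
    """
    if belief.is_diagonal:
        return {
            "max_symmetry_defect": 0.0,
            "min_diagonal": float(belief.var.min()),
            "max_offdiag": 0.0,
        }
    sym = 0.0
    min_diag = np.inf
    max_off = -np.inf
    for c in belief.cov_blocks:
        sym = max(sym, float(np.abs(c - c.T).max()))
        min_diag = min(min_diag, float(np.diag(c).min()))
        if c.shape[0] > 1:
            off = c[~np.eye(c.shape[0], dtype=bool)]
            max_off = max(max_off, float(off.max()))
    if not np.isfinite(max_off):
        max_off = 0.0
    return {
        "max_symmetry_defect": sym,
        "min_diagonal": min_diag,
        "max_offdiag": max_off,
    }


# ---------------------------------------------------------------------------
# estimators


class SynapticFilter(BaseEstimator):
    """Online Gaussian assumed-density filter over synaptic weights.

    Parameters
    ----------
    variant : {"full", "block", "diagonal"}
        Block structure of the posterior covariance.
    block_size : int
        Channels per covariance block (``block`` variant only).
    prior : OUPrior or None
        OU prior over the hidden weights; a standard homogeneous prior
        (mu=0, sigma2=1, tau=20 s) matching the input dimension is built at
        fit time when None.
    neuron : NeuronParams or None
        Gain parameters of the observation model (g0=20 Hz, beta=0.1,
        tau_m=25 ms when None).
    dt : float
        Integration step in seconds.
    mu0, sigma2_0 : array-like or None
        Initial belief; defaults to the prior equilibrium.
    symmetrize : bool
        Re-symmetrise covariance blocks every step (guards float drift).
    store_trajectory : bool
        Keep per-step mean and variance trajectories on ``fit``.

    Attributes
    ----------
    belief_ : GaussianBelief
        Current posterior after fitting.
    mu_ : ndarray of shape (d,)
        Posterior mean (alias of ``belief_.mu``).
    mu_trajectory_, var_trajectory_ : ndarray of shape (n_steps, d)
        Per-step posterior mean and marginal variances (if stored).
    n_steps_ : int
        Number of bins consumed.
    """

    def __init__(
        self,
        variant: str = "full",
        block_size: int = 8,
        prior: OUPrior | None = None,
        neuron: NeuronParams | None = None,
        dt: float = 1e-3,
        mu0=None,
        sigma2_0=None,
        symmetrize: bool = True,
        store_trajectory: bool = True,
    ) -> None:
        self.variant = variant
        self.block_size = block_size
        self.prior = prior
        self.neuron = neuron
        self.dt = dt
        self.mu0 = mu0
        self.sigma2_0 = sigma2_0
        self.symmetrize = symmetrize
        self.store_trajectory = store_trajectory

    # -- plumbing ----------------------------------------------------------
    def _init_state(self, d: int) -> None:
        self.prior_ = self.prior if self.prior is not None else OUPrior.homogeneous(d)
        self.neuron_ = self.neuron if self.neuron is not None else NeuronParams()
        if self.prior_.d != d:
            raise ValueError(f"prior dimension {self.prior_.d} != input dimension {d}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.belief_ = GaussianBelief.from_prior(
            self.prior_, self.variant, self.block_size,
            mu0=self.mu0, sigma2_0=self.sigma2_0,
        )
        self.n_steps_ = 0

    @staticmethod
    def _check_stream(X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} time bins but y has {y.shape[0]}"
            )
        return X, y

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        """Filter a whole session.

        ``X``: presynaptic traces, shape (n_steps, d); ``y``: binary output
        spike indicators, shape (n_steps,).
        """
        X, y = self._check_stream(X, y)
        self._init_state(X.shape[1])
        if self.store_trajectory:
            n = X.shape[0]
            self.mu_trajectory_ = np.empty((n, X.shape[1]))
            self.var_trajectory_ = np.empty((n, X.shape[1]))
        self._run(X, y)
        return self

    def partial_fit(self, X, y):
        """Consume one chunk of the stream, keeping the belief across calls."""
        X, y = self._check_stream(X, y)
        if not hasattr(self, "belief_"):
            self._init_state(X.shape[1])
        self._run(X, y, record=False)
        return self

    def _run(self, X, y, record: bool | None = None) -> None:
        record = self.store_trajectory if record is None else record
        belief, prior, neuron = self.belief_, self.prior_, self.neuron_
        dt, sym = self.dt, self.symmetrize
        for k in range(X.shape[0]):
            sf_step_(belief, X[k], int(y[k]), dt, prior, neuron, sym)
            if record:
                self.mu_trajectory_[self.n_steps_] = belief.mu
                self.var_trajectory_[self.n_steps_] = belief.diagonal()
            self.n_steps_ += 1

    def step(self, x_trace, spike: int) -> GaussianBelief:
        """Advance the belief by a single bin (in place); returns it."""
        if not hasattr(self, "belief_"):
            self._init_state(np.asarray(x_trace).size)
        sf_step_(self.belief_, np.asarray(x_trace, dtype=float), int(spike),
                 self.dt, self.prior_, self.neuron_, self.symmetrize)
        self.n_steps_ += 1
        return self.belief_

    @property
    def mu_(self) -> np.ndarray:
        return self.belief_.mu

    @property
    def cov_(self) -> np.ndarray:
        return self.belief_.cov()

    def trajectory_frame(self) -> "pd.DataFrame":
        """Tidy belief-trajectory export: t, mean and variance per channel.

        Requires ``store_trajectory=True`` and a prior ``fit``.
        """
        import pandas as pd

        if not hasattr(self, "mu_trajectory_"):
            raise AttributeError(
                "no stored trajectory; fit with store_trajectory=True first"
            )
        n, d = self.mu_trajectory_.shape
        data = {"t": np.arange(n) * self.dt}
        for i in range(d):
            data[f"mu_{i}"] = self.mu_trajectory_[:, i]
            data[f"var_{i}"] = self.var_trajectory_[:, i]
        return pd.DataFrame(data)

    def predict(self, X) -> np.ndarray:
        """Posterior expected firing rate (Hz) for rows of traces ``X``,
        using the current belief without updating it."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array(
            [expected_rate(self.belief_, x, self.neuron_) for x in X]
        )


class GradientFilter(BaseEstimator):
    """Gradient-rule point estimator of the weights (baseline learner).

    Same stream interface as :class:`SynapticFilter`; fitted attributes are
    ``w_`` (current estimate) and ``w_trajectory_``.
    """

    def __init__(
        self,
        eta: float = 0.08,
        neuron: NeuronParams | None = None,
        dt: float = 1e-3,
        w0=None,
        double_beta: bool = True,
        store_trajectory: bool = True,
    ) -> None:
        self.eta = eta
        self.neuron = neuron
        self.dt = dt
        self.w0 = w0
        self.double_beta = double_beta
        self.store_trajectory = store_trajectory

    def _init_state(self, d: int) -> None:
        self.neuron_ = self.neuron if self.neuron is not None else NeuronParams()
        w0 = np.zeros(d) if self.w0 is None else np.asarray(self.w0, dtype=float)
        self.state_ = GradientState(w=w0, eta=self.eta)
        self.n_steps_ = 0

    def fit(self, X, y):
        X, y = SynapticFilter._check_stream(X, y)
        self._init_state(X.shape[1])
        if self.store_trajectory:
            self.w_trajectory_ = np.empty_like(X)
        neuron, dt, db = self.neuron_, self.dt, self.double_beta
        pref = self.eta * neuron.beta * (neuron.beta if db else 1.0)
        w = self.state_.w
        for k in range(X.shape[0]):
            x = X[k]
            expo = neuron.beta * float(w @ x)
            if expo > _MAX_EXPONENT:
                raise DivergenceError("gradient-rule rate exponent overflows")
            g = neuron.g0 * np.exp(expo)
            w = w + pref * x * (y[k] - g * dt)
            if self.store_trajectory:
                self.w_trajectory_[k] = w
        self.state_ = GradientState(w=w, eta=self.eta)
        self.n_steps_ = X.shape[0]
        return self

    @property
    def w_(self) -> np.ndarray:
        return self.state_.w
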