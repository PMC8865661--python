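"""Bootstrap particle filter for the tutor model — a brute-force oracle.

Used to check that the Gaussian assumed-density filter tracks the true
filtering distribution at low dimension.  Particles are propagated through
the OU transition and re-weighted with the per-bin point-process
log-likelihood ``y*log(g dt) - g dt``; systematic resampling is triggered
when the effective sample size drops below half the ensemble.

Particle filters degenerate in high dimension; keep d <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DegenerateEnsembleError
from .generative import NeuronParams, OUPrior, _MAX_EXPONENT

__all__ = [
    "ParticleEnsemble",
    "pf_step",
    "compare_moments",
    "ParticleFilterOracle",
]


@dataclass
class ParticleEnsemble:
    """Weighted particle approximation of the filtering distribution."""

    particles: np.ndarray            # (n, d)
    log_weights: np.ndarray          # (n,)
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )

    def __post_init__(self) -> None:
        self.particles = np.atleast_2d(np.asarray(self.particles, dtype=float))
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if self.particles.shape[0] != self.log_weights.shape[0]:
            raise ValueError("particles and log_weights disagree in length")
        if self.particles.shape[0] < 100:
            raise ValueError("need at least 100 particles")

    @classmethod
    def from_prior(
        cls, prior: OUPrior, n_particles: int = 10_000,
        seed: int | np.random.Generator | None = None,
    ) -> "ParticleEnsemble":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        w = prior.mu + np.sqrt(prior.sigma2) * rng.standard_normal(
            (n_particles, prior.d)
        )
        return cls(w, np.zeros(n_particles), rng)

    @property
    def n(self) -> int:
        return self.particles.shape[0]

    def normalized_weights(self) -> np.ndarray:
        lw = self.log_weights - self.log_weights.max()
        w = np.exp(lw)
        return w / w.sum()

    def ess(self) -> float:
        w = self.normalized_weights()
        return 1.0 / float(w @ w)

    def mean(self) -> np.ndarray:
        return self.normalized_weights() @ self.particles

    def var(self) -> np.ndarray:
        w = self.normalized_weights()
        m = w @ self.particles
        return w @ (self.particles - m) ** 2

    def cov(self) -> np.ndarray:
        w = self.normalized_weights()
        m = w @ self.particles
        c = self.particles - m
        return (c * w[:, None]).T @ c


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def pf_step(
    ensemble: ParticleEnsemble,
    x_trace: np.ndarray,
    spike: int,
    dt: float,
    prior: OUPrior,
    neuron: NeuronParams,
) -> ParticleEnsemble:
    """Propagate, reweight and (conditionally) resample; in place."""
    p, rng = ensemble.particles, ensemble.rng
    noise = rng.standard_normal(p.shape)
    p += (prior.mu - p) * (dt / prior.tau) + np.sqrt(
        2.0 * prior.sigma2 * dt / prior.tau
    ) * noise
    expo = neuron.beta * (p @ np.asarray(x_trace, dtype=float))
    np.clip(expo, None, _MAX_EXPONENT, out=expo)
    g = neuron.g0 * np.exp(expo)
    if spike:
        ensemble.log_weights += np.log(g * dt)
    ensemble.log_weights -= g * dt
    if not np.any(np.isfinite(ensemble.log_weights)):
        raise DegenerateEnsembleError("all particle log-weights are -inf")
    if ensemble.ess() < ensemble.n / 2:
        idx = _systematic_resample(ensemble.normalized_weights(), rng)
        ensemble.particles = p[idx].copy()
        ensemble.log_weights = np.zeros(ensemble.n)
    return ensemble


def compare_moments(
    pf_mean: np.ndarray,
    pf_var: np.ndarray,
    adf_mean: np.ndarray,
    adf_var: np.ndarray,
) -> dict:
    """Time-resolved and maximal divergences of first/second central moments."""
    pf_mean, adf_mean = np.asarray(pf_mean), np.asarray(adf_mean)
    pf_var, adf_var = np.asarray(pf_var), np.asarray(adf_var)
    if pf_mean.shape != adf_mean.shape or pf_var.shape != adf_var.shape:
        raise ValueError("trajectories must share one time grid and dimension")
    dmean = np.abs(pf_mean - adf_mean)
    dvar = np.abs(pf_var - adf_var)
    return {
        "mean_divergence": dmean,
        "var_divergence": dvar,
        "max_mean_divergence": float(dmean.max()),
        "max_var_divergence": float(dvar.max()),
    }


class ParticleFilterOracle(BaseEstimator):
    """Sequential Monte Carlo estimator of the filtering moments.

    Same (traces, spikes) stream interface as
    :class:`synfilter.filters.SynapticFilter`.  Fitted attributes:
    ``mean_trajectory_``, ``var_trajectory_`` (marginal), ``ensemble_``.
    """

    def __init__(
        self,
        n_particles: int = 10_000,
        prior: OUPrior | None = None,
        neuron: NeuronParams | None = None,
        dt: float = 1e-3,
        random_state: int = 0,
    ) -> None:
        self.n_particles = n_particles
        self.prior = prior
        self.neuron = neuron
        self.dt = dt
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).ravel()
        d = X.shape[1]
        if d > 3:
            raise ValueError(
                "particle oracle restricted to d <= 3 (weight degeneracy)"
            )
        self.prior_ = self.prior if self.prior is not None else OUPrior.homogeneous(d)
        self.neuron_ = self.neuron if self.neuron is not None else NeuronParams()
        self.ensemble_ = ParticleEnsemble.from_prior(
            self.prior_, self.n_particles, self.random_state
        )
        n = X.shape[0]
        self.mean_trajectory_ = np.empty((n, d))
        self.var_trajectory_ = np.empty((n, d))
        for k in range(n):
            pf_step(self.ensemble_, X[k], int(y[k]), self.dt, self.prior_, self.neuron_)
            self.mean_trajectory_[k] = self.ensemble_.mean()
            self.var_trajectory_[k] = self.ensemble_.var()
        return self
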