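"""Filter tests: expected rate, belief updates, baseline rule, estimators."""

import numpy as np
import pytest
from sklearn.base import clone

from synfilter import (
    GaussianBelief,
    GradientFilter,
    GradientState,
    NeuronParams,
    OUPrior,
    SynapticFilter,
    VarianceCollapseError,
    expected_rate,
    gradient_step,
    make_partition,
    sf_step,
    validate_belief,
)


def random_belief(rng, d=3, variant="full"):
    mu = rng.normal(size=d)
    a = rng.normal(size=(d, d))
    cov = a @ a.T + 0.2 * np.eye(d)
    if variant == "full":
        return GaussianBelief(mu, [slice(0, d)], cov_blocks=[cov])
    return GaussianBelief(mu, make_partition(d, "diagonal"), var=np.diag(cov).copy())


class TestExpectedRate:
    def test_point_mass_limit(self, rng):
        d = 3
        mu = rng.normal(size=d)
        b = GaussianBelief(mu, make_partition(d, "diagonal"), var=np.full(d, 1e-14))
        x = rng.random(d)
        p = NeuronParams(g0=5.0, beta=0.7)
        assert np.isclose(expected_rate(b, x, p), 5.0 * np.exp(0.7 * mu @ x))

    def test_no_input_gives_baseline(self, rng):
        b = random_belief(rng)
        assert np.isclose(expected_rate(b, np.zeros(3), NeuronParams(g0=7.0)), 7.0)

    def test_matches_monte_carlo_integration(self, rng):
        # closed form vs sample mean of g(w.x) over Gaussian draws
        p = NeuronParams(g0=10.0, beta=0.4)
        for _ in range(5):
            b = random_belief(rng)
            x = rng.random(3)
            w = rng.multivariate_normal(b.mu, b.cov(), size=1_000_000)
            samples = p.g0 * np.exp(p.beta * w @ x)
            mc, se = samples.mean(), samples.std() / 1000.0
            assert abs(expected_rate(b, x, p) - mc) < 3 * se

    def test_monotone_in_diagonal_variance(self, rng):
        # convex gain: inflating any variance can only raise the rate
        p = NeuronParams(g0=10.0, beta=0.5)
        for _ in range(10):
            b = random_belief(rng)
            x = rng.random(3)
            base = expected_rate(b, x, p)
            i = rng.integers(3)
            b.cov_blocks[0][i, i] += 0.5
            assert expected_rate(b, x, p) >= base


class TestSFStep:
    def test_beta_zero_relaxes_to_prior(self):
        prior = OUPrior.homogeneous(2, mu=0.5, sigma2=2.0, tau=0.05)
        neuron = NeuronParams(g0=20.0, beta=0.0)
        b = GaussianBelief(np.array([3.0, -1.0]), [slice(0, 2)],
                           cov_blocks=[np.array([[0.3, 0.1], [0.1, 0.4]])])
        x = np.array([1.0, 1.0])
        for k in range(5000):  # 5 s = 100 relaxation times at dt=1e-3
            b = sf_step(b, x, k % 2, 1e-3, prior, neuron)
        assert np.allclose(b.mu, prior.mu, atol=1e-6)
        assert np.allclose(b.cov(), np.diag(prior.sigma2), atol=1e-6)

    def test_covariance_ignores_observation_mean_jumps_by_sigma_x(self, rng):
        prior = OUPrior.homogeneous(3, tau=10.0)
        neuron = NeuronParams(g0=20.0, beta=0.3)
        for _ in range(20):
            b = random_belief(rng)
            x = rng.random(3)
            b0 = sf_step(b, x, 0, 1e-3, prior, neuron)
            b1 = sf_step(b, x, 1, 1e-3, prior, neuron)
            assert np.array_equal(b0.cov(), b1.cov())
            # unit observation jump: mean difference is exactly beta*Sigma*x
            expected_jump = neuron.beta * (b.cov() @ x)
            assert np.allclose(b1.mu - b0.mu, expected_jump, rtol=0, atol=1e-15)

    def test_heterogeneous_relaxation_rates(self):
        # covariance entry (i,j) must relax at rate 1/tau_i + 1/tau_j
        prior = OUPrior(np.zeros(2), np.ones(2), np.array([0.05, 0.5]))
        neuron = NeuronParams(beta=0.0)
        c0 = np.array([[2.0, -0.5], [-0.5, 2.0]])
        b = GaussianBelief(np.zeros(2), [slice(0, 2)], cov_blocks=[c0])
        dt, n = 1e-4, 2000
        for _ in range(n):
            b = sf_step(b, np.zeros(2), 0, dt, prior, neuron)
        t = n * dt
        rates = 1.0 / prior.tau
        expected = np.diag(prior.sigma2) + (
            c0 - np.diag(prior.sigma2)
        ) * np.exp(-(rates[:, None] + rates[None, :]) * t)
        assert np.allclose(b.cov(), expected, rtol=5e-3)

    def test_offdiagonal_stays_negative_two_synapses(self, rng):
        # the negativity guarantee for weight correlations is two-dimensional:
        # at the zero crossing the update is -gamma*S11*x1*S22*x2 <= 0
        prior = OUPrior.homogeneous(2, tau=5.0)
        neuron = NeuronParams(g0=20.0, beta=0.3)
        b = GaussianBelief.from_prior(prior, "full")
        decay = np.exp(-1e-3 / 0.025)
        trace = np.zeros(2)
        for _ in range(5000):
            trace = trace * decay + (rng.random(2) < 0.05)
            b = sf_step(b, trace, int(rng.random() < 0.02), 1e-3, prior, neuron)
            assert validate_belief(b)["max_offdiag"] <= 1e-12

    def test_variance_collapse_raises(self):
        prior = OUPrior.homogeneous(1, tau=1e4)
        neuron = NeuronParams(g0=50.0, beta=3.0)
        b = GaussianBelief(np.array([2.0]), [slice(0, 1)],
                           cov_blocks=[np.array([[1.0]])])
        with pytest.raises(VarianceCollapseError, match="dt"):
            for _ in range(100):
                b = sf_step(b, np.array([3.0]), 0, 0.05, prior, neuron)


class TestStaticEvidenceOracle:
    def test_projection_against_exact_no_spike_posterior(self):
        """Silent-output evidence on two synapses vs the exact posterior.

        With effectively frozen weights and no output spikes, the exact
        posterior is prior * exp(-integral of g), integrable by plain Monte
        Carlo.  The Gaussian filter's continuous projection must land near
        the exact mean; its anticorrelation is known to be deeper than the
        exact one (both strictly negative) — asserted, since the
        heterosynaptic slope inherits this bias.
        """
        dt, tau_m, n = 1e-4, 0.025, 1550
        prior = OUPrior.homogeneous(2, 0.0, 1.0, 1e12)
        neuron = NeuronParams(g0=1.0, beta=1.0, tau_m=tau_m)
        b = GaussianBelief(np.ones(2), [slice(0, 2)], cov_blocks=[np.eye(2)])
        x = np.zeros(2)
        decay = np.exp(-dt / tau_m)
        spike_bins = {0, int(5e-3 / dt)}
        xs = np.empty((n, 2))
        for k in range(n):
            x = x * decay
            if k in spike_bins:
                x += 1.0
            xs[k] = x
            b = sf_step(b, x, 0, dt, prior, neuron)
        rng = np.random.default_rng(7)
        w = 1.0 + rng.standard_normal((200_000, 2))
        log_lik = np.zeros(len(w))
        for k in range(0, n, 250):
            log_lik -= np.exp(w @ xs[k:k + 250].T).sum(axis=1) * dt
        lw = log_lik - log_lik.max()
        wt = np.exp(lw)
        wt /= wt.sum()
        m_exact = wt @ w
        c_exact = ((w - m_exact) * wt[:, None]).T @ (w - m_exact)
        assert np.allclose(b.mu, m_exact, atol=0.05)
        ratio_adf = b.cov()[0, 1] / b.cov()[0, 0]
        ratio_exact = c_exact[0, 1] / c_exact[0, 0]
        assert ratio_exact < -0.1
        assert ratio_adf < ratio_exact  # projection overshoots anticorrelation


class TestGradientStep:
    def test_no_drive_no_update(self):
        state = GradientState(np.array([0.3, -0.2]), eta=0.1)
        out = gradient_step(state, np.zeros(2), 0, 1e-3, NeuronParams())
        # x = 0 and no spike: only the -g*dt*x term, which vanishes with x
        assert np.array_equal(out.w, state.w)

    def test_matches_finite_difference_log_likelihood_gradient(self, rng):
        # update direction = eta*beta * grad_w [y log(g dt) - g dt]
        neuron = NeuronParams(g0=15.0, beta=0.4)
        dt = 1e-3
        for spike in (0, 1):
            w = rng.normal(size=3)
            x = rng.random(3)
            state = GradientState(w.copy(), eta=0.05)
            out = gradient_step(state, x, spike, dt, neuron)

            def loglik(wv):
                g = neuron.g0 * np.exp(neuron.beta * wv @ x)
                return spike * np.log(g * dt) - g * dt

            eps = 1e-7
            grad = np.array([
                (loglik(w + eps * e) - loglik(w - eps * e)) / (2 * eps)
                for e in np.eye(3)
            ])
            assert np.allclose(out.w - w, state.eta * neuron.beta * grad,
                               rtol=1e-5, atol=1e-10)

    def test_single_beta_variant(self, rng):
        neuron = NeuronParams(g0=15.0, beta=0.4)
        w = rng.normal(size=2)
        x = rng.random(2)
        d2 = gradient_step(GradientState(w.copy(), 0.1), x, 1, 1e-3, neuron)
        d1 = gradient_step(GradientState(w.copy(), 0.1), x, 1, 1e-3, neuron,
                           double_beta=False)
        assert np.allclose(d2.w - w, neuron.beta * (d1.w - w))


class TestValidateBelief:
    def test_fresh_diagonal_belief_clean(self):
        b = GaussianBelief.from_prior(OUPrior.homogeneous(3), "full")
        rep = validate_belief(b)
        assert rep["max_symmetry_defect"] == 0
        assert rep["min_diagonal"] > 0
        assert rep["max_offdiag"] <= 0

    def test_asymmetry_reported(self):
        c = np.array([[1.0, 0.2], [0.1, 1.0]])
        b = GaussianBelief(np.zeros(2), [slice(0, 2)], cov_blocks=[c])
        assert np.isclose(validate_belief(b)["max_symmetry_defect"], 0.1)


class TestEstimators:
    def test_sklearn_protocol(self, small_session):
        prior, neuron, s = small_session
        est = SynapticFilter("block", block_size=2, prior=prior,
                             neuron=neuron, dt=s.dt)
        cloned = clone(est)
        assert cloned.get_params()["block_size"] == 2
        cloned.set_params(variant="diagonal")
        assert cloned.variant == "diagonal"
        est.fit(s.x_trace, s.y_spikes)
        assert est.mu_.shape == (3,)
        assert est.mu_trajectory_.shape == (s.n_steps, 3)

    def test_variant_consistency_d1(self):
        # with one input, full, block and diagonal structures coincide
        prior = OUPrior.homogeneous(1, tau=2.0)
        neuron = NeuronParams(g0=20.0, beta=0.5)
        rng = np.random.default_rng(3)
        n = 2000
        decay = np.exp(-1e-3 / 0.025)
        X = np.empty((n, 1))
        tr = 0.0
        for k in range(n):
            tr = tr * decay + (rng.random() < 0.03)
            X[k, 0] = tr
        y = (rng.random(n) < 0.02).astype(int)
        fits = [
            SynapticFilter(v, prior=prior, neuron=neuron, dt=1e-3).fit(X, y)
            for v in ("full", "block", "diagonal")
        ]
        for f in fits[1:]:
            assert np.allclose(fits[0].mu_trajectory_, f.mu_trajectory_,
                               atol=1e-12)
            assert np.allclose(fits[0].var_trajectory_, f.var_trajectory_,
                               atol=1e-12)

    def test_full_equals_block_when_inputs_confined_to_one_block(self):
        # inputs on channels 0-1 only; block partition {0,1},{2,3}
        prior = OUPrior.homogeneous(4, tau=2.0)
        neuron = NeuronParams(g0=20.0, beta=0.4)
        rng = np.random.default_rng(5)
        n = 3000
        decay = np.exp(-1e-3 / 0.025)
        X = np.zeros((n, 4))
        tr = np.zeros(4)
        for k in range(n):
            spikes = np.zeros(4)
            spikes[:2] = rng.random(2) < 0.04
            tr = tr * decay + spikes
            X[k] = tr
        y = (rng.random(n) < 0.02).astype(int)
        f_full = SynapticFilter("full", prior=prior, neuron=neuron, dt=1e-3).fit(X, y)
        f_block = SynapticFilter("block", block_size=2, prior=prior,
                                 neuron=neuron, dt=1e-3).fit(X, y)
        assert np.allclose(f_full.mu_trajectory_, f_block.mu_trajectory_, atol=1e-10)
        assert np.allclose(f_full.var_trajectory_, f_block.var_trajectory_, atol=1e-10)

    def test_partial_fit_matches_fit(self, small_session):
        prior, neuron, s = small_session
        whole = SynapticFilter("full", prior=prior, neuron=neuron, dt=s.dt)
        whole.fit(s.x_trace, s.y_spikes)
        chunked = SynapticFilter("full", prior=prior, neuron=neuron, dt=s.dt,
                                 store_trajectory=False)
        half = s.n_steps // 2
        chunked.partial_fit(s.x_trace[:half], s.y_spikes[:half])
        chunked.partial_fit(s.x_trace[half:], s.y_spikes[half:])
        assert np.allclose(whole.mu_, chunked.mu_, atol=1e-14)
        assert np.allclose(whole.cov_, chunked.cov_, atol=1e-14)

    def test_gradient_filter_tracks_direction(self, small_session):
        prior, neuron, s = small_session
        gf = GradientFilter(eta=2.0, neuron=neuron, dt=s.dt).fit(
            s.x_trace, s.y_spikes
        )
        assert gf.w_trajectory_.shape == (s.n_steps, 3)
        assert np.all(np.isfinite(gf.w_))

    def test_trajectory_frame_export(self, small_session):
        prior, neuron, s = small_session
        est = SynapticFilter("full", prior=prior, neuron=neuron, dt=s.dt)
        est.fit(s.x_trace, s.y_spikes)
        frame = est.trajectory_frame()
        assert len(frame) == s.n_steps
        assert {"t", "mu_0", "var_2"} <= set(frame.columns)
        assert np.allclose(frame["mu_1"], est.mu_trajectory_[:, 1])

    def test_make_partition_shapes(self):
        assert make_partition(4, "full") == [slice(0, 4)]
        assert len(make_partition(4, "diagonal")) == 4
        assert make_partition(17, "block", 8) == [
            slice(0, 9), slice(9, 17)
        ]
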