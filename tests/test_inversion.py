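"""Variational-Laplace inversion: conjugate oracles and DCM self-consistency."""

import numpy as np
import pytest
from scipy import stats

import rovingdcm as rd


def linear_problem(seed=0, n=40, p=3, sigma2=0.3):
    """Linear-Gaussian model with its analytic posterior and log evidence."""
    rng = np.random.default_rng(seed)
    J = rng.normal(size=(n, p))
    m0 = np.array([0.5, -0.2, 0.0][:p] + [0.0] * max(0, p - 3))
    S0 = np.diag(np.linspace(1.0, 2.0, p))
    theta = rng.normal(m0, np.sqrt(np.diag(S0)))
    y = J @ theta + rng.normal(0, np.sqrt(sigma2), n)
    P0 = np.linalg.inv(S0)
    H = J.T @ J / sigma2 + P0
    Sq = np.linalg.inv(H)
    mq = Sq @ (J.T @ y / sigma2 + P0 @ m0)
    logev = stats.multivariate_normal.logpdf(
        y, J @ m0, J @ S0 @ J.T + sigma2 * np.eye(n))
    return J, y, rd.PriorDensity(m0, S0), sigma2, mq, Sq, logev


class TestConjugateOracle:
    def test_posterior_and_evidence_match_closed_form(self):
        J, y, prior, sigma2, mq, Sq, logev = linear_problem()
        post = rd.laplace_fit(lambda th: th @ J.T, y, prior,
                              hyper_mean=np.log(1 / sigma2), hyper_var=0.0)
        assert np.max(np.abs(post.mean - mq)) < 1e-6
        assert np.max(np.abs(post.cov - Sq)) < 1e-6
        assert abs(post.free_energy - logev) < 1e-3
        assert post.converged

    def test_posterior_never_wider_than_prior(self):
        J, y, prior, sigma2, mq, Sq, logev = linear_problem(seed=3)
        post = rd.laplace_fit(lambda th: th @ J.T, y, prior,
                              hyper_mean=np.log(1 / sigma2), hyper_var=0.0)
        # prior covariance minus posterior covariance is PSD
        w = np.linalg.eigvalsh(prior.cov - post.cov)
        assert w.min() > -1e-10

    def test_fixed_parameter_stays_at_prior_mean(self):
        J, y, prior, sigma2, *_ = linear_problem(seed=5)
        cov = prior.cov.copy()
        cov[1, :] = 0.0
        cov[:, 1] = 0.0
        fixed_prior = rd.PriorDensity(prior.mean, cov)
        post = rd.laplace_fit(lambda th: th @ J.T, y, fixed_prior,
                              hyper_mean=np.log(1 / sigma2), hyper_var=0.0)
        assert post.mean[1] == pytest.approx(prior.mean[1], abs=1e-12)
        assert post.cov[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_noise_precision_estimated(self):
        # with a free hyperparameter the estimated log precision lands near truth
        J, y, prior, sigma2, mq, *_ = linear_problem(seed=8, n=200)
        post = rd.laplace_fit(lambda th: th @ J.T, y, prior,
                              hyper_mean=0.0, hyper_var=16.0)
        assert abs(post.noise_log_precision[0] - np.log(1 / sigma2)) < 0.4
        assert np.max(np.abs(post.mean - mq)) < 0.05

    def test_invalid_prior_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(rd.InvalidPriorError):
            rd.PriorDensity(np.zeros(2), bad)


@pytest.fixture(scope="module")
def small_fit():
    """One noisy 2-region inversion shared across checks."""
    from conftest import make_event_inputs, make_identifiable_two_region

    spec, params = make_identifiable_two_region(seed=0)
    nvol, TR, sub = 150, 1.54, 8
    u = make_event_inputs(nvol, TR, sub, 0.5, seed=0)
    clean = rd.simulate_timeseries(params, u, TR=TR, n_volumes=nvol,
                                   substeps=sub)
    sd = clean.values.std(axis=0).mean()
    rng = np.random.default_rng(99)
    data = rd.RegionTimeseries(
        values=clean.values + rng.normal(0, sd / 2, clean.values.shape),
        TR=TR, regions=clean.regions)
    post = rd.variational_laplace(
        data, spec, u, substeps=sub,
        settings=rd.InversionSettings(max_iterations=48))
    return spec, params, u, data, post, (nvol, TR, sub)


class TestDCMInversion:

    def test_free_energy_trace_monotone(self, small_fit):
        *_, post, _ = small_fit
        assert np.all(np.diff(post.f_trace) >= -1e-9)
        assert post.converged

    def test_inversion_is_deterministic(self, small_fit):
        spec, params, u, data, post, (nvol, TR, sub) = small_fit
        again = rd.variational_laplace(
            data, spec, u, substeps=sub,
            settings=rd.InversionSettings(max_iterations=48))
        assert np.array_equal(post.mean, again.mean)
        assert post.free_energy == again.free_energy

    def test_fit_improves_over_prior_mean(self, small_fit):
        spec, params, u, data, post, (nvol, TR, sub) = small_fit
        prior = rd.default_priors(spec)
        centred = data.values - data.values.mean(axis=0)

        def resid_var(theta):
            pred = rd.predict_response(theta, spec, u, TR, nvol, substeps=sub)
            pv = pred.values - pred.values.mean(axis=0)
            return np.var(centred - pv)

        assert resid_var(post.mean) <= resid_var(prior.mean)

    def test_self_consistency_at_prior_mean(self):
        """Noise-free data generated at the prior mean leave the posterior
        there (the start is already a stationary point of the fit term)."""
        spec = rd.NetworkSpec(regions=("R1", "R2"))
        prior = rd.default_priors(spec)
        # a prior mean that actually generates signal: put mass on C and A
        mean = prior.mean.copy()
        packer = rd.ParameterPacker(spec)
        mean[list(packer.names).index("C(R1<-u0)")] = 0.8
        mean[list(packer.names).index("A(R2<-R1)")] = 0.3
        prior = rd.PriorDensity(mean, prior.cov)
        seq = rd.generate_sequence(15, seed=3)
        nvol, TR, sub = 100, 1.54, 8
        u = rd.build_input_sticks(seq, nvol, TR, substeps=sub)
        params = packer.unpack(mean)
        clean = rd.simulate_timeseries(params, u, TR=TR, n_volumes=nvol,
                                       substeps=sub)
        post = rd.variational_laplace(
            clean, spec, u, priors=prior, substeps=sub,
            settings=rd.InversionSettings(max_iterations=32))
        assert np.max(np.abs(post.mean - mean)) < 0.02

    def test_predict_matches_simulation_and_zero_params(self, two_region_params,
                                                        two_region_spec):
        seq = rd.generate_sequence(8, seed=1)
        nvol, TR, sub = 60, 1.54, 8
        u = rd.build_input_sticks(seq, nvol, TR, substeps=sub)
        sim = rd.simulate_timeseries(two_region_params, u, TR, nvol, substeps=sub)
        pred = rd.predict_response(two_region_params, two_region_spec, u, TR,
                                   nvol, substeps=sub)
        assert np.allclose(sim.values, pred.values)
        # all-zero couplings (stable self-decay only) give a flat baseline
        packer = rd.ParameterPacker(two_region_spec)
        theta = np.zeros(packer.n_params)
        for i, nm in enumerate(packer.names):
            if nm in ("A(R1<-R1)", "A(R2<-R2)"):
                theta[i] = -0.5
        flat = rd.predict_response(theta, two_region_spec, u, TR, nvol,
                                   substeps=sub)
        assert np.abs(flat.values).max() < 1e-12

    def test_prior_size_mismatch_raises(self, two_region_spec):
        data = rd.RegionTimeseries(values=np.zeros((10, 2)), TR=1.0,
                                   regions=("R1", "R2"))
        bad = rd.PriorDensity(np.zeros(3), np.eye(3))
        with pytest.raises(rd.InvalidPriorError):
            rd.variational_laplace(data, two_region_spec,
                                   np.zeros((10 * 16, 2)), priors=bad)
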