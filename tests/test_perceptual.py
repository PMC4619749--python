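"""Belief dynamics: connectivity, propagation, Bayesian and fixed-gain updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wcst_attend import perceptual as P
from wcst_attend.perceptual import (
    BeliefState,
    Connectivity,
    PerceptualParams,
    PerceptualVariant,
    PredictedBelief,
    build_connectivity,
    bayes_update,
    hypothesis_posterior,
    initial_belief,
    jacobian_g,
    nonbayes_update,
    predict_belief,
    propagate_mean,
    run_filter,
)


def params(**kw):
    return PerceptualParams(**kw)


class TestConnectivity:
    def test_w1_lateral_weights_are_twice_kappa(self):
        c = build_connectivity(PerceptualVariant("w1"), params(kappa_e=1.0, kappa_f=0.5))
        off = c.W_lat_e[~np.eye(6, dtype=bool)]
        assert np.all(off == -2.0)
        assert np.all(np.diag(c.W_lat_e) == 0)
        assert np.all(c.W_lat_f[~np.eye(3, dtype=bool)] == -1.0)

    def test_w2_has_no_exemplar_inhibition(self):
        c = build_connectivity(PerceptualVariant("w2"), params(kappa_e=9.9, kappa_f=0.5))
        assert np.all(c.W_lat_e == 0)          # kappa_e structurally zero
        assert np.any(c.W_lat_f != 0)

    def test_structure_free_is_bottom_up_only(self):
        c = build_connectivity(PerceptualVariant("d"), params(w_dist=0.7))
        assert np.all(c.W_lat_e == 0) and np.all(c.W_lat_f == 0)
        assert np.all(c.W_dist_fe == 0)        # no top-down excitation
        for j in range(3):
            assert c.W_dist_ef[j, 2 * j] == 0.7
            assert c.W_dist_ef[j, 2 * j + 1] == 0.7
        c2 = build_connectivity(PerceptualVariant("d"), params(w_dist=0.7),
                                bidirectional_d=True)
        assert np.all(c2.W_dist_fe == c2.W_dist_ef.T)

    def test_dist_matrices_are_transposes(self):
        c = build_connectivity(PerceptualVariant("w1"), params(w_dist=0.3))
        np.testing.assert_array_equal(c.W_dist_ef, c.W_dist_fe.T)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity(PerceptualVariant("w1"), params(kappa_e=-1.0))


class TestPropagation:
    def test_pure_decay_fixed_point_at_zero(self):
        v = PerceptualVariant("rd")
        g = propagate_mean(np.zeros(6), v, params(tau_e=0.8))
        np.testing.assert_allclose(g, 0.0)

    def test_identity_limit(self):
        # tau = 1, kappa = 0, w_dist = 0 leaves the state unchanged
        v = PerceptualVariant("d")
        p = params(tau_e=1.0, tau_f=1.0, w_dist=0.0)
        mu = np.arange(9, dtype=float) - 4.0
        np.testing.assert_allclose(propagate_mean(mu, v, p), mu)

    def test_wta_attractor_preserves_winner(self):
        # noise-free iteration from a state with a clear winner keeps it on top
        v = PerceptualVariant("w1")
        p = params(tau_e=0.75, tau_f=0.75, kappa_e=0.5, kappa_f=0.5, w_dist=0.5)
        mu = np.zeros(9)
        mu[2] = 2.0
        for _ in range(300):
            mu = propagate_mean(mu, v, p)
        assert np.argmax(mu[:6]) == 2
        # exemplars of the two losing features are firmly suppressed (the
        # winner's sibling exemplar shares the top-down drive of its feature)
        assert mu[2] > max(mu[[0, 1, 4, 5]]) + 0.5
        assert np.argmax(mu[6:]) == 1  # corresponding feature wins too

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            propagate_mean(np.zeros(9), PerceptualVariant("rd"), params())


class TestJacobian:
    def test_reduced_diffusive_is_scaled_identity(self):
        J = jacobian_g(np.ones(6), PerceptualVariant("rd"), params(tau_e=0.7))
        np.testing.assert_allclose(J, 0.7 * np.eye(6))

    @pytest.mark.parametrize("structure", ["w1", "w2", "w3", "d", "rw", "rd"])
    def test_matches_finite_differences(self, structure, rng):
        v = PerceptualVariant(structure)
        p = params(tau_e=0.8, tau_f=0.7, kappa_e=0.6, kappa_f=0.4, w_dist=0.5)
        mu = rng.normal(size=v.dim)
        J = jacobian_g(mu, v, p)
        h = 1e-6
        for j in range(v.dim):
            e = np.zeros(v.dim)
            e[j] = h
            fd = (propagate_mean(mu + e, v, p) - propagate_mean(mu - e, v, p)) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, atol=1e-6)

    def test_decoupled_levels_give_block_diagonal(self, rng):
        v = PerceptualVariant("w1")
        p = params(kappa_e=0.5, kappa_f=0.5, w_dist=0.0)
        J = jacobian_g(rng.normal(size=9), v, p)
        assert np.all(J[:6, 6:] == 0) and np.all(J[6:, :6] == 0)


class TestPredict:
    def test_noise_only_propagation(self):
        v = PerceptualVariant("rd")
        p = params(tau_e=0.8, q_e=0.3)
        pred = predict_belief(BeliefState(np.zeros(6), 1e-14 * np.eye(6)), v, p)
        np.testing.assert_allclose(pred.cov, 0.3 * np.eye(6), atol=1e-10)

    def test_reduced_diffusive_scalar_algebra(self):
        # linear dynamics: cov = tau^2 sigma I + q I
        v = PerceptualVariant("rd")
        p = params(tau_e=0.7, q_e=0.2)
        pred = predict_belief(BeliefState(np.zeros(6), 0.5 * np.eye(6)), v, p)
        np.testing.assert_allclose(pred.cov, (0.49 * 0.5 + 0.2) * np.eye(6))

    def test_output_covariance_symmetric_pd(self, rng):
        v = PerceptualVariant("w1")
        p = params(tau_e=0.8, tau_f=0.7, kappa_e=0.5, kappa_f=0.5,
                   w_dist=0.5, q_e=0.1, q_f=0.1)
        for _ in range(200):
            A = rng.normal(size=(9, 9))
            Sigma = A @ A.T + 0.01 * np.eye(9)
            pred = predict_belief(BeliefState(rng.normal(size=9), Sigma), v, p)
            np.testing.assert_allclose(pred.cov, pred.cov.T)
            assert np.linalg.eigvalsh(pred.cov).min() > 0


class TestHypothesisPosterior:
    def test_flat_likelihood_returns_prediction(self, rng):
        g = rng.normal(size=9)
        e = np.array([1, 0, 1, 0, 1, 0])
        hyp = hypothesis_posterior(e, g, 0.5 - 1e-12)
        np.testing.assert_allclose(hyp.rho, hyp.pi_pred, atol=1e-9)

    def test_uniform_prediction_analytic_values(self):
        e = np.array([1, 0, 1, 0, 1, 0])
        hyp = hypothesis_posterior(e, np.zeros(9), 0.2)
        expected = np.array([0.8, 0.2, 0.8, 0.2, 0.8, 0.2]) / 3.0
        np.testing.assert_allclose(hyp.rho, expected)

    def test_matches_direct_summation(self, rng):
        for _ in range(50):
            g = rng.normal(size=9, scale=2.0)
            eps = rng.uniform(0.05, 0.45)
            perm = rng.permutation(6)
            e = np.zeros(6, dtype=int)
            # one exemplar per feature
            for j in range(3):
                e[2 * j + rng.integers(2)] = 1
            hyp = hypothesis_posterior(e, g, eps)
            brute = np.array([
                ((1 - eps) if e[k] else eps) * np.exp(g[k]) for k in range(6)
            ])
            np.testing.assert_allclose(hyp.rho, brute / brute.sum(), rtol=1e-10)

    def test_delta_feature_block_zero(self, rng):
        e = np.array([0, 1, 1, 0, 0, 1])
        hyp = hypothesis_posterior(e, rng.normal(size=9), 0.3)
        assert np.all(hyp.delta[6:] == 0)
        assert np.all(hyp.Y[6:, :] == 0) and np.all(hyp.Y[:, 6:] == 0)

    def test_malformed_evidence_rejected(self):
        with pytest.raises(ValueError):
            hypothesis_posterior(np.array([1, 1, 1, 1, 0, 0]), np.zeros(9), 0.2)


def _variational_energy(h, e, eps, pred_mean, pred_cov):
    """Independent implementation of the variational energy of the Gaussian
    belief: sum_k rho_k ln pi_k(h_e) + ln N(h; g, Sigma_hat) (up to consts)."""
    from scipy.stats import multivariate_normal

    lik = np.where(e == 1, 1 - eps, eps)
    z = np.exp(pred_mean[:6])
    rho = lik * z / (lik * z).sum()
    log_pi = h[:6] - np.log(np.exp(h[:6]).sum())
    return float(rho @ log_pi) + multivariate_normal.logpdf(h, pred_mean, pred_cov)


class TestBayesUpdate:
    def test_zero_prediction_error_keeps_mean(self, rng):
        g = rng.normal(size=9)
        cov = np.eye(9)
        hyp = hypothesis_posterior(np.array([1, 0, 1, 0, 1, 0]), g, 0.5 - 1e-13)
        out = bayes_update(PredictedBelief(g, cov), hyp)
        np.testing.assert_allclose(out.mu, g, atol=1e-9)

    def test_zero_curvature_keeps_covariance(self, rng):
        g = rng.normal(size=9)
        A = rng.normal(size=(9, 9))
        cov = A @ A.T + 0.1 * np.eye(9)
        hyp = hypothesis_posterior(np.array([1, 0, 1, 0, 1, 0]), g, 0.2)
        hyp.Y = np.zeros((9, 9))
        out = bayes_update(PredictedBelief(g, cov), hyp)
        np.testing.assert_allclose(out.Sigma, cov, atol=1e-10)

    def test_equals_newton_step_on_variational_energy(self, rng):
        # one Newton step from the expansion point of the quadratic
        # approximation, with gradient/Hessian assembled independently
        for _ in range(20):
            g = rng.normal(size=9)
            A = rng.normal(size=(9, 9)) * 0.3
            cov = A @ A.T + 0.2 * np.eye(9)
            e = np.zeros(6, dtype=int)
            for j in range(3):
                e[2 * j + rng.integers(2)] = 1
            eps = rng.uniform(0.05, 0.45)
            hyp = hypothesis_posterior(e, g, eps)
            out = bayes_update(PredictedBelief(g, cov), hyp)

            # independent: exact derivatives of the energy at the expansion point
            lik = np.where(e == 1, 1 - eps, eps)
            z = np.exp(g[:6] - g[:6].max())
            pi = z / z.sum()
            rho = lik * z / (lik * z).sum()
            grad = -np.linalg.solve(cov, g - g)  # Gaussian part, zero at g
            grad = grad + np.concatenate([rho - pi, np.zeros(3)])
            hess = -np.linalg.inv(cov) - np.diag(np.concatenate([pi, np.zeros(3)])) \
                + np.pad(np.outer(pi, pi), ((0, 3), (0, 3)))
            newton = g - np.linalg.solve(hess, grad)
            np.testing.assert_allclose(out.mu, newton, atol=1e-8)

    def test_energy_derivatives_validated_numerically(self, rng):
        # cross-check the analytic gradient used above against the energy itself
        g = rng.normal(size=9)
        cov = 0.5 * np.eye(9)
        e = np.array([1, 0, 0, 1, 1, 0])
        eps = 0.3
        lik = np.where(e == 1, 1 - eps, eps)
        z = np.exp(g[:6])
        pi = z / z.sum()
        rho = lik * z / (lik * z).sum()
        grad = np.concatenate([rho - pi, np.zeros(3)])
        h = 1e-6
        for j in range(9):
            d = np.zeros(9)
            d[j] = h
            fd = (_variational_energy(g + d, e, eps, g, cov)
                  - _variational_energy(g - d, e, eps, g, cov)) / (2 * h)
            assert fd == pytest.approx(grad[j], abs=1e-5)

    def test_covariance_update_forms_agree(self, rng):
        # (Sigma_hat^-1 + Y)^-1 vs Sigma_hat (I + Y Sigma_hat)^-1
        for _ in range(50):
            A = rng.normal(size=(9, 9)) * 0.5
            S = A @ A.T + 0.3 * np.eye(9)
            pi = rng.dirichlet(np.ones(6))
            Y = np.pad(np.diag(pi) - np.outer(pi, pi), ((0, 3), (0, 3)))
            direct = np.linalg.inv(np.linalg.inv(S) + Y)
            fraction = S @ np.linalg.inv(np.eye(9) + Y @ S)
            np.testing.assert_allclose(direct, fraction, atol=1e-10)


class TestNonBayesUpdate:
    def test_zero_gain_is_pure_propagation(self, rng):
        v = PerceptualVariant("rd", bayesian=False)
        p = params(tau_e=0.8, alpha=0.0, evidence_weight=0.2)
        mu = rng.normal(size=6)
        out = nonbayes_update(mu, np.array([1, 0, 1, 0, 1, 0]), v, p)
        np.testing.assert_allclose(out, propagate_mean(mu, v, p))

    def test_unnormalized_evidence_arithmetic(self):
        # g = 0: update is alpha (rho - 1/6) with rho in {0.8, 0.2}
        v = PerceptualVariant("rd", bayesian=False)
        p = params(tau_e=0.8, alpha=1.0, evidence_weight=0.2)
        out = nonbayes_update(np.zeros(6), np.array([1, 0, 1, 0, 1, 0]), v, p)
        expected = np.array([0.8, 0.2, 0.8, 0.2, 0.8, 0.2]) - 1.0 / 6.0
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_uninformative_evidence_gives_uniform_shift(self):
        v = PerceptualVariant("rd", bayesian=False)
        p = params(tau_e=0.8, alpha=2.0, evidence_weight=0.5 - 1e-13)
        out = nonbayes_update(np.zeros(6), np.array([0, 1, 0, 1, 0, 1]), v, p)
        np.testing.assert_allclose(out, 2.0 * (0.5 - 1.0 / 6.0), atol=1e-9)

    def test_full_hierarchy_feature_level_not_corrected(self, rng):
        v = PerceptualVariant("w1", bayesian=False)
        p = params(tau_e=0.8, tau_f=0.8, kappa_e=0.5, kappa_f=0.5,
                   w_dist=0.5, alpha=1.0, evidence_weight=0.3)
        mu = rng.normal(size=9)
        out = nonbayes_update(mu, np.array([1, 0, 1, 0, 1, 0]), v, p)
        np.testing.assert_allclose(out[6:], propagate_mean(mu, v, p)[6:])


class TestRunFilter:
    def test_empty_block_returns_initial_state(self):
        v = PerceptualVariant("w1")
        res = run_filter(np.zeros((0, 6)), v, params())
        assert len(res.beliefs) == 1
        np.testing.assert_array_equal(res.beliefs[0].mu,
                                      initial_belief(v, params()).mu)

    def test_consistent_evidence_selects_exemplar(self):
        v = PerceptualVariant("w1")
        p = params(error_rate=0.2, tau_e=0.75, tau_f=0.75, kappa_e=0.5,
                   kappa_f=0.5, w_dist=0.5, q_e=1.0, q_f=1.0)
        e = np.tile([1, 0, 1, 0, 1, 0], (40, 1))
        # exemplar 0 (red) always on the chosen card along with 2 and 4;
        # by symmetry all three supported exemplars should dominate
        res = run_filter(e, v, p)
        mu_e = res.beliefs[-1].mu[:6]
        assert min(mu_e[[0, 2, 4]]) > max(mu_e[[1, 3, 5]])

    def test_trajectory_length_and_posteriors(self, rng, switch_block):
        v = PerceptualVariant("w1")
        res = run_filter(switch_block, v, params(kappa_e=0.5, kappa_f=0.5,
                                                 w_dist=0.5))
        assert len(res.beliefs) == len(switch_block.trials) + 1
        assert len(res.posteriors) == len(switch_block.trials)
        for hyp in res.posteriors:
            assert hyp.rho.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonbayesian_covariance_fixed(self, switch_block):
        v = PerceptualVariant("rw", bayesian=False)
        p = params(tau_e=0.8, kappa_e=0.5, alpha=0.7, evidence_weight=0.3)
        res = run_filter(switch_block, v, p)
        for b in res.beliefs:
            np.testing.assert_array_equal(b.Sigma, 0.7 * np.eye(6))

    def test_covariances_stay_symmetric_pd(self, rng):
        v = PerceptualVariant("w1")
        for _ in range(30):
            p = params(
                error_rate=float(rng.uniform(0.1, 0.4)),
                tau_e=float(rng.uniform(0.6, 0.95)),
                tau_f=float(rng.uniform(0.6, 0.95)),
                kappa_e=float(rng.uniform(0.0, 1.5)),
                kappa_f=float(rng.uniform(0.0, 1.5)),
                w_dist=float(rng.uniform(0.0, 1.5)),
                q_e=float(rng.uniform(0.01, 2.0)),
                q_f=float(rng.uniform(0.01, 2.0)),
                sigma_e0=float(rng.uniform(0.1, 2.0)),
                sigma_f0=float(rng.uniform(0.1, 2.0)),
            )
            e = np.zeros((40, 6), dtype=int)
            for t in range(40):
                for j in range(3):
                    e[t, 2 * j + rng.integers(2)] = 1
            res = run_filter(e, v, p)
            for b in res.beliefs:
                np.testing.assert_allclose(b.Sigma, b.Sigma.T, atol=1e-12)
                assert np.linalg.eigvalsh(b.Sigma).min() > 0

    def test_trajectory_export_round_trip(self, switch_block):
        v = PerceptualVariant("w1")
        res = run_filter(switch_block, v, params(kappa_e=0.5, kappa_f=0.5,
                                                 w_dist=0.5))
        df = res.to_frame()
        assert len(df) == len(switch_block.trials) + 1
        np.testing.assert_allclose(
            df[["mu_red", "mu_color"]].to_numpy(),
            res.means[:, [0, 6]])
        d = res.to_dict()
        np.testing.assert_allclose(np.array(d["means"]), res.means)
        assert len(d["covariances"][0]) == 81

    def test_diffusive_decay_without_prediction_error(self):
        # epsilon -> 1/2 makes evidence uninformative: mean decays geometrically
        v = PerceptualVariant("rd")
        p = params(error_rate=0.5 - 1e-12, tau_e=0.8, q_e=0.1, mu_e0=1.0)
        e = np.tile([1, 0, 1, 0, 1, 0], (10, 1))
        res = run_filter(e, v, p)
        means = res.means
        for t in range(1, 11):
            np.testing.assert_allclose(means[t], 0.8 ** t * np.ones(6), atol=1e-6)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_rho_normalization_property(seed):
    rng = np.random.default_rng(seed)
    g = rng.normal(size=9, scale=3.0)
    e = np.zeros(6, dtype=int)
    for j in range(3):
        e[2 * j + rng.integers(2)] = 1
    hyp = hypothesis_posterior(e, g, float(rng.uniform(0.01, 0.49)))
    assert abs(hyp.rho.sum() - 1.0) < 1e-12
    assert np.all(hyp.rho > 0)
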