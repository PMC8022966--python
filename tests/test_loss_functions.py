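import numpy as np
import pytest
from scipy.stats import norm

import bdtsel as b
from bdtsel.loss_functions import _sample_truncated_gibbs


class TestTruncatedNormalMean:
    def test_no_truncation_limit(self):
        assert b.truncated_normal_mean(0.0, 1.0, -np.inf) == 0.0

    def test_half_normal(self):
        assert b.truncated_normal_mean(0.0, 1.0, 0.0) == pytest.approx(
            np.sqrt(2 / np.pi), abs=1e-5
        )

    def test_location_scale(self):
        assert b.truncated_normal_mean(5.0, 2.0, 5.0) == pytest.approx(
            5.0 + 2.0 * np.sqrt(2 / np.pi), abs=1e-5
        )

    def test_deep_tail_stability(self):
        # alpha = 8: Mills ratio ~ alpha + 1/alpha - 2/alpha^3
        got = b.truncated_normal_mean(0.0, 1.0, 8.0)
        assert np.isfinite(got)
        assert got == pytest.approx(8.0 + 1 / 8 - 2 / 8**3, rel=1e-4)

    def test_matches_numerical_integration(self):
        mu, sd, yc = 1.0, 1.5, 2.0
        from scipy.integrate import quad

        z = norm.sf((yc - mu) / sd)
        num, _ = quad(lambda y: y * norm.pdf(y, mu, sd) / z, yc, np.inf)
        assert b.truncated_normal_mean(mu, sd, yc) == pytest.approx(num, rel=1e-8)

    def test_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            b.truncated_normal_mean(0.0, 0.0, 1.0)


class TestKLUnivariate:
    def test_zero_heritability_reduces_to_log_inverse_pr(self):
        sel = b.UnivariateSelection(mu1=0.0, sigma2=1.0, yc=0.7, h2=0.0)
        assert b.kl_univariate(sel) == pytest.approx(np.log(1 / sel.Pr), abs=1e-12)

    def test_full_heritability_at_mean_threshold(self):
        # Pr = 1/2, i = sqrt(2/pi): KL = log 2 - 1/pi
        sel = b.UnivariateSelection(mu1=0.0, sigma2=1.0, yc=0.0, h2=1.0)
        assert b.kl_univariate(sel) == pytest.approx(np.log(2) - 1 / np.pi, abs=1e-6)

    def test_two_algebraic_forms_agree(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sel = b.UnivariateSelection(
                mu1=rng.normal(), sigma2=rng.uniform(0.2, 4.0),
                yc=rng.normal(scale=2.0), h2=rng.uniform(0.0, 1.0),
            )
            d = b.kl_univariate(sel, "difference") - b.kl_univariate(sel, "heritability")
            assert abs(d) < 1e-12

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sel = b.UnivariateSelection(
                mu1=rng.normal(), sigma2=rng.uniform(0.2, 4.0),
                yc=rng.normal(scale=2.0), h2=rng.uniform(0.0, 1.0),
            )
            assert b.kl_univariate(sel) >= 0.0

    def test_strictly_decreasing_in_h2(self):
        grid = np.linspace(0.01, 0.99, 25)
        vals = [
            b.kl_univariate(b.UnivariateSelection(mu1=0.0, sigma2=1.0, yc=0.5, h2=h))
            for h in grid
        ]
        assert np.all(np.diff(vals) < 0)

    def test_threshold_beyond_support_raises(self):
        sel = b.UnivariateSelection(mu1=0.0, sigma2=1.0, yc=50.0, h2=0.5)
        with pytest.raises(ValueError, match="relax"):
            b.kl_univariate(sel)


class TestOrthantProbability:
    def test_independent_halves(self):
        assert b.mvn_upper_orthant([0, 0], np.eye(2), [0, 0]) == pytest.approx(0.25, abs=1e-9)

    def test_full_support(self):
        assert b.mvn_upper_orthant([0, 0], np.eye(2), [-np.inf, -np.inf]) == pytest.approx(1.0)

    def test_arcsine_closed_form(self):
        P = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = 0.25 + np.arcsin(0.5) / (2 * np.pi)
        assert b.mvn_upper_orthant([0, 0], P, [0, 0]) == pytest.approx(expected, abs=1e-6)

    def test_univariate_reduction(self):
        assert b.mvn_upper_orthant([1.0], [[4.0]], [2.0]) == pytest.approx(
            norm.sf(0.5), abs=1e-12
        )

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            b.mvn_upper_orthant([0, 0], [[1.0, 2.0], [2.0, 1.0]], [0, 0])


class TestTruncatedMVN:
    P = np.array([[1.0, 0.5], [0.5, 1.0]])

    def test_samples_respect_support(self):
        S = b.sample_truncated_mvn([0, 0], self.P, [0.5, -0.2], 500, rng=0)
        assert np.all(S >= np.array([0.5, -0.2]))

    def test_moments_no_truncation(self):
        muS, z, _ = b.truncated_mvn_moments(
            [1.0, -1.0], self.P, [-np.inf, -np.inf], mc_draws=500, seed=0
        )
        np.testing.assert_allclose(muS, [1.0, -1.0], atol=0.15)
        assert z == pytest.approx(1.0)

    def test_diagonal_reduces_to_univariate_truncated_means(self):
        P = np.diag([1.0, 4.0])
        yc = np.array([0.3, -0.5])
        muS, _, se = b.truncated_mvn_moments([0.0, 1.0], P, yc, mc_draws=40_000, seed=2)
        expected = [
            b.truncated_normal_mean(0.0, 1.0, 0.3),
            b.truncated_normal_mean(1.0, 2.0, -0.5),
        ]
        assert np.all(np.abs(muS - expected) < 3 * se + 1e-9)

    def test_exact_mean_matches_sampling(self):
        yc = np.array([0.0, 0.4])
        muS_exact = b.truncated_mvn_mean([0.0, 0.0], self.P, yc)
        muS_mc, _, se = b.truncated_mvn_moments([0.0, 0.0], self.P, yc, mc_draws=60_000, seed=3)
        assert np.all(np.abs(muS_exact - muS_mc) < 4 * se)

    def test_gibbs_fallback_in_deep_orthant(self):
        yc = np.array([3.0, 3.0])  # z ~ 1e-4: rejection would be hopeless
        S = _sample_truncated_gibbs(np.zeros(2), self.P, yc, 4000,
                                    np.random.default_rng(4))
        assert np.all(S >= yc)
        exact = b.truncated_mvn_mean([0.0, 0.0], self.P, yc)
        np.testing.assert_allclose(S.mean(axis=0), exact, atol=0.05)


class TestKLMultivariate:
    def test_univariate_reduction(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            mu1 = rng.normal()
            s2 = rng.uniform(0.3, 3.0)
            yc = mu1 + rng.uniform(-1.5, 1.5) * np.sqrt(s2)
            h2 = rng.uniform(0.0, 1.0)
            sel = b.UnivariateSelection(mu1=mu1, sigma2=s2, yc=yc, h2=h2)
            par = b.ParentalDistribution.from_components([mu1], [[s2]], [yc])
            m2 = mu1 + h2 * par.S[0]
            assert abs(b.kl_multivariate(par, [m2]) - b.kl_univariate(sel)) < 1e-10

    def test_candidate_at_truncated_mean(self):
        P = np.array([[1.0, 0.3], [0.3, 1.0]])
        par = b.ParentalDistribution.from_components([0.0, 0.0], P, [0.2, 0.1])
        S = par.S
        expected = -np.log(par.z) - 0.5 * S @ np.linalg.solve(P, S)
        assert b.kl_multivariate(par, par.muS) == pytest.approx(expected, abs=1e-10)

    def test_heritability_matrix_form_identity(self):
        # closed form in terms of (I - GP^-1) equals the generic expression
        # when the candidate mean is mu1 + GP^-1 S
        rng = np.random.default_rng(6)
        for _ in range(20):
            A = rng.normal(size=(2, 2))
            Gm = A @ A.T + 0.1 * np.eye(2)
            E = rng.normal(size=(2, 2))
            P = Gm + np.diag(rng.uniform(0.2, 1.0, 2))
            mu1 = rng.normal(size=2)
            yc = mu1 + rng.uniform(-1.0, 0.5, 2)
            par = b.ParentalDistribution.from_components(mu1, P, yc)
            Pinv = np.linalg.inv(P)
            H = Gm @ Pinv
            m2 = mu1 + H @ par.S
            direct = b.kl_multivariate(par, m2)
            I = np.eye(2)
            printed = (
                -np.log(par.z)
                + 0.5 * par.S @ ((I - H).T @ Pinv @ (I - H) - Pinv) @ par.S
            )
            assert direct == pytest.approx(printed, abs=1e-10)

    def test_monte_carlo_integral_oracle(self):
        # average of log(TMVN/MVN) under truncated samples vs closed form
        rng = np.random.default_rng(7)
        P = np.array([[1.0, 0.5], [0.5, 1.0]])
        mu1 = np.zeros(2)
        yc = np.zeros(2)
        m2 = np.array([0.3, 0.3])
        par = b.ParentalDistribution.from_components(mu1, P, yc)
        Y = b.sample_truncated_mvn(mu1, P, yc, 100_000, rng=rng)
        Pinv = np.linalg.inv(P)
        d1 = Y - mu1
        d2 = Y - m2
        vals = (
            -np.log(par.z)
            - 0.5 * np.einsum("ij,jk,ik->i", d1, Pinv, d1)
            + 0.5 * np.einsum("ij,jk,ik->i", d2, Pinv, d2)
        )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - b.kl_multivariate(par, m2)) < 3 * se


class TestEnergyScore:
    def test_identical_samples_score_zero(self):
        X = np.random.default_rng(8).normal(size=(300, 3))
        assert abs(b.energy_score(X, X)) < 1e-10

    def test_univariate_normal_closed_form(self):
        # X~N(0,1), Y~N(2,1): E|X-Y| has a folded-normal closed form
        rng = np.random.default_rng(9)
        N = 5000
        X = rng.normal(size=(N, 1))
        Y = rng.normal(loc=2.0, size=(N, 1))

        def e_abs(m, s):
            return s * np.sqrt(2 / np.pi) * np.exp(-m * m / (2 * s * s)) + m * (
                1 - 2 * norm.cdf(-m / s)
            )

        closed = 2 * e_abs(2.0, np.sqrt(2)) - 2 * e_abs(0.0, np.sqrt(2))
        assert b.energy_score(X, Y) == pytest.approx(closed, abs=0.03)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(150, 2))
        Y = rng.normal(size=(200, 2)) + 1.0
        perm = rng.permutation(150)
        assert b.energy_score(X[perm], Y) == pytest.approx(b.energy_score(X, Y), abs=1e-12)

    def test_nonnegative_up_to_noise(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(400, 2))
        Y = rng.normal(size=(400, 2))
        assert b.energy_score(X, Y) > -1e-6

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            b.energy_score(np.zeros((100, 2)), np.zeros((100, 3)))


class TestMALF:
    def test_draws_exactly_at_threshold(self):
        Y = np.full((200, 3), 2.0)
        assert b.malf(Y, [2.0, 2.0, 2.0], 0.9) == 0.0

    def test_symmetric_tau_reduces_to_scaled_l1(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(500, 2))
        yc = np.array([0.3, -0.2])
        expected = 0.5 * np.abs(Y - yc).mean(axis=0).sum()
        assert b.malf(Y, yc, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_half_normal_oracle(self):
        # N(0,1) at yc=0: tau*E(-Y)_+ + (1-tau)*E(Y)_+ = phi(0) for any tau
        Y = np.random.default_rng(13).normal(size=(200_000, 1))
        se = 3 / np.sqrt(200_000)
        assert abs(b.malf(Y, [0.0], 0.9) - norm.pdf(0)) < 3 * se

    def test_invalid_tau(self):
        with pytest.raises(ValueError, match="tau"):
            b.malf(np.zeros((100, 1)), [0.0], 1.0)


class TestDirectionTransform:
    def test_all_increase_is_identity(self):
        v = np.array([1.0, -2.0, 3.0])
        out = b.apply_direction_transform(v, ["increase"] * 3)
        np.testing.assert_array_equal(out, v)

    def test_involution(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=(20, 3))
        dirs = ["decrease", "increase", "decrease"]
        out = b.apply_direction_transform(b.apply_direction_transform(v, dirs), dirs)
        np.testing.assert_array_equal(out, v)

    def test_loss_equivalence_under_consistent_negation(self):
        rng = np.random.default_rng(15)
        Y = rng.normal(size=(400, 2))
        yc = np.array([0.5, -0.3])
        dirs = ["decrease", "decrease"]
        direct = b.malf(Y, yc, 0.5)
        # tau=1/2 makes the penalty symmetric, so consistent negation of
        # draws and thresholds leaves the loss unchanged exactly
        flipped = b.malf(
            b.apply_direction_transform(Y, dirs),
            b.apply_direction_transform(yc, dirs),
            0.5,
        )
        assert flipped == pytest.approx(direct, abs=1e-12)

    def test_covariance_conjugation(self):
        P = np.array([[1.0, 0.5], [0.5, 2.0]])
        out = b.orient_covariance(P, ["decrease", "increase"])
        np.testing.assert_allclose(out, [[1.0, -0.5], [-0.5, 2.0]])
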