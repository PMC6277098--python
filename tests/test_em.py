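"""Beta-likelihood objective, EM updates and robustness properties."""
import numpy as np
import pytest
from scipy import integrate, stats

import betaqtl as bq
from betaqtl.em import (
    DegenerateFitError,
    LOG10E,
    Theta,
    beta_likelihood,
    component_means,
    e_step,
    estimating_function_bound_check,
    fit,
    fit_null,
    l_beta_normalizer,
    lod_beta,
    m_step,
    mixture_density,
)
from betaqtl.studies import simulate_unlinked


def classical_em_oracle(Y, X, Q, D, tol=1e-12, max_iter=500):
    """Textbook EM for a Gaussian mixture with shared variance and means
    mu_ji = X_j gamma + D_i E: deliberately independent of the package's
    update algebra (scipy densities, explicit per-class loops)."""
    n, m = Q.shape
    p = D.shape[1]
    coef, *_ = np.linalg.lstsq(np.hstack([X, Q @ D]), Y, rcond=None)
    gamma, E = coef[: X.shape[1]], coef[X.shape[1] :]
    s2 = np.var(Y - X @ gamma - (Q @ D) @ E)
    ll_old = -np.inf
    for _ in range(max_iter):
        mu = (X @ gamma)[:, None] + (D @ E)[None, :]
        dens = Q * stats.norm.pdf(Y[:, None], mu, np.sqrt(s2))
        f = dens.sum(axis=1)
        post = dens / f[:, None]
        # M-step: joint weighted regression of y on [X | class codes]
        Xb = np.vstack([np.hstack([X, np.tile(D[i], (n, 1))]) for i in range(m)])
        Yb = np.tile(Y, m)
        wb = np.sqrt(post.T.ravel())
        coef, *_ = np.linalg.lstsq(Xb * wb[:, None], Yb * wb, rcond=None)
        gamma, E = coef[: X.shape[1]], coef[X.shape[1] :]
        mu = (X @ gamma)[:, None] + (D @ E)[None, :]
        s2 = float((post * (Y[:, None] - mu) ** 2).sum() / n)
        ll = np.log(f).sum()
        if ll - ll_old < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return E, gamma, s2


class TestComponentMeans:
    def test_null_effects_give_covariate_mean(self):
        th = Theta(E=[0.0, 0.0], gamma=[2.0], sigma2=1.0)
        X = np.ones((4, 1))
        D = bq.design_matrix("f2", 1).D
        np.testing.assert_allclose(component_means(th, X, D), 2.0)

    def test_f2_printed_means(self):
        th = Theta(E=[1.0, 0.0], gamma=[0.0], sigma2=1.0)
        mu = component_means(th, np.ones((1, 1)), bq.design_matrix("f2", 1).D)
        np.testing.assert_allclose(mu[0], [1.0, 0.0, -1.0])

    def test_bc_shifted_means(self):
        th = Theta(E=[2.0], gamma=[5.0], sigma2=1.0)
        mu = component_means(th, np.ones((1, 1)), bq.design_matrix("bc", 1).D)
        np.testing.assert_allclose(mu[0], [7.0, 5.0])


class TestMixtureDensity:
    def test_single_component(self):
        th = Theta(E=[0.0], gamma=[0.0], sigma2=4.0)
        v = mixture_density(1.0, th, [1.0, 0.0], [0.5, 9.9])
        assert v == pytest.approx(stats.norm.pdf(1.0, 0.5, 2.0), rel=1e-12)

    def test_symmetric_midpoint(self):
        th = Theta(E=[0.0], gamma=[0.0], sigma2=1.0)
        a = mixture_density(0.0, th, [0.5, 0.5], [-1.0, 1.0])
        b = mixture_density(0.0, th, [0.5, 0.5], [1.0, -1.0])
        assert a == pytest.approx(b, rel=1e-14)

    def test_three_component_value(self):
        """1:2:1 mixture at means (1,0,-1), sigma=1, y=0: direct evaluation."""
        th = Theta(E=[1.0, 0.0], gamma=[0.0], sigma2=1.0)
        v = mixture_density(0.0, th, [0.25, 0.5, 0.25], [1.0, 0.0, -1.0])
        direct = 0.25 * stats.norm.pdf(1.0) + 0.5 * stats.norm.pdf(0.0) + 0.25 * stats.norm.pdf(-1.0)
        assert direct == pytest.approx(0.3204565, abs=1e-7)
        assert v == pytest.approx(direct, rel=1e-12)


class TestNormalizer:
    def _normalizer(self, th, probs, beta, n=1):
        X = np.zeros((probs.shape[0], 1))
        D = np.zeros((probs.shape[1], 0))
        return l_beta_normalizer(th, probs, X, D, beta)

    def test_beta_zero_is_one(self):
        th = Theta(E=[], gamma=[0.0], sigma2=2.0)
        np.testing.assert_allclose(self._normalizer(th, np.ones((3, 1)), 0.0), 1.0)

    def test_closed_form_value(self):
        th = Theta(E=[], gamma=[0.0], sigma2=1.0)
        v = self._normalizer(th, np.ones((1, 1)), 0.1)[0]
        expect = ((2 * np.pi) ** (-0.05) * 1.1 ** (-0.5)) ** (0.1 / 1.1)
        assert v == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("sigma2", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("beta", [0.01, 0.1, 0.5])
    def test_closed_form_matches_quadrature(self, sigma2, beta):
        """Null-model closed form vs independent adaptive quadrature (1e-8)."""
        mu, s = 0.7, np.sqrt(sigma2)
        I, _ = integrate.quad(
            lambda y: stats.norm.pdf(y, mu, s) ** (1 + beta), mu - 30 * s, mu + 30 * s
        )
        expect = I ** (beta / (1 + beta))
        th = Theta(E=[], gamma=[mu], sigma2=sigma2)
        X = np.ones((1, 1))
        got = l_beta_normalizer(th, np.ones((1, 1)), X, np.zeros((1, 0)), beta)[0]
        assert got == pytest.approx(expect, rel=1e-8)

    def test_equal_component_mixture_matches_gaussian(self):
        """A mixture whose components coincide is a single Gaussian."""
        th = Theta(E=[0.0], gamma=[0.3], sigma2=1.7)
        X = np.ones((2, 1))
        D = np.zeros((3, 1))
        got = l_beta_normalizer(th, np.full((2, 3), 1 / 3), X, D, 0.2)
        expect = self._normalizer(Theta(E=[], gamma=[0.0], sigma2=1.7), np.ones((1, 1)), 0.2)[0]
        np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_true_mixture_quadrature_vs_adaptive(self):
        """Separated-component rows: panel quadrature vs scipy adaptive."""
        beta, s2 = 0.3, 0.8
        probs = np.array([[0.3, 0.7]])
        means = np.array([[-2.0, 1.5]])

        def f(y):
            return (
                probs[0, 0] * stats.norm.pdf(y, means[0, 0], np.sqrt(s2))
                + probs[0, 1] * stats.norm.pdf(y, means[0, 1], np.sqrt(s2))
            )

        I, _ = integrate.quad(lambda y: f(y) ** (1 + beta), -30, 30)
        expect = I ** (beta / (1 + beta))
        from betaqtl.em import log_l_beta

        got = np.exp(log_l_beta(means, s2, probs, beta))[0]
        assert got == pytest.approx(expect, rel=1e-8)


class TestBetaLikelihood:
    def test_limit_matches_beta_zero_branch(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        th = Theta(E=[1.2], gamma=[0.1], sigma2=1.5)
        a = beta_likelihood(Y, X, probs.Q, th, D.D, 1e-8)
        b = beta_likelihood(Y, X, probs.Q, th, D.D, 0.0)
        assert a == pytest.approx(b, abs=1e-6)

    def test_single_observation_hand_identity(self):
        """n=1: objective equals (f(y)^beta / l_beta - 1)/beta exactly."""
        th = Theta(E=[], gamma=[0.4], sigma2=2.0)
        X = np.ones((1, 1))
        probs = np.ones((1, 1))
        beta = 0.25
        from betaqtl.em import _log_l_beta_gaussian

        for y in (-1.0, 0.4, 3.7):
            f = stats.norm.pdf(y, 0.4, np.sqrt(2.0))
            l = np.exp(_log_l_beta_gaussian(2.0, beta))
            expect = (f**beta / l - 1.0) / beta
            val = beta_likelihood(np.array([y]), X, probs, th, np.zeros((1, 0)), beta)
            assert val == pytest.approx(expect, rel=1e-12)

    def test_beta_zero_matches_direct_loglik(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        th = Theta(E=[1.5], gamma=[0.0], sigma2=2.0)
        mu = (X @ th.gamma)[:, None] + (D.D @ th.E)[None, :]
        direct = np.mean(
            np.log(
                (probs.Q * stats.norm.pdf(Y[:, None], mu, np.sqrt(th.sigma2))).sum(axis=1)
            )
        )
        got = beta_likelihood(Y, X, probs.Q, th, D.D, 0.0)
        assert got == pytest.approx(direct, rel=1e-12)


class TestESten:
    def test_row_sums_are_density_powers(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        th = Theta(E=[1.0], gamma=[0.2], sigma2=1.2)
        for beta in (0.0, 0.1, 0.4):
            Pi = e_step(Y, X, probs.Q, th, D.D, beta)
            mu = component_means(th, X, D.D)
            f = (probs.Q * stats.norm.pdf(Y[:, None], mu, np.sqrt(th.sigma2))).sum(axis=1)
            np.testing.assert_allclose(Pi.Pi.sum(axis=1), f**beta, rtol=1e-10)

    def test_beta_zero_rows_are_posteriors(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        Pi = e_step(Y, X, probs.Q, Theta(E=[1.0], gamma=[0.0], sigma2=1.0), D.D, 0.0)
        np.testing.assert_allclose(Pi.Pi.sum(axis=1), 1.0, atol=1e-12)
        assert (Pi.Pi >= 0).all()

    def test_degenerate_prior_forces_class(self):
        Y = np.array([0.3, -0.2])
        X = np.ones((2, 1))
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        th = Theta(E=[1.0], gamma=[0.0], sigma2=1.0)
        D = bq.design_matrix("bc", 1).D
        beta = 0.2
        Pi = e_step(Y, X, Q, th, D, beta)
        mu = component_means(th, X, D)
        f0 = stats.norm.pdf(Y[0], mu[0, 0], 1.0)
        f1 = stats.norm.pdf(Y[1], mu[1, 1], 1.0)
        np.testing.assert_allclose(Pi.Pi[0], [f0**beta, 0.0], rtol=1e-10)
        np.testing.assert_allclose(Pi.Pi[1], [0.0, f1**beta], rtol=1e-10)


class TestMStepAndFit:
    def test_matches_classical_em_oracle_at_beta_zero(self, small_f2_cross):
        """Full beta=0 fit equals an independently coded classical EM."""
        cross = small_f2_cross
        probs = bq.interval_qtl_probs(cross, "1", 15.0)
        D = bq.design_matrix("f2", 1)
        X = np.ones((cross.n, 1))
        res = fit(cross.phenotype, X, probs, D, beta=0.0, tol=1e-12, max_iter=500)
        E_o, g_o, s2_o = classical_em_oracle(cross.phenotype, X, probs.Q, D.D)
        np.testing.assert_allclose(res.theta_hat.E, E_o, atol=1e-4)
        np.testing.assert_allclose(res.theta_hat.gamma, g_o, atol=1e-4)
        assert res.theta_hat.sigma2 == pytest.approx(s2_o, abs=1e-4)

    def test_near_zero_beta_matches_oracle(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        res = fit(Y, X, probs, D, beta=1e-8, tol=1e-12, max_iter=500)
        E_o, g_o, s2_o = classical_em_oracle(Y, X, probs.Q, D.D)
        np.testing.assert_allclose(res.theta_hat.E, E_o, atol=1e-4)
        np.testing.assert_allclose(res.theta_hat.gamma, g_o, atol=1e-4)

    def test_degenerate_posterior_reduces_to_ols(self):
        """All mass in observed classes at beta=0: fit is OLS on the codes."""
        rng = np.random.default_rng(13)
        g = rng.integers(0, 2, size=80)
        Y = 1.4 * g + rng.normal(size=80)
        X = np.ones((80, 1))
        Q = np.zeros((80, 2))
        Q[np.arange(80), 1 - g] = 1.0  # class order (QQ, Qq)
        D = bq.design_matrix("bc", 1)
        res = fit(Y, X, Q, D, beta=0.0)
        codes = np.column_stack([np.ones(80), g])
        coef, *_ = np.linalg.lstsq(codes, Y, rcond=None)
        assert res.theta_hat.gamma[0] == pytest.approx(coef[0], abs=1e-8)
        assert res.theta_hat.E[0] == pytest.approx(coef[1], abs=1e-8)

    @pytest.mark.parametrize("beta", [0.0, 0.05, 0.1, 0.3])
    def test_objective_monotone_and_fixed_point(self, bc_fit_fixture, beta):
        Y, X, probs, D = bc_fit_fixture
        res = fit(Y, X, probs, D, beta=beta)
        assert res.converged
        assert np.all(np.diff(res.objective_trace) >= -1e-10)
        # polish to the exact fixed point, then one more cycle moves nothing
        th = res.theta_hat
        for _ in range(5000):
            Pi = e_step(Y, X, probs.Q, th, D.D, beta)
            th2 = m_step(Pi, Y, X, D.D, th, beta)
            if np.max(np.abs(th2.pack() - th.pack())) < 1e-13:
                th = th2
                break
            th = th2
        Pi = e_step(Y, X, probs.Q, th, D.D, beta)
        th2 = m_step(Pi, Y, X, D.D, th, beta)
        assert np.max(np.abs(th2.pack() - th.pack())) < 1e-10

    def test_jacobi_recurrence_same_fixed_point(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        a = fit(Y, X, probs, D, beta=0.1, tol=1e-12, max_iter=1000)
        b = fit(Y, X, probs, D, beta=0.1, tol=1e-12, max_iter=1000, e_update="jacobi")
        np.testing.assert_allclose(a.theta_hat.E, b.theta_hat.E, atol=1e-6)
        np.testing.assert_allclose(a.theta_hat.gamma, b.theta_hat.gamma, atol=1e-6)

    def test_parameter_recovery_f2(self):
        """Mean (a_hat, d_hat) over replicates within 3 Ses of truth."""
        reps, a_true, d_true = 30, 1.0, 0.5
        est = np.empty((reps, 2))
        for i in range(reps):
            gmap = bq.sim_map(1, 4, 10.0)
            cross = bq.sim_cross(gmap, 300, "f2", seed=100 + i)
            cross = bq.sim_phenotype(
                cross, [bq.QTLSpec("1", 10.0, a_true, d_true)], 0.5, seed=200 + i
            )
            probs = bq.interval_qtl_probs(cross, "1", 10.0)
            res = fit(cross.phenotype, np.ones((300, 1)), probs, bq.design_matrix("f2", 1))
            est[i] = res.theta_hat.E
        for j, true in enumerate((a_true, d_true)):
            se = est[:, j].std(ddof=1) / np.sqrt(reps)
            assert abs(est[:, j].mean() - true) < 3 * se + 1e-9

    def test_robustness_smaller_error_with_positive_beta(self):
        """5% gross outliers: beta=0.1 beats beta=0 on mean |a_hat - a|."""
        errs = {0.0: [], 0.1: []}
        for seed in range(25):
            cross = simulate_unlinked(seed, contaminated=True)
            probs = bq.interval_qtl_probs(cross, "1", 20.0)
            D = bq.design_matrix("bc", 1)
            X = np.ones((cross.n, 1))
            for b in errs:
                r = fit(cross.phenotype, X, probs, D, beta=b)
                errs[b].append(abs(r.theta_hat.E[0] - 2.12))
        assert np.mean(errs[0.1]) < np.mean(errs[0.0])

    def test_invalid_beta_rejected(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        with pytest.raises(ValueError):
            fit(Y, X, probs, D, beta=-0.1)

    def test_singular_design_raises(self):
        Y = np.arange(10.0)
        X = np.ones((10, 2))  # duplicated intercept
        with pytest.raises(DegenerateFitError):
            fit_null(Y, X, beta=0.1)


class TestFitNull:
    def test_beta_zero_is_ols(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(2.0, 1.5, size=200)
        res = fit_null(Y, np.ones((200, 1)), beta=0.0)
        assert res.theta_hat.gamma[0] == pytest.approx(Y.mean(), abs=1e-10)
        assert res.theta_hat.sigma2 == pytest.approx(np.mean((Y - Y.mean()) ** 2), abs=1e-10)

    def test_robust_location_resists_gross_outlier(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(0.0, 1.0, size=100)
        Y[0] = 60.0
        ols = fit_null(Y, np.ones((100, 1)), beta=0.0)
        rob = fit_null(Y, np.ones((100, 1)), beta=0.2)
        clean_mean = Y[1:].mean()
        assert abs(rob.theta_hat.gamma[0] - clean_mean) < abs(
            ols.theta_hat.gamma[0] - clean_mean
        )


class TestLod:
    def test_null_vs_itself_is_zero(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        nul = fit_null(Y, X, beta=0.1)
        assert lod_beta(nul, nul, Y.size) == 0.0

    def test_beta_zero_matches_brute_force_lr(self, bc_fit_fixture):
        """Classical LOD equals log10 of the likelihood ratio."""
        Y, X, probs, D = bc_fit_fixture
        alt = fit(Y, X, probs, D, beta=0.0, tol=1e-12)
        nul = fit_null(Y, X, beta=0.0, tol=1e-12)
        mu = component_means(alt.theta_hat, X, D.D)
        ll_alt = np.log(
            (probs.Q * stats.norm.pdf(Y[:, None], mu, np.sqrt(alt.theta_hat.sigma2))).sum(axis=1)
        ).sum()
        ll_nul = stats.norm.logpdf(
            Y, nul.theta_hat.gamma[0], np.sqrt(nul.theta_hat.sigma2)
        ).sum()
        expect = LOG10E * (ll_alt - ll_nul)
        assert lod_beta(alt, nul, Y.size) == pytest.approx(expect, abs=1e-6)

    def test_mismatched_beta_rejected(self, bc_fit_fixture):
        Y, X, probs, D = bc_fit_fixture
        with pytest.raises(ValueError):
            lod_beta(fit(Y, X, probs, D, beta=0.1), fit_null(Y, X, beta=0.0), Y.size)


class TestBoundedness:
    def _setup(self):
        th = Theta(E=[1.0], gamma=[0.0], sigma2=1.0)
        probs_row = np.array([0.6, 0.4])
        X_row = np.array([1.0])
        D = bq.design_matrix("bc", 1)
        return th, probs_row, X_row, D

    def test_positive_beta_bounded_interior_supremum(self):
        """beta > 0: suprema finite, attained in the grid interior, and
        unchanged when the grid is extended tenfold."""
        th, probs_row, X_row, D = self._setup()
        g1 = np.linspace(-1e3, 1e3, 40001)
        g2 = np.linspace(-1e4, 1e4, 400001)
        s1 = estimating_function_bound_check(th, probs_row, X_row, D, 0.1, g1)
        s2 = estimating_function_bound_check(th, probs_row, X_row, D, 0.1, g2)
        for name in s1:
            sup1, arg1 = s1[name]
            sup2, _ = s2[name]
            assert np.isfinite(sup1)
            assert abs(arg1) < 50  # interior, not at the boundary
            assert sup2 == pytest.approx(sup1, abs=1e-9 + 1e-6 * sup1)

    def test_beta_zero_unbounded_at_boundary(self):
        """beta = 0 (maximum likelihood): suprema grow with the grid and sit
        on its boundary — the estimating function is unbounded."""
        th, probs_row, X_row, D = self._setup()
        g1 = np.linspace(-1e3, 1e3, 40001)
        g2 = np.linspace(-1e4, 1e4, 400001)
        s1 = estimating_function_bound_check(th, probs_row, X_row, D, 0.0, g1)
        s2 = estimating_function_bound_check(th, probs_row, X_row, D, 0.0, g2)
        for name in ("E[0]", "gamma[0]", "sigma2"):
            sup1, arg1 = s1[name]
            sup2, arg2 = s2[name]
            assert sup2 > 5 * sup1  # keeps growing as the grid extends
            assert abs(arg2) == pytest.approx(1e4, rel=1e-3)  # at the boundary

    def test_additive_component_scaling_envelope(self):
        """The additive-effect component behaves like e^{-beta z^2} poly(z):
        its supremum location scales like (2 beta)^{-1/2}."""
        th = Theta(E=[0.0], gamma=[0.0], sigma2=1.0)
        probs_row = np.array([1.0, 0.0])  # single component: psi_a ~ z e^{-beta z^2/...}
        X_row = np.array([1.0])
        D = bq.design_matrix("bc", 1)
        locs = {}
        for beta in (0.05, 0.2):
            grid = np.linspace(-50, 50, 200001)
            res = estimating_function_bound_check(th, probs_row, X_row, D, beta, grid)
            locs[beta] = res["E[0]"][1]
        # z* = 1/sqrt(2 beta) for the dominant e^{-beta z^2} z envelope;
        # the l_beta factor preserves the scaling (ratio sqrt(0.2/0.05) = 2)
        assert abs(locs[0.05] / locs[0.2]) == pytest.approx(2.0, rel=0.2)
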