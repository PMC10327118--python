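"""The coordinate-ascent fitting loop: equivalence of the individual-data
and sufficient-statistic paths, EM scale estimation against a grid-search
oracle, ELBO exactness and monotonicity, agreement with exhaustive
enumeration of causal configurations, and reduction to univariate SuSiE."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal as mvn

import mvsusie as mv
from mvsusie.ibss import _marginal_stats, compute_elbo, estimate_prior_scale
from mvsusie.model_core import MarginalStats, MixturePrior, single_effect_posterior


def _make_data(seed, n=300, J=20, R=2, pve=0.05):
    X = mv.simulate_genotypes(n, J, ld_decay=0.6, seed=seed)
    sc = mv.default_scenario(R=R, target_max_pve=pve, seed=seed + 1000)
    Y, truth = mv.simulate_traits(X, sc)
    return X, Y, truth


class TestCenterStandardize:
    def test_center_only(self):
        out, means, sds = mv.center_standardize(np.array([[1.0], [2.0], [3.0]]),
                                                standardize=False)
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1])
        assert means[0] == 2.0

    def test_constant_column_raises(self):
        M = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match=r"\[0\]"):
            mv.center_standardize(M, standardize=True)

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((5, 3)) * 3 + 1
        out, _, _ = mv.center_standardize(M, standardize=True)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose((out**2).mean(axis=0), 1.0, atol=1e-12)  # divisor N


class TestFitEquivalences:
    def test_ibss_equals_ibss_ss(self):
        X, Y, _ = _make_data(7, n=100, J=10, R=2)
        prior = mv.canonical_prior(2)
        V = np.cov(Y, rowvar=False)
        opts = mv.FitOptions(L=3)
        f1 = mv.fit_individual(X, Y, prior, V, opts)
        Xc, _, _ = mv.center_standardize(X, False)
        Yc, _, _ = mv.center_standardize(Y, False)
        ss = mv.SufficientStats(xtx=Xc.T @ Xc, xty=Xc.T @ Yc, n=X.shape[0], yty=Yc.T @ Yc)
        f2 = mv.fit_ss(ss, prior, V, opts)
        assert max(abs(a - b) for a, b in zip(f1.elbo_trace, f2.elbo_trace)) < 1e-8
        np.testing.assert_allclose(mv.compute_pip(f1), mv.compute_pip(f2), atol=1e-10)

    def test_single_pass_L1_equals_direct_single_effect(self):
        X, Y, _ = _make_data(9, n=200, J=15, R=2)
        prior = mv.canonical_prior(2)
        V = np.cov(Y, rowvar=False)
        opts = mv.FitOptions(L=1, estimate_prior_scale=False, prior_scale_init=0.5,
                             max_iter=3)
        fit = mv.fit_individual(X, Y, prior, V, opts)
        Xc, _, _ = mv.center_standardize(X, False)
        Yc, _, _ = mv.center_standardize(Y, False)
        d = (Xc**2).sum(axis=0)
        stats = MarginalStats(bhat=(Xc.T @ Yc) / d[:, None], shat_cov=V / d[0]
                              if np.allclose(d, d[0]) else V[None] / d[:, None, None])
        sep = single_effect_posterior(stats, prior, 0.5)
        np.testing.assert_allclose(fit.effects[0].alpha, sep.alpha, atol=1e-12)
        np.testing.assert_allclose(fit.effects[0].post_mean, sep.post_mean, atol=1e-12)

    def test_null_data_drives_scales_to_zero(self):
        J, R = 12, 2
        ss = mv.SufficientStats(xtx=100 * np.eye(J), xty=np.zeros((J, R)), n=100)
        fit = mv.fit_ss(ss, mv.canonical_prior(R), np.eye(R), mv.FitOptions(L=3))
        assert np.all(fit.scales < 1e-9)
        np.testing.assert_allclose(fit.b_bar, 0.0, atol=1e-12)
        for e in fit.effects:
            np.testing.assert_allclose(e.alpha, 1.0 / J, atol=1e-12)

    def test_strong_single_causal_concentrates_and_prunes(self):
        rng = np.random.default_rng(33)
        n, J = 2000, 50
        X = mv.simulate_genotypes(n, J, ld_decay=0.3, seed=5)
        Xs, _, _ = mv.center_standardize(X, True)
        b = np.zeros((J, 2))
        b[17] = [0.4, 0.3]
        Y = Xs @ b + rng.standard_normal((n, 2))
        fit = mv.fit_individual(X, Y, mv.canonical_prior(2), np.eye(2),
                                mv.FitOptions(L=2))
        active = fit.active_effects()
        assert len(active) == 1
        assert fit.effects[active[0]].alpha[17] > 0.95

    def test_row_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="rows"):
            mv.fit_individual(np.zeros((10, 3)), np.zeros((8, 2)),
                              mv.canonical_prior(2), np.eye(2))


class TestEstimatePriorScale:
    def test_noise_updates_decay_toward_zero(self):
        rng = np.random.default_rng(2)
        J, R = 40, 2
        v = 0.01
        bhat = rng.standard_normal((J, R)) * np.sqrt(v)   # pure noise at scale 0
        stats = MarginalStats(bhat=bhat, shat_cov=v * np.eye(R))
        prior = MixturePrior([np.eye(R)], [1.0])
        s = 1.0
        for _ in range(25):
            s = estimate_prior_scale(stats, prior, s)
        assert s < 0.05

    def test_em_fixed_point_matches_grid_search_1d(self):
        rng = np.random.default_rng(12)
        J = 25
        v = 0.05
        bhat = (rng.standard_normal(J) * np.sqrt(0.4 + v))[:, None]
        stats = MarginalStats(bhat=bhat, shat_cov=np.array([[v]]))
        prior = MixturePrior([np.array([[1.0]])], [1.0])
        s = 1.0
        for _ in range(400):
            s = estimate_prior_scale(stats, prior, s)

        def marg_loglik(s2):
            lbf = 0.5 * np.log(v / (s2 + v)) + bhat[:, 0]**2 * s2 / (2 * v * (s2 + v)) \
                if s2 > 0 else np.zeros(J)
            return logsumexp(np.log(1.0 / J) + lbf)

        grid = np.arange(1e-3, 2.0, 1e-3)
        best = grid[np.argmax([marg_loglik(g) for g in grid])]
        assert abs(s - best) <= 2e-3  # grid resolution

    def test_marginal_likelihood_monotone_under_em(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            J, R = rng.integers(5, 20), rng.integers(1, 4)
            K = rng.integers(1, 4)
            comps = []
            for _ in range(K):
                A = rng.standard_normal((R, rng.integers(1, R + 1)))
                comps.append(A @ A.T)
            w = rng.dirichlet(np.ones(K))
            prior = MixturePrior(comps, w)
            S = np.eye(R) * rng.uniform(0.02, 0.5)
            bhat = rng.standard_normal((J, R))
            stats = MarginalStats(bhat=bhat, shat_cov=S)

            def marg(s2):
                if s2 == 0:
                    return 0.0
                sep = single_effect_posterior(stats, prior, s2)
                return sep.logbf_model

            s = rng.uniform(0.2, 2.0)
            prev = marg(s)
            for _ in range(5):
                s = estimate_prior_scale(stats, prior, s)
                cur = marg(s)
                assert cur >= prev - 1e-9
                prev = cur


class TestElbo:
    def test_null_posterior_elbo_is_null_loglik(self):
        rng = np.random.default_rng(6)
        n, J, R = 50, 5, 2
        X = rng.standard_normal((n, J)); X -= X.mean(0)
        Y = rng.standard_normal((n, R)); Y -= Y.mean(0)
        V = np.cov(Y, rowvar=False)
        opts = mv.FitOptions(L=2, estimate_prior_scale=False, prior_scale_init=0.0,
                             max_iter=2)
        fit = mv.fit_individual(X, Y, prior=mv.canonical_prior(R), V=V, opts=opts)
        # null model: vec(Y) ~ N(0, V x I_n)
        expected = sum(
            mvn.logpdf(Y[i], mean=np.zeros(R), cov=V) for i in range(n))
        assert fit.elbo_trace[-1] == pytest.approx(expected, rel=1e-10)

    def test_L1_elbo_equals_exact_log_marginal(self):
        # with one effect the variational family contains the exact
        # posterior, so the bound must be tight
        rng = np.random.default_rng(5)
        n, J, R = 60, 4, 2
        X = rng.standard_normal((n, J)); X -= X.mean(0)
        Y = rng.standard_normal((n, R)); Y -= Y.mean(0)
        V = np.array([[1.0, 0.2], [0.2, 1.0]])
        prior = MixturePrior([np.eye(R), np.ones((R, R))], [0.6, 0.4])
        scale = 0.8
        opts = mv.FitOptions(L=1, estimate_prior_scale=False, prior_scale_init=scale,
                             max_iter=5)
        fit = mv.fit_individual(X, Y, prior, V, opts)
        yv = Y.T.ravel()
        base = np.kron(V, np.eye(n))
        lls = []
        for j in range(J):
            xx = np.outer(X[:, j], X[:, j])
            comps = [np.log(prior.weights[k]) +
                     mvn.logpdf(yv, cov=np.kron(scale * U, xx) + base, allow_singular=True)
                     for k, U in enumerate(prior.components)]
            lls.append(np.log(1.0 / J) + logsumexp(comps))
        assert fit.elbo_trace[-1] == pytest.approx(logsumexp(lls), abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_trace_nondecreasing_fixed_scales(self, seed):
        X, Y, _ = _make_data(seed + 200, n=150, J=12, R=2)
        V = np.cov(Y, rowvar=False)
        opts = mv.FitOptions(L=3, estimate_prior_scale=False, prior_scale_init=0.3,
                             max_iter=30)
        fit = mv.fit_individual(X, Y, mv.canonical_prior(2), V, opts)
        deltas = np.diff(fit.elbo_trace)
        assert np.all(deltas > -1e-6)

    def test_yty_only_shifts_elbo_by_constant(self):
        X, Y, _ = _make_data(3, n=120, J=8, R=2)
        Xc, _, _ = mv.center_standardize(X, False)
        Yc, _, _ = mv.center_standardize(Y, False)
        V = np.cov(Y, rowvar=False)
        opts = mv.FitOptions(L=2, max_iter=20)
        ss1 = mv.SufficientStats(xtx=Xc.T @ Xc, xty=Xc.T @ Yc, n=120, yty=Yc.T @ Yc)
        ss2 = mv.SufficientStats(xtx=Xc.T @ Xc, xty=Xc.T @ Yc, n=120)
        f1 = mv.fit_ss(ss1, mv.canonical_prior(2), V, opts)
        f2 = mv.fit_ss(ss2, mv.canonical_prior(2), V, opts)
        assert f1.elbo_has_constant and not f2.elbo_has_constant
        d1 = np.diff(f1.elbo_trace)
        d2 = np.diff(f2.elbo_trace)
        np.testing.assert_allclose(d1, d2, atol=1e-8)


class TestExhaustiveOracle:
    def test_pips_match_enumeration_of_configurations(self):
        # exact posterior by enumerating all (j1, j2) single-effect
        # placements and all component pairs, via dense Gaussian densities
        rng = np.random.default_rng(55)
        n, J, R, L = 80, 6, 2, 2
        X = mv.simulate_genotypes(n, J, ld_decay=0.4, seed=14)
        Xc, _, _ = mv.center_standardize(X, True)
        b = np.zeros((J, R)); b[1] = [0.8, 0.5]; b[4] = [-0.25, 0.2]
        Y = Xc @ b + rng.standard_normal((n, R)) * 0.8
        Y -= Y.mean(0)
        V = 0.64 * np.eye(R)
        prior = MixturePrior([np.eye(R), np.ones((R, R))], [0.5, 0.5])
        scale = 1.0

        yv = Y.T.ravel()
        base = np.kron(V, np.eye(n))
        K = prior.n_components
        logjoint = np.full((J, K, J, K), -np.inf)
        for j1 in range(J):
            for k1 in range(K):
                c1 = np.kron(scale * prior.components[k1], np.outer(Xc[:, j1], Xc[:, j1]))
                for j2 in range(J):
                    for k2 in range(K):
                        c2 = np.kron(scale * prior.components[k2],
                                     np.outer(Xc[:, j2], Xc[:, j2]))
                        logjoint[j1, k1, j2, k2] = (
                            np.log(prior.weights[k1]) + np.log(prior.weights[k2])
                            + mvn.logpdf(yv, cov=base + c1 + c2, allow_singular=True))
        flat = logjoint.reshape(J * K, J * K)
        post = np.exp(flat - logsumexp(flat))
        post /= post.sum()
        post_jj = post.reshape(J, K, J, K).sum(axis=(1, 3))
        # P(SNP j in neither effect)
        pip_exact = np.zeros(J)
        for j in range(J):
            mask = np.ones((J, J), dtype=bool)
            mask[j, :] = False
            mask[:, j] = False
            pip_exact[j] = 1.0 - post_jj[mask].sum()

        opts = mv.FitOptions(L=L, estimate_prior_scale=False, prior_scale_init=scale,
                             max_iter=200, tol=1e-8)
        fit = mv.fit_individual(X, Y, prior, V, opts, standardize=True)
        pip = mv.compute_pip(fit, prune_tol=-1.0)
        assert np.argmax(pip) == np.argmax(pip_exact)
        rank_corr = np.corrcoef(np.argsort(np.argsort(pip)),
                                np.argsort(np.argsort(pip_exact)))[0, 1]
        assert rank_corr > 0.99


class TestUnivariateSusieOracle:
    @staticmethod
    def _susie_1d(X, y, L, scale, max_iter=200, tol=1e-8):
        """Independently coded scalar SuSiE (fixed prior variance)."""
        n, J = X.shape
        X = X - X.mean(0)
        y = y - y.mean()
        d = (X**2).sum(0)
        sigma2 = float(np.var(y))
        alpha = np.full((L, J), 1.0 / J)
        mu = np.zeros((L, J))
        for _ in range(max_iter):
            alpha_old = alpha.copy()
            for l in range(L):
                r = y - X @ (alpha * mu).sum(0) + X @ (alpha[l] * mu[l])
                bhat = X.T @ r / d
                s2 = sigma2 / d
                post_var = 1.0 / (1.0 / scale + 1.0 / s2)
                mu[l] = post_var / s2 * bhat
                lbf = 0.5 * np.log(s2 / (scale + s2)) + bhat**2 * scale / (2 * s2 * (scale + s2))
                alpha[l] = np.exp(lbf - logsumexp(lbf))
                alpha[l] /= alpha[l].sum()
            if np.abs(alpha - alpha_old).max() < tol:
                break
        return 1.0 - np.prod(1.0 - alpha, axis=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_pipeline_matches_univariate_susie(self, seed):
        rng = np.random.default_rng(seed)
        n, J = 250, 15
        X = mv.simulate_genotypes(n, J, ld_decay=0.5, seed=seed + 77)
        Xc, _, _ = mv.center_standardize(X, True)
        b = np.zeros(J); b[rng.integers(J)] = 0.5
        y = Xc @ b + rng.standard_normal(n)
        y -= y.mean()
        sigma2 = float(np.var(y))
        scale = 0.2 / sigma2 * sigma2  # prior variance on the raw-effect scale
        pip_oracle = self._susie_1d(Xc, y, L=2, scale=0.2)

        prior = MixturePrior([np.array([[1.0]])], [1.0])
        opts = mv.FitOptions(L=2, estimate_prior_scale=False, prior_scale_init=0.2,
                             max_iter=200, tol=1e-10)
        fit = mv.fit_individual(Xc, y[:, None], prior, np.array([[sigma2]]), opts)
        pip = mv.compute_pip(fit, prune_tol=-1.0)
        np.testing.assert_allclose(pip, pip_oracle, atol=1e-6)


class TestArd:
    def test_few_effects_survive_with_L10(self):
        # with S true causal SNPs and L = 10, at most S + 1 effects stay
        # active in at least 90% of seeded replicates
        ok = 0
        reps = 50
        for seed in range(reps):
            X, Y, truth = _make_data(seed + 600, n=400, J=40, R=2, pve=0.05)
            V = np.cov(Y, rowvar=False)
            fit = mv.fit_individual(X, Y, mv.canonical_prior(2), V, mv.FitOptions(L=10))
            S = truth.causal_indices.size
            if len(fit.active_effects()) <= S + 1:
                ok += 1
        assert ok / reps >= 0.9
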