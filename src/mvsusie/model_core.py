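"""Exact Bayesian computations for one "single effect".

A single effect assigns a multivariate regression coefficient b in R^R to
exactly one of J SNPs. Given per-SNP least-squares summaries (bhat_j, S_j)
the model is conjugate under a mixture-of-multivariate-normals prior

    b | gamma_j = 1  ~  sum_k  omega_k N(0, sigma0^2 U_k),

so per-SNP, per-component Bayes factors, posterior moments, SNP inclusion
probabilities and conditional local false sign rates (clfsr) all have closed
forms. Everything here is log-space and "singular safe": the prior patterns
U_k may be singular (rank-1 trait-specific patterns, the all-ones equal-
effects pattern) and are never inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp, ndtr

__all__ = [
    "MixturePrior",
    "MarginalStats",
    "SingleEffectPosterior",
    "component_posterior",
    "single_effect_posterior",
    "conditional_lfsr",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixturePrior:
    """Effect-sharing prior: covariance patterns ``U_k``, weights ``omega``.

    Parameters
    ----------
    components
        List of K symmetric PSD matrices of shape (R, R). These are unitless
        *patterns*; the overall magnitude of each single effect is carried by
        a per-effect scale sigma0l^2.
    weights
        Mixture weights on the probability simplex, length K.
    scales
        Optional per-single-effect scales sigma0l^2 >= 0 (length L). When
        None the fitting loop initialises them itself.
    epsilon
        Diagonal regularizer that was added to the components (recorded for
        serialization; 0 means none was applied).
    """

    components: list
    weights: np.ndarray
    scales: np.ndarray | None = None
    epsilon: float = 0.0

    def __post_init__(self):
        self.components = [np.asarray(U, dtype=float) for U in self.components]
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.components) < 1:
            raise ValueError("mixture prior needs at least one component")
        R = self.components[0].shape[0]
        for k, U in enumerate(self.components):
            if U.shape != (R, R):
                raise ValueError(f"component {k} has shape {U.shape}, expected ({R}, {R})")
            if not np.allclose(U, U.T, atol=1e-8):
                raise ValueError(f"component {k} is not symmetric")
            w = np.linalg.eigvalsh((U + U.T) / 2)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValueError(f"component {k} is not positive semi-definite")
        if self.weights.shape != (len(self.components),):
            raise ValueError("weights length must match number of components")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must lie on the probability simplex")
        if self.scales is not None:
            self.scales = np.asarray(self.scales, dtype=float)
            if np.any(self.scales < 0):
                raise ValueError("prior scales must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_traits(self) -> int:
        return self.components[0].shape[0]

    def _pinv_rank(self):
        """Cached (pseudo-inverse, rank) per component, for the EM scale step."""
        cached = getattr(self, "_pinv_rank_cache", None)
        if cached is None:
            cached = [
                (np.linalg.pinv(U, hermitian=True),
                 int(np.linalg.matrix_rank(U, hermitian=True)))
                for U in self.components
            ]
            object.__setattr__(self, "_pinv_rank_cache", cached)
        return cached


@dataclass
class MarginalStats:
    """Per-SNP multivariate least-squares summaries on current residuals.

    ``bhat`` is J x R; ``shat_cov`` is the sampling covariance of bhat_j,
    either one shared (R, R) matrix (standardized X: V / N for every SNP) or
    a (J, R, R) stack. ``prior_inclusion`` is the prior pi on the J SNPs.
    """

    bhat: np.ndarray
    shat_cov: np.ndarray
    prior_inclusion: np.ndarray | None = None

    def __post_init__(self):
        self.bhat = np.atleast_2d(np.asarray(self.bhat, dtype=float))
        self.shat_cov = np.asarray(self.shat_cov, dtype=float)
        J = self.bhat.shape[0]
        if self.prior_inclusion is None:
            self.prior_inclusion = np.full(J, 1.0 / J)
        else:
            self.prior_inclusion = np.asarray(self.prior_inclusion, dtype=float)
            if abs(self.prior_inclusion.sum() - 1.0) > 1e-8:
                raise ValueError("prior inclusion probabilities must sum to 1")

    @property
    def n_snps(self) -> int:
        return self.bhat.shape[0]

    @property
    def n_traits(self) -> int:
        return self.bhat.shape[1]

    @property
    def shared_cov(self) -> bool:
        return self.shat_cov.ndim == 2

    def cov_for(self, j: int) -> np.ndarray:
        return self.shat_cov if self.shared_cov else self.shat_cov[j]


@dataclass
class SingleEffectPosterior:
    """Posterior of one single effect over J SNPs under the mixture prior."""

    alpha: np.ndarray          # (J,) inclusion probabilities, sums to 1
    logbf: np.ndarray          # (J,) per-SNP log Bayes factors (mixture)
    comp_weights: np.ndarray   # (J, K) component posteriors given inclusion
    post_mean: np.ndarray      # (J, R) E[b_j | gamma_j = 1]
    post_mean2: np.ndarray     # (J, R) E[b_jr^2 | gamma_j = 1]
    post_cov: np.ndarray       # (J, R, R) mixture-collapsed Cov[b_j | gamma_j=1]
    clfsr: np.ndarray          # (J, R) conditional local false sign rates
    scale: float
    # per-component conditional moments, kept for the EM scale update
    comp_means: np.ndarray = field(repr=False, default=None)  # (J, K, R)
    comp_covs: np.ndarray = field(repr=False, default=None)   # (J, K, R, R)
    # KL(q_l || prior_l), evaluated at construction time when the posterior
    # is exact for its residual data (the identity used is only valid then)
    kl: float = field(repr=False, default=0.0)

    @property
    def logbf_model(self) -> float:
        """log BF of "some SNP has an effect" vs the null, under pi."""
        return float(self._logbf_model)

    _logbf_model: float = field(repr=False, default=0.0)


def _check_spd(S: np.ndarray, j: int):
    try:
        return cho_factor(S, lower=True, check_finite=False)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"sampling covariance for SNP index {j} is not positive definite") from e


def component_posterior(bhat_j, S_j, U_k, scale):
    """Conjugate update for one SNP under one prior component.

    Returns ``(logbf, mean, cov)`` where

    - logbf = log N(bhat; 0, scale*U + S) - log N(bhat; 0, S)
    - mean  = scale*U (scale*U + S)^-1 bhat
    - cov   = scale*U (scale*U + S)^-1 S

    The ``scale*U (scale*U + S)^-1`` form never inverts U, so singular
    patterns (rank-1, all-ones) are handled exactly.
    """
    bhat_j = np.asarray(bhat_j, dtype=float).ravel()
    S_j = np.asarray(S_j, dtype=float)
    U_k = np.asarray(U_k, dtype=float)
    if scale < 0:
        raise ValueError("prior scale must be non-negative")
    R = bhat_j.shape[0]
    _check_spd(S_j, 0)
    if scale == 0:
        return 0.0, np.zeros(R), np.zeros((R, R))
    P = scale * U_k
    T = P + S_j
    cT = _check_spd(T, 0)
    cS = cho_factor(S_j, lower=True)
    logdet_T = 2.0 * np.sum(np.log(np.diag(cT[0])))
    logdet_S = 2.0 * np.sum(np.log(np.diag(cS[0])))
    Tib = cho_solve(cT, bhat_j)
    Sib = cho_solve(cS, bhat_j)
    logbf = -0.5 * (logdet_T - logdet_S) - 0.5 * (bhat_j @ Tib - bhat_j @ Sib)
    mean = P @ Tib
    cov = P @ cho_solve(cT, S_j)
    cov = (cov + cov.T) / 2.0
    return float(logbf), mean, cov


def _batched_component_stats(stats: MarginalStats, prior: MixturePrior, scale: float):
    """Per-SNP, per-component (logbf, mean, cov) for all J x K at once.

    Returns ``lbf (J,K)``, ``means (J,K,R)``, ``covs``, ``Sinv_bhat (J,R)``
    (S_j^-1 bhat_j) and ``Sinv``. When the sampling covariance is shared
    across SNPs the per-component posterior covariances are too, so ``covs``
    is (K,R,R) and ``Sinv`` is (R,R); otherwise (J,K,R,R) and (J,R,R).
    """
    J, R = stats.bhat.shape
    K = prior.n_components
    bhat = stats.bhat
    lbf = np.zeros((J, K))
    means = np.zeros((J, K, R))
    if scale == 0:
        return lbf, means, np.zeros((K, R, R)), None, None

    if stats.shared_cov:
        S = stats.shat_cov
        covs = np.zeros((K, R, R))
        cS = _check_spd(S, 0)
        logdet_S = 2.0 * np.sum(np.log(np.diag(cS[0])))
        Sinv = cho_solve(cS, np.eye(R), check_finite=False)
        Sib = cho_solve(cS, bhat.T, check_finite=False)      # (R, J)
        quad0 = np.einsum("jr,rj->j", bhat, Sib)
        for k, U in enumerate(prior.components):
            P = scale * U
            T = P + S
            cT = _check_spd(T, 0)
            logdet_T = 2.0 * np.sum(np.log(np.diag(cT[0])))
            Tib = cho_solve(cT, bhat.T, check_finite=False)  # (R, J)
            quad = np.einsum("jr,rj->j", bhat, Tib)
            lbf[:, k] = -0.5 * (logdet_T - logdet_S) - 0.5 * (quad - quad0)
            means[:, k, :] = (P @ Tib).T
            C = P @ cho_solve(cT, S, check_finite=False)
            covs[k] = (C + C.T) / 2.0
        sinv_bhat = Sib.T
    else:
        S = stats.shat_cov                        # (J, R, R)
        covs = np.zeros((J, K, R, R))
        sign0, logdet_S = np.linalg.slogdet(S)
        if np.any(sign0 <= 0):
            bad = int(np.argmax(sign0 <= 0))
            raise ValueError(f"sampling covariance for SNP index {bad} is not positive definite")
        Sinv = np.linalg.inv(S)
        Sib = np.linalg.solve(S, bhat[:, :, None])[:, :, 0]
        quad0 = np.einsum("jr,jr->j", bhat, Sib)
        for k, U in enumerate(prior.components):
            P = scale * U
            T = P[None, :, :] + S
            sign, logdet_T = np.linalg.slogdet(T)
            if np.any(sign <= 0):
                bad = int(np.argmax(sign <= 0))
                raise ValueError(f"prior+sampling covariance for SNP index {bad} is singular")
            Tib = np.linalg.solve(T, bhat[:, :, None])[:, :, 0]
            quad = np.einsum("jr,jr->j", bhat, Tib)
            lbf[:, k] = -0.5 * (logdet_T - logdet_S) - 0.5 * (quad - quad0)
            means[:, k, :] = np.einsum("rs,js->jr", P, Tib)
            C = np.einsum("rs,jst->jrt", P, np.linalg.solve(T, S))
            covs[:, k, :, :] = (C + np.swapaxes(C, -1, -2)) / 2.0
        sinv_bhat = Sib
    return lbf, means, covs, sinv_bhat, Sinv


def single_effect_posterior(stats: MarginalStats, prior: MixturePrior, scale: float,
                            compute_clfsr: bool = True) -> SingleEffectPosterior:
    """Full posterior for one single effect: alpha, moments, clfsr.

    Per SNP j: lbf_jk from :func:`component_posterior`; the SNP-level log
    Bayes factor is logsumexp_k(log omega_k + lbf_jk); inclusion
    probabilities alpha_j are proportional to pi_j exp(logbf_j) (normalised
    in log space); component weights and mixture-collapsed moments follow
    the law of total variance.
    """
    if scale < 0:
        raise ValueError("prior scale must be non-negative")
    J, R = stats.bhat.shape
    K = prior.n_components
    lbf, means, covs, sinv_bhat, Sinv = _batched_component_stats(stats, prior, scale)

    logw = np.log(prior.weights + np.finfo(float).tiny)
    lw = lbf + logw[None, :]
    lw_max = lw.max(axis=1, keepdims=True)
    lw_exp = np.exp(lw - lw_max)
    lw_sum = lw_exp.sum(axis=1)
    lbf_mix = lw_max[:, 0] + np.log(lw_sum)                  # (J,)
    if not np.any(np.isfinite(lbf_mix)):
        raise ValueError("all per-SNP log Bayes factors are -inf; degenerate input")

    logpi = np.full(J, -np.inf)
    pos = stats.prior_inclusion > 0
    logpi[pos] = np.log(stats.prior_inclusion[pos])
    logpost = logpi + lbf_mix
    logbf_model = logsumexp(logpost)
    alpha = np.exp(logpost - logbf_model)
    alpha /= alpha.sum()

    # posterior component weights given inclusion
    comp_weights = lw_exp / lw_sum[:, None]

    post_mean = np.einsum("jk,jkr->jr", comp_weights, means)
    if covs.ndim == 3:        # shared across SNPs: covs is (K, R, R)
        var_diag = np.einsum("krr->kr", covs)[None, :, :]
        cov_mix = np.einsum("jk,krs->jrs", comp_weights, covs)
    else:
        var_diag = np.einsum("jkrr->jkr", covs)
        cov_mix = np.einsum("jk,jkrs->jrs", comp_weights, covs)
    post_mean2 = np.einsum("jk,jkr->jr", comp_weights, means**2 + var_diag)
    post_cov = cov_mix + np.einsum("jk,jkr,jks->jrs", comp_weights, means, means) \
        - np.einsum("jr,js->jrs", post_mean, post_mean)

    # KL(q || prior) via the residual-likelihood identity, exact here
    # because q is the exact single-effect posterior for `stats`:
    # KL = sum_j a_j [ m_j' S_j^-1 bhat_j - 0.5 tr(S_j^-1 E[bb'|j]) ] - logBF
    if scale == 0:
        kl = 0.0
    else:
        Ebb = post_cov + np.einsum("jr,js->jrs", post_mean, post_mean)
        t1 = np.einsum("jr,jr->j", post_mean, sinv_bhat)
        if Sinv.ndim == 2:
            t2 = np.einsum("rs,jsr->j", Sinv, Ebb)
        else:
            t2 = np.einsum("jrs,jsr->j", Sinv, Ebb)
        kl = float(alpha @ (t1 - 0.5 * t2) - logbf_model)

    sep = SingleEffectPosterior(
        alpha=alpha, logbf=lbf_mix, comp_weights=comp_weights,
        post_mean=post_mean, post_mean2=post_mean2, post_cov=post_cov,
        clfsr=None, scale=float(scale), kl=kl,
        comp_means=means, comp_covs=covs,
    )
    sep._logbf_model = float(logbf_model)
    if compute_clfsr:
        sep.clfsr = conditional_lfsr(sep, prior)
    return sep


def conditional_lfsr(sep: SingleEffectPosterior, prior: MixturePrior) -> np.ndarray:
    """Conditional local false sign rate per SNP and trait.

    clfsr_jr = 1 - max(Pr(b_jr > 0 | gamma_j = 1), Pr(b_jr < 0 | gamma_j = 1)),
    mixing per-component Gaussian tail probabilities over the posterior
    component weights. A component with exactly zero posterior variance in
    trait r contributes a point mass at its (then necessarily zero) mean,
    counted toward neither sign.
    """
    means = sep.comp_means                       # (J, K, R)
    if sep.comp_covs.ndim == 3:                  # shared (K, R, R)
        vars_ = np.broadcast_to(np.einsum("krr->kr", sep.comp_covs)[None, :, :], means.shape)
    else:
        vars_ = np.einsum("jkrr->jkr", sep.comp_covs)
    vars_ = np.maximum(vars_, 0.0)
    w = sep.comp_weights                         # (J, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        zpos = np.where(vars_ > 0, means / np.sqrt(np.where(vars_ > 0, vars_, 1.0)), 0.0)
    phi = ndtr(zpos)                             # Pr(b > 0) per component when var > 0
    p_pos_k = np.where(vars_ > 0, phi, np.where(means > 0, 1.0, 0.0))
    p_neg_k = np.where(vars_ > 0, 1.0 - phi, np.where(means < 0, 1.0, 0.0))
    p_pos = np.einsum("jk,jkr->jr", w, p_pos_k)
    p_neg = np.einsum("jk,jkr->jr", w, p_neg_k)
    clfsr = 1.0 - np.maximum(p_pos, p_neg)
    return np.clip(clfsr, 0.0, 1.0)
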