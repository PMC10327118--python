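"""Iterative Bayesian Stepwise Selection for the multivariate SuSiE model.

The model is Y = X B + E with matrix-normal noise (row covariance I_N,
column covariance V) and B a sum of L "single effects", each placing a
multivariate coefficient on exactly one SNP. The fit is coordinate ascent on
a variational bound (ELBO): each sweep residualises out the other L-1
effects, computes the exact single-effect posterior via
:mod:`mvsusie.model_core`, and optionally takes one EM step on the
per-effect prior scale sigma0l^2 (automatic relevance determination - scales
driven to ~0 prune unneeded effects).

Both the individual-data fit and the sufficient-statistics fit ("IBSS-ss")
live here; they are algebraically identical because the likelihood depends
on the data only through X'X, X'Y (and Y'Y for the ELBO constant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model_core import (
    MarginalStats,
    MixturePrior,
    SingleEffectPosterior,
    single_effect_posterior,
)

__all__ = [
    "SufficientStats",
    "FitOptions",
    "MvSusieFit",
    "center_standardize",
    "fit_ss",
    "fit_individual",
    "estimate_prior_scale",
    "compute_elbo",
]

logger = logging.getLogger("mvsusie")

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SufficientStats:
    """X'X, X'Y and N; optionally Y'Y for an absolute-scale ELBO."""

    xtx: np.ndarray
    xty: np.ndarray
    n: float
    yty: np.ndarray | None = None
    diag_xtx: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.xtx = np.asarray(self.xtx, dtype=float)
        self.xty = np.atleast_2d(np.asarray(self.xty, dtype=float))
        if self.xtx.shape[0] != self.xtx.shape[1]:
            raise ValueError("xtx must be square")
        if not np.allclose(self.xtx, self.xtx.T, atol=1e-6 * max(1.0, np.abs(self.xtx).max())):
            raise ValueError("xtx is not symmetric")
        self.xtx = (self.xtx + self.xtx.T) / 2.0
        if self.xty.shape[0] != self.xtx.shape[0]:
            raise ValueError(
                f"xty has {self.xty.shape[0]} rows but xtx is {self.xtx.shape[0]}x{self.xtx.shape[0]}"
            )
        if self.n < 2:
            raise ValueError("sample size n must be at least 2")
        self.diag_xtx = np.diag(self.xtx).copy()
        if np.any(self.diag_xtx <= 0):
            bad = np.flatnonzero(self.diag_xtx <= 0)
            raise ValueError(f"xtx has non-positive diagonal at SNP indices {bad.tolist()}")
        if self.yty is not None:
            self.yty = np.asarray(self.yty, dtype=float)
            if not np.allclose(self.yty, self.yty.T, atol=1e-8):
                raise ValueError("yty is not symmetric")

    @property
    def n_snps(self) -> int:
        return self.xtx.shape[0]

    @property
    def n_traits(self) -> int:
        return self.xty.shape[1]


@dataclass
class FitOptions:
    """Fitting knobs; defaults follow standard SuSiE practice."""

    L: int = 10
    max_iter: int = 1000
    tol: float = 1e-3
    estimate_prior_scale: bool = True
    prior_scale_init: float = 1.0
    prune_tol: float = 1e-9
    seed: int | None = None  # reserved; the sweeps are deterministic

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class MvSusieFit:
    """Result of an IBSS run: L single-effect posteriors plus bookkeeping."""

    effects: list          # L SingleEffectPosterior
    prior: MixturePrior    # with fitted per-effect scales
    resid_cov: np.ndarray  # V (fixed during fitting)
    pi: np.ndarray
    elbo_trace: list
    converged: bool
    niter: int
    b_bar: np.ndarray      # (J, R) overall posterior mean sum_l alpha*mean
    elbo_has_constant: bool = True   # False when yty was unavailable
    snp_ids: list | None = None
    trait_ids: list | None = None

    @property
    def scales(self) -> np.ndarray:
        return np.array([e.scale for e in self.effects])

    def active_effects(self, prune_tol: float = 1e-9) -> list:
        return [l for l, e in enumerate(self.effects) if e.scale > prune_tol]

    @property
    def alpha(self) -> np.ndarray:
        """(L, J) inclusion-probability matrix."""
        return np.array([e.alpha for e in self.effects])


def center_standardize(M: np.ndarray, standardize: bool = True):
    """Column-center (and optionally scale to unit variance, divisor N).

    Returns ``(matrix, means, sds)``. With ``standardize`` the columns
    satisfy sum(x^2) = N, matching the standardized-data convention used by
    the z-score pathway. Zero-variance columns raise when scaling is
    requested.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-d matrix with at least 2 rows")
    means = M.mean(axis=0)
    out = M - means
    sds = np.sqrt((out**2).mean(axis=0))
    if standardize:
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            raise ValueError(f"zero-variance columns cannot be standardized: {zero.tolist()}")
        out = out / sds
    return out, means, sds


def _marginal_stats(xtr: np.ndarray, diag_xtx: np.ndarray, V: np.ndarray,
                    pi: np.ndarray) -> MarginalStats:
    """Least-squares summaries for the current residual cross-products."""
    bhat = xtr / diag_xtx[:, None]
    d0 = diag_xtx[0]
    if np.allclose(diag_xtx, d0, rtol=1e-12, atol=0.0):
        shat = V / d0                      # shared across SNPs (standardized X)
    else:
        shat = V[None, :, :] / diag_xtx[:, None, None]
    return MarginalStats(bhat=bhat, shat_cov=shat, prior_inclusion=pi)


def estimate_prior_scale(stats: MarginalStats, prior: MixturePrior,
                         current_scale: float) -> float:
    """One EM update of the single-effect prior scale sigma0l^2.

    E-step: inclusion probabilities alpha and component posteriors at the
    current scale. M-step:

        sigma^2 <- sum_{j,k} q_jk E[b' U_k^+ b | j,k] / sum_{j,k} q_jk rank(U_k)

    with q_jk = alpha_j * w_jk and pseudo-inverses for singular patterns.
    Returns max(update, 0); degenerate input yields 0.
    """
    if current_scale < 0:
        raise ValueError("current_scale must be non-negative")
    if current_scale == 0:
        return 0.0
    sep = single_effect_posterior(stats, prior, current_scale, compute_clfsr=False)
    num = 0.0
    den = 0.0
    pinv_rank = prior._pinv_rank()
    for k in range(prior.n_components):
        Upinv, rank = pinv_rank[k]
        if rank == 0:
            continue
        q = sep.alpha * sep.comp_weights[:, k]            # (J,)
        m = sep.comp_means[:, k, :]                       # (J, R)
        e_quad = np.einsum("jr,rs,js->j", m, Upinv, m)
        if sep.comp_covs.ndim == 3:                       # shared (K, R, R)
            e_quad = e_quad + float(np.einsum("rs,sr->", Upinv, sep.comp_covs[k]))
        else:
            e_quad = e_quad + np.einsum("rs,jsr->j", Upinv, sep.comp_covs[:, k])
        num += float(q @ e_quad)
        den += float(q.sum() * rank)
    if den <= 0 or not np.isfinite(num):
        return 0.0
    return max(num / den, 0.0)


def _null_sep(J: int, R: int, K: int, pi: np.ndarray) -> SingleEffectPosterior:
    """Zero-scale placeholder posterior used to initialise the sweep."""
    return SingleEffectPosterior(
        alpha=pi.copy(), logbf=np.zeros(J),
        comp_weights=np.full((J, K), 1.0 / K),
        post_mean=np.zeros((J, R)), post_mean2=np.zeros((J, R)),
        post_cov=np.zeros((J, R, R)), clfsr=np.full((J, R), 1.0),
        scale=0.0,
        comp_means=np.zeros((J, K, R)), comp_covs=np.zeros((K, R, R)),
    )


def compute_elbo(fit: MvSusieFit, ss: SufficientStats) -> float:
    """Evidence lower bound of the current variational posterior.

    ELBO = E_q[log p(Y | X, B)] - sum_l KL(q_l || prior_l), expanded through
    tr(V^-1 ...) so only the sufficient statistics are needed. The per-effect
    KL is an intrinsic functional of (q_l, prior_l) and is taken from the
    value stored when q_l was last refreshed. When Y'Y is absent the
    data-only constant tr(V^-1 Y'Y) is replaced by 0 and the value is an
    ELBO up to an additive constant (flagged on the fit).
    """
    V = fit.resid_cov
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise ValueError("residual covariance V is not positive definite")
    Vinv = np.linalg.inv(V)
    J, R = ss.n_snps, ss.n_traits
    n = ss.n
    d = ss.diag_xtx

    mu1 = [e.alpha[:, None] * e.post_mean for e in fit.effects]   # (J, R) each
    b_bar = sum(mu1) if fit.effects else np.zeros((J, R))

    # E[B' X'X B] = Bbar' X Bbar - sum_l Bbar_l' X Bbar_l + sum_l sum_j a_j d_j E[bb'|j]
    EBXXB = b_bar.T @ ss.xtx @ b_bar
    kl_total = 0.0
    for e, m1 in zip(fit.effects, mu1):
        EBXXB -= m1.T @ ss.xtx @ m1
        Ebb = e.post_cov + np.einsum("jr,js->jrs", e.post_mean, e.post_mean)
        wEbb = np.einsum("j,jrs->rs", e.alpha * d, Ebb)
        EBXXB += wEbb
        kl_total += e.kl

    tr_yty = float(np.einsum("rs,sr->", Vinv, ss.yty)) if ss.yty is not None else 0.0
    exp_loglik = (
        -0.5 * n * R * _LOG2PI
        - 0.5 * n * logdetV
        - 0.5 * (tr_yty - 2.0 * float(np.einsum("rs,sr->", Vinv, b_bar.T @ ss.xty))
                 + float(np.einsum("rs,sr->", Vinv, EBXXB)))
    )
    return exp_loglik - kl_total


def fit_ss(ss: SufficientStats, prior: MixturePrior, V: np.ndarray,
           opts: FitOptions | None = None, pi: np.ndarray | None = None,
           snp_ids=None, trait_ids=None) -> MvSusieFit:
    """Fit the model from sufficient statistics (the IBSS-ss algorithm).

    Coordinate ascent over the L single effects: residualise, form marginal
    stats (bhat_j = xtr_j / d_j, S_j = V / d_j), EM-update the prior scale,
    refresh the single-effect posterior. Stops when the ELBO changes by
    less than ``opts.tol`` between sweeps.
    """
    opts = opts or FitOptions()
    V = np.asarray(V, dtype=float)
    R = ss.n_traits
    J = ss.n_snps
    if V.shape != (R, R):
        raise ValueError(f"V has shape {V.shape}, expected ({R}, {R})")
    if prior.n_traits != R:
        raise ValueError(f"prior is for {prior.n_traits} traits, data has {R}")
    ev = np.linalg.eigvalsh((V + V.T) / 2)
    if ev.min() <= 0:
        if ev.min() > -1e-10 * max(1.0, ev.max()):
            warnings.warn("residual covariance V has tiny negative eigenvalues; clipping at 1e-10")
            w, Q = np.linalg.eigh((V + V.T) / 2)
            V = (Q * np.maximum(w, 1e-10)) @ Q.T
        else:
            raise ValueError("residual covariance V is not positive definite")
    if pi is None:
        pi = np.full(J, 1.0 / J)
    else:
        pi = np.asarray(pi, dtype=float)

    L = opts.L
    K = prior.n_components
    if prior.scales is not None and len(prior.scales) >= L:
        scales = np.asarray(prior.scales[:L], dtype=float).copy()
    else:
        scales = np.full(L, float(opts.prior_scale_init))

    effects = [_null_sep(J, R, K, pi) for _ in range(L)]
    b_bar = np.zeros((J, R))
    elbo_trace: list[float] = []
    converged = False
    niter = 0

    fitted_prior = MixturePrior(
        components=[U.copy() for U in prior.components],
        weights=prior.weights.copy(), scales=scales, epsilon=prior.epsilon,
    )
    fit = MvSusieFit(
        effects=effects, prior=fitted_prior, resid_cov=V, pi=pi,
        elbo_trace=elbo_trace, converged=False, niter=0, b_bar=b_bar,
        elbo_has_constant=ss.yty is not None,
        snp_ids=snp_ids, trait_ids=trait_ids,
    )

    for it in range(1, opts.max_iter + 1):
        for l in range(L):
            m1_old = effects[l].alpha[:, None] * effects[l].post_mean
            xtr = ss.xty - ss.xtx @ (b_bar - m1_old)
            stats = _marginal_stats(xtr, ss.diag_xtx, V, pi)
            if opts.estimate_prior_scale:
                scales[l] = estimate_prior_scale(stats, fitted_prior, scales[l])
            if scales[l] > 0:
                effects[l] = single_effect_posterior(stats, fitted_prior, scales[l],
                                                     compute_clfsr=False)
                # null check (ARD): if the single-effect evidence at the
                # updated scale does not beat the null model, zero the scale
                # -- this is itself an ELBO-ascent move and prunes unneeded
                # effects instead of letting their scales creep toward 0.
                if opts.estimate_prior_scale and effects[l].logbf_model <= 0.0:
                    scales[l] = 0.0
                    effects[l] = _null_sep(J, R, K, pi)
            else:
                effects[l] = _null_sep(J, R, K, pi)
            b_bar = b_bar - m1_old + effects[l].alpha[:, None] * effects[l].post_mean
        fitted_prior.scales = scales
        fit.effects = effects
        fit.b_bar = b_bar
        elbo = compute_elbo(fit, ss)
        if not np.isfinite(elbo):
            raise RuntimeError(f"non-finite ELBO at iteration {it}")
        elbo_trace.append(elbo)
        niter = it
        if it > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < opts.tol:
            converged = True
            break
        if it % 10 == 0:
            logger.info("sweep %d: ELBO = %.6f", it, elbo)

    if not converged:
        logger.warning("IBSS did not converge in %d sweeps (last ELBO change %.3g)",
                       niter, abs(elbo_trace[-1] - elbo_trace[-2]) if len(elbo_trace) > 1 else np.nan)
    # clfsr depends only on the stored per-component moments; fill it once
    from .model_core import conditional_lfsr
    for e in effects:
        if e.clfsr is None:
            e.clfsr = conditional_lfsr(e, fitted_prior)
    fit.converged = converged
    fit.niter = niter
    return fit


def fit_individual(X: np.ndarray, Y: np.ndarray, prior: MixturePrior,
                   V: np.ndarray, opts: FitOptions | None = None,
                   standardize: bool = False, pi: np.ndarray | None = None,
                   snp_ids=None, trait_ids=None) -> MvSusieFit:
    """Fit from individual-level data by reduction to sufficient statistics.

    Centers X and Y (optionally standardizes), forms X'X, X'Y, Y'Y and
    delegates to :func:`fit_ss`; the result is identical by construction
    because the likelihood depends on the data only through these
    cross-products.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] != X.shape[0]:
        if Y.shape == (1, X.shape[0]):  # a 1-d trait vector
            Y = Y.T
        else:
            raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    Xc, _, _ = center_standardize(X, standardize=standardize)
    Yc, _, _ = center_standardize(Y, standardize=standardize)
    ss = SufficientStats(xtx=Xc.T @ Xc, xty=Xc.T @ Yc, n=X.shape[0], yty=Yc.T @ Yc)
    return fit_ss(ss, prior, V, opts, pi=pi, snp_ids=snp_ids, trait_ids=trait_ids)
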