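"""Construction of the effect-sharing prior and the residual covariance.

Two prior families are provided. The *canonical* prior is a fixed library
of R x R sharing patterns (independent effects, equal effects, trait-
specific effects, uniformly heterogeneous effects) with uniform weights.
The *data-driven* prior learns patterns from the strongest association
signal in each fine-mapping region: initial covariance estimates come from
the empirical covariance and a truncated SVD of the matrix of top z-scores,
then Extreme Deconvolution (an EM algorithm for a mixture of multivariate
normals observed with noise V) refines the patterns and estimates the
mixture weights. The residual covariance V itself is estimated from the
weakest signals: z-score rows whose largest entry magnitude is below a
threshold are treated as null draws from N(0, V).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_core import MixturePrior

__all__ = [
    "TopZMatrix",
    "canonical_prior",
    "collect_top_z",
    "init_datadriven_covs",
    "extreme_deconvolution",
    "regularize_covs",
    "estimate_residual_cov",
    "data_driven_prior",
]

logger = logging.getLogger("mvsusie")

DEFAULT_HET_GRID = (0.25, 0.5, 0.75)


@dataclass
class TopZMatrix:
    """One row per fine-mapping region: the z-score vector of the SNP with
    the largest |z| over all traits in that region (M x R)."""

    z_top: np.ndarray
    region_ids: list | None = None

    def __post_init__(self):
        self.z_top = np.atleast_2d(np.asarray(self.z_top, dtype=float))
        if self.z_top.shape[0] < 1:
            raise ValueError("need at least one region")
        if not np.all(np.isfinite(self.z_top)):
            raise ValueError("top z-scores must be finite")

    @property
    def n_regions(self) -> int:
        return self.z_top.shape[0]

    @property
    def n_traits(self) -> int:
        return self.z_top.shape[1]


def canonical_prior(R: int, het_grid=DEFAULT_HET_GRID, scales=None) -> MixturePrior:
    """The canonical library of sharing patterns with uniform weights.

    Components, in order: the identity (independent effects); the all-ones
    equal-effects matrix; R rank-1 trait-specific patterns e_r e_r'; one
    pattern per heterogeneity level sigma in ``het_grid`` with ones on the
    diagonal and sigma off it. K = R + 2 + len(het_grid), which is R + 5
    at the default grid.
    """
    if R < 1:
        raise ValueError("trait count R must be at least 1")
    comps = [np.eye(R), np.ones((R, R))]
    for r in range(R):
        U = np.zeros((R, R))
        U[r, r] = 1.0
        comps.append(U)
    for s in het_grid:
        U = np.full((R, R), float(s))
        np.fill_diagonal(U, 1.0)
        if R > 1 and not (-1.0 / (R - 1) < s < 1.0):
            raise ValueError(
                f"heterogeneity {s} outside (-1/(R-1), 1) gives a non-PSD pattern for R={R}"
            )
        comps.append(U)
    K = len(comps)
    return MixturePrior(components=comps, weights=np.full(K, 1.0 / K), scales=scales)


def collect_top_z(regions) -> TopZMatrix:
    """Per region, pick the z-row of the SNP maximizing max_r |z_jr|.

    Ties are broken by the lowest SNP index.
    """
    if len(regions) == 0:
        raise ValueError("need at least one region")
    rows = []
    for m, zr in enumerate(regions):
        zr = np.atleast_2d(np.asarray(zr, dtype=float))
        if zr.shape[0] == 0:
            raise ValueError(f"region {m} is empty")
        j = int(np.argmax(np.abs(zr).max(axis=1)))  # argmax takes the first max
        rows.append(zr[j])
    return TopZMatrix(z_top=np.array(rows))


def init_datadriven_covs(topz: TopZMatrix, rank3: bool = True,
                         factor_backend=None, het_grid=DEFAULT_HET_GRID) -> list:
    """Initial covariance estimates for the data-driven prior.

    In order: the R + 5 canonical patterns; the empirical covariance
    Z'Z / M; up to three rank-1 matrices v_r v_r' from the right singular
    vectors of Z; the rank-3 SVD reconstruction sum_{r<=3} s_r^2 v_r v_r'/M.
    If a ``factor_backend`` is supplied (callable Z -> (L, F) loadings and
    factors of a sparse low-rank approximation), F L'L F'/M and per-factor
    f_r f_r' patterns are appended.
    """
    Z = topz.z_top
    M, R = Z.shape
    if M < R:
        logger.warning("only %d regions for %d traits; data-driven covariances "
                       "may be poorly estimated", M, R)
    covs = list(canonical_prior(R, het_grid=het_grid).components)
    covs.append(Z.T @ Z / M)
    try:
        _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    except np.linalg.LinAlgError as e:
        raise RuntimeError("SVD of the top-z matrix failed") from e
    for r in range(min(3, Vt.shape[0])):
        v = Vt[r]
        covs.append(np.outer(v, v))
    if rank3:
        k = min(3, svals.size)
        covs.append(sum(svals[r] ** 2 * np.outer(Vt[r], Vt[r]) for r in range(k)) / M)
    if factor_backend is not None:
        Lmat, F = factor_backend(Z)
        covs.append(F @ Lmat.T @ Lmat @ F.T / M)
        for r in range(F.shape[1]):
            covs.append(np.outer(F[:, r], F[:, r]))
    return covs


def extreme_deconvolution(topz: TopZMatrix, V: np.ndarray, covs_init: list,
                          weights_init: np.ndarray | None = None,
                          max_iter: int = 500, tol: float = 1e-6):
    """EM for the noisy mixture z_m ~ sum_k omega_k N(0, U_k + V).

    E-step computes responsibilities and the conditional moments of the
    latent effect b_m given component k; the M-step averages: omega_k is
    the mean responsibility, U_k the responsibility-weighted mean of
    E[b_m b_m' | m, k]. The observed-data log-likelihood is non-decreasing;
    iteration stops when its change (per observation) drops below ``tol``.
    Components whose weight collapses below 1e-12 are frozen, not deleted.

    Returns ``(covs, weights, loglik_trace)``.
    """
    Z = topz.z_top
    M, R = Z.shape
    V = np.asarray(V, dtype=float)
    K = len(covs_init)
    covs = [np.asarray(U, dtype=float).copy() for U in covs_init]
    if weights_init is None:
        w = np.full(K, 1.0 / K)
    else:
        w = np.asarray(weights_init, dtype=float).copy()
        if abs(w.sum() - 1.0) > 1e-8 or np.any(w < 0):
            raise ValueError("weights_init must lie on the probability simplex")
    frozen = np.zeros(K, dtype=bool)
    loglik_trace: list[float] = []

    for it in range(max_iter):
        # E-step: log density of z under each component
        logdens = np.empty((M, K))
        mus = np.empty((K, M, R))
        Sigmas = np.empty((K, R, R))
        for k in range(K):
            T = covs[k] + V
            sign, logdet = np.linalg.slogdet(T)
            if sign <= 0:
                raise RuntimeError(f"component {k}: U_k + V is not positive definite")
            Tinv_z = np.linalg.solve(T, Z.T)               # (R, M)
            quad = np.einsum("mr,rm->m", Z, Tinv_z)
            logdens[:, k] = -0.5 * (R * np.log(2 * np.pi) + logdet + quad)
            mus[k] = (covs[k] @ Tinv_z).T                  # E[b | z, k]
            Sig = covs[k] - covs[k] @ np.linalg.solve(T, covs[k])
            Sigmas[k] = (Sig + Sig.T) / 2.0
        with np.errstate(divide="ignore"):
            lw = np.log(np.where(w > 0, w, np.finfo(float).tiny))
        joint = logdens + lw[None, :]
        norm = np.logaddexp.reduce(joint, axis=1)
        loglik = float(norm.sum())
        loglik_trace.append(loglik)
        resp = np.exp(joint - norm[:, None])               # (M, K)

        # M-step
        w_new = resp.mean(axis=0)
        for k in range(K):
            if frozen[k]:
                continue
            rk = resp[:, k].sum()
            if w_new[k] < 1e-12 or rk <= 0:
                logger.warning("ED component %d collapsed (weight %.3g); freezing", k, w_new[k])
                frozen[k] = True
                continue
            Ebb = np.einsum("m,mr,ms->rs", resp[:, k], mus[k], mus[k]) / rk + Sigmas[k]
            covs[k] = (Ebb + Ebb.T) / 2.0
        w = w_new / w_new.sum()

        if it > 0 and abs(loglik_trace[-1] - loglik_trace[-2]) / M < tol:
            break
    return covs, w, loglik_trace


def regularize_covs(covs: list, eps: float | None = None) -> list:
    """Add eps * I to every covariance so all are strictly invertible.

    Default eps is 1e-6 times the mean diagonal entry across the list
    (floored at 1e-12). Singular prior patterns make the conditional lfsr
    ill-behaved; this small ridge avoids that.
    """
    covs = [np.asarray(U, dtype=float) for U in covs]
    if eps is None:
        mean_diag = float(np.mean([np.mean(np.diag(U)) for U in covs]))
        eps = max(1e-6 * mean_diag, 1e-12)
    if eps <= 0:
        raise ValueError("eps must be positive")
    R = covs[0].shape[0]
    return [U + eps * np.eye(R) for U in covs]


def estimate_residual_cov(z_null: np.ndarray, zmax_thresh: float = 2.0) -> np.ndarray:
    """Residual correlation matrix from pooled null-ish z-scores.

    Rows whose largest |z| across traits is below ``zmax_thresh`` are
    treated as draws from N(0, V); V is estimated as the mean outer product
    over the J' surviving rows and then rescaled to a correlation matrix.
    """
    z = np.atleast_2d(np.asarray(z_null, dtype=float))
    keep = np.abs(z).max(axis=1) < zmax_thresh
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError(
            f"only {n_keep} z-score rows survive the |z| < {zmax_thresh} filter; need at least 2"
        )
    zk = z[keep]
    V = zk.T @ zk / n_keep
    d = np.sqrt(np.diag(V))
    if np.any(d <= 0):
        raise ValueError("estimated residual covariance has a zero diagonal entry")
    return (V / d).T / d


def data_driven_prior(regions, V: np.ndarray | None = None,
                      zmax_thresh: float = 2.0, rank3: bool = True,
                      factor_backend=None, eps: float | None = None,
                      max_iter: int = 500, tol: float = 1e-6) -> MixturePrior:
    """End-to-end data-driven prior: top-z collection, SVD initialisation,
    Extreme Deconvolution refinement, and diagonal regularization.

    ``regions`` is a list of per-region J x R z-score matrices. If V is not
    supplied it is estimated from the pooled z-scores.
    """
    if V is None:
        V = estimate_residual_cov(np.vstack([np.atleast_2d(z) for z in regions]),
                                  zmax_thresh=zmax_thresh)
    topz = collect_top_z(regions)
    covs0 = init_datadriven_covs(topz, rank3=rank3, factor_backend=factor_backend)
    covs, weights, _ = extreme_deconvolution(topz, V, covs0, max_iter=max_iter, tol=tol)
    if eps is None:
        eps = max(1e-6 * float(np.mean([np.mean(np.diag(U)) for U in covs])), 1e-12)
    covs = regularize_covs(covs, eps=eps)
    return MixturePrior(components=covs, weights=weights / weights.sum(),
                        epsilon=float(eps))
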