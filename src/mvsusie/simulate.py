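"""Synthetic fine-mapping data: LD-structured genotypes, multi-trait
phenotypes drawn from the model, marginal association statistics, and the
phenotype QC utilities (quantile normalization, Mahalanobis outlier filter).

The trait simulator follows the study design used to benchmark multivariate
fine-mapping: draw the number of causal SNPs S from {1..5} with
probabilities (0.3, 0.3, 0.2, 0.1, 0.1), place them uniformly, draw their
multivariate effects from a mixture-of-normals sharing prior with unit
scale, then calibrate the residual variance so the largest per-trait
proportion of variance explained (PVE) hits a target (0.05% by default,
matching effect sizes typical of biobank-scale GWAS). Genotypes are
synthetic: a latent Gaussian AR(1) chain per haplotype, thresholded by
per-SNP minor allele frequency, giving tunable LD at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .ibss import center_standardize
from .model_core import MixturePrior
from .prior import canonical_prior

__all__ = [
    "Scenario",
    "SimulationTruth",
    "DEFAULT_CAUSAL_DIST",
    "sample_causal_count",
    "simulate_genotypes",
    "simulate_traits",
    "marginal_assoc",
    "quantile_normalize",
    "mahalanobis_filter",
    "default_scenario",
    "simulate_region_and_finemap",
]

# P(S = s) for s = 1..5
DEFAULT_CAUSAL_DIST = (0.3, 0.3, 0.2, 0.1, 0.1)


@dataclass
class Scenario:
    """Generative settings for one batch of simulated regions."""

    n_traits: int
    causal_count_dist: tuple = DEFAULT_CAUSAL_DIST
    prior_for_effects: MixturePrior | None = None
    resid_corr: np.ndarray | None = None     # C; V = sigma^2 C
    target_max_pve: float = 0.0005
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.causal_count_dist, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("causal_count_dist must be a probability vector")
        if not 0.0 < self.target_max_pve < 1.0:
            raise ValueError("target_max_pve must lie in (0, 1)")
        if self.prior_for_effects is None:
            self.prior_for_effects = canonical_prior(self.n_traits)
        if self.resid_corr is None:
            self.resid_corr = np.eye(self.n_traits)
        else:
            self.resid_corr = np.asarray(self.resid_corr, dtype=float)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated region."""

    causal_indices: np.ndarray
    B: np.ndarray               # (J, R) true effects on standardized X, pre Y-scaling
    sigma2: float
    V_true: np.ndarray
    pve: np.ndarray             # per-trait population PVE
    y_scale: np.ndarray = field(default=None)  # per-trait sd applied in step 9


def default_scenario(R: int = 5, target_max_pve: float = 0.0005,
                     seed: int | None = None, resid_corr=None) -> Scenario:
    """The default benchmark scenario: canonical-prior effects, independent
    residuals."""
    return Scenario(n_traits=R, target_max_pve=target_max_pve, seed=seed,
                    resid_corr=resid_corr)


def sample_causal_count(rng: np.random.Generator,
                        dist=DEFAULT_CAUSAL_DIST, size=None):
    """Draw the number of causal SNPs S from the scenario distribution."""
    p = np.asarray(dist, dtype=float)
    vals = np.arange(1, p.size + 1)
    return rng.choice(vals, size=size, p=p / p.sum())


def simulate_genotypes(n: int, j: int, ld_decay: float = 0.9,
                       maf_range=(0.05, 0.5), seed: int | None = None) -> np.ndarray:
    """0/1/2 genotypes with AR(1)-style LD.

    Two latent Gaussian AR(1) chains (one per haplotype) with lag-1
    correlation ``ld_decay`` are thresholded at the per-SNP minor allele
    frequency (drawn uniformly from ``maf_range``) and summed, so adjacent
    SNPs are correlated while marginal frequencies follow Hardy-Weinberg.
    """
    if n < 1 or j < 1:
        raise ValueError("n and j must be positive")
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError("ld_decay must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_range[0], maf_range[1], size=j)
    thresh = sps.norm.ppf(1.0 - maf)
    G = np.zeros((n, j), dtype=np.int8)
    scale = np.sqrt(1.0 - ld_decay**2)
    for _hap in range(2):
        z = np.empty((n, j))
        z[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, j - 1)) if j > 1 else None
        for col in range(1, j):
            z[:, col] = ld_decay * z[:, col - 1] + scale * eps[:, col - 1]
        G += (z > thresh[None, :]).astype(np.int8)
    return G.astype(float)


def simulate_traits(X: np.ndarray, scenario: Scenario):
    """Simulate an N x R trait matrix from the multivariate model.

    Steps: standardize X; draw S causal SNPs and their effects b_j from the
    scenario's mixture prior at unit scale; solve the residual variance
    sigma^2 so that the largest per-trait PVE equals the target (the PVE is
    computed from the population variance of the genetic predictor on the
    standardized genotypes, removing sampling noise from the calibration);
    set V = sigma^2 C; add matrix-normal noise; center and standardize Y.

    Returns ``(Y, truth)``.
    """
    rng = np.random.default_rng(scenario.seed)
    X = np.asarray(X, dtype=float)
    N, J = X.shape
    R = scenario.n_traits
    Xs, _, _ = center_standardize(X, standardize=True)

    S = int(sample_causal_count(rng, scenario.causal_count_dist))
    if S > J:
        raise ValueError(f"drew {S} causal SNPs but the region has only {J}")
    causal = rng.choice(J, size=S, replace=False)

    gprior = scenario.prior_for_effects
    B = np.zeros((J, R))
    for jdx in causal:
        k = rng.choice(gprior.n_components, p=gprior.weights)
        U = gprior.components[k]
        # draw N(0, U) allowing singular U via its matrix square root
        w, Q = np.linalg.eigh(U)
        B[jdx] = Q @ (np.sqrt(np.maximum(w, 0.0)) * rng.standard_normal(R))

    yhat = Xs @ B
    var_g = (yhat**2).mean(axis=0)         # population variance: columns centered
    var_g_max = var_g.max()
    t = scenario.target_max_pve
    if var_g_max <= 0:
        sigma2 = 1.0
    else:
        sigma2 = var_g_max * (1.0 - t) / t
    C = scenario.resid_corr
    V = sigma2 * C
    cholV = np.linalg.cholesky(V + 1e-12 * sigma2 * np.eye(R))
    E = rng.standard_normal((N, R)) @ cholV.T
    Y = yhat + E
    Y, _, y_sd = center_standardize(Y, standardize=True)

    pve = var_g / (var_g + sigma2 * np.diag(C))
    truth = SimulationTruth(causal_indices=np.sort(causal), B=B, sigma2=sigma2,
                            V_true=V, pve=pve, y_scale=y_sd)
    return Y, truth


def simulate_region_and_finemap(seed: int, n: int = 5000, j: int = 500,
                                r: int = 5, ld_decay: float = 0.9,
                                target_max_pve: float = 0.05, L: int = 10,
                                rho: float = 0.95, min_purity: float = 0.5):
    """One benchmark replicate of the full summary-data pipeline.

    Simulates a region (genotypes with AR(1) LD, traits from the default
    scenario), computes marginal z-scores and in-sample LD, estimates the
    residual correlation from the region's near-null z-scores, fits the
    model from the summary data with a canonical prior, and builds
    level-``rho`` credible sets with the purity filter.

    Returns ``(truth, credible_sets, fit, pip)``.
    """
    from .prior import estimate_residual_cov
    from .rss import SummaryData, fit_rss
    from .summaries import compute_pip, credible_sets
    from .ibss import FitOptions

    X = simulate_genotypes(n, j, ld_decay=ld_decay, seed=seed)
    sc = default_scenario(R=r, target_max_pve=target_max_pve, seed=seed + 1)
    Y, truth = simulate_traits(X, sc)
    Xs, _, _ = center_standardize(X, standardize=True)
    _, _, z, ld = marginal_assoc(Xs, Y)
    try:
        V = estimate_residual_cov(z)
    except ValueError:                       # pervasive signal: fall back
        V = np.eye(r)
    fit = fit_rss(SummaryData(z=z, ld=ld, n=n), canonical_prior(r), V,
                  FitOptions(L=L))
    css = credible_sets(fit, ld, rho=rho, min_purity=min_purity)
    return truth, css, fit, compute_pip(fit)


def marginal_assoc(X: np.ndarray, Y: np.ndarray):
    """Per-SNP, per-trait simple linear regression summary statistics.

    Returns ``(bhat, se, z, ld)`` with the slope, its standard error
    (residual degrees of freedom n - 2), z = bhat / se, and the LD matrix
    R_hat = D^{-1/2} X'X D^{-1/2}, D = diag(X'X). X and Y must be
    column-centered.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T if Y.shape == (Y.shape[0], X.shape[0]) else Y
    n = X.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 samples for standard errors")
    sxx = (X**2).sum(axis=0)
    if np.any(sxx == 0):
        bad = np.flatnonzero(sxx == 0)
        raise ValueError(f"constant genotype columns: {bad.tolist()}")
    sxy = X.T @ Y                                  # (J, R)
    syy = (Y**2).sum(axis=0)                       # (R,)
    bhat = sxy / sxx[:, None]
    rss = syy[None, :] - bhat * sxy
    if np.any(rss <= 1e-12 * syy[None, :]):
        raise ValueError("zero residual variance for some SNP/trait pair")
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx[:, None])
    z = bhat / se
    dinv = 1.0 / np.sqrt(sxx)
    ld = (X.T @ X * dinv).T * dinv
    np.fill_diagonal(ld, 1.0)
    return bhat, se, z, ld


def quantile_normalize(y: np.ndarray) -> np.ndarray:
    """Map a trait to standard-normal quantiles at (rank - 0.5) / N.

    Rank-based and monotone; ties receive averaged ranks.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ranks = sps.rankdata(y, method="average")
    return sps.norm.ppf((ranks - 0.5) / y.size)


def mahalanobis_filter(Y: np.ndarray, quantile: float = 0.99) -> np.ndarray:
    """Indices of rows whose Mahalanobis distance is below the chi-square
    quantile with R degrees of freedom.

    Distances use the sample mean and covariance of Y; rows in the extreme
    [quantile, 1] tail are dropped as multivariate outliers.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    R = Y.shape[1]
    Yc = Y - Y.mean(axis=0)
    cov = Yc.T @ Yc / (Y.shape[0] - 1)
    ev = np.linalg.eigvalsh(cov)
    if ev.min() <= 1e-12 * max(ev.max(), 1.0):
        raise ValueError("sample covariance of Y is singular")
    sol = np.linalg.solve(cov, Yc.T)
    d2 = np.einsum("ir,ri->i", Yc, sol)
    return np.flatnonzero(d2 <= sps.chi2.ppf(quantile, df=R))
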