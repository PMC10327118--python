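"""Fine-mapping from GWAS summary data: z-scores, LD and sample size.

When X and Y are column-standardized (sum of squares = N), the sufficient
statistics are recovered from the marginal association z-scores and the LD
matrix:

    X'X = N * R_hat          X'Y = sqrt(N) * Z_tilde

where Z_tilde holds the "adjusted" z-scores z~ = z * sqrt(N / (N + z^2)).
With the in-sample LD matrix this reconstruction is exact, so fitting from
summary data reproduces the individual-level fit; with out-of-sample LD it
is an approximate-likelihood regression (RSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ibss import FitOptions, MvSusieFit, SufficientStats, fit_ss
from .model_core import MixturePrior

__all__ = ["SummaryData", "adjust_z", "ss_from_summary", "fit_rss"]

logger = logging.getLogger("mvsusie")


@dataclass
class SummaryData:
    """Marginal z-scores (J x R), LD correlation matrix (J x J), sample size."""

    z: np.ndarray
    ld: np.ndarray
    n: float
    snp_ids: list | None = None
    trait_ids: list | None = None

    def __post_init__(self):
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.ld = np.asarray(self.ld, dtype=float)
        J = self.z.shape[0]
        if self.ld.shape != (J, J):
            raise ValueError(f"LD matrix is {self.ld.shape}, expected ({J}, {J})")
        if not np.allclose(self.ld, self.ld.T, atol=1e-6):
            raise ValueError("LD matrix is not symmetric")
        if np.any(np.abs(np.diag(self.ld) - 1.0) > 1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.ld) > 1.0 + 1e-6):
            raise ValueError("LD entries must lie in [-1, 1]")
        if np.ndim(self.n) != 0:
            raise ValueError("a single shared sample size N is required; "
                             "per-trait sample sizes are not supported")
        if self.n <= 1:
            raise ValueError("sample size must exceed 1")

    @property
    def n_snps(self) -> int:
        return self.z.shape[0]

    @property
    def n_traits(self) -> int:
        return self.z.shape[1]


def adjust_z(z: np.ndarray, n: float) -> np.ndarray:
    """Adjusted z-scores z~ = z * sqrt(n / (n + z^2)).

    Strictly shrinks each z toward zero, preserves sign, and tends to z as
    n grows (for small effects z~ is essentially z).
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    z = np.asarray(z, dtype=float)
    return z * np.sqrt(n / (n + z**2))


def _project_psd(ld: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at zero and rescale to unit diagonal."""
    w, Q = np.linalg.eigh((ld + ld.T) / 2.0)
    if w.min() >= -1e-8:
        return (ld + ld.T) / 2.0
    logger.warning("LD matrix has negative eigenvalues (min %.3g); projecting to PSD", w.min())
    A = (Q * np.maximum(w, 0.0)) @ Q.T
    d = np.diag(A).copy()
    if np.any(d <= 0):
        raise ValueError("LD matrix is not PSD even after eigenvalue clipping; "
                         "regularize the LD estimate (e.g. shrink toward identity)")
    s = 1.0 / np.sqrt(d)
    return (A * s).T * s


def ss_from_summary(sd: SummaryData) -> SufficientStats:
    """Reconstruct sufficient statistics from z-scores, LD and N.

    xtx = n * ld (PSD-projected if needed), xty = sqrt(n) * adjusted z.
    Y'Y is not recoverable from z-scores, so the ELBO of downstream fits is
    reported up to an additive constant.
    """
    ld = _project_psd(sd.ld)
    xtx = sd.n * ld
    xty = np.sqrt(sd.n) * adjust_z(sd.z, sd.n)
    return SufficientStats(xtx=xtx, xty=xty, n=sd.n, yty=None)


def fit_rss(sd: SummaryData, prior: MixturePrior, V: np.ndarray,
            opts: FitOptions | None = None, pi: np.ndarray | None = None,
            in_sample_ld: bool = True) -> MvSusieFit:
    """Fit from summary data by running IBSS-ss on the reconstructed
    sufficient statistics.

    With in-sample LD this equals the individual-data fit (on standardized
    data). With out-of-sample LD the likelihood is approximate; a warning is
    logged and the LD matrix is PSD-repaired if necessary. V should normally
    be a correlation matrix (the traits are standardized in this pathway).
    """
    if not in_sample_ld:
        logger.warning("out-of-sample LD supplied: operating in the "
                       "approximate-likelihood (RSS) regime")
    ss = ss_from_summary(sd)
    return fit_ss(ss, prior, V, opts, pi=pi,
                  snp_ids=sd.snp_ids, trait_ids=sd.trait_ids)
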