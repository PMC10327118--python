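import numpy as np
import pytest

import mvsusie as mv


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated region with a clear signal, shared by tests.

    Returns a dict with raw and standardized data, summary statistics and
    the generating truth.
    """
    X = mv.simulate_genotypes(1200, 60, ld_decay=0.8, seed=42)
    sc = mv.default_scenario(R=3, target_max_pve=0.05, seed=43)
    Y, truth = mv.simulate_traits(X, sc)
    Xs, _, _ = mv.center_standardize(X, standardize=True)
    Ys, _, _ = mv.center_standardize(Y, standardize=True)
    bhat, se, z, ld = mv.marginal_assoc(Xs, Ys)
    return dict(X=X, Y=Y, Xs=Xs, Ys=Ys, bhat=bhat, se=se, z=z, ld=ld,
                truth=truth, n=1200, J=60, R=3)


def random_psd(rng, R, rank=None):
    """A random symmetric PSD matrix, optionally rank-deficient."""
    rank = rank or R
    A = rng.standard_normal((R, rank))
    return A @ A.T / rank
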