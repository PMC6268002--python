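"""Shared dense-Gaussian helpers used by every fine-mapping engine."""

from __future__ import annotations

import numpy as np

#: Ridge added to an LD matrix only when it is numerically singular
#: (e.g. perfect-LD duplicate SNPs). Well-conditioned matrices are
#: factorized exactly so closed-form checks hold at full precision.
DEFAULT_RIDGE = 1e-6


def safe_cholesky(sigma: np.ndarray, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Lower Cholesky factor of ``sigma``, ridging the diagonal only on failure."""
    sigma = np.asarray(sigma, dtype=float)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        pass
    m = sigma.shape[0]
    bump = ridge
    for _ in range(12):
        try:
            return np.linalg.cholesky(sigma + bump * np.eye(m))
        except np.linalg.LinAlgError:
            bump *= 10.0
    raise np.linalg.LinAlgError(
        "matrix not positive definite even after ridging; check the LD input"
    )


def mvn_logpdf(x: np.ndarray, mean: np.ndarray, chol_lower: np.ndarray) -> float:
    """Multivariate-normal log density given a precomputed Cholesky factor."""
    from scipy.linalg import solve_triangular

    x = np.asarray(x, dtype=float)
    dev = x - np.asarray(mean, dtype=float)
    m = dev.shape[0]
    u = solve_triangular(chol_lower, dev, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol_lower)))
    return float(-0.5 * (m * np.log(2.0 * np.pi) + logdet + u @ u))
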