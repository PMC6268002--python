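import numpy as np
import pytest

from finelocus.ldtools import LDMatrix, SummaryStats, p_from_z
from finelocus.locus import Locus


def make_locus(r_mat, z, ids=None, n=10_000, annotations=None) -> Locus:
    """Locus from an explicit LD matrix and z-vector (betas on the z/sqrt(n) scale)."""
    z = np.asarray(z, dtype=float)
    m = z.shape[0]
    ids = ids or [f"s{i + 1}" for i in range(m)]
    stats = SummaryStats(
        ids=ids,
        effect_allele=["G"] * m,
        other_allele=["A"] * m,
        freq=np.full(m, 0.3),
        beta=z / np.sqrt(n),
        se=np.full(m, 1.0 / np.sqrt(n)),
        p=p_from_z(z),
        n=np.full(m, float(n)),
    )
    return Locus(stats=stats, ld=LDMatrix(np.asarray(r_mat, dtype=float), ids),
                 annotations=annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_corr(rng, m: int) -> np.ndarray:
    """A random well-conditioned correlation matrix (positive definite)."""
    a = rng.standard_normal((m, m)) * 0.4
    b = a @ a.T + m * np.eye(m)
    d = np.sqrt(np.diag(b))
    return b / np.outer(d, d)
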