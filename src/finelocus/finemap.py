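"""Posterior over causal configurations from summary z-scores and LD.

The model integrates the causal non-centrality parameters out against a
Normal(0, s^2) prior, giving the prior-integrated marginal likelihood

    Z ~ N(0, Sigma + s^2 * Sigma_C Sigma_C^T)

for a configuration with causal columns ``Sigma_C`` of the LD matrix, versus
Z ~ N(0, Sigma) under the null.  The Bayes factor is the density ratio.  The
unnormalized posterior of a size-k configuration is

    (m choose k)^{-1} * p_k * BF(config : null)

normalized over every configuration evaluated (exhaustive enumeration up to
``k_max``, or the distinct set visited by shotgun stochastic search).  All
arithmetic is in log space with log-sum-exp normalization.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from finelocus._linalg import mvn_logpdf, safe_cholesky
from finelocus.ldtools import LDMatrix
from finelocus.locus import Locus

DEFAULT_PRIOR_SD = 3.0
DEFAULT_K_MAX = 5
ENUMERATION_GUARD = 25


@dataclass
class CausalConfig:
    """Binary causal-status vector with per-SNP non-centrality parameters."""

    c: np.ndarray
    lam: np.ndarray | None = None
    effect_mle: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=int)
        if not np.isin(self.c, (0, 1)).all():
            raise ValueError("causal vector must be binary")
        if self.lam is None:
            self.lam = np.zeros(self.c.shape[0])
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.shape != self.c.shape:
            raise ValueError("lambda length must match causal vector")
        if np.any((self.c == 0) & (self.lam != 0)):
            raise ValueError("lambda must be zero at non-causal SNPs")

    @property
    def k(self) -> int:
        return int(self.c.sum())

    @property
    def m(self) -> int:
        return self.c.shape[0]

    @property
    def causal_idx(self) -> np.ndarray:
        return np.flatnonzero(self.c)

    @classmethod
    def from_indices(cls, m: int, idx, lam=None) -> "CausalConfig":
        c = np.zeros(m, dtype=int)
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        c[idx] = 1
        full_lam = np.zeros(m)
        if lam is not None:
            full_lam[idx] = np.atleast_1d(np.asarray(lam, dtype=float))
        return cls(c=c, lam=full_lam)


@dataclass
class FinemapResult:
    """Evaluated configurations with log BFs and posteriors, plus per-SNP PIPs."""

    variant_ids: list[str]
    configs: list[tuple[int, ...]]  # causal index tuples, sorted
    log_bf: np.ndarray
    posterior: np.ndarray
    pip: np.ndarray
    k_max: int
    prior_sd: float
    p_k: np.ndarray
    mode: str
    seed: int | None = None
    n_evaluated: int = 0

    def top_config(self) -> tuple[int, ...]:
        return self.configs[int(np.argmax(self.posterior))]

    def to_frame(self):
        import pandas as pd

        order = np.argsort(-self.pip, kind="stable")
        return pd.DataFrame(
            {
                "id": [self.variant_ids[i] for i in order],
                "pip": self.pip[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    def configs_frame(self):
        import pandas as pd

        m = len(self.variant_ids)
        rows = []
        for cfg, lbf, post in zip(self.configs, self.log_bf, self.posterior):
            bits = np.zeros(m, dtype=int)
            bits[list(cfg)] = 1
            rows.append(
                {
                    "config": "".join(map(str, bits)),
                    "k": len(cfg),
                    "log_bf": lbf,
                    "posterior": post,
                }
            )
        return pd.DataFrame(rows).sort_values("posterior", ascending=False, kind="stable")


def config_log_bf(
    z: np.ndarray,
    ld: LDMatrix,
    config: CausalConfig,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> float:
    """Log Bayes factor of a causal configuration against the global null."""
    z = np.asarray(z, dtype=float)
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if config.m != ld.m or z.shape[0] != ld.m:
        raise ValueError("dimension mismatch between z, LD and configuration")
    idx = config.causal_idx
    if idx.size == 0:
        return 0.0
    sigma = ld.r
    sigma_c = sigma[:, idx]
    cov_alt = sigma + prior_sd**2 * (sigma_c @ sigma_c.T)
    l_null = safe_cholesky(sigma)
    l_alt = safe_cholesky(cov_alt)
    zero = np.zeros_like(z)
    return mvn_logpdf(z, zero, l_alt) - mvn_logpdf(z, zero, l_null)


def _log_prior(k: int, m: int, log_p_k: np.ndarray) -> float:
    # (m choose k)^{-1} p_k
    log_binom = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    return float(log_p_k[k] - log_binom)


def _normalize(
    locus: Locus,
    configs: list[tuple[int, ...]],
    log_bf: np.ndarray,
    log_p_k: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    m = locus.m
    log_unnorm = np.array(
        [lbf + _log_prior(len(cfg), m, log_p_k) for cfg, lbf in zip(configs, log_bf)]
    )
    posterior = np.exp(log_unnorm - logsumexp(log_unnorm))
    pip = np.zeros(m)
    for cfg, post in zip(configs, posterior):
        for j in cfg:
            pip[j] += post
    return posterior, pip


def _prepare_pk(p_k, k_max: int) -> np.ndarray:
    if p_k is None:
        p_k = np.full(k_max + 1, 1.0 / (k_max + 1))
    p_k = np.asarray(p_k, dtype=float)
    if p_k.shape[0] != k_max + 1 or np.any(p_k < 0) or p_k.sum() <= 0:
        raise ValueError("p_k must be a nonnegative vector of length k_max + 1")
    p_k = p_k / p_k.sum()
    with np.errstate(divide="ignore"):
        return np.log(p_k)


def posterior_exhaustive(
    locus: Locus,
    k_max: int = DEFAULT_K_MAX,
    p_k=None,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> FinemapResult:
    """Enumerate every configuration with k <= k_max and normalize exactly."""
    m = locus.m
    if m > ENUMERATION_GUARD:
        raise ValueError(
            f"locus has {m} SNPs > enumeration guard {ENUMERATION_GUARD}; "
            "use posterior_sss for larger loci"
        )
    k_max = min(k_max, m)
    log_p_k = _prepare_pk(p_k, k_max)
    configs: list[tuple[int, ...]] = []
    log_bf = []
    l_null = safe_cholesky(locus.ld.r)
    zero = np.zeros(m)
    log_null = mvn_logpdf(locus.z, zero, l_null)
    for k in range(k_max + 1):
        for idx in itertools.combinations(range(m), k):
            configs.append(idx)
            log_bf.append(_log_bf_cached(locus, idx, prior_sd, log_null))
    log_bf = np.asarray(log_bf)
    posterior, pip = _normalize(locus, configs, log_bf, log_p_k)
    return FinemapResult(
        variant_ids=locus.ids,
        configs=configs,
        log_bf=log_bf,
        posterior=posterior,
        pip=pip,
        k_max=k_max,
        prior_sd=prior_sd,
        p_k=np.exp(log_p_k),
        mode="exhaustive",
        n_evaluated=len(configs),
    )


def _log_bf_cached(locus: Locus, idx: tuple[int, ...], prior_sd: float, log_null: float) -> float:
    if len(idx) == 0:
        return 0.0
    sigma = locus.ld.r
    sigma_c = sigma[:, list(idx)]
    cov_alt = sigma + prior_sd**2 * (sigma_c @ sigma_c.T)
    l_alt = safe_cholesky(cov_alt)
    return mvn_logpdf(locus.z, np.zeros(locus.m), l_alt) - log_null


def posterior_sss(
    locus: Locus,
    k_max: int = DEFAULT_K_MAX,
    p_k=None,
    prior_sd: float = DEFAULT_PRIOR_SD,
    n_iter: int = 500,
    seed: int = 0,
) -> FinemapResult:
    """Shotgun stochastic search: score every add/delete/swap neighbor each
    iteration, accumulate all distinct evaluated configurations, and move to a
    neighbor with probability proportional to its unnormalized posterior."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    m = locus.m
    k_max = min(k_max, m)
    log_p_k = _prepare_pk(p_k, k_max)
    rng = np.random.default_rng(seed)
    l_null = safe_cholesky(locus.ld.r)
    log_null = mvn_logpdf(locus.z, np.zeros(m), l_null)

    cache: dict[tuple[int, ...], float] = {}

    def score(idx: tuple[int, ...]) -> float:
        if idx not in cache:
            lbf = _log_bf_cached(locus, idx, prior_sd, log_null)
            cache[idx] = lbf + _log_prior(len(idx), m, log_p_k)
        return cache[idx]

    score(())
    if k_max == 0:
        configs = [()]
        log_bf = np.array([0.0])
        posterior, pip = _normalize(locus, configs, log_bf, log_p_k)
        return FinemapResult(
            variant_ids=locus.ids, configs=configs, log_bf=log_bf,
            posterior=posterior, pip=pip, k_max=k_max, prior_sd=prior_sd,
            p_k=np.exp(log_p_k), mode="sss", seed=seed, n_evaluated=1,
        )

    # start from the best marginal single-SNP configuration
    current = (int(np.argmax(np.abs(locus.z))),)
    score(current)

    expanded: set[tuple[int, ...]] = set()
    for _ in range(n_iter):
        expanded.add(current)
        cur = set(current)
        neighbors: list[tuple[int, ...]] = []
        if len(cur) < k_max:
            for j in range(m):
                if j not in cur:
                    neighbors.append(tuple(sorted(cur | {j})))
        for j in cur:
            neighbors.append(tuple(sorted(cur - {j})))
        for j in cur:
            for j2 in range(m):
                if j2 not in cur:
                    neighbors.append(tuple(sorted((cur - {j}) | {j2})))
        for nb in neighbors:
            score(nb)
        # move to an evaluated-but-unexpanded configuration sampled by its
        # posterior weight; never re-expanding a state makes the search sweep
        # the whole neighborhood graph instead of lingering at the mode
        frontier = [cfg for cfg in cache if cfg not in expanded]
        if not frontier:
            break
        weights = np.array([cache[cfg] for cfg in frontier])
        prob = np.exp(weights - logsumexp(weights))
        current = frontier[rng.choice(len(frontier), p=prob)]

    configs = sorted(cache.keys(), key=lambda t: (len(t), t))
    log_weight = np.array([cache[cfg] for cfg in configs])
    log_bf = np.array(
        [cache[cfg] - _log_prior(len(cfg), m, log_p_k) for cfg in configs]
    )
    posterior = np.exp(log_weight - logsumexp(log_weight))
    pip = np.zeros(m)
    for cfg, post in zip(configs, posterior):
        for j in cfg:
            pip[j] += post
    return FinemapResult(
        variant_ids=locus.ids,
        configs=configs,
        log_bf=log_bf,
        posterior=posterior,
        pip=pip,
        k_max=k_max,
        prior_sd=prior_sd,
        p_k=np.exp(log_p_k),
        mode="sss",
        seed=seed,
        n_evaluated=len(configs),
    )


def credible_set(result: FinemapResult, level: float = 0.95) -> list[str]:
    """Smallest SNP set, by descending PIP, whose cumulative PIP reaches ``level``.

    PIPs are renormalized to sum to 1 before accumulating; ties broken by id.
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    total = result.pip.sum()
    if total == 0:
        warnings.warn("all PIPs are zero; credible set is empty", stacklevel=2)
        return []
    norm = result.pip / total
    order = sorted(
        range(len(norm)), key=lambda j: (-norm[j], result.variant_ids[j])
    )
    out: list[str] = []
    cum = 0.0
    for j in order:
        if norm[j] <= 0:
            break
        out.append(result.variant_ids[j])
        cum += norm[j]
        if cum >= level - 1e-12:
            break
    return out
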