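"""Permutation-based probabilistic identification of causal SNPs (PICS).

With the lead association fixed at its observed strength S = -log10(p_lead),
each SNP in LD with the lead (r^2 above a threshold) is considered in turn
as the causal hypothesis.  Under "SNP j causal at strength S", every
candidate SNP i has an expected association r^2_{ij} * S with spread
sd_model(r_{ij}, S); permuted association profiles are drawn from this
model, the likelihood of the observed profile under each hypothesis is
estimated (kernel density per SNP, independence approximation), and
posteriors follow Bayes' rule with equal priors over candidate hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import logsumexp

DEFAULT_N_PERM = 10_000
DEFAULT_R2_MIN = 0.5

_SD_FLOOR = 1e-6


def default_sd_model(r: np.ndarray, strength: float) -> np.ndarray:
    """Empirical spread of -log10 p at LD r from a lead of strength S:
    sd = sqrt(1 - |r|^6.4) * sqrt(S) / 2, floored for the perfect-LD case."""
    sd = np.sqrt(np.clip(1.0 - np.abs(r) ** 6.4, 0.0, 1.0)) * np.sqrt(max(strength, 0.0)) / 2.0
    return np.maximum(sd, _SD_FLOOR)


@dataclass
class PicsResult:
    """Per-SNP causal probabilities over the candidate set (zero elsewhere)."""

    variant_ids: list[str]
    prob: np.ndarray
    candidate_idx: np.ndarray
    r2_to_lead: np.ndarray
    lead_idx: int
    n_permutations: int
    seed: int
    #: per-candidate hypothesis log-likelihoods (NaN outside the candidate
    #: set); the probabilities are these, exponentiated and normalized, so
    #: they remain comparable when posteriors underflow to exactly 0.
    log_likelihood: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "id": self.variant_ids,
                "r2_to_lead": self.r2_to_lead,
                "pics_probability": self.prob,
            }
        )
        # ranking: by probability, then r2 to lead, then id (stable)
        return df.sort_values(
            by=["pics_probability", "r2_to_lead", "id"],
            ascending=[False, False, True],
            kind="stable",
        ).reset_index(drop=True)


def _profile_loglik(
    observed: np.ndarray,
    draws: np.ndarray,
    method: str,
    means: np.ndarray,
    sds: np.ndarray,
) -> float:
    """Log likelihood of the observed -log10 p profile under one hypothesis.

    ``draws`` has shape (n_perm, n_candidates).  'kde' uses a per-SNP Gaussian
    kernel density with Silverman bandwidth; 'normal' evaluates the model
    density in closed form.  Both assume independence across SNPs.
    """
    if method == "normal":
        return float(
            np.sum(
                -0.5 * ((observed - means) / sds) ** 2
                - np.log(sds)
                - 0.5 * np.log(2.0 * np.pi)
            )
        )
    n_perm = draws.shape[0]
    total = 0.0
    for i in range(draws.shape[1]):
        x = draws[:, i]
        sd = x.std()
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        h = max(0.9 * spread * n_perm ** (-0.2), 1e-3)
        logk = (
            -0.5 * ((observed[i] - x) / h) ** 2
            - np.log(h)
            - 0.5 * np.log(2.0 * np.pi)
        )
        total += logsumexp(logk) - np.log(n_perm)
    return total


def pics_posterior(
    locus,
    lead_idx: int | None = None,
    n_perm: int = DEFAULT_N_PERM,
    r2_min: float = DEFAULT_R2_MIN,
    seed: int = 0,
    sd_model: Callable[[np.ndarray, float], np.ndarray] = default_sd_model,
    likelihood: str = "kde",
) -> PicsResult:
    """Posterior causal probabilities with the lead association fixed."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must lie in [0, 1]")
    if likelihood not in ("kde", "normal"):
        raise ValueError("likelihood must be 'kde' or 'normal'")
    z = locus.z
    neglogp = -np.log10(np.clip(locus.stats.p, np.finfo(float).tiny, 1.0))
    if lead_idx is None:
        lead_idx = int(np.argmax(neglogp))
    elif neglogp[lead_idx] < neglogp.max() - 1e-9:
        raise ValueError("lead_idx must carry the maximal -log10 p in the locus")
    m = locus.m
    r_lead = locus.ld.r[:, lead_idx]
    r2_lead = r_lead**2
    cand = np.flatnonzero(r2_lead >= r2_min)
    cand = np.unique(np.append(cand, lead_idx))
    prob = np.zeros(m)
    if cand.size == 1:
        prob[lead_idx] = 1.0
        return PicsResult(
            variant_ids=locus.ids, prob=prob, candidate_idx=cand,
            r2_to_lead=r2_lead, lead_idx=lead_idx, n_permutations=n_perm, seed=seed,
        )

    strength = float(neglogp[lead_idx])
    observed = neglogp[cand]
    rng = np.random.default_rng(seed)
    logliks = np.empty(cand.size)
    r_cand = locus.ld.r[np.ix_(cand, cand)]
    for h, j in enumerate(cand):
        r_ij = r_cand[:, h]
        means = r_ij**2 * strength
        sds = sd_model(r_ij, strength)
        draws = rng.normal(means, sds, size=(n_perm, cand.size))
        logliks[h] = _profile_loglik(observed, draws, likelihood, means, sds)
    post = np.exp(logliks - logsumexp(logliks))
    prob[cand] = post
    full_ll = np.full(m, np.nan)
    full_ll[cand] = logliks
    return PicsResult(
        variant_ids=locus.ids,
        prob=prob,
        candidate_idx=cand,
        r2_to_lead=r2_lead,
        lead_idx=lead_idx,
        n_permutations=n_perm,
        seed=seed,
        log_likelihood=full_ll,
    )
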