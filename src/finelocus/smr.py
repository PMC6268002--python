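"""Summary-based Mendelian randomization with the HEIDI heterogeneity test.

SMR tests whether a trait and gene expression share a causal variant via
the ratio estimate b_xy = beta_GWAS / beta_eQTL at the top cis-eQTL SNP
(the instrument): T_SMR = z_g^2 z_e^2 / (z_g^2 + z_e^2) ~ chi-square(1).
HEIDI then asks whether b_xy is homogeneous across the instrument's LD
neighborhood: under a single shared causal variant (pleiotropy) every SNP
estimates the same b_xy, whereas under linkage (distinct causal variants)
the ratios disagree.  The heterogeneity statistic is the sum of squared
standardized differences d_i = b_xy(i) - b_xy(top), with delta-method
variances and LD-driven covariances, referred to a Satterthwaite-scaled
chi-square that matches the first two moments of the correlated sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from finelocus.ldtools import LDMatrix, SummaryStats

#: default decision thresholds: cis-eQTL instrument significance,
#: GWAS association filter, and the colocalization rule
#: p_smr < alpha_smr and p_heidi > alpha_heidi.
P_EQTL_FILTER = 5e-5
P_GWAS_FILTER = 0.05
ALPHA_SMR = 0.05
ALPHA_HEIDI = 0.05

#: HEIDI secondary-SNP selection defaults: eQTL p below ~chi2(1)=10,
#: LD pruning window with the instrument, cap on the number of SNPs.
HEIDI_P_EQTL = 1.57e-3
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 3


@dataclass
class SMRResult:
    gene: str
    instrument: str
    b_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    passes_eqtl_filter: bool
    passes_gwas_filter: bool
    colocalized: bool
    reason: str = ""


def smr_test(
    z_gwas: float, z_eqtl: float, beta_gwas: float, beta_eqtl: float
) -> tuple[float, float, float]:
    """Single-instrument SMR: returns (b_xy, T_smr, p_smr)."""
    if z_eqtl == 0:
        raise ValueError("instrument eQTL z-score is zero; b_xy undefined")
    zg2, ze2 = z_gwas**2, z_eqtl**2
    t = zg2 * ze2 / (zg2 + ze2) if (zg2 + ze2) > 0 else 0.0
    p = float(sps.chi2.sf(t, df=1))
    return beta_gwas / beta_eqtl, float(t), max(p, np.finfo(float).tiny)


def _bxy_cov(
    bg: np.ndarray, seg: np.ndarray, be: np.ndarray, see: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Delta-method covariance of b_xy across SNPs.

    GWAS effects across SNPs are correlated through LD (cov = r * se_i * se_j),
    likewise the eQTL effects; the two studies are independent samples.
    """
    inv_be = 1.0 / be
    # d b_i / d bg_i = 1/be_i ; d b_i / d be_i = -bg_i / be_i^2
    g_term = np.outer(inv_be, inv_be) * r * np.outer(seg, seg)
    e_term = (
        np.outer(bg * inv_be**2, bg * inv_be**2) * r * np.outer(see, see)
    )
    return g_term + e_term


def heidi_test(
    gwas: SummaryStats,
    eqtl: SummaryStats,
    ld: LDMatrix,
    instrument_idx: int | None = None,
    p_eqtl_select: float = HEIDI_P_EQTL,
    r2_min: float = HEIDI_R2_MIN,
    r2_max: float = HEIDI_R2_MAX,
    max_snps: int = HEIDI_MAX_SNPS,
) -> tuple[float | None, int, str]:
    """HEIDI heterogeneity test; returns (p_heidi or None, n snps used, reason)."""
    if gwas.m != eqtl.m or gwas.m != ld.m:
        raise ValueError("gwas, eqtl and LD must cover the same SNPs")
    if list(gwas.ids) != list(eqtl.ids):
        raise ValueError("gwas and eqtl variant ids differ; harmonize first")
    z_e = eqtl.z
    if instrument_idx is None:
        instrument_idx = int(np.argmax(np.abs(z_e)))
    t = instrument_idx
    if z_e[t] == 0:
        return None, 0, "instrument eQTL z is zero"

    r_t = ld.r[:, t]
    r2_t = r_t**2
    eligible = (
        (eqtl.p < p_eqtl_select)
        & (r2_t >= r2_min)
        & (r2_t <= r2_max)
        & (np.arange(gwas.m) != t)
        & (z_e != 0)
    )
    idx = np.flatnonzero(eligible)
    if idx.size > max_snps:
        idx = idx[np.argsort(eqtl.p[idx], kind="stable")[:max_snps]]
        idx = np.sort(idx)
    if idx.size < HEIDI_MIN_SNPS:
        return None, int(idx.size), "fewer than 3 usable secondary SNPs"

    sel = np.append(idx, t)  # instrument last
    bg, seg = gwas.beta[sel], gwas.se[sel]
    be, see = eqtl.beta[sel], eqtl.se[sel]
    r_sel = ld.r[np.ix_(sel, sel)]
    b = bg / be
    cov_b = _bxy_cov(bg, seg, be, see, r_sel)

    k = idx.size
    # d_i = b_i - b_top ; J maps b -> d
    jac = np.hstack([np.eye(k), -np.ones((k, 1))])
    cov_d = jac @ cov_b @ jac.T
    d = b[:k] - b[k]
    var_d = np.diag(cov_d)
    if np.any(var_d <= 0):
        return None, k, "non-positive variance of b_xy difference"
    z_d = d / np.sqrt(var_d)
    corr_d = cov_d / np.sqrt(np.outer(var_d, var_d))
    q = float(np.sum(z_d**2))

    # Satterthwaite: match E[Q]=k, Var[Q]=2 tr(R^2) with g * chi2(h)
    tr_r2 = float(np.sum(corr_d**2))
    g = tr_r2 / k
    h = k**2 / tr_r2
    p = float(sps.chi2.sf(q / g, df=h))
    return max(p, np.finfo(float).tiny), k, ""


def heidi_pvalue_eigen(
    q: float, corr_d: np.ndarray, n_mc: int = 200_000, seed: int = 0
) -> float:
    """Eigenvalue-weighted chi-square reference for Q (Monte Carlo), for cross-checks."""
    lam = np.linalg.eigvalsh(corr_d)
    lam = lam[lam > 1e-12]
    rng = np.random.default_rng(seed)
    draws = (lam[None, :] * rng.chisquare(1, size=(n_mc, lam.size))).sum(axis=1)
    return float((draws >= q).mean())


def smr_pipeline(
    gwas: SummaryStats,
    eqtl_by_gene: dict[str, SummaryStats],
    ld: LDMatrix,
    p_eqtl_filter: float = P_EQTL_FILTER,
    p_gwas_filter: float = P_GWAS_FILTER,
    alpha_smr: float = ALPHA_SMR,
    alpha_heidi: float = ALPHA_HEIDI,
    heidi_kwargs: dict | None = None,
) -> list[SMRResult]:
    """Per-gene SMR + HEIDI with the nominal filtering and decision rule."""
    heidi_kwargs = heidi_kwargs or {}
    results: list[SMRResult] = []
    for gene, eqtl in eqtl_by_gene.items():
        if list(eqtl.ids) != list(gwas.ids):
            raise ValueError(f"gene {gene}: eQTL ids differ from GWAS; harmonize first")
        top = int(np.argmin(eqtl.p))
        if eqtl.p[top] >= p_eqtl_filter:
            results.append(
                SMRResult(
                    gene=gene, instrument=eqtl.ids[top], b_xy=np.nan,
                    t_smr=np.nan, p_smr=np.nan, p_heidi=None, n_heidi_snps=0,
                    passes_eqtl_filter=False, passes_gwas_filter=False,
                    colocalized=False, reason="no cis-eQTL passes the eQTL filter",
                )
            )
            continue
        passes_gwas = bool(gwas.p[top] < p_gwas_filter)
        b_xy, t_smr, p_smr = smr_test(
            gwas.z[top], eqtl.z[top], gwas.beta[top], eqtl.beta[top]
        )
        p_heidi, n_heidi, reason = heidi_test(
            gwas, eqtl, ld, instrument_idx=top, **heidi_kwargs
        )
        coloc = (
            passes_gwas
            and p_smr < alpha_smr
            and p_heidi is not None
            and p_heidi > alpha_heidi
        )
        results.append(
            SMRResult(
                gene=gene, instrument=eqtl.ids[top], b_xy=b_xy, t_smr=t_smr,
                p_smr=p_smr, p_heidi=p_heidi, n_heidi_snps=n_heidi,
                passes_eqtl_filter=True, passes_gwas_filter=passes_gwas,
                colocalized=bool(coloc), reason=reason,
            )
        )
    return results


def results_frame(results: list[SMRResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "instrument": [r.instrument for r in results],
            "b_xy": [r.b_xy for r in results],
            "p_smr": [r.p_smr for r in results],
            "p_heidi": [r.p_heidi for r in results],
            "n_heidi": [r.n_heidi_snps for r in results],
            "colocalized": [r.colocalized for r in results],
        }
    )
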