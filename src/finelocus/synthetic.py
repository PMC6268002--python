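"""Synthetic inputs with the statistical structure the downstream models assume.

Haplotypes follow a first-order Markov copy process (copy the previous
allele with probability ``rho``, else redraw at the site's target
frequency), which gives tunable exponentially decaying LD at desk scale.
Association z-scores are exact multivariate-normal draws from
N(Sigma (lambda o C), Sigma), the standard summary-statistic model with
non-centrality lambda at causal SNPs propagated to neighbors by LD.
Betas and standard errors assume a standardized trait and genotypes:
beta = z / sqrt(n), se = 1 / sqrt(n).

Every generator takes an explicit integer seed; identical seed and
parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from finelocus._linalg import safe_cholesky
from finelocus.finemap import CausalConfig
from finelocus.ldtools import LDMatrix, SummaryStats, ld_from_haplotypes, p_from_z
from finelocus.locus import Locus


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (rows) by SNPs (columns)."""

    alleles: np.ndarray  # n_hap x m, entries in {0,1}
    variant_ids: list[str]
    positions: np.ndarray  # 1-based bp
    allele_freqs: np.ndarray  # alt-allele frequency = column mean

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=int)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(self.allele_freqs, self.alleles.mean(axis=0)):
            raise ValueError("allele_freqs must equal column means")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def m(self) -> int:
        return self.alleles.shape[1]

    def to_vcf(self, path, chrom: str = "1") -> None:
        """Minimal VCF v4.2 with phased GT only (haplotypes paired into samples)."""
        n_sample = self.n_hap // 2
        if n_sample * 2 != self.n_hap:
            raise ValueError("need an even number of haplotypes to write diploid VCF")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(f"S{i + 1}" for i in range(n_sample))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            for j in range(self.m):
                gts = "\t".join(
                    f"{self.alleles[2 * i, j]}|{self.alleles[2 * i + 1, j]}"
                    for i in range(n_sample)
                )
                fh.write(
                    f"{chrom}\t{self.positions[j]}\t{self.variant_ids[j]}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "HaplotypePanel":
        """Read phased GTs from a VCF (requires all genotypes phased and biallelic)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        cols, ids, pos = [], [], []
        for var in vcf:
            ph = np.asarray(var.genotype.array())
            if ph.shape[1] < 3 or not np.all(ph[:, 2]):
                raise ValueError(f"variant {var.ID} is not fully phased")
            cols.append(ph[:, :2].reshape(-1))
            ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
            pos.append(var.POS)
        alleles = np.column_stack(cols)
        return cls(
            alleles=alleles,
            variant_ids=ids,
            positions=np.asarray(pos),
            allele_freqs=alleles.mean(axis=0),
        )


@dataclass
class SimScenario:
    """A paired GWAS/eQTL simulation condition.

    pleiotropy: the same variant drives both traits; linkage: two distinct
    (possibly correlated) causal variants; null: no GWAS signal.
    """

    scenario_kind: str
    causal_gwas: int
    causal_eqtl: int
    lambda_gwas: float
    lambda_eqtl: float
    n_gwas: int
    n_eqtl: int

    def __post_init__(self) -> None:
        if self.scenario_kind not in ("pleiotropy", "linkage", "null"):
            raise ValueError(f"unknown scenario kind {self.scenario_kind!r}")
        if self.scenario_kind == "pleiotropy" and self.causal_gwas != self.causal_eqtl:
            raise ValueError("pleiotropy requires causal_gwas == causal_eqtl")
        if self.scenario_kind == "linkage" and self.causal_gwas == self.causal_eqtl:
            raise ValueError("linkage requires distinct causal variants")
        if self.scenario_kind == "null" and self.lambda_gwas != 0:
            raise ValueError("null scenario requires lambda_gwas == 0")


def sim_haplotypes(
    n_hap: int,
    m_snp: int,
    rho: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    start_pos: int = 1000,
    spacing: int = 1000,
) -> HaplotypePanel:
    """First-order Markov haplotype panel with adjacent-site correlation ~ rho."""
    if n_hap < 2 or m_snp < 1:
        raise ValueError("need n_hap >= 2 and m_snp >= 1")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m_snp)
    alleles = np.empty((n_hap, m_snp), dtype=np.int8)
    alleles[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m_snp):
        copy = rng.random(n_hap) < rho
        fresh = (rng.random(n_hap) < freqs[j]).astype(np.int8)
        alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
    # guard against monomorphic columns (possible at small n_hap)
    for j in range(m_snp):
        col = alleles[:, j]
        if col.min() == col.max():
            col[rng.integers(n_hap)] ^= 1
    positions = start_pos + spacing * np.arange(m_snp)
    return HaplotypePanel(
        alleles=alleles,
        variant_ids=[f"snp{j + 1}" for j in range(m_snp)],
        positions=positions,
        allele_freqs=alleles.mean(axis=0),
    )


def sim_gwas_z(ld: LDMatrix, config: CausalConfig, seed: int = 0, rng=None) -> np.ndarray:
    """One exact draw Z ~ N(Sigma (lambda o C), Sigma)."""
    if config.m != ld.m:
        raise ValueError("configuration length does not match LD matrix")
    if rng is None:
        rng = np.random.default_rng(seed)
    mean = ld.r @ (config.lam * config.c)
    chol = safe_cholesky(ld.r)
    return mean + chol @ rng.standard_normal(ld.m)


def _stats_from_z(z: np.ndarray, panel: HaplotypePanel, n: int) -> SummaryStats:
    se = np.full(panel.m, 1.0 / np.sqrt(n))
    return SummaryStats(
        ids=list(panel.variant_ids),
        effect_allele=["G"] * panel.m,
        other_allele=["A"] * panel.m,
        freq=panel.allele_freqs.copy(),
        beta=z / np.sqrt(n),
        se=se,
        p=p_from_z(z),
        n=np.full(panel.m, float(n)),
        chrom=["1"] * panel.m,
        pos=panel.positions.copy(),
    )


def sim_pair_scenario(
    panel: HaplotypePanel, scen: SimScenario, seed: int = 0
) -> tuple[SummaryStats, SummaryStats]:
    """Paired GWAS and eQTL summary tables under a pleiotropy/linkage/null scenario."""
    if max(scen.causal_gwas, scen.causal_eqtl) >= panel.m:
        raise ValueError("causal index outside the panel")
    ld = ld_from_haplotypes(panel)
    rng = np.random.default_rng(seed)
    cfg_g = CausalConfig.from_indices(panel.m, [scen.causal_gwas], [scen.lambda_gwas])
    cfg_e = CausalConfig.from_indices(panel.m, [scen.causal_eqtl], [scen.lambda_eqtl])
    z_g = sim_gwas_z(ld, cfg_g, rng=rng)
    z_e = sim_gwas_z(ld, cfg_e, rng=rng)
    return _stats_from_z(z_g, panel, scen.n_gwas), _stats_from_z(z_e, panel, scen.n_eqtl)


def sim_annotations(
    config: CausalConfig, gamma0: float, gamma1: float, seed: int = 0, n_annot: int = 1
) -> np.ndarray:
    """Binary annotation matrix with a logistic enrichment at causal SNPs.

    P(annotated | causal) = logistic(gamma0 + gamma1);
    P(annotated | non-causal) = logistic(gamma0).
    """
    if not (np.isfinite(gamma0) and np.isfinite(gamma1)):
        raise ValueError("gamma values must be finite")
    rng = np.random.default_rng(seed)
    logit = gamma0 + gamma1 * config.c
    prob = 1.0 / (1.0 + np.exp(-logit))
    return (rng.random((config.m, n_annot)) < prob[:, None]).astype(np.int8)


DEFAULT_MIXING_LOG2 = np.array([2.0, 1.0, 0.0, -1.0, -2.0])  # 4:1, 2:1, 1:1, 1:2, 1:4


def sim_qpcr_series(
    true_log2_ratios: np.ndarray = DEFAULT_MIXING_LOG2,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """TaqMan-style calibration mixing series: measured = intercept + slope*true + noise."""
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    true = np.asarray(true_log2_ratios, dtype=float)
    rng = np.random.default_rng(seed)
    measured = intercept + slope * true + rng.normal(0.0, noise_sd, size=true.shape)
    return pd.DataFrame(
        {"true_log2_ratio": true, "measured_log2_ratio": measured}
    )


def marginal_stats(genotypes: np.ndarray, phenotype: np.ndarray) -> "pd.DataFrame":
    """Per-SNP simple linear regression of phenotype on dosage.

    Returns a frame with slope, se, z (t-statistic) and two-sided p per SNP.
    Monomorphic SNPs get z = 0 and se = +inf.
    """
    import pandas as pd

    geno = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(geno).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if y.var() == 0:
        raise ValueError("phenotype variance must be positive")
    n, m = geno.shape
    xc = geno - geno.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    slope = (xc * yc[:, None]).sum(axis=0) / sxx_safe
    resid_ss = (yc**2).sum() - slope**2 * sxx_safe
    dof = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(resid_ss, 0.0) / dof / sxx_safe)
    zero_resid = se == 0
    z = np.where(zero_resid, np.inf, slope / np.where(se == 0, 1.0, se))
    p = 2.0 * sps.t.sf(np.abs(z), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    slope[mono] = 0.0
    se[mono] = np.inf
    z[mono] = 0.0
    p[mono] = 1.0
    return pd.DataFrame({"slope": slope, "se": se, "z": z, "p": p})


def sim_locus(
    m_snp: int = 12,
    causal_idx: int | None = None,
    lam: float = 6.0,
    rho: float = 0.9,
    n_hap: int = 1000,
    n_sample: int = 50000,
    seed: int = 0,
    annotations: np.ndarray | None = None,
) -> tuple[Locus, CausalConfig]:
    """One planted-causal synthetic locus: panel -> LD -> z-draw -> Locus."""
    rng = np.random.default_rng(seed)
    panel = sim_haplotypes(n_hap, m_snp, rho, seed=int(rng.integers(2**31)))
    ld = ld_from_haplotypes(panel)
    if causal_idx is None:
        causal_idx = int(rng.integers(m_snp))
    cfg = CausalConfig.from_indices(m_snp, [causal_idx], [lam])
    z = sim_gwas_z(ld, cfg, rng=rng)
    stats = _stats_from_z(z, panel, n_sample)
    return Locus(stats=stats, ld=ld, annotations=annotations), cfg
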