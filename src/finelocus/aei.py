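"""Calibrated allelic-expression-imbalance (AEI) quantification.

A TaqMan genotyping assay reports a log2 fluorescence ratio (VIC/FAM) that
is linear in the log2 allelic input ratio but with assay-specific slope and
intercept.  A mixing series of homozygous DNA at known ratios
(4:1, 2:1, 1:1, 1:2, 1:4) gives a linear calibration curve; measured cDNA
and gDNA log-ratios are inverted through it and the AEI statistic is the
normalized allelic ratio 2^(corrected_cDNA - corrected_gDNA), so 1.0 means
balanced expression.  The same correct-and-normalize operation serves
allele-specific ChIP ratios, with input DNA playing the gDNA role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class CalibrationCurve:
    """OLS fit of measured log2 fluorescence ratio on true log2 allele ratio."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("calibration coefficients must be finite")

    def invert(self, measured_log2: np.ndarray) -> np.ndarray:
        """Map measured log2 ratio back to the true-allele log2 scale."""
        if self.slope == 0:
            raise ValueError("calibration slope is zero; cannot invert")
        return (np.asarray(measured_log2, dtype=float) - self.intercept) / self.slope


@dataclass
class AEIMeasurement:
    sample_id: str
    genotype: str  # 'het', 'hom_ref', 'hom_alt'
    gdna_log2_ratio: float
    cdna_log2_ratio: float
    corrected_cdna_ratio: float = np.nan  # log2, true-allele scale
    normalized_allelic_ratio: float = np.nan  # linear cDNA/gDNA


def fit_calibration(true_log2, measured_log2) -> CalibrationCurve:
    """Ordinary least-squares standard curve from the mixing series."""
    x = np.asarray(true_log2, dtype=float)
    y = np.asarray(measured_log2, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need matching vectors of at least 2 points")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all true ratios identical")
    res = sps.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
    )


def correct_and_normalize(
    cdna_log2: float, gdna_log2: float, calib: CalibrationCurve
) -> float:
    """Calibration-corrected normalized allelic ratio (linear scale).

    Both measured log2 ratios are inverted through the standard curve and the
    ratio 2^(corrected_cdna - corrected_gdna) is returned; 1.0 = balanced.
    """
    corr_c = calib.invert(cdna_log2)
    corr_g = calib.invert(gdna_log2)
    return float(2.0 ** (corr_c - corr_g))


def quantify_samples(
    samples: list[AEIMeasurement], calib: CalibrationCurve
) -> list[AEIMeasurement]:
    """Fill in corrected and normalized ratios for a sample list."""
    out = []
    for s in samples:
        corr_c = float(calib.invert(s.cdna_log2_ratio))
        ratio = correct_and_normalize(s.cdna_log2_ratio, s.gdna_log2_ratio, calib)
        out.append(
            AEIMeasurement(
                sample_id=s.sample_id,
                genotype=s.genotype,
                gdna_log2_ratio=s.gdna_log2_ratio,
                cdna_log2_ratio=s.cdna_log2_ratio,
                corrected_cdna_ratio=corr_c,
                normalized_allelic_ratio=ratio,
            )
        )
    return out


def cohort_imbalance_test(ratios, genotypes=None) -> tuple[float, float]:
    """One-sample t-test of log2 normalized ratios against 0 (balance).

    Returns (mean linear ratio, two-sided p).  AEI is defined only for
    heterozygous samples; if genotypes are supplied any non-het entry is an
    error.  All-identical balanced input (zero variance at ratio 1) returns
    p = 1 ("no evidence").  Relabeling the alleles inverts every ratio and
    leaves the p-value unchanged.
    """
    ratios = np.asarray(ratios, dtype=float)
    if genotypes is not None:
        bad = [g for g in genotypes if g != "het"]
        if bad:
            raise ValueError(
                f"AEI is defined only for heterozygotes; found genotype {bad[0]!r}"
            )
    if ratios.size < 2:
        raise ValueError("need at least 2 heterozygous samples")
    if np.any(ratios <= 0):
        raise ValueError("normalized ratios must be positive")
    logr = np.log2(ratios)
    mean_ratio = float(ratios.mean())
    if np.allclose(logr, logr[0]):
        if abs(logr[0]) < 1e-12:
            return mean_ratio, 1.0
        return mean_ratio, float(np.finfo(float).tiny)
    t, p = sps.ttest_1samp(logr, 0.0)
    return mean_ratio, float(p)


def wilcoxon_imbalance_test(ratios) -> tuple[float, float]:
    """Nonparametric alternative: Wilcoxon signed-rank of log2 ratios vs 0."""
    ratios = np.asarray(ratios, dtype=float)
    logr = np.log2(ratios)
    if np.allclose(logr, 0.0):
        return float(ratios.mean()), 1.0
    stat, p = sps.wilcoxon(logr)
    return float(ratios.mean()), float(p)
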