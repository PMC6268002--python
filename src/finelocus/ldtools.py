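"""LD computation, summary-statistic I/O and harmonization, approximate conditioning.

Coordinates follow the VCF convention (1-based variant positions); BED
intervals elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]

#: A/T and C/G pairs cannot be oriented by allele letters alone.
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SummaryStatsError(ValueError):
    """Malformed or inconsistent summary-statistic input."""


@dataclass
class LDMatrix:
    """Signed pairwise correlation (r) between variants, rows aligned to ``variant_ids``."""

    r: np.ndarray
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = self.r.shape[0]
        if self.r.shape != (m, m):
            raise ValueError("LD matrix must be square")
        if len(self.variant_ids) != m:
            raise ValueError("variant_ids length must match matrix size")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-10):
            raise ValueError("LD entries must satisfy |r| <= 1")

    @property
    def m(self) -> int:
        return self.r.shape[0]

    def r2(self) -> np.ndarray:
        return self.r**2

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, columns=self.variant_ids).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


@dataclass
class SummaryStats:
    """Per-variant association summary records (GCTA ``.ma`` dialect).

    ``beta``/``se`` are on the standardized scale when produced by the
    synthetic generator (beta = z/sqrt(n), se = 1/sqrt(n)).
    """

    ids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    freq: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: np.ndarray
    chrom: list[str] | None = None
    pos: np.ndarray | None = None  # 1-based

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=int)
        m = len(self.ids)
        for name in ("effect_allele", "other_allele"):
            if len(getattr(self, name)) != m:
                raise SummaryStatsError(f"{name} length mismatch")
        for name in ("freq", "beta", "se", "p", "n"):
            if getattr(self, name).shape[0] != m:
                raise SummaryStatsError(f"{name} length mismatch")
        if np.any(self.se <= 0):
            raise SummaryStatsError("standard errors must be positive")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise SummaryStatsError("p-values must lie in (0, 1]")
        if len(set(self.ids)) != m:
            dup = pd.Series(self.ids)
            name = dup[dup.duplicated()].iloc[0]
            raise SummaryStatsError(f"duplicate SNP id {name!r}")

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.ids,
                "A1": self.effect_allele,
                "A2": self.other_allele,
                "freq": self.freq,
                "b": self.beta,
                "se": self.se,
                "p": self.p,
                "N": self.n,
            }
        )


def ld_from_haplotypes(panel) -> LDMatrix:
    """Pearson correlation of phased allele indicators (columns of the panel)."""
    alleles = np.asarray(panel.alleles, dtype=float)
    sd = alleles.std(axis=0)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        raise ValueError(
            f"monomorphic SNP in panel: {panel.variant_ids[mono[0]]!r}"
        )
    r = np.corrcoef(alleles, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(r, list(panel.variant_ids))


def ld_from_genotypes(dosages: np.ndarray, variant_ids: list[str]) -> LDMatrix:
    """Composite-LD from unphased dosages: Pearson correlation of dosage columns."""
    dosages = np.asarray(dosages, dtype=float)
    sd = dosages.std(axis=0)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        raise ValueError(f"monomorphic SNP in genotypes: {variant_ids[mono[0]]!r}")
    r = np.corrcoef(dosages, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(r, list(variant_ids))


def conditional_z(stats_or_z, ld: LDMatrix, cond_idx: int) -> np.ndarray:
    """Single-SNP approximate conditional z-scores.

    z_{j|c} = (z_j - r_{jc} z_c) / sqrt(1 - r_{jc}^2); the conditioned SNP's
    own conditional z is exactly 0. SNPs perfectly collinear with the
    conditioning SNP (|r| = 1, j != c) are non-estimable and returned as NaN.
    """
    z = stats_or_z.z if isinstance(stats_or_z, SummaryStats) else np.asarray(
        stats_or_z, dtype=float
    )
    if z.shape[0] != ld.m:
        raise ValueError("z length does not match LD matrix")
    if not 0 <= cond_idx < ld.m:
        raise IndexError("cond_idx out of range")
    r = ld.r[:, cond_idx]
    out = np.empty_like(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (z - r * z[cond_idx]) / np.sqrt(1.0 - r**2)
    collinear = (np.abs(r) >= 1.0 - 1e-12)
    out[collinear] = np.nan
    out[cond_idx] = 0.0
    return out


def write_summary(stats: SummaryStats, path) -> None:
    """Write a whitespace ``.ma`` table (columns SNP A1 A2 freq b se p N)."""
    stats.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary(path, reference_alleles: dict[str, tuple[str, str]] | None = None) -> SummaryStats:
    """Read a ``.ma`` summary table, optionally harmonizing allele orientation.

    ``reference_alleles`` maps SNP id to the reference (effect, other)
    orientation.  A record whose alleles are swapped relative to the
    reference gets its beta (and hence z) sign-flipped and freq complemented.
    Strand-ambiguous variants (A/T, C/G) that do not match either orientation
    raise an error rather than being silently flipped.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SummaryStatsError(f"cannot parse summary table {path}: {exc}") from exc
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"summary table {path} missing required column(s): {', '.join(missing)}"
        )
    for col in ("freq", "b", "se", "p", "N"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            # +2: header line and 1-based numbering
            raise SummaryStatsError(
                f"non-numeric value in column {col!r} at line {bad + 2} of {path}"
            )
    dup = df["SNP"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise SummaryStatsError(
            f"duplicate SNP id {df['SNP'][dup.idxmax()]!r} at line {line} of {path}"
        )

    a1 = df["A1"].astype(str).str.upper().tolist()
    a2 = df["A2"].astype(str).str.upper().tolist()
    beta = df["b"].to_numpy(dtype=float)
    freq = df["freq"].to_numpy(dtype=float)

    if reference_alleles is not None:
        for i, snp in enumerate(df["SNP"].astype(str)):
            if snp not in reference_alleles:
                continue
            ref_ea, ref_oa = (x.upper() for x in reference_alleles[snp])
            if (a1[i], a2[i]) == (ref_ea, ref_oa):
                continue
            if (a1[i], a2[i]) == (ref_oa, ref_ea):
                if (a1[i], a2[i]) in _AMBIGUOUS:
                    raise SummaryStatsError(
                        f"strand-ambiguous variant {snp!r} ({a1[i]}/{a2[i]}) cannot "
                        "be harmonized by allele letters; resolve strand upstream"
                    )
                beta[i] = -beta[i]
                freq[i] = 1.0 - freq[i]
                a1[i], a2[i] = ref_ea, ref_oa
            else:
                raise SummaryStatsError(
                    f"alleles of {snp!r} ({a1[i]}/{a2[i]}) do not match reference "
                    f"orientation {ref_ea}/{ref_oa}"
                )

    return SummaryStats(
        ids=df["SNP"].astype(str).tolist(),
        effect_allele=a1,
        other_allele=a2,
        freq=freq,
        beta=beta,
        se=df["se"].to_numpy(dtype=float),
        p=df["p"].to_numpy(dtype=float),
        n=df["N"].to_numpy(dtype=float),
    )


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value, floored away from exact zero."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)
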