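"""Position-weight-matrix parsing, allele-aware scoring and density profiling.

Scoring follows the JASPAR scan-tool conventions: counts get a pseudocount
(default 0.8, distributed proportionally to the background composition),
per-column probabilities are converted to log2 odds against the background,
a window's raw score is the summed log-odds, and the relative score rescales
it to [0,1] via the matrix's minimal and maximal attainable sums.  P-values
under a background-random L-mer come from the exact distribution of the
integer-discretized score, computed by dynamic-programming convolution
across columns.  Hits are reported 0-based half-open; a '-'-strand hit's
start refers to the forward-strand window start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G

UNIFORM_BG = np.full(4, 0.25)
#: background base composition used for genome scanning (A, C, G, T)
GENOME_SCAN_BG = np.array([0.29, 0.21, 0.21, 0.29])
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_P_CUTOFF = 1e-4
DEFAULT_GRANULARITY = 1e-3


class MotifError(ValueError):
    pass


@dataclass
class MotifHit:
    seq_id: str
    start: int  # 0-based, forward strand
    strand: str  # '+' or '-'
    score: float  # summed log2 odds
    rel_score: float
    pvalue: float

    @property
    def end(self) -> int:
        return self.start + getattr(self, "_length", 0)


@dataclass
class PWM:
    """Position frequency matrix with background composition and log-odds scoring."""

    counts: np.ndarray  # 4 x L, rows A,C,G,T
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    name: str = "motif"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise MotifError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise MotifError("matrix must have at least one column")
        if np.any(self.counts < 0):
            raise MotifError("counts must be nonnegative")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise MotifError("background must sum to 1")
        if self.pseudocount <= 0:
            raise MotifError("pseudocount must be positive")
        self._dist_cache: dict = {}

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probs(self) -> np.ndarray:
        adj = self.counts + self.pseudocount * self.background[:, None]
        return adj / adj.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    @property
    def score_min(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def score_max(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def information_content(self) -> float:
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = p * np.log2(np.where(p > 0, p, 1.0) / self.background[:, None])
        return float(ic.sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            counts=self.counts[_COMPLEMENT_PERM][:, ::-1].copy(),
            background=self.background[_COMPLEMENT_PERM].copy(),
            pseudocount=self.pseudocount,
            name=self.name + "_rc",
        )


def parse_jaspar(text: str) -> PWM:
    """Parse a JASPAR PFM record: '>ID NAME' header, four bracketed base rows."""
    name = "motif"
    rows: dict[str, list[float]] = {}
    for line in text.strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip() or "motif"
            continue
        m = re.match(r"^([ACGTacgt])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$", line)
        if not m:
            raise MotifError(f"unrecognized matrix row: {line!r}")
        base = m.group(1).upper()
        if base in rows:
            raise MotifError(f"duplicate row for base {base}")
        try:
            vals = [float(x) for x in m.group(2).split()]
        except ValueError:
            raise MotifError(f"non-numeric count in row for base {base}")
        rows[base] = vals
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise MotifError(f"missing base row(s): {', '.join(missing)}")
    lengths = {b: len(v) for b, v in rows.items()}
    if len(set(lengths.values())) != 1:
        detail = ", ".join(f"{b}:{n}" for b, n in lengths.items())
        raise MotifError(f"rows have unequal lengths ({detail})")
    counts = np.array([rows[b] for b in BASES])
    if np.any(counts < 0):
        bad = BASES[int(np.argwhere(counts < 0)[0][0])]
        raise MotifError(f"negative count in row for base {bad}")
    return PWM(counts=counts, name=name)


def write_jaspar(pwm: PWM) -> str:
    lines = [f">{pwm.name}"]
    for i, b in enumerate(BASES):
        vals = " ".join(f"{v:g}" for v in pwm.counts[i])
        lines.append(f"{b} [ {vals} ]")
    return "\n".join(lines) + "\n"


def encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            raise MotifError(f"non-ACGT character {ch!r} at position {i}")
        out[i] = idx
    return out


def raw_score(pwm: PWM, window) -> float:
    idx = encode(window) if isinstance(window, str) else np.asarray(window)
    if idx.shape[0] != pwm.length:
        raise MotifError(
            f"window length {idx.shape[0]} != matrix length {pwm.length}"
        )
    lo = pwm.log_odds
    return float(lo[idx, np.arange(pwm.length)].sum())


def relative_score(pwm: PWM, window) -> float:
    """(S - S_min) / (S_max - S_min) of the summed log-odds, in [0, 1]."""
    s = raw_score(pwm, window)
    smin, smax = pwm.score_min, pwm.score_max
    if smax == smin:
        return 1.0
    return (s - smin) / (smax - smin)


def _score_distribution(pwm: PWM, granularity: float = DEFAULT_GRANULARITY):
    """Exact distribution of the integer-discretized score sum under the background.

    Returns (offset, probs) where probs[i] = P(S_int = offset + i) and
    S_int is the sum over columns of round(log_odds / granularity).
    """
    key = granularity
    if key in pwm._dist_cache:
        return pwm._dist_cache[key]
    iscores = np.round(pwm.log_odds / granularity).astype(np.int64)
    bg = pwm.background
    lo_off = int(iscores.min(axis=0).sum())
    hi_off = int(iscores.max(axis=0).sum())
    probs = np.array([1.0])
    offset = 0
    for col in range(pwm.length):
        cmin = int(iscores[:, col].min())
        width = int(iscores[:, col].max()) - cmin
        new = np.zeros(probs.size + width)
        for b in range(4):
            sh = int(iscores[b, col]) - cmin
            new[sh : sh + probs.size] += bg[b] * probs
        probs = new
        offset += cmin
    assert offset == lo_off and offset + probs.size - 1 == hi_off
    # survival function P(S_int >= offset + i)
    sf = np.cumsum(probs[::-1])[::-1]
    pwm._dist_cache[key] = (offset, probs, sf)
    return pwm._dist_cache[key]


def score_pvalue(
    pwm: PWM, score: float, granularity: float = DEFAULT_GRANULARITY
) -> float:
    """P(S >= score) for a background-random L-mer, from the exact DP distribution."""
    offset, probs, sf = _score_distribution(pwm, granularity)
    s_int = int(round(score / granularity))
    if s_int <= offset:
        return 1.0
    if s_int > offset + probs.size - 1:
        # beyond the maximal attainable score: report the boundary mass
        return float(probs[-1])
    return float(sf[s_int - offset])


def scan_sequences(
    sequences: dict[str, str],
    pwm: PWM,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    both_strands: bool = True,
    non_overlapping: bool = True,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan sequences for windows with background p-value <= cutoff.

    With ``non_overlapping``, hits are selected greedily by descending score
    (ties: leftmost first, then '+' strand first).
    """
    length = pwm.length
    rc = pwm.reverse_complement() if both_strands else None
    hits: list[MotifHit] = []
    smin, smax = pwm.score_min, pwm.score_max
    span = smax - smin if smax != smin else 1.0
    for seq_id, seq in sequences.items():
        if len(seq) < length:
            continue
        idx = encode(seq)
        lo_f = pwm.log_odds
        windows = np.lib.stride_tricks.sliding_window_view(idx, length)
        col = np.arange(length)
        scores_f = lo_f[windows, col].sum(axis=1)
        strand_scores = [("+", scores_f, pwm)]
        if both_strands:
            lo_r = rc.log_odds
            scores_r = lo_r[windows, col].sum(axis=1)
            strand_scores.append(("-", scores_r, rc))
        for strand, scores, mat in strand_scores:
            # smallest integer score whose survival probability clears the cutoff
            offset, _, sf = _score_distribution(mat, granularity)
            passing = np.flatnonzero(sf <= p_cutoff)
            if passing.size == 0:
                continue
            s_threshold = (offset + passing[0]) * granularity
            for start in np.flatnonzero(scores >= s_threshold - granularity / 2):
                p = score_pvalue(mat, float(scores[start]), granularity)
                if p <= p_cutoff:
                    h = MotifHit(
                        seq_id=seq_id,
                        start=int(start),
                        strand=strand,
                        score=float(scores[start]),
                        rel_score=(float(scores[start]) - smin) / span,
                        pvalue=p,
                    )
                    h._length = length
                    hits.append(h)
    if not non_overlapping:
        hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
        return hits
    # greedy: descending score, ties leftmost then '+' strand
    hits.sort(key=lambda h: (-h.score, h.start, 0 if h.strand == "+" else 1))
    chosen: list[MotifHit] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        spans = occupied.setdefault(h.seq_id, [])
        lo, hi = h.start, h.start + length
        if any(lo < e and s < hi for s, e in spans):
            continue
        spans.append((lo, hi))
        chosen.append(h)
    chosen.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return chosen


def scan_fasta(path, pwm: PWM, **kwargs) -> list[MotifHit]:
    """Scan every record of a FASTA file."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return scan_sequences(seqs, pwm, **kwargs)


def allele_best_scores(
    pwm: PWM,
    flank5: str,
    ref_allele: str,
    alt_allele: str,
    flank3: str,
    granularity: float = DEFAULT_GRANULARITY,
) -> tuple[MotifHit, MotifHit, float]:
    """Best motif match overlapping each allele of a variant (indel-aware).

    Builds flank5+allele+flank3 per allele, scans every window (both strands)
    overlapping the allele bases, and returns the maximal-relative-score hit
    per allele plus (ref - alt) relative-score difference.
    """
    length = pwm.length
    if len(flank5) < length - 1 or len(flank3) < length - 1:
        raise MotifError(
            f"flanks must each be at least {length - 1} bases for a length-{length} matrix"
        )

    def best(allele: str, tag: str) -> MotifHit:
        hap = flank5 + allele + flank3
        idx = encode(hap)
        lo_start = len(flank5) - length + 1
        hi_start = len(flank5) + max(len(allele), 1) - 1
        best_hit: MotifHit | None = None
        smin, smax = pwm.score_min, pwm.score_max
        span = smax - smin if smax != smin else 1.0
        # '+' strand scanned first, so a strict comparison breaks ties toward it
        for mat, strand in ((pwm, "+"), (pwm.reverse_complement(), "-")):
            lo = mat.log_odds
            for start in range(max(lo_start, 0), min(hi_start, len(hap) - length) + 1):
                s = float(lo[idx[start : start + length], np.arange(length)].sum())
                if best_hit is None or s > best_hit.score:
                    h = MotifHit(
                        seq_id=tag,
                        start=start,
                        strand=strand,
                        score=s,
                        rel_score=(s - smin) / span,
                        pvalue=score_pvalue(mat, s, granularity),
                    )
                    h._length = length
                    best_hit = h
        assert best_hit is not None
        return best_hit

    ref_hit = best(ref_allele, "ref")
    alt_hit = best(alt_allele, "alt")
    return ref_hit, alt_hit, ref_hit.rel_score - alt_hit.rel_score


def shuffle_pwm(pwm: PWM, seed: int = 0) -> PWM:
    """Column-order permutation control: same column multiset, shuffled order."""
    if pwm.length < 2:
        raise MotifError("need at least 2 columns to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pwm.length)
    return PWM(
        counts=pwm.counts[:, perm].copy(),
        background=pwm.background.copy(),
        pseudocount=pwm.pseudocount,
        name=pwm.name + "_shuffled",
    )


@dataclass
class DensityProfile:
    """Fold-change of target-site abundance around reference feature centers."""

    bin_centers: np.ndarray  # signed bp offsets
    fold_change: np.ndarray
    window_bp: int
    range_bp: int

    def central_bin(self) -> int:
        """Index of the bin whose half-open interval contains offset 0."""
        d = np.abs(self.bin_centers)
        ties = np.flatnonzero(d == d.min())
        # bins are right-open, so offset 0 lands in the bin starting at 0
        return int(ties[-1])


def density_profile(
    reference_centers: np.ndarray,
    target_sites: np.ndarray,
    range_bp: int = 10_000,
    window_bp: int = 500,
    genome_length: int | None = None,
) -> DensityProfile:
    """Histogram of target sites at signed offsets from reference centers,
    normalized to fold change relative to a uniform genome average.

    The expected count per bin under uniform targets is
    n_ref * n_target * window_bp / genome_length; dividing by it makes 1.0
    the no-enrichment baseline.
    """
    if genome_length is None or genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if range_bp <= 0 or window_bp <= 0 or (2 * range_bp) % window_bp != 0:
        raise ValueError("window_bp must divide 2*range_bp")
    refs = np.sort(np.asarray(reference_centers, dtype=np.int64))
    targets = np.sort(np.asarray(target_sites, dtype=np.int64))
    n_bins = 2 * range_bp // window_bp
    edges = np.linspace(-range_bp, range_bp, n_bins + 1)
    counts = np.zeros(n_bins)
    if targets.size == 0:
        import warnings

        warnings.warn("no target sites; profile is all zero", stacklevel=2)
        centers = (edges[:-1] + edges[1:]) / 2.0
        return DensityProfile(centers, counts, window_bp, range_bp)
    for ref in refs:
        lo = np.searchsorted(targets, ref - range_bp, side="left")
        hi = np.searchsorted(targets, ref + range_bp, side="right")
        if hi > lo:
            counts += np.histogram(targets[lo:hi] - ref, bins=edges)[0]
    expected = refs.size * targets.size * window_bp / genome_length
    centers = (edges[:-1] + edges[1:]) / 2.0
    return DensityProfile(centers, counts / expected, window_bp, range_bp)
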