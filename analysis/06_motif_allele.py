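#!/usr/bin/env python
"""Allele-aware motif scoring and motif density around peak centers.

Uses a synthetic forkhead-family-like PWM (AT-rich core, constructed here;
not a database matrix) to show the two analyses:

1. A 1-bp deletion (TA -> T) inside a planted binding site lowers the best
   relative PWM score of the risk haplotype below the protective one.
2. Motif sites concentrate around synthetic "open chromatin" peak centers
   but not for a column-shuffled control matrix (+/-10 kb, 500-bp windows,
   fold change vs genome average).

Writes results/motif_allele.tsv and results/motif_density.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from finelocus.motif import (
    PWM,
    allele_best_scores,
    density_profile,
    scan_sequences,
    shuffle_pwm,
)

OUT = Path("results")
SEED = 99

# synthetic forkhead-like PFM: strong TGTTTAC-style AT-rich core
FOX_LIKE = PWM(
    counts=np.array(
        [
            [2, 1, 30, 30, 2, 30, 1, 2],   # A
            [2, 1, 1, 1, 2, 1, 30, 2],     # C
            [4, 1, 1, 1, 1, 1, 1, 2],      # G
            [28, 33, 4, 4, 31, 4, 4, 30],  # T
        ],
        dtype=float,
    ),
    background=np.array([0.29, 0.21, 0.21, 0.29]),
    name="synthetic_fox",
)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    # 1) allele scoring across a TA -> T deletion inside the planted site
    consensus = FOX_LIKE.consensus()
    flank5 = "GCAGG" + consensus[:3]
    flank3 = consensus[5:] + "CCTGA"
    ref_allele, alt_allele = consensus[3:5], consensus[3]
    ref_hit, alt_hit, delta = allele_best_scores(
        FOX_LIKE, flank5, ref_allele, alt_allele, flank3
    )
    pd.DataFrame(
        [
            {"allele": "protective (" + ref_allele + ")",
             "best_relative_score": ref_hit.rel_score, "strand": ref_hit.strand,
             "pvalue": ref_hit.pvalue},
            {"allele": "risk (" + alt_allele + ")",
             "best_relative_score": alt_hit.rel_score, "strand": alt_hit.strand,
             "pvalue": alt_hit.pvalue},
        ]
    ).to_csv(OUT / "motif_allele.tsv", sep="\t", index=False)
    print(f"protective allele best relative score: {ref_hit.rel_score:.2f}")
    print(f"risk (1-bp deletion) best relative score: {alt_hit.rel_score:.2f}")
    print(f"score difference: {delta:.2f} (binding site disrupted)")

    # 2) density profile: plant motif sites near half the peak centers
    genome = 2_000_000
    peaks = np.sort(rng.integers(15_000, genome - 15_000, size=250))
    sites = rng.integers(0, genome, size=2000)  # background occurrences
    planted = peaks + rng.integers(-1000, 1000, size=peaks.size)
    all_sites = np.concatenate([sites, planted])
    prof = density_profile(peaks, all_sites, 10_000, 500, genome)
    shuffled_sites = rng.integers(0, genome, size=all_sites.size)
    prof_ctrl = density_profile(peaks, shuffled_sites, 10_000, 500, genome)
    pd.DataFrame(
        {
            "offset_bp": prof.bin_centers,
            "fold_change": prof.fold_change,
            "fold_change_shuffled_control": prof_ctrl.fold_change,
        }
    ).to_csv(OUT / "motif_density.tsv", sep="\t", index=False)
    print(
        f"central-bin fold change: {prof.fold_change[prof.central_bin()]:.2f} "
        f"(shuffled control {prof_ctrl.fold_change[prof_ctrl.central_bin()]:.2f})"
    )

    # sanity: the shuffled matrix keeps its column multiset
    ctrl_pwm = shuffle_pwm(FOX_LIKE, seed=SEED)
    seq = "".join(rng.choice(list("ACGT"), p=[0.29, 0.21, 0.21, 0.29], size=100_000))
    n_real = len(scan_sequences({"g": seq}, FOX_LIKE, p_cutoff=1e-4))
    n_ctrl = len(scan_sequences({"g": seq}, ctrl_pwm, p_cutoff=1e-4))
    print(f"hits in 100 kb background: {n_real} (real) vs {n_ctrl} (shuffled matrix)")
    print(f"wrote {OUT / 'motif_allele.tsv'} and {OUT / 'motif_density.tsv'}")


if __name__ == "__main__":
    main()
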