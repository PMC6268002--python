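#!/usr/bin/env python
"""Bayes-factor fine-mapping of the study locus: enumeration vs stochastic search.

Computes per-SNP posterior inclusion probabilities (PIPs) over causal
configurations (k up to 3) by exhaustive enumeration and by shotgun
stochastic search, reports the 95% credible set, and verifies the two
posteriors agree. Writes results/finemap_pips.tsv and finemap_configs.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from finelocus.finemap import credible_set, posterior_exhaustive, posterior_sss
from finelocus.ldtools import LDMatrix, read_summary
from finelocus.locus import Locus

OUT = Path("results")


def main() -> None:
    stats = read_summary(OUT / "locus" / "gwas.ma")
    ld = LDMatrix.from_tsv(OUT / "locus" / "ld.tsv")
    locus = Locus(stats=stats, ld=ld)

    ex = posterior_exhaustive(locus, k_max=3)
    ss = posterior_sss(locus, k_max=3, n_iter=500, seed=1)
    gap = float(np.max(np.abs(ex.pip - ss.pip)))

    ex.to_frame().to_csv(OUT / "finemap_pips.tsv", sep="\t", index=False)
    ex.configs_frame().to_csv(OUT / "finemap_configs.tsv", sep="\t", index=False)

    top = ex.to_frame().iloc[0]
    cs = credible_set(ex, 0.95)
    print(f"evaluated {ex.n_evaluated} configurations exhaustively")
    print(f"top PIP: {top['id']} = {top['pip']:.3f}")
    print(f"95% credible set ({len(cs)} SNPs): {', '.join(cs)}")
    print(f"max |PIP difference| exhaustive vs stochastic search: {gap:.2e}")
    print(f"wrote {OUT / 'finemap_pips.tsv'} and {OUT / 'finemap_configs.tsv'}")


if __name__ == "__main__":
    main()
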