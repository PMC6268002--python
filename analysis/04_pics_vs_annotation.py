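#!/usr/bin/env python
"""LD-only vs annotation-informed fine-mapping of the study locus.

The permutation method (lead association fixed) ranks variants purely by
their LD with the lead SNP, so the lead itself tops its list.  The
empirical-Bayes annotation model learns an enrichment of causal variants in
functional annotations from a panel of training loci and can promote an
annotated variant above an unannotated one in comparable LD — the key
qualitative difference between the two approaches.  Writes results/pics.tsv
and results/paintor_pips.tsv.
"""

from pathlib import Path

import pandas as pd

from finelocus.ldtools import LDMatrix, read_summary
from finelocus.locus import Locus
from finelocus.paintor_em import em_fit
from finelocus.pics import pics_posterior
from finelocus.synthetic import sim_annotations, sim_locus

OUT = Path("results")
SEED = 777


def main() -> None:
    stats = read_summary(OUT / "locus" / "gwas.ma")
    ld = LDMatrix.from_tsv(OUT / "locus" / "ld.tsv")
    ann = pd.read_csv(OUT / "locus" / "annotations.tsv", sep="\t")
    locus = Locus(stats=stats, ld=ld,
                  annotations=ann["open_chromatin"].to_numpy()[:, None])

    pics = pics_posterior(locus, n_perm=10_000, r2_min=0.5, seed=SEED)
    pics.to_frame().to_csv(OUT / "pics.tsv", sep="\t", index=False)

    # enrichment is learned jointly across the study locus and training loci
    train = []
    for i in range(30):
        loc, cfg = sim_locus(m_snp=10, seed=SEED + 10 + i)
        a = sim_annotations(cfg, -2.0, 2.0, seed=SEED + 500 + i)
        train.append(Locus(stats=loc.stats, ld=loc.ld, annotations=a))
    model, pips = em_fit(train + [locus], k_max=2)
    pd.DataFrame({"id": locus.ids, "pip": pips[-1]}).sort_values(
        "pip", ascending=False
    ).to_csv(OUT / "paintor_pips.tsv", sep="\t", index=False)

    pics_top = pics.to_frame().iloc[0]["id"]
    em_top = locus.ids[int(pips[-1].argmax())]
    print(f"LD-only permutation ranking: top variant {pics_top}")
    print(f"fitted annotation log-odds: {model.gamma[1]:.2f} "
          f"(intercept {model.gamma[0]:.2f}, {model.n_iter} EM iterations)")
    print(f"annotation-informed ranking: top variant {em_top}")
    print(f"wrote {OUT / 'pics.tsv'} and {OUT / 'paintor_pips.tsv'}")


if __name__ == "__main__":
    main()
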