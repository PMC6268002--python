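# finelocus

Statistical machinery for nominating a causal regulatory variant and its
target gene at a GWAS locus, built for the common situation where a
non-coding variant in tight LD with the lead SNP is the better functional
candidate. The package implements, over summary statistics and an LD
reference panel:

- **LD-aware fine-mapping** three ways: permutation-based causal
  probabilities with the lead association fixed (PICS-style), Bayes-factor
  posteriors over causal configurations with exhaustive enumeration or
  shotgun stochastic search (FINEMAP-style), and annotation-informed
  empirical-Bayes posteriors with a logistic enrichment prior fitted by EM
  (PAINTOR-style);
- **GWAS–eQTL colocalization** via summary-based Mendelian randomization
  (SMR) with the HEIDI heterogeneity test separating pleiotropy from
  linkage;
- **allele-aware transcription-factor motif scoring** (including 1-bp
  indels), exact score-distribution p-values by dynamic programming, matrix
  randomization controls, and peak-centered motif density profiles;
- **calibrated allelic-expression-imbalance (AEI) quantification** from
  TaqMan-style mixing-series standard curves;
- a **synthetic-data generator** producing every input with the statistical
  structure the models assume, so the entire study runs offline.

## Models in brief

Association z-scores at a locus follow the standard summary-statistic model

    Z ~ N(Σ (λ ∘ C), Σ)

where `Σ` is the LD correlation matrix, `C` the binary causal-configuration
vector and `λ` the non-centrality parameters. The Bayes-factor engine
integrates `λ` out against a N(0, s²) prior, giving
`Z ~ N(0, Σ + s² Σ_C Σ_Cᵀ)` against the null `N(0, Σ)`, and scores a size-k
configuration by `(m choose k)⁻¹ p_k · BF`. The annotation model keeps the
plug-in mean `Σ(λ∘C)` with `λ_j = z_j` and a per-SNP prior
`logistic(γ₀ + γ·A_j)` learned across loci by EM. SMR tests the ratio
`b_xy = β_GWAS/β_eQTL` at the top cis-eQTL with
`T_SMR = z_g² z_e²/(z_g² + z_e²) ~ χ²(1)`; HEIDI measures heterogeneity of
`b_xy` across the instrument's LD neighborhood. Motif scores are summed
log2 odds rescaled to [0, 1] by the matrix's attainable extremes; AEI is
the calibration-corrected ratio `2^(corrected cDNA − corrected gDNA)`.

## Worked example

The numbered drivers under `analysis/` run the synthetic study end to end
and write their tables under `results/`:

```
$ python analysis/01_simulate_locus.py
simulated 12-SNP locus (seed 20260944)
planted causal variant: snp3 (lambda = 6)
lead (top |z|) variant: snp4

$ python analysis/04_pics_vs_annotation.py
LD-only permutation ranking: top variant snp4
fitted annotation log-odds: 2.55 (intercept -3.12, 8 EM iterations)
annotation-informed ranking: top variant snp3
```

The draw is the instructive regime: the planted causal variant (snp3, which
carries the functional annotation) is in tight LD (r² = 0.81) with the lead
SNP (snp4), so the LD-only permutation method ranks the lead first while
the annotation-informed model promotes the annotated causal variant — the
reason annotation-aware fine-mapping can overturn a purely LD-based
ranking. The other drivers show the remaining stages:

```
$ python analysis/05_smr_heidi.py
pleiotropy: colocalized in 187/200 replicates
linkage: colocalized in 55/200 replicates
null: colocalized in 9/200 replicates

$ python analysis/06_motif_allele.py
protective allele best relative score: 1.00
risk (1-bp deletion) best relative score: 0.74
score difference: 0.26 (binding site disrupted)
central-bin fold change: 1.42 (shuffled control 0.96)

$ python analysis/07_aei.py
12 of 12 heterozygous samples show ratio < 1
mean normalized allelic ratio: 0.64 (planted 0.65)
cohort imbalance p = 1.59e-08
```

A shared causal variant colocalizes (SMR significant, HEIDI quiet); two
linked causal variants are mostly rejected by HEIDI; a 1-bp deletion inside
a forkhead-like binding site drops the best match score; and a planted 0.65
allelic ratio is recovered from calibrated qPCR ratios with a strongly
significant cohort test.

The same stages are available as a CLI (`finelocus --help`), including a
YAML-configured end-to-end run (`finelocus run --config toy.yaml`) that
writes a checksummed output manifest; fixed configs reproduce byte-identical
outputs.

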