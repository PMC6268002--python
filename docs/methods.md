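# Methods

## Scope and data model

`finelocus` analyzes one genomic region ("locus") at a time: per-SNP GWAS
or eQTL summary statistics (effect, SE, z, p, n, alleles), an LD matrix of
signed Pearson correlations from a phased reference panel, and optional
binary functional annotations. Variant coordinates are 1-based (VCF
convention); BED-style intervals and motif hits are 0-based half-open.
Summary tables use the whitespace-delimited `SNP A1 A2 freq b se p N`
layout. Allele harmonization against a reference orientation flips the
effect sign and complements the frequency for swapped records;
strand-ambiguous variants (A/T, C/G) that mismatch raise an error rather
than being silently flipped, because silent strand flips are the classic
summary-statistic bug.

## Synthetic data generator

The generator exists so every engine can be exercised and calibrated
offline, with inputs drawn from exactly the models the engines assume.

* **Haplotypes.** First-order Markov copy process: site j copies site j−1
  with probability ρ, else redraws at the site's target frequency (MAF
  uniform in (0.05, 0.5) by default). Adjacent-site correlation ≈ ρ and LD
  decays geometrically with distance. This is deliberately not a coalescent
  simulation: no recombination hotspots, no demography, no rare-variant
  spectrum — sufficient for LD-structure properties, not for population-
  genetic realism. Monomorphic columns (possible at small panel sizes) are
  repaired by flipping one haplotype.
* **Association statistics.** `Z ~ N(Σ(λ∘C), Σ)` drawn exactly through a
  Cholesky factor; β = z/√n and se = 1/√n correspond to a standardized
  trait and genotypes, keeping summary-level quantities internally
  consistent without individual data. Defaults plant a single causal SNP
  with λ = 6 (a clearly genome-wide-significant effect) on a ρ = 0.9 panel.
* **Paired GWAS/eQTL scenarios.** pleiotropy (shared causal index),
  linkage (distinct causal indices), null (λ_GWAS = 0); default sample
  sizes n_GWAS = 100,000 and n_eQTL = 500, and default non-centralities
  λ_eQTL = 8 (strong instrument) and λ_GWAS = 6, typical of a large CAD
  meta-analysis paired with a tissue eQTL study.
* **Annotations.** Bernoulli with logit γ₀ + γ₁·causal; defaults γ₀ = −2,
  γ₁ = 2 (≈12% background annotation rate, ≈50% at causal SNPs).
* **qPCR calibration series.** The 4:1, 2:1, 1:1, 1:2, 1:4 mixing design
  (log2 ratios 2, 1, 0, −1, −2) with a linear assay response
  `measured = intercept + slope·true + N(0, σ)`.

Every generator takes an explicit integer seed; identical seeds give
bit-identical output. What passing tests on these inputs do **not** show:
robustness to LD-panel mismatch, allele-frequency-dependent effect sizes,
non-Gaussian effect distributions, or assay nonlinearity outside the
calibrated range.

## Bayes-factor configuration posterior

For a configuration with causal set J and prior effect scale s on the
non-centrality, the marginal likelihood is `Z ~ N(0, Σ + s²Σ_JΣ_Jᵀ)` and the
Bayes factor is the density ratio against `N(0, Σ)`. We use this
prior-integrated (centered) form rather than a plug-in mean form; the two
parameterizations coincide in ranking for single-causal identity-LD cases,
and the integrated form makes the null BF exactly 1. The unnormalized
posterior of a size-k configuration is `(m choose k)⁻¹ p_k BF`, with m the
number of SNPs in the locus, p_k uniform over k ∈ {0..k_max} and k_max = 5
by default; the null configuration is a scored hypothesis. Defaults
s = 3.0 on the z scale (typical significant hits have |z| 5–8); exposed.

Exhaustive mode enumerates all `Σ_k (m choose k)` configurations and is
guarded at m ≤ 25. Shotgun stochastic search scores every add/delete/swap
neighbor of the current configuration each iteration, caches all distinct
evaluated configurations, and moves to an evaluated-but-never-expanded
configuration sampled in proportion to its posterior weight. Never
re-expanding a state makes the search sweep the neighborhood graph rather
than lingering at the mode; on small loci it typically covers the entire
configuration space, which is why its posterior can match enumeration to
machine precision. Posteriors are normalized over the evaluated set by
log-sum-exp; PIP_j sums posteriors of configurations containing j; the
credible set takes SNPs by descending PIP (ties by id) until the cumulative
renormalized PIP reaches the level.

Numerics: all engines factorize Σ by Cholesky, adding a 1e-6 diagonal ridge
**only when the unridged factorization fails** (e.g. perfect-LD duplicate
SNPs). The adaptive ridge keeps well-conditioned loci exact — closed-form
checks hold to 1e-10 — while still handling singular LD.

## Permutation-based causal probabilities (lead fixed)

With the lead SNP's observed strength S = −log10 p fixed, every SNP with
r² ≥ 0.5 to the lead (configurable) is a causal hypothesis. Under
"j causal at strength S", SNP i's −log10 p is modeled as
`N(r²_ij·S, sd(r_ij, S))` with the empirical spread
`sd = √(1 − |r|^6.4)·√S/2` (a configurable callable, floored at 1e-6 so the
perfect-LD case is well defined). The likelihood of the observed profile
under each hypothesis is estimated from 10,000 permuted profiles via
per-SNP Gaussian kernel densities (Silverman bandwidth, floored at 1e-3)
under an independence approximation; a closed-form normal-density variant
is provided and agrees in ranking. Posteriors follow Bayes' rule with equal
priors over hypotheses (the lead included).

A structural consequence: the model's spread vanishes as r → 1, so each
hypothesis is near-degenerate at its own SNP and normalized posteriors
saturate to 0/1 unless observed associations are effectively tied. The
result object therefore also carries the per-hypothesis log-likelihoods,
which remain comparable after underflow. Ranking ties are broken by
probability, then r² to the lead, then id.

## Annotation-informed empirical-Bayes fine-mapping

Locus likelihood: `N(Z; Σ(λ∘C), Σ)` with plug-in `λ_j = z_j` at causal
positions (the prior-integrated alternative is available through the
Bayes-factor engine). The plug-in form admits an algebraic simplification,
`log f(C) = log f(0) + Σ_{j∈J} z_j² − ½ z_Jᵀ Σ_JJ z_J`, which the EM uses;
equivalence with the generic MVN density is tested. Configuration prior:
product of per-SNP Bernoulli probabilities `logistic(γ·[1, A_j])`.

EM across loci: the E-step enumerates configurations with k ≤ k_max
(default 2; full 2^m enumeration is intractable and k ≤ 2 is the
conventional cap) and computes config posteriors ∝ prior × likelihood; the
M-step fits weighted logistic regression of per-SNP posterior causal
probabilities on annotations by Newton–Raphson with step halving
(tol 1e-6). The truncated-support marginal log-likelihood is monotone
under this EM (the Jensen bound holds over the truncated latent set) and
is asserted non-decreasing in tests on every run. Perfect separation
(an annotation exactly predicting causality) is caught by clipping γ at
±10 with a warning; non-convergence at max_iter flags the result.
Enrichment standard errors come from the observed information of the final
weighted logistic fit.

With ~50 single-causal training loci the γ₁ estimator is unbiased with
Monte-Carlo sd ≈ 0.36 (dominated by the binomial noise of ~50 causal
annotation draws); recovery tests are therefore calibrated at a 3σ
tolerance.

## SMR and HEIDI

SMR: `b_xy = β_GWAS/β_eQTL` at the instrument (top cis-eQTL SNP);
`T_SMR = z_g²z_e²/(z_g²+z_e²)` against χ²(1). Pipeline filters follow the
nominal decision rule exactly: instrument eQTL p < 5e-5, GWAS p at the
instrument < 0.05, and the colocalization call
`p_SMR < 0.05 AND p_HEIDI > 0.05` with no multiple-testing correction.

HEIDI: secondary SNPs with eQTL p < 1.57e-3 and 0.05 ≤ r² ≤ 0.9 with the
instrument (capped at the 20 most significant; at least 3 required, else
the p-value is reported missing with a reason code). For each secondary
SNP, `d_i = b_xy(i) − b_xy(top)` is standardized by the delta-method
variance, with cross-SNP covariance propagated from LD within each study
(the two studies are independent). The statistic Σ z_d² is referred to a
Satterthwaite-scaled chi-square matching the first two moments of the
correlated sum (scale tr(R²)/k, df k²/tr(R²)); an eigenvalue-weighted
Monte-Carlo reference is provided for cross-checks. The eQTL significance
floor on secondary SNPs keeps β_eQTL bounded away from zero, where the
delta method would fail. Under the default strong-instrument scenario the
empirical type-I error at α = 0.05 is ≈0.06 — the mild inflation expected
from plug-in delta-method covariances.

## Motif machinery

Counts get a pseudocount of 0.8 distributed proportionally to the
background (the common matrix-database convention; exposed because
published relative scores depend on it), are column-normalized to
probabilities, and scored as summed log2 odds against the background.
Relative score rescales by the matrix's minimal/maximal attainable sums, so
the consensus scores exactly 1. The background defaults to uniform 0.25 for
allele scoring; genome scanning documents the 0.29/0.21/0.21/0.29
composition as its stated default.

P-values come from the exact distribution of the integer-discretized score
(granularity 1e-3 on log-odds; p-value error < 1e-6 on test matrices),
computed by dynamic-programming convolution across columns and validated
against brute-force enumeration of all 4^L sequences for L ≤ 8. Scanning
evaluates both strands (the reverse-complement matrix with complemented
background is scanned over the forward sequence; a '−' hit's start is the
forward-strand window start); non-overlapping selection is greedy by
descending score with ties to the leftmost window and '+' strand. Allele
scoring builds each haplotype as flank5+allele+flank3 — alleles may differ
in length, handling indels — and takes the best-scoring window overlapping
the allele on either strand. Matrix randomization permutes column order
(seeded), preserving the column multiset and total information content;
for an L-column matrix the chance that a random permutation reproduces the
original order is 1/L!.

Density profiles histogram target sites at signed offsets from reference
feature centers (±10,000 bp in 500-bp windows by default) and normalize by
`n_ref·n_target·window/genome_length`, the expected count per window under
uniformly scattered targets, so 1.0 is the no-enrichment baseline.
Reference features within one range of the genome edge lose tail counts;
callers placing features near edges should expect depressed outer bins.

## Allelic expression imbalance

The mixing series is fitted by OLS (slope, intercept, r²); measured log2
cDNA and gDNA ratios are inverted through the curve
(`(measured − intercept)/slope`), and the normalized allelic ratio is
`2^(corrected cDNA − corrected gDNA)` — 1.0 means balanced expression. The
cohort test is a one-sample t-test of log2 ratios against 0 (matching
mean ± sd reporting; a Wilcoxon signed-rank option is provided). The test
is symmetric under allele relabeling, defined only for heterozygotes
(homozygous samples are rejected), and an all-balanced zero-variance cohort
returns p = 1 ("no evidence") by convention. The same correct-and-normalize
operation serves allele-specific ChIP ratios, with input DNA in the gDNA
role.

## Orchestration and reproducibility

The `finelocus` CLI wraps each stage 1:1 and a YAML-configured `run`
executes stages in dependency order, requiring an explicit seed for every
stochastic stage and rejecting unknown config keys. The output manifest
lists each file with its sha256; a fixed config reproduces byte-identical
outputs. Exit codes: 0 ok, 2 config error, 3 stage failure.

Problem sizes throughout (panel sizes of 1000–2000 haplotypes, loci of
10–30 SNPs, 100–2000 simulation replicates, 10⁴ permutations) were chosen
as the smallest scales at which the statistical properties under test are
clearly resolved.

## Known limitations

* Single-SNP approximate conditioning only; no stepwise joint model
  selection, no shrinkage LD estimators.
* The haplotype model has no recombination map, demography or imputation
  error; LD decays geometrically by construction.
* The annotation EM caps enumeration at k ≤ k_max per locus and assumes a
  shared annotation set across loci.
* HEIDI's delta-method covariances mildly inflate type-I error with noisy
  instruments; the eQTL filter mitigates but does not remove this.
* Genome-scale motif scans are supported by the scan operation but the
  package ships no genome; reproducing published genome-wide site counts
  requires external sequence and matrix files.
* AEI assumes the assay is linear over the calibrated range and that raw
  fluorescence processing happened upstream.
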