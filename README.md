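# regjoint

Large-region joint association testing for quantitative traits.

Genome-wide association studies test SNPs one at a time, yet much of the
heritability of polygenic traits appears to come from many weak effects
clustered over extended chromosomal regions — effects no single-SNP test can
see. `regjoint` is a toolkit for detecting and quantifying such *regional*
associations: it implements and compares the standard families of regional
association models, characterizes when the simple multivariate additive
model suffices, and provides an empirical sliding-window pipeline with a
permutation-based estimate of the phenotypic variance regional associations
explain. It is aimed at statistical geneticists analyzing GWAS-scale
genotype data (PLINK format) and at methodologists studying regional tests
by simulation.

## The model

The trait is assumed to be generated from unobserved haplotypes over `m`
biallelic SNPs:

    Y = D beta + eps,   eps ~ N(0, 1)

where `D` (n x k) counts each individual's copies of the k haplotypes
(two independent draws from the frequency vector `pi` under Hardy-Weinberg
equilibrium) and `beta` holds per-copy haplotype effects. The genetic
variance is

    sigma2_H = sum_i beta_i^2 2 pi_i (1-pi_i) - 4 sum_{i<j} beta_i beta_j pi_i pi_j.

Five families of working models, all fitted on the unphased genotypes
`G = D H`, try to recover that variance:

| model | design columns | df |
|---|---|---|
| additive | allele counts per SNP | m |
| interaction | + all pairwise genotype products | m + C(m,2) |
| genotypic | multilocus genotype-class indicators | up to 3^m - 1 |
| haplotype probability | EM posterior haplotype dosages | up to k - 1 |
| variance component | Haseman-Elston on the GRM `ZZ'/m`; Davies-type p | — |

How much of `sigma2_H` the *additive* design can capture is governed by a
non-additivity measure `tau' in [0, 1]`: the fraction of haplotype variance
missed by the additive projection, normalized by its maximum at the given
frequencies (`tau' = 0`: strictly additive effects; `tau' = 1`: maximal
deviation). `regjoint` computes `tau'` exactly, constructs effect vectors
with any prescribed `(sigma2_H, tau')`, and provides analytic power via the
noncentral F distribution (`ncp = n R^2/(1-R^2)`) and via weighted
chi-square tail probabilities for the variance component.

The empirical pipeline tests windows of SNPs (default 100 SNPs, step 50,
after LD pruning at r^2 = 0.8) with the joint additive F-test, slides
windows away from candidate loci to map how far regional signal extends,
estimates the total variance explained by candidate-centered windows with a
permutation-adjusted sum (window R^2 minus its mean over phenotype
permutations), and quantifies enrichment of candidate loci among
small-p windows (ROC/AUC with Mann-Whitney p, threshold odds ratios).

See `docs/methods.md` for estimator details, numerical choices, and known
limitations.

## Worked example

Build a two-SNP haplotype system with the package's reference frequency set,
give it effects that explain 0.006 of trait variance at non-additivity
`tau' = 0.5`, and compare the additive and haplotype-probability models by
simulation:

```python
import numpy as np
from regjoint import HaplotypeSystem, haplotype_variance, pairwise_ld
from regjoint.nonadd_power import effect_path, tau
from regjoint.simkit import common_variant_scenario, run_scenario

pi = [0.10, 0.30, 0.15, 0.45]          # haplotypes 00, 01, 10, 11
system = HaplotypeSystem(np.array([[0,0],[0,1],[1,0],[1,1]]), pi)
print(pairwise_ld(system, 0, 1)[2])     # r2 between the two SNPs: 0.0

beta = effect_path(system, sigma2_H=0.006, tau_prime_target=0.5)
s = system.with_beta(beta)
print(np.round(beta, 4))                # [-0.0776  0.0912  0.1186  0.1048]
print(haplotype_variance(s))            # 0.006
print(tau(s).tau_prime)                 # 0.5

cfg = common_variant_scenario(pi, 0.006, 0.5, n=5000, n_replicates=500,
                              models=("additive", "haplotype"), seed=42)
print(run_scenario(cfg).table[["model", "mean_sigma2_adj",
                               "se_sigma2_adj", "power"]])
```

```
    model  mean_sigma2_adj  se_sigma2_adj  power
 additive         0.002992       0.000073  0.304
haplotype         0.004374       0.000087  0.552
```

At `tau' = 0.5` the additive model recovers half the generative variance
(population value 0.003 — the mean adjusted estimate is unbiased for it),
while the haplotype-probability model recovers more (0.0045 is the exact
ceiling for unphased data here); `power` is the fraction of replicates with
joint-test p below the suggestive threshold 5e-5, and the additive empirical
power matches the noncentral-F analytic value 0.321 within Monte-Carlo
error. A command-line surface wraps the same machinery:

```
regjoint simulate cfg.yaml --out out/          # scenario TSVs
regjoint power --n 5000 --r2 0.006 --df1 2 --out out/
regjoint scan --bfile data --pheno pheno.tsv --candidates cands.tsv --out out/
regjoint center-scan ... ; regjoint variance ... ; regjoint enrich ...
regjoint make-panel --out panel/               # synthetic phased fixtures
```

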