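# Methods

`regjoint` tests whether many individually weak SNP associations cluster into
*large-region joint associations* with a quantitative trait, and quantifies
the phenotypic variance such regions explain. This note records the models,
the estimators, the simulation machinery, the numerical choices, and the
known limitations.

## Generative model

The trait is generated from unobserved haplotypes. For `m` biallelic SNPs,
`H` (k x m) lists the distinct haplotypes (0 = reference allele, 1 =
alternate), `pi` their population frequencies, and each individual carries
two independent draws from `pi` (Hardy-Weinberg random mating), summarized by
the copy-count matrix `D` (n x k, rows summing to 2). The trait is

    Y = D beta + eps,    eps ~ N(0, 1),

so the genetic variance is

    sigma2_H = Var(D beta)
             = sum_i beta_i^2 * 2 pi_i (1 - pi_i) - 4 sum_{i<j} beta_i beta_j pi_i pi_j,

and the total trait variance is `sigma2_H + 1`. Unphased genotypes are
`G = D H`.

All population-level quantities in `hapcore` (allele frequencies, pairwise
`D`, `D'`, `r^2`, `sigma2_H`, and the variance captured by any design) are
computed by exact enumeration over the k^2 ordered diplotypes with HWE
weights — no sampling — so they serve as oracles for the estimators.

## The five association models

All are tests of one region at a time, on centered data with an implicit
intercept:

* **additive** — one alternate-allele-count column per SNP (`X = G`);
* **interaction** — additive plus all `C(m,2)` pairwise genotype products;
* **genotypic** — indicators of the observed multilocus genotype classes
  (up to `3^m`; refused above `m = 8` by default), with the most frequent
  class dropped against the intercept;
* **haplotype probability** — posterior-expected haplotype counts from an
  EM fit under HWE on the unphased genotypes (in-sample frequencies; one
  column dropped against the intercept since rows sum to 2);
* **variance component** — Haseman-Elston regression of squared pairwise
  trait differences on the genomic relationship matrix
  `Gamma = ZZ'/m`, where `z_il = (g_il - 2 xi_l) / sqrt(2 xi_l (1 - xi_l))`
  uses sample allele frequencies. The genetic variance is `-v1/2` on this
  scaling; significance comes from the quadratic form `Q = y'Gamma y`, a
  weighted sum of chi-square(1) variables with the eigenvalues of `Gamma`
  as weights.

The first four are fitted by rank-revealing pivoted QR (relative tolerance
1e-8); dropped collinear columns are reported and the joint F-test uses
`df1 = retained rank`. Two variance estimates are reported per fit:

* raw: `ESS / n` (the in-sample explained variance `B'X'XB/n`);
* adjusted: `(ESS - df1 * RSS / df2) / n`, which is unbiased for the
  population captured variance under the model and may be negative. This
  equals the familiar adjusted-R^2 correction scaled by `TSS/n`.

On genotypes with exactly orthogonal standardized columns the additive
model's explained variance equals `y'ZZ'y/n`, the variance-component
quadratic form — the two families estimate the same quantity in linkage
equilibrium (asserted to 1e-10 in the tests).

### Quadratic-form p-values

`P(Q > q)` is evaluated exactly with a deterministic method dispatch: a
scaled (noncentral) chi-square closed form when all weights are equal; a
smooth one-dimensional conditioning integral for two positive weights (the
oscillatory inversion converges poorly there); otherwise the
characteristic-function inversion (Imhof/Davies integral) via adaptive
quadrature, with a Kuonen saddlepoint fallback when the integration error
estimate exceeds 1e-5 or the probability falls below the inversion's ~1e-8
absolute accuracy. Tail probabilities are therefore accurate to ~1e-3
relative in the ranges used (sizes and powers at alpha >= 5e-5); the
quantile function inverts the same survival function by bracketing.

## Non-additivity

The additive design misses the fraction

    tau = (sigma2_H - sigma2_G) / sigma2_H,

where `sigma2_G` is the variance captured by the additive projection.
Both numerator pieces are quadratic forms in `beta`
(`sigma2_H = beta'A beta` with `A = 2(diag(pi) - pi pi')`, and
`sigma2_G = beta'P beta` with `P` assembled from exact HWE design moments),
so the maximum of `tau` at fixed frequencies is one minus the smallest
generalized eigenvalue of `(P, A)` on the complement of the constant
vector. We solve this in closed form rather than by stochastic search: the
result is exact, deterministic, and scale-invariant. `tau' = tau/tau_max`
normalizes to [0, 1].

`effect_path(pi, sigma2_H, t)` produces effect vectors sweeping `tau'` from
0 (a strictly additive vector `H alpha`) to 1 (the maximizing eigenvector),
by interpolating between the two endpoints, rescaling to hold `sigma2_H`
fixed, and solving the interpolation weight by root bracketing. The path is
one of many possible; every downstream result depends on it only through
`(sigma2_H, tau')`, which the tests verify by recomputing `tau'` from the
returned vector (self-consistent to 1e-6).

**A structural fact the simulations surface:** at `m = 2` the
phase-unambiguous effect subspace `{beta : beta_00 + beta_11 = beta_01 +
beta_10}` coincides with the additive span, so *any* effect vector with
`tau > 0` loses part of `sigma2_H` to phase ambiguity — no model fitted on
unphased genotypes (genotypic or haplotype-probability included) can capture
all of `sigma2_H` once `tau' > 0`. The exact ordering that does hold, and
that the tests assert, is

    sigma2_X(additive) <= sigma2_X(interaction)
        <= sigma2_X(genotypic) = sigma2_X(haplotype prob) <= sigma2_H,

with the additive capture falling linearly to 0 at `tau' = 1` while the
unphased designs retain strictly more.

## Analytic power

For the F-tested models, power uses the noncentral F distribution with
`ncp = n R^2 / (1 - R^2)`, where `R^2 = sigma2_X / (sigma2_H + 1)` is the
population proportion of variance explained by the design. (The quotient
form is the standard fixed-score noncentrality; a product form is
dimensionally inconsistent with the Monte-Carlo power it must match, and the
tests verify the quotient against simulation at three grid points within
2 SE.) For the variance component, under the random-effect alternative the
standardized trait has covariance `s2g*Gamma + (1 - s2g) I`, so `Q` remains
a weighted chi-square sum with weights `lam_j (s2g lam_j + 1 - s2g)`; power
is that distribution's survival at the null critical value. A spectrum
proportional to the identity therefore carries no power — genetic similarity
indistinguishable from noise — which the tests assert.

## Simulation engine

`ScenarioConfig` couples a haplotype system, a sample size, a replicate
count, a model list, a test level, a mask (SNP columns hidden from fitting),
and a seed. Replicates draw haplotype index pairs from `pi`, form `G` and
`y = Dbeta + eps`, drop SNPs monomorphic in-sample, fit every requested
model, and aggregate means, Monte-Carlo SEs, and empirical power. Each
replicate consumes an independent child stream spawned from the master seed,
so results are independent of execution order.

Study conditions follow the simulation study the package reproduces:
n = 5,000 individuals per replicate, `sigma2_H = 0.006` for the
common-variant experiments, suggestive threshold `alpha = 5e-5`, and the
two reference 2-SNP frequency sets (0.10, 0.30, 0.15, 0.45) with `r^2 = 0`
and (0.42, 0.18, 0.10, 0.30) with `r^2 = 0.195`. The acceptance runs use
5,000 replicates (the figures behind the study used 10,000) purely to keep
the recomputation short; Monte-Carlo SEs are reported alongside.

**Nuisance SNPs at fixed LD.** Non-associated SNPs are appended by solving
for joint haplotype frequencies on the enlarged simplex (SLSQP, multi-start)
that hit the target pairwise `r^2` for every pair involving a nuisance SNP,
holding the causal sub-distribution fixed; effects extend by zeros. Targets
achieved to 1e-6 or an infeasibility error names the violated pair (e.g.
all-pairs `r^2 = 0.8` is infeasible when the preserved causal pair sits at
0.2). Default nuisance allele frequency: the causal SNPs' mean frequency.

**Rare-variant tagging.** Two common SNPs with equal allele frequency `p` in
mutual linkage equilibrium define a 1-1 tagging haplotype of frequency
`h = p^2`; the rare allele (frequency `f`) resides only on that haplotype
(`D' = 1`), giving `r2_hap = f(1-h)/(h(1-f))` and per-common-SNP
`r^2 = p/(1+p)`. Defaults: per-SNP `r^2 = 0.04`, i.e. `p = 1/24` and
`f = 1/576 ~= 0.0017` at `r2_hap = 1`. The rare effect is sized so
`2f(1-f)beta^2` equals the requested variance contribution; the rare SNP is
masked from fitting unless the typed variant of the experiment is requested.

**Panel windows.** `generate_fixture_panel` emulates a phased reference
panel with a founder-mosaic copying process: haplotypes copy segments from a
founder pool, switching founders between adjacent SNPs with probability
`ld_decay`, plus sparse mutation; columns outside the requested MAF band are
dropped. It reproduces the two features the experiments need — a MAF
spectrum under control and LD that decays monotonically with distance — and
nothing else: no recombination hotspots, no demography, no selection, so
passing panel-window tests says nothing about those aspects of real data.
`panel_window_scenario` then filters MAF > 0.01, prunes to max pairwise
`r^2 = 0.80`, takes a fixed-size window, designates a causal pair at the
requested LD, and assigns its effects from the non-additivity path.

## Empirical pipeline

`prepare_phenotype` optionally log2-transforms, removes samples outside the
1st-99th percentile range (removal is the default reading of trait
winsorization here; a clamping mode exists behind a flag), residualizes
jointly on covariates and all candidate-SNP dosages at once, and
standardizes. `ld_prune` is greedy windowed pruning (window 100, step 50,
`r^2 = 0.80` defaults; the earlier-position SNP wins ties).
`make_windows` emits fixed-size windows per chromosome (default size 100,
step 50), dropping trailing partial windows — window counts follow
`floor((m_c - size)/step) + 1` per chromosome. `scan_windows` runs the joint
additive F-test per window; `centered_scan` re-centers windows on candidate
SNPs and slides them away one SNP at a time, reporting per-offset p-values
and genomic-distance summaries (median center-to-candidate and minimal
boundary-to-candidate distances, Kb).

**Permutation-adjusted variance.** Window R^2 is inflated by `df/n` and by
LD; permuting the phenotype against genotype rows preserves the LD structure
and measures exactly that null inflation. Adjusted per-window variance =
real R^2 minus the permutation mean; the total over candidate windows sums
the adjusted values (additive-contribution assumption; overlapping windows
are detected and reported, not merged). The one-sided p counts centered
permutation totals at least as large as the observed total, with the +1
correction; the 95% CI adds the 2.5/97.5 percentiles of the centered
permutation totals to the observed total (a normal-approximation CI is
available behind a flag). Default 1,000 permutations.

*Known limitation:* the permutation distribution reflects only null noise.
When the signal is concentrated (per-window noncentrality comparable to the
window df), the estimator's sampling error additionally carries a
signal-noise cross term the CI cannot see, and the nominal 95% interval
under-covers — e.g. five 100-SNP windows each explaining 0.01 at n = 3,740
give ~85% coverage. In the diffuse regime the pipeline targets (a hundred-plus
candidate windows, per-window R^2 of order df/n), the null term dominates and
coverage is close to nominal. A closed-form estimator robust to both LD and
concentrated signals is an open problem.

A related finite-sample effect touches the rare-variant experiment: with a
heavy-tailed signal carried by ~n*f ~ 17 carriers, squared sample covariances
between the tag SNPs and the signal acquire a Jensen-type inflation of order
`2 Var(cov_hat)/Var(g) ~ 5e-5`, so the additive model's mean adjusted
estimate at n = 5,000 is ~8.5e-4 against a population value of 8.0e-4. The
df-based adjustment cannot remove it (it is signal noise, not error-fit
noise); it shrinks like 1/n.

## Enrichment

Windows whose bp span contains a candidate locus (inclusive endpoints) are
positives. AUC uses midranks (tie-corrected Mann-Whitney variance); the AUC
p-value is one-sided in the enrichment direction, as is the permutation p
above — both choices are flagged in output metadata. Threshold enrichment
builds the 2x2 table of {window p < threshold} x {contains candidate}; OR by
cross-product, CI by the Woolf log-OR normal method with the Haldane 0.5
correction when a cell is empty (flagged), p by Fisher's exact test.
`offset_enrichment` compares windows at each offset from the candidates
against all scan windows and reports the largest offset with a contiguous
run of significant AUCs from offset 0.

## I/O and reproducibility

PLINK bed/bim/fam is read and written directly (SNP-major 2-bit codes;
genotypes are A1-allele counts; missing calls keep a sentinel and are
mean-imputed only when a design is built, never at I/O). Phased VCF is read
through cyvcf2 (multi-allelic and unphased records skipped and counted) and
written as plain text. Every CLI run writes a manifest with parameters,
seeds, library versions, and input checksums; identical manifests produce
byte-identical outputs.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| window size / step | 100 / 50 SNPs | scan windows (centered scans: step 1) |
| prune r^2 | 0.80 | max pairwise LD retained in a window |
| trim percentiles | 1, 99 | trait values removed before analysis |
| genotypic_max | 8 SNPs | refuse 3^m designs beyond this |
| EM tolerance / iterations | 1e-8 / 1000 | haplotype-frequency convergence |
| rank tolerance | 1e-8 | pivoted-QR collinearity threshold |
| n_perm | 1000 | phenotype permutations for variance CIs |
| alpha (simulations) | 5e-5 | suggestive regional association |
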