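# Methods

## Overview

`slabgwas` implements a two-step mixed-model association workflow for
biobank-style cohorts. Step 1 ("model fitting") learns a whole-genome
polygenic predictor under a sparsity-aware prior; step 2 ("testing") scans
each variant with a score statistic whose null model is the step-1
predictor built from every chromosome *except* the one being tested
(leave-one-chromosome-out, LOCO), which prevents proximal contamination.
A synthetic-data module generates genotypes and traits under the designs
the method is meant to handle — population stratification, close
relatives, sparse and infinitesimal architectures, rare variants, binary
traits of low prevalence — so that calibration and power properties are
verifiable end to end without external data.

## Step 1: spike-and-slab whole-genome regression

For a covariate-adjusted, standardized genotype matrix X (N samples, M
variants) and adjusted trait y, the model is

    y | X, beta     ~ N(X beta, sigma_e^2 I)          (quantitative)
    y_n | X, beta   ~ Bernoulli(sigmoid(X_n beta))    (binary)
    beta_j          ~ (1 - pi) delta_0 + pi N(0, sigma^2)

with a fully factorized spike-and-slab variational posterior
q(beta_j) = (1 - psi_j) delta_0 + psi_j N(mu_j, sigma_j^2). The evidence
lower bound (ELBO) is

    E_q[log p(y | X, beta)] - sum_j KL_j,
    KL_j = psi_j log(psi_j / pi) + (1 - psi_j) log((1 - psi_j)/(1 - pi))
         + psi_j * 1/2 [ -1 + (mu_j^2 + sigma_j^2)/sigma^2
                         - log(sigma_j^2 / sigma^2) ],

maximized by minibatch Adam on the unconstrained parameters
(logit psi_j, mu_j, log sigma_j^2). Two variance-reduction devices keep
the stochastic objective usable:

* **Local reparameterization** — instead of sampling beta, each sample's
  linear predictor is drawn from its implied Gaussian with mean
  sum_j x_ij psi_j mu_j and variance
  sum_j x_ij^2 [psi_j (sigma_j^2 + mu_j^2) - psi_j^2 mu_j^2].
* **Antithetic variates** — each draw is used as a +/-z pair, cancelling
  the odd-order Monte-Carlo noise.

For the linear model the expectation of the quadratic data term has a
closed form ((y_i - m_i)^2 + v_i in the notation above), so
`n_mc_samples=0` selects the exact (Rao–Blackwellised) objective; this is
the limit of the antithetic estimator as the number of draws grows and is
what the quantitative pipeline uses by default, since at desk scale it
converges deterministically at the same per-epoch cost. The logistic
model has no closed form and always samples.

Gradients are derived analytically (chain rule through the predictor
moments; the per-sample derivative of the data loss is (eta - y)/sigma_e^2
for the linear model and sigmoid(eta) - y for the logistic one) and are
verified in the test suite against central differences under common
random numbers.

**LOCO refits and transfer.** After the whole-genome fit, each chromosome
is refitted with its columns removed, warm-started from the whole-genome
posterior. Warm starts reach the cold-start ELBO in a quarter of the
epochs or fewer, which is what makes 22 refits affordable.

**Prior hyperparameters.** pi defaults to 0.01; sigma^2 = h^2/(M pi) and
sigma_e^2 = 1 - h^2 tie the prior to the trait's heritability, which is
estimated first (below). h^2 is clamped to [0.01, 0.95] to keep the prior
proper. Optimizer defaults: step size 0.01, batch 128, at most 100
epochs, convergence when the 5-epoch smoothed ELBO changes by less than
1e-4 relative.

**Binary covariates.** Covariate effects are estimated once by plain
logistic regression and enter the SVI as a fixed offset on the logit
scale. The alternative — residualizing genotypes only — reads equally
well from the model statement; the offset form keeps the Bernoulli
likelihood exact.

## Heritability estimation

Quantitative traits use single-component randomized Haseman–Elston
regression: with K = X X'/M, solve

    [ tr(K^2)  tr(K) ] [sigma_g^2]   [ y' K y ]
    [ tr(K)      N   ] [sigma_e^2] = [ y' y   ]

where tr(K^2) is estimated with 50 Hutchinson Rademacher vectors (one
genotype pass per vector, shared across traits) and y'Ky = ||X'y||^2/M.
Negative estimates are clamped to zero. The randomized estimate converges
to the explicit-GRM solution as vectors are added; the suite checks both
the convergence and the unbiasedness on simulated traits.

Binary traits use a grid search h^2 in {0.01, 0.25, 0.5, 0.75}: the
step-1 logistic regression is fitted at each value and the value with the
highest converged ELBO wins. The ELBO is the package's reading of "model
likelihood" for this selection; the comparison needs near-converged fits,
because an under-fitted ELBO systematically favors the smallest prior
variance (the KL is cheapest there).

## Step 2: calibrated score tests

Quantitative raw statistic per variant: (x' y_loco)^2 / (x' x var(y_loco)),
with x standardized and covariate-adjusted and y_loco the LOCO residual
phenotype of the variant's chromosome. The per-chromosome variance in the
denominator matters under designs that concentrate signal on some
chromosomes: those chromosomes' LOCO residuals retain their own genetic
variance, and a single genome-wide constant would otherwise over-shrink
statistics on signal-free chromosomes (the residual-variance denominator
is also how BLUP-based statistics are conventionally scaled). Binary: (x'(y - p))^2 / (x' W x) with p the LOCO null-model
probabilities and W = diag(p(1-p)). Both are proportional to chi^2_1
under the null; the constant is fixed per trait by effective-sample-size
matching:

    gamma = [ (ref_mean - 1) * neff_gain * rel_adj + 1 ] / raw_mean

* `ref_mean` — mean chi^2 of plain linear (or covariate-only logistic
  efficient-score) regression on an unrelated homogeneous calibration
  subset, over a genome-wide random calibration set of 5% of variants
  (at least 1,000).
* `neff_gain` — var(y_adj) divided by the held-out residual variance of
  the whole-genome predictor (fitted on 75% of samples, evaluated on the
  other 25%): the effective-sample-size gain the Bayesian regression
  buys. Set to 1 for binary traits, where the reference comparison on the
  subset already carries the scale.
* `rel_adj` — N_eff / N_subset, N_eff = N - sum over detected relative
  pairs of 2 phi, with kinship phi taken from the standardized-genotype
  GRM and pairs flagged down to the third-degree cutoff 2^-4.5.

`raw_mean` is the mean raw statistic over the same calibration variants,
so shared sampling noise in the two means largely cancels. Reported SEs
are |beta|/sqrt(chi^2_cal), keeping effect, SE and P mutually consistent;
P-values are computed in log space via P(chi^2_1 > s) = 2 Phi(-sqrt(s)),
which stays finite beyond the 1e-300 underflow limit.

**Approximate Firth fallback (binary).** The normal approximation behind
the score test degrades for rare variants or rare traits. Variants with
score P < 0.05 that are rare (MAF < 5%) or belong to a rare trait
(prevalence < 5%) are re-tested: the covariate+LOCO-offset null model is
fitted once, then the single variant coefficient maximizes the
Jeffreys-penalized likelihood l(beta) + 1/2 log I(beta) by damped Newton
(I(beta) = x' W(beta) x), and the test is the penalized likelihood ratio
against chi^2_1. The penalty guarantees finite estimates under complete
separation. No saddle-point approximation is used.

**Participation weights.** `weighted_score_test` runs weighted least
squares with a Huber–White sandwich, Var = (x'Wx)^-2 sum_i w_i^2 x_i^2
r_i^2. Note this estimator (the survey-weight convention, identical to
statsmodels WLS HC0) is not invariant to splitting one observation into
two half-weight copies: beta is unchanged but the sandwich meat halves,
so the SE contracts by sqrt(2). Unit weights reduce it exactly to the
heteroskedasticity-robust unweighted test.

## Synthetic data

The generator reproduces the axes the method is evaluated on, not
real-genome LD:

* **Genotypes.** Founder allele frequencies are drawn from a two-part
  spectrum (10% rare, log-uniform on [1e-4, 0.01]; the rest uniform on
  [0.01, 0.5]); discrete populations drift under a Balding–Nichols beta
  model with parameter F_ST; samples are Hardy–Weinberg binomial within
  population. Relative pairs are gene-dropped from shared parents (full
  sibs for first degree, half sibs for second); variants are split evenly
  across a configurable number of chromosomes (default 22).
* **Traits.** y_i = sum_j G_ij beta_j + A gamma + tau + eps with
  beta_j ~ N(0, h_g^2 c_f / (M p)), c_f proportional to (2f(1-f))^alpha
  (alpha = -0.3 by default), h_g^2 = 0.4, and the realized genetic
  component rescaled to explain exactly h_g^2. A gamma is a fixed,
  equally spaced per-population offset scaled to its variance share
  (5% in stratified designs); tau is one Gaussian draw shared within each
  relative cluster (variance 0.20 first degree / 0.10 second); eps fills
  each sample's budget to unit variance. Alternative effect laws: a
  two-Gaussian mixture whose small-variance component carries fraction
  f of effect variance (components 2f V and 2(1-f) V at equal mixing —
  one concrete reading of "f controls the small component's variance
  share"), Laplace, and Gaussian; the last two are fully polygenic.
* **Causal parity.** With the parity flag, causal variants are confined
  to odd chromosomes, making even chromosomes exact nulls — the device
  that turns false-positive-rate measurement into simple counting.
* **Binary traits.** Liability thresholding at the empirical
  (1 - prevalence) quantile gives an exact case count; ties are broken by
  sample order, deterministically.

What the generator does *not* emulate: linkage disequilibrium from
recombination, imputation dosage noise, haplotype structure, or
assortative mating. Passing tests therefore certify the statistical
machinery (calibration, power ordering, heritability recovery) under
independent-variant architectures, not robustness to LD-induced
confounding, which in real data is handled by the LOCO construction and
the calibration subset.

## Numerical choices

* Posterior slab probabilities are clamped to [1e-6, 1 - 1e-6];
  unconstrained parameters to |logit psi| <= 30 and log sigma_j^2 in
  [-40, 10].
* Genotype work arrays are float32 in the pipeline (the gradient
  bookkeeping and all scalar reductions stay float64); the working copy
  is kept C-contiguous — minibatch row gathers from the F-ordered view a
  column subset produces are several-fold slower.
* Zero-variance (or all-missing) columns are excluded before fitting and
  accounted for in the output row count.
* Missing genotypes are mean-imputed; standardization divides by the
  empirical SD by default, with sqrt(2f(1-f)) as an option.
* HWE filtering uses the exact conditional test (sum of heterozygote-count
  probabilities no larger than the observed one).
* Calibration and false-positive-rate studies test variants with at least
  ~10 minor-allele copies (MAF >= 10/2N): below that the score statistic
  is visibly discrete and both it and the Firth LRT are conservative by
  construction, so nominal-rate accounting is not meaningful there.
* All randomness flows from explicit seeds; fits are bit-reproducible.

## Problem sizes

The shipped test suite and the reproduction script run the full designs
at desk scale — N = 2,000 samples and M = 20,000 variants for the
calibration/power study (10 quantitative and 5 binary traits fitted
jointly), N = 2,000 / M = 5,000 with 25 replicates for heritability
recovery, and N = 1,500 / M = 8,000 for the end-to-end reproduction run —
sizes chosen so every property is measured on the same designs the method
targets while a complete run stays in the minutes range on one CPU core.

## Known limitations

* Single-GRM heritability only; MAF/LD-stratified multi-component
  estimation is out of scope (a variant-exclusion hook covers
  HLA-style region masking).
* No BGEN/VCF dosage input; testing operates on hard calls through the
  PLINK bed codec.
* The binary grid search selects among four h^2 values; liability- vs
  observed-scale mapping is not attempted.
* Mean-field variational posteriors underestimate posterior variances;
  the package only consumes posterior means (and the ELBO), which the
  enumeration oracle shows are accurate at desk scale.
* Participation weighting is applied in step 2 only.
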