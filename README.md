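# slabgwas

Two-step mixed-model genome-wide association testing with a sparsity-aware
whole-genome prior, for cohorts with relatedness and population structure.

Genome-wide association studies on biobank cohorts need mixed models to
stay calibrated in the presence of relatives and stratification, and they
gain power when the polygenic background is modeled well. `slabgwas`
implements both steps of that recipe:

1. **Model fitting** — a Bayesian whole-genome regression with a
   spike-and-slab prior on standardized variant effects,

       beta_j ~ (1 - pi) delta_0 + pi N(0, sigma^2),

   fitted by stochastic variational inference (mean-field spike-and-slab
   posterior, local reparameterization, antithetic variates, Adam). The
   linear model serves quantitative traits; a Bernoulli-logit variant with
   covariate offsets serves binary traits. Prior scales come from the
   trait's heritability: randomized Haseman–Elston regression
   (quantitative) or an ELBO grid search over h² ∈ {0.01, 0.25, 0.5, 0.75}
   (binary). Each chromosome is then refitted without its own columns
   (leave-one-chromosome-out, warm-started from the whole-genome fit).

2. **Testing** — per-variant proportional score statistics,

       chi2_Q ∝ (x' y_LOCO)^2 / (x' x)            (quantitative)
       T_B    ∝ x'(y - p) / sqrt(x' W x)           (binary),

   calibrated per trait by effective-sample-size matching against plain
   regression on an unrelated homogeneous subset, with corrections for the
   held-out accuracy of the step-1 predictor and for relative pairs up to
   the third degree. Rare binary signals (MAF < 5% or prevalence < 5%,
   score P < 0.05) are re-tested with approximate Firth penalized
   likelihood-ratio tests. Optional per-sample participation weights give
   Huber–White sandwich-variance tests.

A first-class synthetic-data module simulates genotypes (Balding–Nichols
population drift, gene-dropped relative pairs, rare variants down to MAF
1e-4) and traits (MAF-dependent effect variance with alpha = -0.3,
heritability 0.4, stratification and shared-environment components,
liability-threshold case/control status), with causal variants confined to
odd chromosomes so even chromosomes are exact nulls for false-positive-rate
measurement.

See `docs/methods.md` for the model, estimators, calibration details and
known limitations.

## Worked example

```python
import numpy as np
import pandas as pd
from slabgwas import (SimulationConfig, simulate_genotypes, sample_effects,
                      simulate_quantitative, run_step1, run_step2, evaluate,
                      Step1Options, OptimizerConfig)

cfg = SimulationConfig(n_samples=1000, n_variants=6000, n_chromosomes=22,
                       h_g2=0.4, polygenicity=0.01,
                       causal_chromosome_parity=True, seed=11)
G = simulate_genotypes(cfg)
rng = np.random.default_rng(12)
eff = sample_effects(cfg, G.variants, rng)
trait = simulate_quantitative(G, eff, cfg, rng)

pheno = pd.DataFrame({"FID": [s[0] for s in G.samples],
                      "IID": [s[1] for s in G.samples],
                      "height": trait.values})
s1 = run_step1(G, pheno, "quantitative",
               options=Step1Options(optimizer=OptimizerConfig(max_epochs=40),
                                    seed=5))
results, calibration = run_step2(G, s1, seed=6)["height"]

truth = pd.DataFrame({"SNP": [v.identifier for v in G.variants],
                      "height.causal": eff.causal_mask.astype(int)})
report = evaluate(results, truth[truth.SNP.isin(results.SNP)],
                  "height.causal")
print(f"h2 = {s1.h2[0]:.2f}")
print(f"null mean chi2 = {report.mean_chisq_null:.3f}")
print(f"causal mean chi2 = {report.mean_chisq_causal:.1f}")
print(f"FPR at 0.05 = {report.fpr[0.05]:.4f}")
```

Output from this exact run:

```
h2 = 0.43
null mean chi2 = 1.007
causal mean chi2 = 9.1
FPR at 0.05 = 0.0510
```

The heritability estimate recovers the simulated 0.4; calibrated null
statistics sit at mean ~1 with a false-positive rate at the nominal 5%;
the 57 tested causal variants average a chi-square near 9, i.e. the
sparse signal is strongly detected at N = 1,000.

The same workflow is scriptable from the shell:

```bash
slabgwas simulate --n-samples 1000 --n-variants 6000 --seed 11 --out data/toy
slabgwas step1 --bed data/toy.bed --pheno data/toy.pheno --seed 5 --out out/toy
slabgwas step2 --bed data/toy.bed --pheno data/toy.pheno \
               --step1-prefix out/toy --seed 6 --out out/toy
slabgwas evaluate --results out/toy.trait1.sumstats.tsv \
                  --truth data/toy.truth --trait trait1
```

Summary statistics are tab-separated with columns
`CHR SNP BP A1 A2 A1FREQ N TEST BETA SE CHISQ LOG10P P`.

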