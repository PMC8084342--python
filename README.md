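# mrslope

Bayesian two-step Mendelian randomization (MR) for estimating the causal
effect of a gene's expression on a downstream trait from eQTL and GWAS
summary statistics, for loci with **allelic heterogeneity** (two or more
independent cis-eQTL signals). Intended for statistical geneticists
prioritizing candidate causal genes for functional follow-up, where
honest uncertainty and the *heterogeneity* of per-signal effects matter as
much as the point estimate.

## The model

**Step 1 — per-cluster colocalization.** The locus is split into
nearly-LD-independent signal clusters by greedy LD clumping on eQTL
p-values (index p < 10⁻³, r² ≥ 0.1, 500 kb window), trimmed so cluster key
SNPs are pairwise r² < 0.05, allele-flipped so every SNP is in positive LD
with a positive-eQTL index, and collapsed at r > 0.95 to representatives.
Within a cluster, for each study S ∈ {A = eQTL, B = GWAS} with observed
coefficients β̂ᵢ, standard errors seᵢ and signed LD matrix R:

```
β̂ᵢ ~ N((R β)ᵢ, seᵢ),   βᵢ = τ λᵢ zᵢ,   zᵢ ~ N(0,1),
λᵢ ~ C⁺(0, 1),          τ ~ C⁺(0, τ₀)
```

— a univariate likelihood per SNP with a horseshoe prior on the true
effects, sampled by an exact conjugate Gibbs sampler. The **candidate
causal SNP** is the member with the largest posterior mean eQTL effect;
its posterior means and sds for both studies become one *instrument*.

**Step 2 — hierarchical slope.** Across clusters j = 1..J:

```
β̂_jA ~ N(β_jA, se_jA)      β̂_jB ~ N(β_jB, se_jB)
β_jA ~ N(0, SD_β)          β_jB ~ N(α β_jA, σ)
```

α is the gene-to-trait slope (origin-anchored: no intercept), σ the
**dispersion** of per-cluster effects around the slope line — the model's
measure of allelic effect heterogeneity. Latent effects are marginalized
analytically and the 3-parameter posterior is sampled with an ensemble
MCMC sampler; intervals are posterior quantiles (default level 0.80).
Derived summaries: the mean mediated effect α̂ · mean(β̂_jA) and the
dispersion ratio σ̂ / |mean mediated effect|.

The package also ships the full simulation framework used to validate the
method (AR(1)-LD synthetic genotype panels, mediated / null /
horizontal-pleiotropy paired studies, correlated-instrument nulls) and the
benchmark metrics (RMAE, bias, interval coverage, candidate-SNP accuracy,
IVW fixed-effects comparator).

## Worked example

```python
import numpy as np
from mrslope import (simulate_genotypes, simulate_study, analyze_locus,
                     RunConfig, mean_mediated, dispersion_ratio)

panel_e = simulate_genotypes(500, 1000, seed=12)                 # eQTL cohort
panel_g = simulate_genotypes(100_000, 1000, dtype=np.float32, seed=13)
eqtl, gwas, truth = simulate_study(panel_e, panel_g,
                                   h2g=0.1, h2med=0.01, seed=6)
res = analyze_locus(eqtl, gwas, panel_e.ld_matrix(),
                    config=RunConfig(seed=11))
fit = res.slope_fit
print(f"clusters: {res.counts['clusters_after_trim2']},  true alpha: {truth.alpha:.3f}")
print(f"alpha = {fit.alpha_mean:.3f}  80% CI ({fit.alpha_interval[0]:.3f}, "
      f"{fit.alpha_interval[1]:.3f})  sigma = {fit.sigma_mean:.3f}")
mm = mean_mediated(fit.alpha_mean, res.instruments.beta_a)
print(f"mean mediated = {mm:.4f}  dispersion ratio = "
      f"{dispersion_ratio(fit.sigma_mean, mm):.2f}")
```

prints

```
clusters: 3,  true alpha: 0.317
alpha = 0.251  80% CI (0.128, 0.398)  sigma = 0.020
mean mediated = 0.0399  dispersion ratio = 0.50
```

Three nearly-LD-independent eQTL clusters survive trimming; the posterior
slope 0.25 (80% interval covering the simulated truth 0.32) says a one-SD
increase in expression raises the trait by ~0.25 trait SDs, and the
dispersion ratio of 0.5 says per-cluster effects scatter around half the
typical mediated effect — a consistent mediation story.

The same pipeline runs from the shell on delimited summary-statistic and
LD files:

```bash
mrslope simulate --n-snp 200 --n-gwas 10000 --seed 4 --out locus/
mrslope run-all --eqtl locus/eqtl.tsv --gwas locus/gwas.tsv \
        --ld locus/ld.tsv --seed 11 --out results/ --plot
```

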