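# Methods

## Scope and model

`mrslope` estimates the causal effect of one gene's expression on one
trait (the gene-to-trait slope α) from two sets of summary statistics —
an exposure study A (cis-eQTL) and an outcome study B (GWAS) — plus
signed LD, for loci with two or more independent eQTL signals. The core
assumptions are the usual two-sample MR ones: the instruments (one
candidate SNP per nearly-LD-independent signal cluster) affect the trait
only through the gene (encoded by the origin-anchored slope: a cluster
with zero expression effect is modelled as having zero mediated trait
effect), the two studies index the same underlying population so a
single LD matrix can be shared (distinct matrices are supported), and
coefficients are on whatever per-allele scale each study reports — α is
then in units of (trait scale) per (expression scale).

### Pre-processing

SNPs are matched across studies by identifier, and study B is re-coded
to study A's effect alleles (sign flips where effect/other are swapped,
directly or on the opposite strand). Strand-ambiguous A/T and C/G SNPs
are dropped with a logged reason rather than guessed from allele
frequency: a wrong guess silently flips a coefficient's sign, which is
far more damaging to a slope estimate than losing a SNP. SNPs with
MAF < 0.01 are removed (boundary kept, PLINK-like). Signal clusters come
from greedy clumping on exposure p-values (index p < 0.001, members with
r² ≥ 0.1 to the index within 500 kb; p-value ties break by genomic
position), followed by greedy trimming so cluster key SNPs are pairwise
r² < 0.05, keeping stronger-signal clusters first. Trimming runs twice:
keyed on clump indexes before colocalization and on candidate causal
SNPs after it. Within each cluster, alleles are flipped so every member
is in positive LD with an index whose exposure coefficient is positive,
and SNPs with r > 0.95 are collapsed to the group's smallest-p member;
downstream "per-SNP" statements are about these representatives — the
method fine-maps to a tight LD group, not to a single nucleotide.

### Colocalization (per cluster)

Observed coefficients are modelled univariately per SNP with the signed
LD matrix entering only through the mean, `beta_hat_i ~ N((R beta)_i,
se_i)`, independently per study, with a horseshoe prior
`beta_i = tau lambda_i z_i`, `lambda_i ~ half-Cauchy(0,1)`,
`tau ~ half-Cauchy(0, tau0)`. The univariate likelihood (rather than a
multivariate normal over the whole z-score vector) keeps the model cheap
and lets the prior do the sparsification; the horseshoe concentrates the
posterior on few SNPs so the cluster's candidate causal SNP — the
member with the largest posterior mean exposure effect, ties broken by
smaller exposure p then position — is well separated. The global scale
adapts to each study's noise level: `tau0 = median(se) * p0 / n` with
p0 = 1 expected causal SNP per cluster (both configurable). The two
studies use independent horseshoes: nothing forces a shared causal SNP,
which is exactly what lets a non-colocalizing cluster push its outcome
posterior toward zero and drag the slope with it.

Because the likelihood is linear-Gaussian in `beta`, the posterior is
sampled by an exact Gibbs sampler using the inverse-gamma auxiliary
representation of the half-Cauchy scales (Makalic & Schmidt 2016). All
conditionals are closed-form; four chains run batched through stacked
Cholesky factorizations, 1000 warmup + 1000 kept sweeps each by default.
Split-Rhat across the four independent chains above 1.05 attaches a
warning to the fit. The LD matrix gets a ridge of 10⁻³ on the diagonal
before use; as a Gibbs sampler has no divergences, that diagnostic field
is always zero.

Instruments passed to the slope step are the candidate's posterior mean
and posterior sd per study (posterior sd is used as the slope-step SE).
A `raw` mode instead passes the candidate's original observed
coefficient and SE, for externally chosen candidates.

### Slope and dispersion (across clusters)

```
beta_hat_jA ~ N(beta_jA, se_jA)     beta_hat_jB ~ N(beta_jB, se_jB)
beta_jA ~ N(0, SD_beta)             beta_jB ~ N(alpha beta_jA, sigma)
```

All normals are (mean, sd)-parameterized, so σ is the standard deviation
of true per-cluster outcome effects around the slope line — the
dispersion, an interpretable counterpart to meta-analytic heterogeneity
statistics. Unlike IVW regression, the instrument effects themselves
carry uncertainty (errors-in-variables), which is what restores interval
coverage when instruments are weak. Fitting requires J ≥ 2 clusters;
J = 1 produces an "insufficient allelic heterogeneity" warning and is
refused unless forced, J = 0 is fatal.

The latent `(beta_jA, beta_jB)` are jointly Gaussian given
`(alpha, sigma, SD_beta)` and are integrated out analytically; each
instrument contributes a bivariate normal with covariance
`[[SD² + seA², α SD²], [α SD², α² SD² + σ² + seB²]]`. The resulting
3-dimensional posterior is sampled with the affine-invariant ensemble
sampler (emcee; 24 walkers, 400 warmup + 600 kept steps, thinned by 2,
~600 effective draws at typical autocorrelation ≈ 25 steps), with the
scale parameters on the log scale. This marginal-then-recover scheme
samples the identical posterior a gradient-based sampler would, and was
verified against dense 3-D grid integration (quantiles agree to < 0.01).
Latent effects are recovered afterwards by exact conditional normal
draws. Convergence is summarized by split-Rhat over four groups of
walkers (treating each coupled walker as a chain systematically inflates
Rhat at practical lengths) with a warning above 1.05. Credible intervals
are empirical quantiles at the requested level, default 0.80.

Hyperpriors (weakly informative, all configurable, adapted to the data):

- `SD_beta ~ half-normal(max |beta_hat_A|)` — the instrument scale is at
  most the largest observed exposure effect;
- `alpha ~ N(0, 2 * scale_B / scale_A)` with `scale_X = max(|beta_hat_X|
  + se_X)` — twice the largest slope the data could plausibly support;
- `sigma ~ half-normal(s)` with `s` the RMS residual of a preliminary
  weighted least-squares slope fit (floored at 10⁻³ of the outcome
  scale) — dispersion up to the total unexplained residual scale.

The σ scale was chosen among residual-RMS / excess-variance / median-SE
half-normal and half-Cauchy candidates by a calibration battery
(80%-interval coverage of α and σ on data drawn from the model itself,
plus the correlated-instrument null below); only the residual-RMS
half-normal gave nominal coverage for both parameters. A deliberate
consequence is mild conservatism when instruments are few and outcome
noise dominates: posterior mass on σ > 0 widens the α interval, so null
rejection rates run a few points below the nominal complement (see
"Calibration results").

Summaries: the mean mediated effect is the posterior mean α times the
arithmetic mean of the instrument exposure coefficients (the typical
trait shift delivered through the gene at this locus); the dispersion
ratio is posterior mean σ over the absolute mean mediated effect
(undefined and reported as NaN when the latter is 0; 0 when σ̂ = 0).

## Synthetic data

The generator reproduces the structure of a TWAS-style simulation over a
cis locus, with defaults equal to the benchmark study conditions:
N_eQTL = 500 (optionally 1000), N_GWAS = 100,000, 1000 SNPs per locus,
1% causal SNPs, h²g = 0.1, h²med = 0.01.

**Genotypes.** Real reference panels are replaced by a download-free
stand-in: per individual, two latent Gaussian haplotypes with AR(1)
correlation ρ = 0.9 between adjacent SNPs, thresholded at each SNP's
MAF quantile (MAF ~ U(0.01, 0.5)) and summed to a dosage, then columns
standardized. The implied adjacent-dosage correlation (~0.5–0.7,
decaying geometrically) yields clumps a handful of SNPs wide —
block-like LD without the long-range irregularity, allele-frequency
spectrum, or recombination hotspots of real panels. Passing tests
therefore demonstrate calibration under idealized LD, not robustness to
real LD pathologies; the two cohorts are always drawn as disjoint
individuals (two-sample MR), with the exposure panel's sample LD used as
the shared reference matrix.

**Paired studies.** Causal SNPs C (1% of the locus) get
`beta_eQTL ~ N(0, h2g / n_causal)`; expression is `Z beta + eps` with
the noise variance set from the realized sample variance of `Z beta` so
the locus explains exactly h²g of expression variance, and the phenotype
is standardized before per-SNP simple-regression summary statistics are
computed. The trait reuses the same causal set and effect values with
noise set by h²med (mediated mode), so the per-SNP ratio of
standardized-scale coefficients is exactly constant — that common ratio
is the true slope, and h²med ≈ h²g·α² holds. Null mode draws an
independent causal set and effects for the trait (true slope 0,
trait-only signal strength still h²med); horizontal-pleiotropy mode adds
three large trait-only signals (each ~ N(0, h2g/3)) to the mediated
trait. Degenerate requests (mediated with h²med = 0) fall back to null
semantics with a warning.

**Correlated instruments.** Exposure coefficients are drawn MVN centred
at 10 with unit scale and the stated r² as the correlation between
adjacent clusters (all other pairs 0; the tridiagonal matrix is PD for
values below ~0.5 and an eigenvalue-clip guard covers the rest), outcome
coefficients MVN centred at the origin — true slope 0 — with unit SEs
attached. Draws depend only on (J, n_iter, seed), so re-running with the
same seed at different r² reuses the same normals: false-positive-rate
differences across r² are then driven by the correlation, not
Monte-Carlo noise.

## Calibration results (recomputed by the test suite and acceptance script)

- Slope-model recovery (J = 8, α = 0.3, σ = 0.05, SEs 0.05, 200
  replicates): α and σ 80%-interval coverage within binomial tolerance
  of nominal, α unbiased within Monte-Carlo error.
- Main mediated setting (h²g = 0.1, h²med = 0.01, ≥ 20 qualifying loci):
  observed slope coverage at or above the nominal 80%.
- Null settings (h²g ∈ {0.05, 0.1, 0.2}): coverage of the zero slope
  near (in practice slightly above) nominal — the conservative direction.
- Correlated-instrument nulls at the r² = 0.05 trimming threshold: the
  interval-excludes-zero rate runs mildly below the nominal 20%
  (~0.12–0.17 across J ∈ {4, 6, 8}) and rises monotonically with r²,
  supporting the r² < 0.05 trimming recommendation. The shortfall from
  exactly 20% is the σ-mass conservatism discussed above, under this
  simulation's convention that the attached SEs equal the coefficient
  scatter.

Problem sizes used by `scripts/acceptance.py`: 750-SNP loci (package
default 1000), 30 mediated and 3 × 15 null qualifying loci at the full
cohort sizes (N_eQTL = 500, N_GWAS = 100,000); the heavy test-suite
benchmarks use 500-SNP loci and the same cohort sizes. These sizes are
the package's reporting choices; all thresholds and generator parameters
are the study-condition defaults above.

## Numerical choices and edge cases

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; identical (inputs, config, seed)
  reproduce byte-identical outputs.
- Inverse-gamma draws are clipped to [10⁻¹², 10¹²] to keep the Gibbs
  precision matrix finite under extreme shrinkage.
- LD matrices are symmetrized exactly, forced to unit diagonal, and
  validated (|r| ≤ 1, asymmetry tolerance 10⁻⁸ on input).
- Monomorphic synthetic genotype columns are redrawn independently of
  their neighbours (bounded retries) — a slight local LD distortion in a
  rare corner preferred over failing the draw.
- p-values from the marginal-regression generator are clipped into
  (0, 1] at the smallest positive double so record invariants hold.
- Ties in candidate selection (to relative 10⁻¹²) break by exposure
  p-value then position, making pipelines reproducible across platforms.

## Known limitations

- No intercept / pleiotropy term: large directional horizontal
  pleiotropy biases α (dispersion absorbs balanced pleiotropy only).
- Palindromic SNPs are always dropped; in studies with many A/T, C/G
  variants this discards signal that frequency-based harmonization
  could rescue.
- The synthetic LD generator underrepresents long-range and irregular
  LD; candidate-SNP accuracy on real panels will be lower than on these
  fixtures.
- Dispersion is weakly identified for J ≲ 4 clusters; intervals are then
  prior-sensitive and deliberately conservative.
- The per-SNP univariate likelihood ignores the sampling covariance of
  coefficients within a cluster; it is a modelling simplification
  inherited by design, compensated by the cluster-level trimming.
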