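"""Synthetic data generation for paired eQTL/GWAS experiments.

This module emulates the study conditions of a transcriptome-wide
association simulation: a cis locus of LD-correlated SNPs, a gene whose
expression has target cis heritability h2g from a small causal set, and a
downstream trait with expression-mediated heritability h2med. Genotypes are
synthetic: two latent Gaussian haplotypes per individual with AR(1)
correlation across SNPs, thresholded at MAF-matched quantiles and summed to
dosages, standing in for a real reference panel so everything runs
download-free. Null (independent trait-only signals) and horizontal-
pleiotropy variants are provided, along with a direct multivariate-normal
generator of correlated instrument coefficients and draws from the slope
model itself for parameter-recovery studies.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import InstrumentSet
from .io import LDMatrix, SumStats

DEFAULT_N_EQTL = 500
DEFAULT_N_GWAS = 100_000
DEFAULT_N_SNP = 1000
DEFAULT_CAUSAL_FRAC = 0.01
DEFAULT_H2G = 0.1
DEFAULT_H2MED = 0.01
DEFAULT_RHO = 0.9
DEFAULT_MAF_RANGE = (0.01, 0.5)
N_HP_SIGNALS = 3


@dataclass
class GenotypePanel:
    """N x n matrix of zero-centered, unit-variance genotype dosages plus metadata."""

    Z: np.ndarray
    meta: pd.DataFrame  # columns id, chrom, pos, a1, a2, maf
    ld_spec: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_ind(self) -> int:
        return self.Z.shape[0]

    @property
    def n_snp(self) -> int:
        return self.Z.shape[1]

    def ld_matrix(self) -> LDMatrix:
        """Sample correlation of dosages (signed, oriented to the effect allele)."""
        z = self.Z.astype(np.float64, copy=False)
        r = (z.T @ z) / self.n_ind
        np.fill_diagonal(r, 1.0)
        np.clip(r, -1.0, 1.0, out=r)
        return LDMatrix(self.meta["id"].tolist(), r)


@dataclass
class SimTruth:
    """Ground truth of one paired-study simulation."""

    causal_eqtl: np.ndarray
    causal_gwas: np.ndarray
    beta_eqtl: np.ndarray
    beta_gwas: np.ndarray
    h2g: float
    h2med: float
    alpha: float
    mode: str
    seed: int | None
    s2_gene: float = float("nan")
    s2_err: float = float("nan")
    s2_trait: float = float("nan")
    s2_err_trait: float = float("nan")
    sd_gene: float = float("nan")
    sd_trait: float = float("nan")
    alpha_defined: bool = True


def _ar1_latent(rng: np.random.Generator, n_ind: int, n_snp: int, rho: float,
                dtype) -> np.ndarray:
    """Stationary AR(1) Gaussian field across SNPs, independent across individuals.

    Returned SNP-major, shape (n_snp, n_ind); the recursion runs over
    contiguous rows, which is what makes large cohorts affordable.
    """
    gen_dtype = np.float32 if np.dtype(dtype) == np.float32 else np.float64
    e = rng.standard_normal((n_snp, n_ind), dtype=gen_dtype)
    if rho == 0 or n_snp == 1:
        return e
    innov = gen_dtype(math.sqrt(1.0 - rho ** 2))
    r = gen_dtype(rho)
    e[1:] *= innov
    for k in range(1, n_snp):
        e[k] += r * e[k - 1]
    return e


def simulate_genotypes(n_ind: int, n_snp: int,
                       ld_spec: dict | None = None,
                       seed: int | None = None,
                       dtype=np.float64,
                       chrom: str = "1", pos_step: int = 1000,
                       max_retries: int = 10) -> GenotypePanel:
    """Synthetic standardized genotype dosages with AR(1)-block LD.

    Two latent Gaussian haplotypes per individual share an AR(1) correlation
    ``rho`` between adjacent SNPs; each is thresholded at the quantile
    matching that SNP's minor-allele frequency (drawn uniformly from
    ``maf_range``) and the two binary haplotypes are summed to a dosage in
    {0, 1, 2}, then columns are standardized. Monomorphic columns are
    redrawn (independently of their neighbours) a bounded number of times.
    """
    if n_ind < 2 or n_snp < 1:
        raise ValueError("need n_ind >= 2 and n_snp >= 1")
    ld_spec = dict(ld_spec or {})
    rho = float(ld_spec.get("rho", DEFAULT_RHO))
    maf_lo, maf_hi = ld_spec.get("maf_range", DEFAULT_MAF_RANGE)
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_lo, maf_hi, size=n_snp)
    thresh = stats.norm.ppf(maf)

    # SNP-major throughout; Z is exposed as the (n_ind, n_snp) transpose view
    gen_dtype = np.float32 if np.dtype(dtype) == np.float32 else np.float64
    tcol = thresh[:, None].astype(gen_dtype)
    latent = _ar1_latent(rng, n_ind, n_snp, rho, dtype)
    dosage = (latent < tcol).view(np.int8)
    latent = _ar1_latent(rng, n_ind, n_snp, rho, dtype)
    dosage += latent < tcol
    del latent

    for _try in range(max_retries):
        mono = dosage.min(axis=1) == dosage.max(axis=1)
        if not mono.any():
            break
        k = int(mono.sum())
        redraw = (rng.standard_normal((k, n_ind)) < thresh[mono, None]).astype(np.int8)
        redraw += rng.standard_normal((k, n_ind)) < thresh[mono, None]
        dosage[mono] = redraw
    else:
        raise RuntimeError("monomorphic columns persisted across retries")

    # moments from integer counts: d in {0,1,2} so E[d^2] = E[d] + 2 P(d=2)
    s1 = dosage.sum(axis=1, dtype=np.int64)
    n2 = (dosage == 2).sum(axis=1, dtype=np.int64)
    mean = s1 / n_ind
    var = (s1 + 2 * n2) / n_ind - mean ** 2
    sd = np.sqrt(var)
    z = dosage.astype(dtype)
    z -= mean[:, None].astype(dtype)
    z /= sd[:, None].astype(dtype)
    z = z.T
    freq = mean / 2.0
    sample_maf = np.minimum(freq, 1.0 - freq)
    meta = pd.DataFrame({
        "id": [f"snp{i + 1:05d}" for i in range(n_snp)],
        "chrom": chrom,
        "pos": np.arange(1, n_snp + 1) * pos_step,
        "a1": "A",  # minor/effect allele of the dosage coding
        "a2": "G",
        "maf": sample_maf,
    })
    return GenotypePanel(Z=z, meta=meta,
                         ld_spec={"rho": rho, "maf_range": (maf_lo, maf_hi)},
                         seed=seed)


def marginal_sumstats(panel: GenotypePanel, y: np.ndarray,
                      study_label: str = "A") -> SumStats:
    """Per-SNP simple-regression summary statistics of ``y`` on each dosage column.

    ``y`` must be the standardized phenotype of the panel's individuals.
    Coefficients are per standard deviation of genotype since columns are
    standardized.
    """
    y = np.asarray(y, dtype=np.float64)
    n = panel.n_ind
    if len(y) != n:
        raise ValueError("phenotype length does not match panel")
    z = panel.Z
    zty = (z.T.astype(np.float64) @ y) if z.dtype != np.float64 else z.T @ y
    ztz = np.einsum("ij,ij->j", z, z, dtype=np.float64)
    beta = zty / ztz
    yty = float(y @ y)
    rss = np.maximum(yty - beta ** 2 * ztz, 0.0)
    dof = max(n - 2, 1)
    se = np.sqrt(rss / dof / ztz)
    se = np.maximum(se, 1e-300)
    tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    table = panel.meta.copy()
    table["beta"] = beta
    table["se"] = se
    table["pvalue"] = pval
    table = table[["id", "chrom", "pos", "a1", "a2", "beta", "se", "pvalue", "maf"]]
    return SumStats(study_label=study_label, table=table)


def _build_phenotype(panel: GenotypePanel, beta: np.ndarray, h2: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, float, float, float]:
    """Genetic value + noise scaled so the genetic fraction of variance is h2.

    Returns (standardized phenotype, s2_genetic, s2_err, sd of raw phenotype).
    """
    g = panel.Z.astype(np.float64) @ beta if panel.Z.dtype != np.float64 \
        else panel.Z @ beta
    s2_g = float(np.var(g, ddof=1))
    if h2 <= 0 or s2_g == 0:
        eps = rng.standard_normal(panel.n_ind)
        y_raw = eps
        s2_err = 1.0
    else:
        s2_err = s2_g * (1.0 / h2 - 1.0)
        eps = rng.normal(0.0, math.sqrt(s2_err), size=panel.n_ind)
        y_raw = g + eps
    sd_raw = float(np.std(y_raw, ddof=1))
    y = (y_raw - y_raw.mean()) / sd_raw
    return y, s2_g, s2_err, sd_raw


def simulate_study(panel_e: GenotypePanel, panel_g: GenotypePanel,
                   h2g: float = DEFAULT_H2G, h2med: float = DEFAULT_H2MED,
                   causal_frac: float = DEFAULT_CAUSAL_FRAC,
                   mode: str = "mediated", seed: int | None = None,
                   ) -> tuple[SumStats, SumStats, SimTruth]:
    """Simulate one paired eQTL/GWAS experiment over a shared locus.

    ``mediated``: the trait shares the gene's causal SNPs and effect sizes,
    with noise scaled so the trait's SNP heritability is ``h2med``; the true
    gene-to-trait slope is the (constant) ratio of standardized-scale
    coefficients, satisfying h2med ~= h2g * alpha^2. ``null``: the trait has
    an independently drawn causal set and effects (no mediation; alpha = 0).
    ``hp``: mediated plus three large-effect trait-only association signals
    (horizontal pleiotropy).
    """
    if not panel_e.meta["id"].equals(panel_g.meta["id"]):
        raise ValueError("panels must share the SNP set")
    if h2g <= 0 or h2g >= 1:
        raise ValueError("h2g must be in (0, 1)")
    if mode not in ("mediated", "null", "hp"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mediated" and h2med == 0:
        warnings.warn("h2med = 0 with mediated mode; falling back to null semantics")
        mode = "null"
    rng = np.random.default_rng(seed)
    n = panel_e.n_snp
    n_causal = max(1, math.ceil(causal_frac * n))
    causal = np.sort(rng.choice(n, size=n_causal, replace=False))
    beta_eqtl = np.zeros(n)
    beta_eqtl[causal] = rng.normal(0.0, math.sqrt(h2g / n_causal), size=n_causal)

    y_gene, s2_gene, s2_err, sd_gene = _build_phenotype(panel_e, beta_eqtl, h2g, rng)

    beta_gwas = np.zeros(n)
    if mode == "null":
        causal_t = np.sort(rng.choice(n, size=n_causal, replace=False))
        beta_gwas[causal_t] = rng.normal(0.0, math.sqrt(h2g / n_causal),
                                         size=n_causal)
        h2_trait = h2med if h2med > 0 else 0.0
    else:
        beta_gwas = beta_eqtl.copy()
        causal_t = causal.copy()
        h2_trait = h2med
        if mode == "hp":
            pool = np.setdiff1d(np.arange(n), causal)
            extra = np.sort(rng.choice(pool, size=N_HP_SIGNALS, replace=False))
            beta_gwas[extra] = rng.normal(0.0, math.sqrt(h2g / N_HP_SIGNALS),
                                          size=N_HP_SIGNALS)
            causal_t = np.sort(np.concatenate([causal_t, extra]))

    y_trait, s2_trait, s2_err_t, sd_trait = _build_phenotype(
        panel_g, beta_gwas, h2_trait, rng)

    ss_a = marginal_sumstats(panel_e, y_gene, study_label="A")
    ss_b = marginal_sumstats(panel_g, y_trait, study_label="B")

    if mode in ("mediated", "hp"):
        alpha = sd_gene / sd_trait  # beta_gwas == beta_eqtl on causal SNPs
        defined = True
    else:
        alpha, defined = 0.0, False
    truth = SimTruth(causal_eqtl=causal, causal_gwas=causal_t,
                     beta_eqtl=beta_eqtl, beta_gwas=beta_gwas,
                     h2g=h2g, h2med=h2med, alpha=alpha, mode=mode, seed=seed,
                     s2_gene=s2_gene, s2_err=s2_err, s2_trait=s2_trait,
                     s2_err_trait=s2_err_t, sd_gene=sd_gene, sd_trait=sd_trait,
                     alpha_defined=defined)
    return ss_a, ss_b, truth


def true_alpha(truth: SimTruth, sd_gene: float | None = None,
               sd_trait: float | None = None) -> float:
    """The common scaled ratio beta_gwas / beta_eqtl over causal SNPs.

    Coefficients are scaled by the raw-phenotype sample standard deviations
    (the phenotypes are standardized before coefficient estimation). In
    mediated mode the per-SNP ratios agree to 1e-8 by construction; in null
    mode the slope is undefined and reported as 0 with ``alpha_defined``
    False on the truth object.
    """
    if not truth.alpha_defined:
        return 0.0
    sd_gene = truth.sd_gene if sd_gene is None else sd_gene
    sd_trait = truth.sd_trait if sd_trait is None else sd_trait
    c = truth.causal_eqtl
    ratios = (truth.beta_gwas[c] / sd_trait) / (truth.beta_eqtl[c] / sd_gene)
    if np.ptp(ratios) > 1e-8 * max(1.0, np.abs(ratios).max()):
        raise AssertionError("causal-SNP ratios are not constant in mediated mode")
    return float(ratios[0])


def simulate_correlated_instruments(J: int, r2_adjacent: float, n_iter: int,
                                    seed: int | None = None,
                                    se_a: float = 1.0, se_b: float = 1.0,
                                    mean_a: float = 10.0,
                                    ) -> list[InstrumentSet]:
    """Instrument coefficients with a prescribed correlation between adjacent clusters.

    Exposure coefficients are multivariate normal centred on
    ``[mean_a, ..., mean_a]``, outcome coefficients on the origin (so the
    true gene-to-trait slope is 0); the correlation between adjacent
    clusters equals ``r2_adjacent`` and all other pairs are uncorrelated.
    Unit-scale standard errors are attached. Because draws depend only on
    (J, n_iter, seed), calling with the same seed and different
    ``r2_adjacent`` reuses the same underlying standard normals (common
    random numbers), which sharpens comparisons of false-positive rates
    across correlation levels.
    """
    if not (0 <= r2_adjacent < 1):
        raise ValueError("r2_adjacent must be in [0, 1)")
    cov = np.eye(J)
    idx = np.arange(J - 1)
    cov[idx, idx + 1] = cov[idx + 1, idx] = r2_adjacent
    # tridiagonal correlation is PD for adjacent values below 1/(2 cos(pi/(J+1)));
    # guard anyway with an eigenvalue clip
    w, v = np.linalg.eigh(cov)
    if w.min() <= 1e-10:
        w = np.clip(w, 1e-10, None)
        cov = (v * w) @ v.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        w, v = np.linalg.eigh(cov)
    chol = v * np.sqrt(w) @ v.T  # symmetric square root: stable under r2 changes
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        beta_a = mean_a + chol @ rng.standard_normal(J)
        beta_b = chol @ rng.standard_normal(J)
        out.append(InstrumentSet(beta_a=beta_a, se_a=np.full(J, se_a),
                                 beta_b=beta_b, se_b=np.full(J, se_b)))
    return out


def simulate_from_slope_model(J: int, alpha: float, sigma: float, sd_beta: float,
                              se_a: float, se_b: float,
                              seed: int | None = None) -> InstrumentSet:
    """Draw one instrument set from the slope model's own generative equations."""
    if sd_beta <= 0 or sigma < 0 or se_a <= 0 or se_b <= 0:
        raise ValueError("scales must be positive (sigma may be 0)")
    rng = np.random.default_rng(seed)
    beta_a = rng.normal(0.0, sd_beta, size=J)
    beta_b = rng.normal(alpha * beta_a, sigma)
    obs_a = rng.normal(beta_a, se_a)
    obs_b = rng.normal(beta_b, se_b)
    return InstrumentSet(beta_a=obs_a, se_a=np.full(J, se_a),
                         beta_b=obs_b, se_b=np.full(J, se_b))
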