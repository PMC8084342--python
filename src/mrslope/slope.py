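"""Hierarchical gene-to-trait slope estimation across signal clusters.

Across clusters j = 1..J, with exposure (eQTL) instrument estimates
beta_hat_jA +/- se_jA and outcome (GWAS) estimates beta_hat_jB +/- se_jB:

    beta_hat_jA ~ N(beta_jA, se_jA)
    beta_hat_jB ~ N(beta_jB, se_jB)
    beta_jA     ~ N(0, SD_beta)
    beta_jB     ~ N(alpha * beta_jA, sigma)

alpha is the gene-to-trait slope (the line passes through the origin: a
cluster with no exposure effect is assumed to have no outcome effect),
SD_beta is the scale of true instrument effects, and sigma is the
*dispersion*: the standard deviation of per-cluster outcome effects around
the slope line, quantifying allelic heterogeneity of the mediated effect.
All normal distributions are parameterised by (mean, standard deviation).

The latent pairs (beta_jA, beta_jB) are jointly Gaussian given the three
hyperparameters, so they are integrated out analytically: each instrument
contributes a bivariate normal likelihood with covariance

    [[SD^2 + seA_j^2,        alpha SD^2              ],
     [alpha SD^2,  alpha^2 SD^2 + sigma^2 + seB_j^2]].

The 3-dimensional marginal posterior over (alpha, log sigma, log SD_beta)
is sampled with an affine-invariant ensemble sampler (emcee); latent
effects are then recovered by exact conditional normal draws. Credible
intervals are empirical quantiles of the posterior draws (default level
0.80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .coloc import InstrumentSet

DEFAULT_LEVEL = 0.80


class HeterogeneityWarning(UserWarning):
    """Fewer than two nearly-LD-independent signal clusters."""


class HeterogeneityError(ValueError):
    """No instruments at all, or fitting refused for lack of heterogeneity."""


def check_heterogeneity(instruments: InstrumentSet) -> bool:
    """Require at least two independent signal clusters for slope fitting.

    Returns True when J >= 2. With J == 1 a :class:`HeterogeneityWarning`
    is issued and False returned (fitting should be refused unless forced);
    J == 0 is a fatal :class:`HeterogeneityError`.
    """
    J = len(instruments)
    if J == 0:
        raise HeterogeneityError("no instruments")
    if J < 2:
        warnings.warn("insufficient allelic heterogeneity: a single signal "
                      "cluster cannot identify slope and dispersion",
                      HeterogeneityWarning)
        return False
    return True


@dataclass
class SlopeFit:
    """Posterior draws and summaries from the hierarchical slope model."""

    alpha: np.ndarray           # posterior draws
    sigma: np.ndarray
    sd_beta: np.ndarray
    beta_a: np.ndarray          # latent draws, (n_draws, J)
    beta_b: np.ndarray
    level: float
    alpha_interval: tuple[float, float]
    sigma_interval: tuple[float, float]
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def alpha_mean(self) -> float:
        return float(self.alpha.mean())

    @property
    def alpha_sd(self) -> float:
        return float(self.alpha.std(ddof=1))

    @property
    def sigma_mean(self) -> float:
        return float(self.sigma.mean())

    def summary(self) -> pd.DataFrame:
        lo, hi = self.alpha_interval
        slo, shi = self.sigma_interval
        return pd.DataFrame({
            "parameter": ["alpha", "sigma", "sd_beta"],
            "mean": [self.alpha_mean, self.sigma_mean, float(self.sd_beta.mean())],
            "sd": [self.alpha_sd, float(self.sigma.std(ddof=1)),
                   float(self.sd_beta.std(ddof=1))],
            "lower": [lo, slo, float(np.quantile(self.sd_beta, (1 - self.level) / 2))],
            "upper": [hi, shi, float(np.quantile(self.sd_beta, 1 - (1 - self.level) / 2))],
        })


def _log_posterior_factory(ba, sa, bb, sb, s_alpha, s_sigma, s_sd):
    """Vectorised log posterior over theta = (alpha, log sigma, log SD_beta)."""
    sa2 = sa ** 2
    sb2 = sb ** 2

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        alpha = theta[:, 0:1]
        log_sigma = theta[:, 1:2]
        log_sd = theta[:, 2:3]
        out = np.full(theta.shape[0], -np.inf)
        ok = (np.abs(log_sigma[:, 0]) < 40) & (np.abs(log_sd[:, 0]) < 40)
        if not ok.any():
            return out
        sig2 = np.exp(2 * log_sigma)
        sd2 = np.exp(2 * log_sd)
        s11 = sd2 + sa2          # (W, J) via broadcast
        s12 = alpha * sd2
        s22 = alpha ** 2 * sd2 + sig2 + sb2
        det = s11 * s22 - s12 ** 2
        quad = (s22 * ba ** 2 - 2 * s12 * ba * bb + s11 * bb ** 2) / det
        loglik = -0.5 * np.sum(np.log(det) + quad, axis=1)
        # priors: alpha ~ N(0, s_alpha); sigma, SD_beta half-normal with
        # log-scale Jacobians
        logprior = (-0.5 * (alpha[:, 0] / s_alpha) ** 2
                    - 0.5 * (sig2[:, 0] / s_sigma ** 2) + log_sigma[:, 0]
                    - 0.5 * (sd2[:, 0] / s_sd ** 2) + log_sd[:, 0])
        res = loglik + logprior
        out[ok] = res[ok]
        return out

    return log_prob


class SlopeModel(BaseEstimator):
    """Bayesian errors-in-variables regression of outcome on exposure effects.

    Parameters
    ----------
    level : float
        Credible level for quantile-based intervals (default 0.80).
    n_walkers, n_warmup, n_steps : int
        Ensemble sampler configuration; posterior draws kept are
        ``n_walkers * n_steps / thin``.
    alpha_prior_scale, sigma_prior_scale, sd_beta_prior_scale : float or None
        Prior scales. ``None`` adapts them to the data: SD_beta half-normal
        at max|beta_hat_A|; alpha normal with scale twice the ratio of
        outcome to exposure data scales; sigma half-normal at the residual
        scale of a preliminary weighted least-squares fit (floored at the
        median outcome SE so that dispersion is never ruled out a priori).
    rhat_warn : float
        Warn when the split-Rhat of any hyperparameter exceeds this.
    random_state : int or None
        Seed controlling the sampler and latent-effect recovery.
    """

    def __init__(self, level: float = DEFAULT_LEVEL, n_walkers: int = 24,
                 n_warmup: int = 400, n_steps: int = 600, thin: int = 2,
                 alpha_prior_scale: float | None = None,
                 sigma_prior_scale: float | None = None,
                 sd_beta_prior_scale: float | None = None,
                 rhat_warn: float = 1.05, force: bool = False,
                 random_state: int | None = None):
        self.level = level
        self.n_walkers = n_walkers
        self.n_warmup = n_warmup
        self.n_steps = n_steps
        self.thin = thin
        self.alpha_prior_scale = alpha_prior_scale
        self.sigma_prior_scale = sigma_prior_scale
        self.sd_beta_prior_scale = sd_beta_prior_scale
        self.rhat_warn = rhat_warn
        self.force = force
        self.random_state = random_state

    # -- prior adaptation -------------------------------------------------
    def _prior_scales(self, ins: InstrumentSet) -> tuple[float, float, float]:
        ba, sa, bb, sb = ins.beta_a, ins.se_a, ins.beta_b, ins.se_b
        scale_a = max(np.max(np.abs(ba) + sa), 1e-8)
        scale_b = max(np.max(np.abs(bb) + sb), 1e-8)
        s_sd = self.sd_beta_prior_scale or max(np.max(np.abs(ba)), 1e-8)
        s_alpha = self.alpha_prior_scale or 2.0 * scale_b / scale_a
        if self.sigma_prior_scale is not None:
            s_sigma = self.sigma_prior_scale
        else:
            w = 1.0 / sb ** 2
            a0 = np.sum(w * ba * bb) / np.sum(w * ba ** 2)
            resid = bb - a0 * ba
            s_sigma = max(float(np.sqrt(np.mean(resid ** 2))),
                          1e-3 * scale_b, 1e-12)
        return float(s_alpha), float(s_sigma), float(s_sd)

    # -- fitting ----------------------------------------------------------
    def fit(self, instruments: InstrumentSet, y=None) -> "SlopeModel":
        ins = instruments if isinstance(instruments, InstrumentSet) else \
            InstrumentSet(*np.asarray(instruments, dtype=float).T)
        if not check_heterogeneity(ins) and not self.force:
            raise HeterogeneityError(
                "refusing to fit with a single signal cluster (use force=True)")
        ba, sa, bb, sb = ins.beta_a, ins.se_a, ins.beta_b, ins.se_b
        s_alpha, s_sigma, s_sd = self._prior_scales(ins)
        self.prior_scales_ = {"alpha": s_alpha, "sigma": s_sigma, "sd_beta": s_sd}
        log_prob = _log_posterior_factory(ba, sa, bb, sb, s_alpha, s_sigma, s_sd)

        rng = np.random.default_rng(self.random_state)
        w = 1.0 / sb ** 2
        a0 = float(np.sum(w * ba * bb) / np.sum(w * ba ** 2))
        sd0 = max(float(np.std(ba)), float(np.mean(sa)), 1e-6)
        p0 = np.column_stack([
            a0 + 0.1 * s_alpha * rng.standard_normal(self.n_walkers),
            np.log(s_sigma) + 0.5 * rng.standard_normal(self.n_walkers),
            np.log(sd0) + 0.5 * rng.standard_normal(self.n_walkers),
        ])
        sampler = emcee.EnsembleSampler(self.n_walkers, 3, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2 ** 31 - 1))).get_state()
        sampler.run_mcmc(p0, self.n_warmup + self.n_steps, progress=False)
        chain = sampler.get_chain(discard=self.n_warmup, thin=self.thin)  # (T, W, 3)
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))
        rhat = self._rhat(chain)
        if rhat > self.rhat_warn:
            warnings.warn(f"slope-model split-Rhat {rhat:.3f} exceeds "
                          f"{self.rhat_warn}; inspect the fit")
        flat = chain.reshape(-1, 3)
        alpha = flat[:, 0]
        sigma = np.exp(flat[:, 1])
        sd_beta = np.exp(flat[:, 2])
        beta_a, beta_b = self._recover_latents(alpha, sigma, sd_beta,
                                               ba, sa, bb, sb, rng)
        q = [(1 - self.level) / 2, 1 - (1 - self.level) / 2]
        self.fit_ = SlopeFit(
            alpha=alpha, sigma=sigma, sd_beta=sd_beta,
            beta_a=beta_a, beta_b=beta_b, level=self.level,
            alpha_interval=tuple(np.quantile(alpha, q)),
            sigma_interval=tuple(np.quantile(sigma, q)),
            diagnostics={"max_rhat": rhat, "divergences": 0.0,
                         "acceptance_fraction": self.acceptance_fraction_},
        )
        self.instruments_ = ins
        self.alpha_mean_ = self.fit_.alpha_mean
        self.alpha_interval_ = self.fit_.alpha_interval
        self.sigma_mean_ = self.fit_.sigma_mean
        self.sigma_interval_ = self.fit_.sigma_interval
        self.sd_beta_mean_ = float(sd_beta.mean())
        return self

    @staticmethod
    def _rhat(chain: np.ndarray, n_groups: int = 4) -> float:
        """Split-Rhat over groups of walkers.

        Walkers of one ensemble are coupled, so treating each as a chain
        inflates Rhat at practical chain lengths; grouping walkers and
        comparing group distributions is the practical ensemble-sampler
        analogue.
        """
        import arviz as az

        groups = np.array_split(np.arange(chain.shape[1]), n_groups)
        stacked = np.stack([np.concatenate([chain[:, i, :] for i in ids], axis=0)
                            for ids in groups])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(np.nanmax(az.rhat(az.convert_to_dataset(stacked))["x"].values))

    @staticmethod
    def _recover_latents(alpha, sigma, sd_beta, ba, sa, bb, sb, rng):
        """Exact conditional draws of the latent effects given hyperparameters."""
        a = alpha[:, None]
        s2 = sigma[:, None] ** 2
        sd2 = sd_beta[:, None] ** 2
        prec_a = 1.0 / sd2 + 1.0 / sa ** 2 + a ** 2 / (s2 + sb ** 2)
        mean_a = (ba / sa ** 2 + a * bb / (s2 + sb ** 2)) / prec_a
        beta_a = mean_a + rng.standard_normal(mean_a.shape) / np.sqrt(prec_a)
        prec_b = 1.0 / np.clip(s2, 1e-300, None) + 1.0 / sb ** 2
        mean_b = (a * beta_a / np.clip(s2, 1e-300, None) + bb / sb ** 2) / prec_b
        beta_b = mean_b + rng.standard_normal(mean_b.shape) / np.sqrt(prec_b)
        return beta_a, beta_b

    # -- post-fit quantities ----------------------------------------------
    def predict(self, beta_a: np.ndarray) -> np.ndarray:
        """Posterior-mean fitted outcome effects alpha_hat * beta_a."""
        return self.alpha_mean_ * np.asarray(beta_a, dtype=float)

    def mean_mediated(self, instruments: InstrumentSet | None = None) -> float:
        ins = instruments if instruments is not None else self.instruments_
        return mean_mediated(self.alpha_mean_, ins.beta_a)

    def dispersion_ratio(self, instruments: InstrumentSet | None = None) -> float:
        ins = instruments if instruments is not None else self.instruments_
        return dispersion_ratio(self.sigma_mean_, self.mean_mediated(ins))


def fit_slope(instruments: InstrumentSet, level: float = DEFAULT_LEVEL,
              seed: int | None = None, force: bool = False,
              **sampler_kwargs) -> SlopeFit:
    """Fit the hierarchical slope model; convenience wrapper over SlopeModel."""
    model = SlopeModel(level=level, random_state=seed, force=force, **sampler_kwargs)
    model.fit(instruments)
    return model.fit_


def mean_mediated(alpha: float, beta_a: np.ndarray) -> float:
    """Mean mediated effect: slope estimate times the mean exposure coefficient.

    The typical outcome change delivered through the gene for a typical
    expression-increasing allele at this locus.
    """
    return float(alpha) * float(np.mean(np.asarray(beta_a, dtype=float)))


def dispersion_ratio(sigma: float, mean_mediated_effect: float) -> float:
    """Dispersion over |mean mediated effect|; nan when the latter is zero.

    Values near or above 1 indicate per-cluster effects as variable as the
    typical mediated effect itself.
    """
    if sigma == 0:
        return 0.0
    if mean_mediated_effect == 0:
        warnings.warn("mean mediated effect is 0; dispersion ratio undefined")
        return float("nan")
    return float(sigma) / abs(float(mean_mediated_effect))
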