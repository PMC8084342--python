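"""Per-cluster Bayesian colocalization with horseshoe shrinkage.

For each study S in {A (eQTL), B (GWAS)} the observed coefficients in one
signal cluster are modelled with a univariate likelihood whose mean couples
SNPs only through the signed LD matrix R_S:

    beta_hat_i ~ Normal((R_S beta)_i, se_i)        independently per SNP i
    beta_i = tau * lambda_i * z_i,  z_i ~ N(0, 1)
    lambda_i ~ half-Cauchy(0, 1),   tau ~ half-Cauchy(0, tau0)

The horseshoe prior concentrates posterior mass of the true coefficients on
a sparse subset of SNPs, so within a cluster a single candidate causal SNP
emerges as the member with the largest posterior mean eQTL effect. Because
the likelihood is linear-Gaussian in beta, the full posterior admits an
exact Gibbs sampler using the inverse-gamma auxiliary-variable
representation of the half-Cauchy densities (Makalic & Schmidt 2016): every
conditional is closed-form, so no gradient-based sampler is required.

The global-scale hyperparameter tau0 adapts to the data scale of each study:
by default tau0 = median(se) * p0/n with p0 = 1 expected nonzero SNP, which
encodes "roughly one causal variant per cluster, at or below the noise
scale" and is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .harmonize import SignalCluster
from .io import LDMatrix

from sklearn.base import BaseEstimator


@dataclass
class ColocFit:
    """Posterior summary of one cluster's colocalization fit."""

    ids: list[str]
    post_mean_a: np.ndarray
    post_sd_a: np.ndarray
    post_mean_b: np.ndarray
    post_sd_b: np.ndarray
    candidate_id: str
    pvalues_a: np.ndarray
    positions: np.ndarray
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict[str, float] = field(default_factory=dict)
    cluster: SignalCluster | None = None

    @property
    def candidate_index(self) -> int:
        return self.ids.index(self.candidate_id)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "post_mean_A": self.post_mean_a,
            "post_sd_A": self.post_sd_a,
            "post_mean_B": self.post_mean_b,
            "post_sd_B": self.post_sd_b,
            "candidate": [s == self.candidate_id for s in self.ids],
        })


@dataclass
class InstrumentSet:
    """One row per nearly-LD-independent signal cluster: the candidate SNP's
    exposure and outcome coefficients with their uncertainties."""

    beta_a: np.ndarray
    se_a: np.ndarray
    beta_b: np.ndarray
    se_b: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta_a = np.atleast_1d(np.asarray(self.beta_a, dtype=float))
        self.se_a = np.atleast_1d(np.asarray(self.se_a, dtype=float))
        self.beta_b = np.atleast_1d(np.asarray(self.beta_b, dtype=float))
        self.se_b = np.atleast_1d(np.asarray(self.se_b, dtype=float))
        J = len(self.beta_a)
        if J == 0:
            raise ValueError("instrument set must contain at least one cluster")
        if not (len(self.se_a) == len(self.beta_b) == len(self.se_b) == J):
            raise ValueError("instrument arrays must share one length")
        arrs = np.concatenate([self.beta_a, self.se_a, self.beta_b, self.se_b])
        if not np.isfinite(arrs).all():
            raise ValueError("non-finite instrument values")
        if (self.se_a <= 0).any() or (self.se_b <= 0).any():
            raise ValueError("instrument standard errors must be positive")

    def __len__(self) -> int:
        return len(self.beta_a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids if self.ids is not None else range(len(self)),
            "beta_a": self.beta_a, "se_a": self.se_a,
            "beta_b": self.beta_b, "se_b": self.se_b,
        })


def _sample_invgamma(rng: np.random.Generator, shape, scale):
    """Draw from InvGamma(shape, scale) with density ~ x^-(shape+1) exp(-scale/x)."""
    return scale / rng.gamma(shape, size=np.shape(scale))


def _gibbs_horseshoe(beta_hat: np.ndarray, se: np.ndarray, r_mat: np.ndarray,
                     tau0: float, n_warmup: int, n_samples: int, n_chains: int,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Exact Gibbs sampler for one study's horseshoe model in one cluster.

    All chains advance together through numpy's batched linear algebra (one
    stacked Cholesky per sweep instead of one per chain). Returns draws of
    beta (chain, draw, n), lambda (chain, draw, n), tau (chain, draw).
    """
    n = len(beta_hat)
    C = n_chains
    d_inv = 1.0 / se ** 2
    # precision contribution of the likelihood: R' D^-1 R, and R' D^-1 beta_hat
    m = r_mat.T * d_inv @ r_mat
    v = r_mat.T @ (d_inv * beta_hat)

    # overdispersed initialisation so between-chain Rhat is informative
    beta = 0.5 * rng.standard_normal((C, n)) * np.abs(beta_hat).max()
    lam2 = np.ones((C, n))
    nu = np.ones((C, n))
    tau2 = np.full(C, tau0 ** 2)
    xi = np.ones(C)
    out_beta = np.empty((C, n_samples, n))
    out_lam = np.empty((C, n_samples, n))
    out_tau = np.empty((C, n_samples))
    clip = (1e-12, 1e12)
    eye = np.arange(n)
    for it in range(n_warmup + n_samples):
        prec = np.broadcast_to(m, (C, n, n)).copy()
        prec[:, eye, eye] += 1.0 / np.clip(tau2[:, None] * lam2, *clip)
        chol = np.linalg.cholesky(prec)  # batched
        z = rng.standard_normal((C, n))
        # beta = prec^-1 v + L^-T z; batched generic solves (n is small)
        mean = np.linalg.solve(prec, np.broadcast_to(v[:, None], (C, n, 1)))[..., 0]
        beta = mean + np.linalg.solve(
            np.transpose(chol, (0, 2, 1)), z[..., None])[..., 0]
        lam2 = np.clip(_sample_invgamma(rng, 1.0, 1.0 / nu + beta ** 2
                                        / (2.0 * tau2[:, None])), *clip)
        nu = _sample_invgamma(rng, 1.0, 1.0 + 1.0 / lam2)
        tau2 = np.clip(_sample_invgamma(
            rng, (n + 1.0) / 2.0, 1.0 / xi + np.sum(beta ** 2 / lam2, axis=1) / 2.0),
            *clip)
        xi = _sample_invgamma(rng, 1.0, 1.0 / tau0 ** 2 + 1.0 / tau2)
        if it >= n_warmup:
            out_beta[:, it - n_warmup] = beta
            out_lam[:, it - n_warmup] = np.sqrt(lam2)
            out_tau[:, it - n_warmup] = np.sqrt(tau2)
    return {"beta": out_beta, "lambda": out_lam, "tau": out_tau}


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter for draws shaped (chain, draw, param)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chains)
        return np.asarray(az.rhat(ds)["x"].values)


class HorseshoeColoc(BaseEstimator):
    """Sparse Bayesian colocalization of one signal cluster.

    Parameters
    ----------
    n_chains, n_warmup, n_samples : int
        Gibbs chains and iterations per chain (draws kept after warmup).
    tau0_scale : float or None
        Global half-Cauchy scale tau0; ``None`` adapts it per study as
        ``median(se) * expected_nonzero / n``.
    expected_nonzero : float
        Expected number of causal SNPs per cluster used by the adaptation.
    ridge : float
        Added to the LD diagonal before use, stabilising near-singular
        correlation patterns.
    rhat_warn : float
        Attach a convergence warning when any split-Rhat exceeds this.
    random_state : int or None
        Seed for the sampler.
    """

    def __init__(self, n_chains: int = 4, n_warmup: int = 1000, n_samples: int = 1000,
                 tau0_scale: float | None = None, expected_nonzero: float = 1.0,
                 ridge: float = 1e-3, rhat_warn: float = 1.05,
                 keep_draws: bool = True, random_state: int | None = None):
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.tau0_scale = tau0_scale
        self.expected_nonzero = expected_nonzero
        self.ridge = ridge
        self.rhat_warn = rhat_warn
        self.keep_draws = keep_draws
        self.random_state = random_state

    def _tau0(self, se: np.ndarray) -> float:
        if self.tau0_scale is not None:
            return float(self.tau0_scale)
        n = len(se)
        return float(np.median(se) * self.expected_nonzero / n)

    def fit(self, cluster: SignalCluster, ld_a: LDMatrix | None = None,
            ld_b: LDMatrix | None = None) -> "HorseshoeColoc":
        """Sample the posterior for both studies of one flipped, collapsed cluster."""
        ids = cluster.ids
        n = len(ids)
        seeds = np.random.SeedSequence(self.random_state).spawn(2)
        draws: dict[str, np.ndarray] = {}
        diagnostics: dict[str, float] = {"divergences": 0.0}
        for k, (study, tab, ld) in enumerate([
                ("a", cluster.a, ld_a if ld_a is not None else cluster.ld),
                ("b", cluster.b, ld_b if ld_b is not None else cluster.ld)]):
            beta_hat = tab["beta"].to_numpy(dtype=float)
            se = tab["se"].to_numpy(dtype=float)
            if not np.isfinite(beta_hat).all() or not np.isfinite(se).all():
                raise ValueError("non-finite inputs to colocalization")
            r_mat = ld.subset(ids).r + self.ridge * np.eye(n)
            tau0 = self._tau0(se)
            rng = np.random.default_rng(seeds[k])
            out = _gibbs_horseshoe(beta_hat, se, r_mat, tau0, self.n_warmup,
                                   self.n_samples, self.n_chains, rng)
            beta_chains = out["beta"]  # (chain, draw, n)
            draws[f"beta_{study}"] = beta_chains.reshape(-1, n)
            draws[f"tau_{study}"] = out["tau"].reshape(-1)
            rhat = _split_rhat(beta_chains) if self.n_chains > 1 else np.ones(n)
            diagnostics[f"max_rhat_{study}"] = float(np.nanmax(rhat))
        max_rhat = max(diagnostics["max_rhat_a"], diagnostics["max_rhat_b"])
        if max_rhat > self.rhat_warn:
            warnings.warn(f"colocalization split-Rhat {max_rhat:.3f} exceeds "
                          f"{self.rhat_warn}; treat posterior summaries with caution")
        self.fit_ = ColocFit(
            ids=list(ids),
            post_mean_a=draws["beta_a"].mean(axis=0),
            post_sd_a=draws["beta_a"].std(axis=0, ddof=1),
            post_mean_b=draws["beta_b"].mean(axis=0),
            post_sd_b=draws["beta_b"].std(axis=0, ddof=1),
            candidate_id="",
            pvalues_a=cluster.a["pvalue"].to_numpy(dtype=float),
            positions=cluster.a["pos"].to_numpy(),
            draws=draws if self.keep_draws else {},
            diagnostics=diagnostics,
            cluster=cluster,
        )
        self.fit_.candidate_id = select_candidate(self.fit_)
        return self


def fit_coloc(cluster: SignalCluster, ld_a: LDMatrix | None = None,
              ld_b: LDMatrix | None = None, seed: int | None = None,
              **sampler_kwargs) -> ColocFit:
    """Fit the horseshoe colocalization model to one signal cluster."""
    model = HorseshoeColoc(random_state=seed, **sampler_kwargs)
    model.fit(cluster, ld_a=ld_a, ld_b=ld_b)
    return model.fit_


def select_candidate(fit: ColocFit) -> str:
    """The member with the largest posterior mean exposure effect.

    After flipping, exposure effects are oriented positive; absolute values
    are used defensively. Ties (to near machine precision) break by smaller
    exposure p-value, then smaller position.
    """
    mag = np.abs(fit.post_mean_a)
    best = mag.max()
    tied = np.flatnonzero(mag >= best * (1 - 1e-12))
    order = sorted(tied, key=lambda i: (fit.pvalues_a[i], fit.positions[i]))
    return fit.ids[order[0]]


def build_instruments(fits: Sequence[ColocFit], mode: str = "posterior",
                      candidates: Sequence[str] | None = None,
                      ) -> InstrumentSet:
    """Assemble the per-cluster instrument table for slope fitting.

    ``mode="posterior"`` (default) emits each cluster candidate's posterior
    mean and posterior sd for both studies. ``mode="raw"`` emits the
    candidate's original observed coefficient and SE (the externally chosen
    candidate pathway); ``candidates`` may override each fit's own choice.
    """
    if len(fits) == 0:
        raise ValueError("no colocalization fits provided")
    rows = []
    for j, fit in enumerate(fits):
        cand = candidates[j] if candidates is not None else fit.candidate_id
        i = fit.ids.index(cand)
        if mode == "posterior":
            rows.append((cand, fit.post_mean_a[i], fit.post_sd_a[i],
                         fit.post_mean_b[i], fit.post_sd_b[i]))
        elif mode == "raw":
            if fit.cluster is None:
                raise ValueError("raw mode requires fits carrying their cluster")
            ra = fit.cluster.a.iloc[i]
            rb = fit.cluster.b.iloc[i]
            rows.append((cand, ra["beta"], ra["se"], rb["beta"], rb["se"]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    ids, ba, sa, bb, sb = zip(*rows)
    return InstrumentSet(beta_a=np.array(ba), se_a=np.array(sa),
                         beta_b=np.array(bb), se_b=np.array(sb), ids=list(ids))
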