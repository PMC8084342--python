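"""Simulation-study drivers: generate loci, run the pipeline, aggregate metrics.

These are the workhorses behind benchmark evaluation: they repeat the
paired-study generator until enough loci qualify (show allelic
heterogeneity), run the full two-step analysis on each, and reduce the
results to an :class:`~mrslope.evaluate.EvalReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import EvalReport, candidate_accuracy
from .pipeline import LocusResult, RunConfig, analyze_locus
from .simulate import (DEFAULT_CAUSAL_FRAC, DEFAULT_H2G, DEFAULT_H2MED,
                       DEFAULT_N_EQTL, DEFAULT_N_GWAS, DEFAULT_N_SNP,
                       SimTruth, simulate_genotypes, simulate_study)
from .slope import fit_slope


@dataclass
class StudyResult:
    """Per-locus outcomes of one simulation study."""

    label: str
    estimates: list[float] = field(default_factory=list)
    intervals: list[tuple[float, float]] = field(default_factory=list)
    truths: list[float] = field(default_factory=list)
    chosen: list[str] = field(default_factory=list)
    causal: list[str] = field(default_factory=list)
    accuracy_hits: list[bool] = field(default_factory=list)
    attempts: int = 0
    no_signal: int = 0
    insufficient: int = 0

    def report(self) -> EvalReport:
        rep = EvalReport(label=self.label,
                         estimates=np.array(self.estimates),
                         intervals=np.array(self.intervals),
                         truths=np.array(self.truths))
        if self.accuracy_hits:
            rep.candidate_accuracy = float(np.mean(self.accuracy_hits))
        return rep


def _locus_candidate_hits(res: LocusResult, truth: SimTruth,
                          ids: list[str], ld, r_threshold: float = 0.95
                          ) -> list[bool]:
    """Whether each cluster's chosen candidate matches (or tags) a causal eSNP."""
    causal_ids = {ids[i] for i in truth.causal_eqtl}
    hits: list[bool] = []
    for cluster, fit in zip(res.clusters, res.fits):
        members = set()
        for rep, group in (cluster.collapsed or {}).items():
            members.update(group)
        members.update(cluster.ids)
        in_cluster = members & causal_ids
        if not in_cluster:
            continue
        cand = fit.candidate_id
        hit = any(c == cand or abs(ld.r[ld.index_of(cand), ld.index_of(c)]) > r_threshold
                  for c in in_cluster)
        hits.append(hit)
    return hits


def run_simulation_study(label: str, mode: str = "mediated",
                         h2g: float = DEFAULT_H2G, h2med: float = DEFAULT_H2MED,
                         n_loci: int = 20, seed: int = 0,
                         n_eqtl: int = DEFAULT_N_EQTL, n_gwas: int = DEFAULT_N_GWAS,
                         n_snp: int = DEFAULT_N_SNP,
                         causal_frac: float = DEFAULT_CAUSAL_FRAC,
                         config: RunConfig | None = None,
                         max_attempts: int | None = None,
                         rho: float | None = None,
                         verbose: bool = False) -> StudyResult:
    """Simulate paired studies until ``n_loci`` qualifying loci are analysed.

    A locus qualifies when it yields at least two nearly-LD-independent
    signal clusters after both trimming rounds (allelic heterogeneity); loci
    with no clump-worthy exposure signal trigger a fresh seed, as do loci
    with a single cluster. Genotypes for the two studies are drawn from the
    same LD specification but independent individuals (two-sample design);
    the exposure panel's sample LD serves as the shared reference matrix.
    """
    cfg = config or RunConfig()
    max_attempts = max_attempts or max(4 * n_loci, 20)
    root = np.random.SeedSequence(seed)
    out = StudyResult(label=label)
    ld_spec = None if rho is None else {"rho": rho}
    for attempt in range(max_attempts):
        if len(out.estimates) >= n_loci:
            break
        out.attempts += 1
        s_panel_e, s_panel_g, s_study, s_cfg = root.spawn(4)
        panel_e = simulate_genotypes(
            n_eqtl, n_snp, ld_spec=ld_spec,
            seed=int(s_panel_e.generate_state(1)[0] % (2 ** 31 - 1)))
        panel_g = simulate_genotypes(
            n_gwas, n_snp, ld_spec=ld_spec, dtype=np.float32,
            seed=int(s_panel_g.generate_state(1)[0] % (2 ** 31 - 1)))
        ss_a, ss_b, truth = simulate_study(
            panel_e, panel_g, h2g=h2g, h2med=h2med, causal_frac=causal_frac,
            mode=mode, seed=int(s_study.generate_state(1)[0] % (2 ** 31 - 1)))
        ld = panel_e.ld_matrix()
        del panel_g
        loc_cfg = RunConfig(**{**cfg.__dict__,
                               "seed": int(s_cfg.generate_state(1)[0] % (2 ** 31 - 1))})
        res = analyze_locus(ss_a, ss_b, ld, config=loc_cfg)
        if "no_signal" in res.flags:
            out.no_signal += 1
            continue
        if not res.qualifying:
            out.insufficient += 1
            continue
        fit = res.slope_fit
        out.estimates.append(fit.alpha_mean)
        out.intervals.append(fit.alpha_interval)
        out.truths.append(truth.alpha)
        ids = ss_a.table["id"].tolist()
        out.accuracy_hits.extend(_locus_candidate_hits(res, truth, ids, ld))
        if verbose:
            print(f"[{label}] locus {len(out.estimates)}/{n_loci}: "
                  f"alpha_hat={fit.alpha_mean:+.3f} "
                  f"CI=({fit.alpha_interval[0]:+.3f}, {fit.alpha_interval[1]:+.3f}) "
                  f"truth={truth.alpha:+.3f} J={len(res.fits)}")
    return out


def false_positive_curve(r2_values, J_values, n_iter: int, seed: int = 0,
                         level: float = 0.80, **slope_kwargs
                         ) -> dict[tuple[float, int], float]:
    """Rate of credible intervals for the slope excluding 0, per (r^2, J).

    Instruments are drawn from the correlated-coefficients generator (true
    slope 0); the same seed is reused across r^2 values so differences in
    rate are driven by the correlation, not by Monte-Carlo noise.
    """
    from .simulate import simulate_correlated_instruments

    rates: dict[tuple[float, int], float] = {}
    for J in J_values:
        for r2 in r2_values:
            sets = simulate_correlated_instruments(J, r2, n_iter, seed=seed + J)
            excl = 0
            for k, ins in enumerate(sets):
                fit = fit_slope(ins, level=level, seed=seed + 1000 * J + k,
                                **slope_kwargs)
                lo, hi = fit.alpha_interval
                excl += not (lo <= 0.0 <= hi)
            rates[(r2, J)] = excl / n_iter
    return rates
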