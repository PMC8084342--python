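"""End-to-end locus analysis: harmonize -> colocalize -> trim -> slope.

`analyze_locus` runs the full two-step procedure on one locus given the two
summary-statistic tables and LD, mirroring the recommended workflow:

1. match studies on SNP id with allele reconciliation, MAF filter;
2. greedy LD clumping on exposure p-values into signal clusters;
3. first trimming round keyed on clump index SNPs (pairwise r^2 < 0.05);
4. per cluster: allele flipping to the positive-exposure index orientation,
   collapsing of highly correlated SNPs, horseshoe colocalization and
   candidate selection;
5. second trimming round keyed on the candidate causal SNPs;
6. hierarchical slope fitting across the surviving clusters (requires at
   least two: allelic heterogeneity).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import harmonize as hz
from .coloc import ColocFit, HorseshoeColoc, InstrumentSet, build_instruments
from .io import AlleleRef, JoinedLocus, LDMatrix, SumStats, match_studies
from .slope import SlopeFit, SlopeModel, check_heterogeneity


@dataclass
class RunConfig:
    """Thresholds, sampler settings and mode flags for a pipeline run."""

    maf: float = hz.DEFAULT_MAF
    clump_p1: float = hz.DEFAULT_CLUMP_P1
    clump_p2: float = hz.DEFAULT_CLUMP_P2
    clump_r2: float = hz.DEFAULT_CLUMP_R2
    clump_kb: int = hz.DEFAULT_CLUMP_KB
    collapse_r: float = hz.DEFAULT_COLLAPSE_R
    trim_r2: float = hz.DEFAULT_TRIM_R2
    level: float = 0.80
    shared_ld: bool = True
    raw_instruments: bool = False
    force_fit: bool = False
    seed: int = 0
    coloc_chains: int = 4
    coloc_warmup: int = 1000
    coloc_samples: int = 1000
    slope_walkers: int = 24
    slope_warmup: int = 400
    slope_steps: int = 600

    def __post_init__(self) -> None:
        if not (0 <= self.maf < 0.5 and 0 < self.clump_p1 <= 1
                and 0 < self.clump_p2 <= 1 and 0 <= self.clump_r2 <= 1
                and self.clump_kb > 0 and 0 < self.collapse_r <= 1
                and 0 < self.trim_r2 <= 1 and 0 < self.level < 1):
            raise ValueError("RunConfig threshold out of range")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class LocusResult:
    """Everything produced by one locus analysis, plus stage-by-stage counts."""

    config: RunConfig
    locus: JoinedLocus | None = None
    clusters: list[hz.SignalCluster] = field(default_factory=list)
    fits: list[ColocFit] = field(default_factory=list)
    instruments: InstrumentSet | None = None
    slope_fit: SlopeFit | None = None
    counts: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def qualifying(self) -> bool:
        """Locus shows allelic heterogeneity and a slope fit was produced."""
        return self.slope_fit is not None


def analyze_locus(ss_a: SumStats, ss_b: SumStats, ld: LDMatrix,
                  ld_b: LDMatrix | None = None, ref: AlleleRef | None = None,
                  config: RunConfig | None = None) -> LocusResult:
    """Run the full two-step analysis on one locus; see module docstring."""
    cfg = config or RunConfig()
    res = LocusResult(config=cfg)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)

    locus = match_studies(ss_a, ss_b, ref=ref, ld_a=ld, ld_b=ld_b,
                          shared_ld=cfg.shared_ld)
    locus = hz.filter_maf(locus, cfg.maf)
    res.locus = locus
    res.counts["snps_after_maf"] = len(locus)
    if len(locus) == 0:
        res.flags.append("empty_after_maf")
        return res
    try:
        clusters = hz.clump(locus, p1=cfg.clump_p1, p2=cfg.clump_p2,
                            r2=cfg.clump_r2, kb=cfg.clump_kb)
    except hz.NoSignalError:
        res.flags.append("no_signal")
        res.counts["clumps"] = 0
        return res
    res.counts["clumps"] = len(clusters)

    clusters = hz.trim_clusters(clusters, locus.ld_a, r2_max=cfg.trim_r2)
    res.counts["clusters_after_trim1"] = len(clusters)

    fits: list[ColocFit] = []
    kept: list[hz.SignalCluster] = []
    coloc_seeds = seeds[0].spawn(len(clusters))
    for cluster, sseq in zip(clusters, coloc_seeds):
        cluster = hz.flip_to_index(cluster)
        cluster = hz.collapse_correlated(cluster, r_threshold=cfg.collapse_r)
        model = HorseshoeColoc(
            n_chains=cfg.coloc_chains, n_warmup=cfg.coloc_warmup,
            n_samples=cfg.coloc_samples, keep_draws=False,
            random_state=int(sseq.generate_state(1)[0] % (2 ** 31 - 1)))
        ld_b_sub = None if cfg.shared_ld else locus.ld_b
        model.fit(cluster, ld_b=ld_b_sub)
        fit = model.fit_
        cluster.key_id = fit.candidate_id
        fits.append(fit)
        kept.append(cluster)

    kept2 = hz.trim_clusters(kept, locus.ld_a, r2_max=cfg.trim_r2)
    keep_idx = [kept.index(c) for c in kept2]
    res.clusters = kept2
    res.fits = [fits[i] for i in keep_idx]
    res.counts["clusters_after_trim2"] = len(kept2)
    if not res.fits:
        res.flags.append("no_clusters")
        return res

    mode = "raw" if cfg.raw_instruments else "posterior"
    instruments = build_instruments(res.fits, mode=mode)
    res.instruments = instruments
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ok = check_heterogeneity(instruments)
    if not ok and not cfg.force_fit:
        res.flags.append("insufficient_heterogeneity")
        return res
    slope_seed = int(seeds[1].generate_state(1)[0] % (2 ** 31 - 1))
    model = SlopeModel(level=cfg.level, n_walkers=cfg.slope_walkers,
                       n_warmup=cfg.slope_warmup, n_steps=cfg.slope_steps,
                       force=cfg.force_fit, random_state=slope_seed)
    model.fit(instruments)
    res.slope_fit = model.fit_
    return res
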