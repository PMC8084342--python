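"""Shared fixtures and factories for the test suite.

All synthetic inputs are generated programmatically and seeded; nothing is
read from disk except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrslope import LDMatrix, SumStats
from mrslope.harmonize import SignalCluster


def canonical_df(ids, betas, ses=None, pvals=None, mafs=None, pos=None,
                 a1="A", a2="G", chrom="1") -> pd.DataFrame:
    n = len(ids)
    return pd.DataFrame({
        "id": list(ids),
        "chrom": chrom,
        "pos": list(pos) if pos is not None else (np.arange(n) + 1) * 1000,
        "a1": [a1] * n if isinstance(a1, str) else list(a1),
        "a2": [a2] * n if isinstance(a2, str) else list(a2),
        "beta": list(betas),
        "se": list(ses) if ses is not None else [0.05] * n,
        "pvalue": list(pvals) if pvals is not None else [0.5] * n,
        "maf": list(mafs) if mafs is not None else [0.3] * n,
    })


def ar_ld(n: int, rho: float = 0.8) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(np.subtract.outer(idx, idx))


def make_cluster(n: int, seed: int, causal: int = 0, se: float = 0.05,
                 beta_causal: float = 0.5, slope: float = 0.3,
                 rho: float = 0.8, b_signal: bool = True) -> SignalCluster:
    """Cluster whose study-A signal propagates from one causal SNP through LD.

    Study B carries ``slope`` times the A signal (or pure noise when
    ``b_signal`` is False), with correlated noise at the stated SEs.
    """
    rng = np.random.default_rng(seed)
    r = ar_ld(n, rho)
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(n))
    beta_true = np.zeros(n)
    beta_true[causal] = beta_causal
    se_vec = np.full(n, se)
    bhat_a = r @ beta_true + se * (chol @ rng.standard_normal(n))
    if b_signal:
        bhat_b = r @ (slope * beta_true) + se * (chol @ rng.standard_normal(n))
    else:
        bhat_b = se * (chol @ rng.standard_normal(n))
    ids = [f"s{i}" for i in range(n)]
    z = np.abs(bhat_a) / se
    pvals = np.clip(np.exp(-0.5 * z ** 2), 1e-300, 1.0)
    a = canonical_df(ids, bhat_a, ses=se_vec, pvals=pvals)
    b = canonical_df(ids, bhat_b, ses=se_vec, pvals=[0.5] * n)
    index = ids[int(np.argmax(np.abs(bhat_a)))]
    return SignalCluster(index_id=index, a=a, b=b, ld=LDMatrix(ids, r))


@pytest.fixture
def toy_sumstats() -> SumStats:
    df = canonical_df([f"rs{i}" for i in range(5)],
                      betas=[0.1, -0.2, 0.3, 0.05, -0.15],
                      pvals=[1e-4, 2e-3, 0.5, 0.9, 3e-5])
    return SumStats("A", df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
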