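"""Benchmark metrics and the inverse-variance-weighted comparator.

Metrics follow the conventions of simulation benchmarking for MR methods:
relative mean absolute error (error divided by |true slope|), bias, observed
interval coverage, false-positive rate for a zero slope, and candidate-SNP
accuracy (chosen instrument equal to, or in high LD with, the causal eSNP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coloc import InstrumentSet
from .io import LDMatrix


def ivw_fixed_effects(instruments: InstrumentSet) -> tuple[float, float]:
    """Fixed-effects inverse-variance-weighted slope through the origin.

    slope = sum_j w_j bA_j bB_j / sum_j w_j bA_j^2 with w_j = 1/seB_j^2 and
    se = (sum_j w_j bA_j^2)^(-1/2): the classical fixed-effects MR estimator,
    equivalent to no-intercept weighted least squares of B on A.
    """
    ba, bb, sb = instruments.beta_a, instruments.beta_b, instruments.se_b
    if np.all(ba == 0):
        raise ValueError("all exposure coefficients are zero; slope undefined")
    w = 1.0 / sb ** 2
    denom = float(np.sum(w * ba ** 2))
    slope = float(np.sum(w * ba * bb)) / denom
    return slope, denom ** -0.5


def rmae(estimates: np.ndarray, truth: float) -> tuple[float, bool]:
    """Relative mean absolute error: mean |estimate - truth| / |truth|.

    When the truth is 0 the plain mean absolute error is returned instead,
    flagged by the second element (True = MAE pathway engaged).
    """
    estimates = np.asarray(estimates, dtype=float)
    mae = float(np.mean(np.abs(estimates - truth)))
    if truth == 0:
        warnings.warn("true slope is 0; reporting plain MAE instead of RMAE")
        return mae, True
    return mae / abs(truth), False


def bias(estimates: np.ndarray, truth: float) -> float:
    """Sample mean of the estimates minus the true value."""
    return float(np.mean(np.asarray(estimates, dtype=float))) - truth


def coverage(intervals: Sequence[tuple[float, float]], truth: float) -> float:
    """Fraction of intervals [lo, hi] containing the truth."""
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    return float(np.mean((arr[:, 0] <= truth) & (truth <= arr[:, 1])))


def fp_rate(intervals: Sequence[tuple[float, float]], null_value: float = 0.0) -> float:
    """Fraction of intervals excluding the null value (1 - coverage of it)."""
    return 1.0 - coverage(intervals, null_value)


def candidate_accuracy(chosen: Sequence[str], causal: Sequence[str],
                       ld: LDMatrix, r_threshold: float = 0.95) -> float:
    """Fraction of clusters whose chosen SNP is the causal eSNP or in high LD with it.

    ``chosen`` and ``causal`` are paired per cluster (clusters without a true
    causal eSNP should be excluded by the caller).
    """
    if len(chosen) != len(causal):
        raise ValueError("chosen and causal lists must be paired")
    if len(chosen) == 0:
        raise ValueError("no clusters to evaluate")
    hits = 0
    for c, t in zip(chosen, causal):
        if c == t or abs(ld.r[ld.index_of(c), ld.index_of(t)]) > r_threshold:
            hits += 1
    return hits / len(chosen)


@dataclass
class EvalReport:
    """Aggregated benchmark results for one method in one simulation setting."""

    label: str
    estimates: np.ndarray
    intervals: np.ndarray  # (n, 2)
    truths: np.ndarray
    rmae: float = field(init=False)
    mae_flag: bool = field(init=False)
    bias: float = field(init=False)
    coverage: float = field(init=False)
    fp_rate: float = field(init=False)
    candidate_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.truths = np.asarray(self.truths, dtype=float)
        if not (len(self.estimates) == len(self.intervals) == len(self.truths)):
            raise ValueError("estimates, intervals, truths must be length-matched")
        truth = float(self.truths[0]) if len(np.unique(self.truths)) == 1 else None
        if truth is not None:
            self.rmae, self.mae_flag = rmae(self.estimates, truth)
            self.bias = bias(self.estimates, truth)
        else:
            rel = np.abs(self.estimates - self.truths) / np.abs(self.truths)
            self.rmae, self.mae_flag = float(np.mean(rel)), False
            self.bias = float(np.mean(self.estimates - self.truths))
        self.coverage = float(np.mean((self.intervals[:, 0] <= self.truths)
                                      & (self.truths <= self.intervals[:, 1])))
        self.fp_rate = 1.0 - float(np.mean((self.intervals[:, 0] <= 0)
                                           & (0 <= self.intervals[:, 1])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": [self.label],
            "n": [len(self.estimates)],
            "rmae": [self.rmae],
            "mae_flag": [self.mae_flag],
            "bias": [self.bias],
            "coverage": [self.coverage],
            "fp_rate": [self.fp_rate],
            "candidate_accuracy": [self.candidate_accuracy],
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
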