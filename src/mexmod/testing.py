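"""Significance testing and scoring of candidate gene-set patterns.

The mutual-exclusivity (ME) test compares the fitted ME model against the
fitted independence null with Vuong's closeness test for non-nested
models: the per-patient log-likelihood ratios are standardized and
corrected for the difference in free-parameter counts; under equal
Kullback-Leibler closeness of both models to the truth the statistic is
asymptotically standard normal, and small upper-tail p-values indicate
the ME model is closer to the generating distribution.

Also provided: the coverage-minus-overlap weight of earlier studies, its
column-permutation test, the imbalance diagnostic, and Benjamini-Hochberg
adjustment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .estimation import (
    EMOptions,
    FitResult,
    IndependenceParameters,
    em_fit,
    fit_independence,
)
from .matrix import AlterationMatrix
from .model import MEParameters, Variant, observation_log_likelihoods

__all__ = [
    "METestResult",
    "PatternEvaluation",
    "me_statistic",
    "me_test",
    "dendrix_weight",
    "permutation_test",
    "imbalance",
    "bh_adjust",
]


@dataclass(frozen=True)
class METestResult:
    statistic: float
    p_value: float
    loglik_me: float
    loglik_ind: float
    df_me: int
    df_ind: int
    degenerate: bool = False
    adjusted_p: float | None = None


@dataclass(frozen=True)
class PatternEvaluation:
    """Per-gene-set summary row: model fit, ME test, weight-based
    comparators and the imbalance diagnostic."""

    gene_set: tuple[str, ...]
    me_fit: FitResult
    test: METestResult
    weight: int
    permutation_p: float | None
    imbalance: float | None
    coverage_count: int

    TABLE_COLUMNS = (
        "genes",
        "coverage",
        "impurity",
        "fp_rate",
        "fn_rate",
        "me_statistic",
        "me_p",
        "me_p_adjusted",
        "weight",
        "permutation_p",
        "imbalance",
    )

    def to_row(self) -> dict:
        p: MEParameters = self.me_fit.params
        return {
            "genes": ",".join(self.gene_set),
            "coverage": p.coverage,
            "impurity": p.impurity,
            "fp_rate": p.fp_rate,
            "fn_rate": p.fn_rate,
            "me_statistic": self.test.statistic,
            "me_p": self.test.p_value,
            "me_p_adjusted": self.test.adjusted_p,
            "weight": self.weight,
            "permutation_p": self.permutation_p,
            "imbalance": self.imbalance,
        }


def _per_row_log_likelihood_ratios(
    matrix: AlterationMatrix,
    me_params: MEParameters,
    ind_params: IndependenceParameters,
) -> np.ndarray:
    """r_i = log P_ME(row_i) - log P_IND(row_i) at the fitted parameters."""
    values = matrix.values.astype(float)
    m = matrix.values.sum(axis=1)
    log_f = observation_log_likelihoods(me_params, matrix.k)
    r_me = log_f[m]
    p = np.asarray(ind_params.frequencies, dtype=float)
    with np.errstate(divide="ignore"):
        lp = np.log(p)
        lq = np.log(1 - p)
    lp = np.where(p > 0, lp, 0.0)  # 0*log 0 := 0 (only hit when o=0/o=1 resp.)
    lq = np.where(p < 1, lq, 0.0)
    # columns at the MLE never give -inf on observed data; the guard is for
    # user-supplied parameters
    with np.errstate(invalid="ignore"):
        r_ind = values @ lp + (1 - values) @ lq
    bad_one = (values == 1) & (p == 0.0)
    bad_zero = (values == 0) & (p == 1.0)
    r_ind = np.where((bad_one | bad_zero).any(axis=1), -np.inf, r_ind)
    return r_me - r_ind


def vuong_correction(df_me: int, df_ind: int, n: int) -> float:
    """BIC-type free-parameter correction ((df_me - df_ind)/2) * log n."""
    return 0.5 * (df_me - df_ind) * math.log(n)


def me_statistic(
    matrix: AlterationMatrix,
    me_fit: FitResult,
    ind_fit: FitResult,
    correction: str = "bic",
) -> tuple[float, bool]:
    """Vuong statistic for ME vs independence on the given matrix.

    statistic = (sum_i r_i - C) / (sqrt(n) * s) with r_i the per-row
    log-likelihood ratios, s their sample standard deviation (n-1
    denominator) and C the free-parameter correction (``bic``:
    ((df_me - df_ind)/2)*log n; ``none``: 0). Returns (statistic,
    degenerate) where degenerate flags s = 0 or infinite ratios.
    """
    me_params: MEParameters = me_fit.params
    ind_params: IndependenceParameters = ind_fit.params
    n = matrix.n
    r = _per_row_log_likelihood_ratios(matrix, me_params, ind_params)
    if np.isneginf(r).any():  # ME model assigns zero probability to a row
        return float("-inf"), True
    if np.isposinf(r).any():  # independence model assigns zero probability
        return float("inf"), True
    if correction == "bic":
        c = vuong_correction(me_params.variant.df, ind_params.df, n)
    elif correction == "none":
        c = 0.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    s = float(r.std(ddof=1)) if n > 1 else 0.0
    if s == 0.0:
        return 0.0, True
    return float((r.sum() - c) / (math.sqrt(n) * s)), False


def me_test(
    matrix: AlterationMatrix,
    variant: Variant | str = Variant.NO_ERRORS,
    options: EMOptions | None = None,
    fixed: dict | MEParameters | None = None,
    seed: int = 0,
    correction: str = "bic",
) -> METestResult:
    """Run the full ME test: fit both models, compute the Vuong statistic
    and the one-sided upper-tail p-value p = 1 - Phi(statistic).

    A degenerate statistic (zero variance of the per-row ratios, or an
    infinite ratio under the ME model) conservatively reports p = 1
    unless the independence model is the one that fails.
    """
    if matrix.k < 2:
        raise ValueError("the ME test requires at least 2 genes")
    variant = Variant(variant)
    me = em_fit(matrix, variant=variant, options=options, fixed=fixed, seed=seed)
    ind = fit_independence(matrix)
    stat, degenerate = me_statistic(matrix, me, ind, correction=correction)
    if degenerate:
        p = 0.0 if stat == float("inf") else 1.0
    else:
        p = float(norm.sf(stat))
    return METestResult(
        statistic=stat,
        p_value=p,
        loglik_me=me.log_likelihood,
        loglik_ind=ind.log_likelihood,
        df_me=variant.df,
        df_ind=matrix.k,
        degenerate=degenerate,
    )


def dendrix_weight(matrix: AlterationMatrix) -> int:
    """Coverage-minus-overlap weight of a gene set:
    2 * (samples with >= 1 alteration) - (total alteration count)."""
    covered = int((matrix.values.sum(axis=1) >= 1).sum())
    return 2 * covered - int(matrix.values.sum())


def _permuted_covered_counts(
    column_sums: np.ndarray, n: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Number of covered rows for each of B independent column permutations.

    Permuting a binary column uniformly is equivalent to re-placing its
    1s on a uniform random subset of rows, so only the positions of the
    1s are drawn. The total alteration count is permutation-invariant,
    hence the weight varies only through the covered-row count.
    """
    covered = np.zeros((n_permutations, n), dtype=bool)
    for c in column_sums:
        c = int(c)
        if c == 0:
            continue
        if c == n:
            covered[:] = True
            break
        u = rng.random((n_permutations, n))
        idx = np.argpartition(u, c - 1, axis=1)[:, :c]
        np.put_along_axis(covered, idx, True, axis=1)
    return covered.sum(axis=1)


def permutation_test(
    matrix: AlterationMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    strict: bool = False,
) -> float:
    """Column-permutation test of the weight: each permutation shuffles
    every column independently, preserving per-gene frequencies.

    By default the p-value is (1 + #{permuted weight >= observed}) /
    (1 + B), which cannot be zero; ``strict=True`` counts only strictly
    larger permuted weights with no pseudocount, the convention under
    which perfectly isolated patterns report p = 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    col_sums = matrix.values.sum(axis=0)
    total = int(col_sums.sum())
    observed = 2 * int((matrix.values.sum(axis=1) >= 1).sum()) - total
    perm_weights = (
        2 * _permuted_covered_counts(col_sums, matrix.n, n_permutations, rng) - total
    )
    if strict:
        return float((perm_weights > observed).sum() / n_permutations)
    return float((1 + (perm_weights >= observed).sum()) / (1 + n_permutations))


def imbalance(matrix: AlterationMatrix) -> float:
    """Fraction of a pattern's coverage contributed by its most frequently
    altered gene; 1 means a single gene dominates the pattern."""
    covered = int((matrix.values.sum(axis=1) >= 1).sum())
    if covered == 0:
        raise ValueError("imbalance undefined: no covered rows")
    return float(matrix.values.sum(axis=0).max() / covered)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
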