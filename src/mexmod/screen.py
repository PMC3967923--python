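"""Exhaustive gene-subset screening with coverage/impurity pre-filters.

Mirrors the two-stage workflow used for real alteration matrices: merge
duplicate columns into meta-genes, optionally keep the most frequently
altered genes, enumerate every gene subset of a fixed size, pre-filter
with the cheap error-free model (estimated coverage above a threshold,
impurity below a threshold, ME statistic positive), then fit the final
model variant on the survivors, test, and Benjamini-Hochberg adjust over
exactly the stage-2 family.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .estimation import EMOptions, em_fit, fit_independence, fit_reduced
from .matrix import AlterationMatrix
from .model import Variant
from .testing import (
    METestResult,
    PatternEvaluation,
    bh_adjust,
    dendrix_weight,
    imbalance,
    me_statistic,
    me_test,
    permutation_test,
)

__all__ = [
    "ScreenConfig",
    "MetaColumnMap",
    "ScreenReport",
    "merge_duplicate_columns",
    "count_subsets",
    "screen_subsets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and model choices for ``screen_subsets``.

    Defaults follow the published workflow: keep subsets with estimated
    coverage > 0.3, impurity < 0.2 and a positive ME statistic, then call
    patterns significant at BH-adjusted p < 0.05.
    """

    subset_size: int = 4
    min_coverage: float = 0.3
    max_impurity: float = 0.2
    require_positive_statistic: bool = True
    significance_level: float = 0.05
    prefilter_variant: Variant = Variant.NO_ERRORS
    final_variant: Variant = Variant.NO_ERRORS
    top_genes_by_frequency: int | None = None
    n_permutations: int = 1000
    em_options: EMOptions | None = None
    fixed_error_rates: dict | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "prefilter_variant", Variant(self.prefilter_variant))
        object.__setattr__(self, "final_variant", Variant(self.final_variant))
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2")
        if not 0 < self.significance_level < 1:
            raise ValueError("significance_level must be in (0, 1)")


@dataclass(frozen=True)
class MetaColumnMap:
    """Matrix with byte-identical columns collapsed, plus the mapping from
    each (meta-)column back to its member gene names."""

    matrix: AlterationMatrix
    members: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of a subset screen: significant patterns plus bookkeeping."""

    patterns: list[PatternEvaluation]
    n_stage1: int
    n_stage2: int
    genes_screened: tuple[str, ...]

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [p.to_row() for p in self.patterns], columns=PatternEvaluation.TABLE_COLUMNS
        )


def merge_duplicate_columns(matrix: AlterationMatrix) -> MetaColumnMap:
    """Collapse identical columns to single meta-gene columns.

    A meta-column is named by joining its sorted member names with '/';
    singleton columns keep their name. The first-seen column order is
    preserved.
    """
    groups: dict[bytes, list[int]] = {}
    for j in range(matrix.k):
        groups.setdefault(matrix.values[:, j].tobytes(), []).append(j)
    keep: list[int] = []
    names: list[str] = []
    members: dict[str, tuple[str, ...]] = {}
    for cols in groups.values():
        keep.append(cols[0])
        member_names = tuple(sorted(matrix.gene_names[j] for j in cols))
        name = member_names[0] if len(cols) == 1 else "/".join(member_names)
        names.append(name)
        members[name] = member_names
    order = np.argsort(keep)
    keep_arr = [keep[i] for i in order]
    names = [names[i] for i in order]
    merged = AlterationMatrix(
        matrix.values[:, keep_arr], tuple(names), matrix.patient_ids
    )
    return MetaColumnMap(matrix=merged, members=members)


def count_subsets(n_genes: int, size: int) -> int:
    """Exact number of gene subsets, C(n_genes, size), in integer arithmetic."""
    if n_genes < 0 or size < 0:
        raise ValueError("n_genes and size must be non-negative")
    if size > n_genes:
        return 0
    return math.comb(n_genes, size)


def _top_frequency_genes(matrix: AlterationMatrix, top: int) -> list[str]:
    """Top genes by alteration frequency; ties at the cutoff broken
    lexicographically by gene name."""
    freq = matrix.values.sum(axis=0)
    order = sorted(zip(-freq, matrix.gene_names))
    return [name for _, name in order[:top]]


def _stage1_no_errors_batch(
    matrix: AlterationMatrix,
    subsets: np.ndarray,
    config: ScreenConfig,
    return_statistics: bool = False,
):
    """Vectorized error-free pre-filter over a chunk of subsets.

    Computes, per subset: closed-form coverage/impurity MLEs from the
    count profile, and the BIC-corrected Vuong statistic against the
    independence fit; returns a boolean keep-mask (and, on request, the
    per-subset statistics). Matches the scalar path (``fit_reduced`` +
    ``me_statistic``) to floating-point accuracy.
    """
    X = matrix.values.astype(np.float64)
    n = matrix.n
    s = subsets.shape[1]
    slab = X[:, subsets]  # (n, n_subsets, s)
    row_m = slab.sum(axis=2)  # (n, n_subsets) counts in 0..s
    n_cov = (row_m >= 1).sum(axis=0).astype(float)
    total = row_m.sum(axis=0)
    coverage = n_cov / n
    with np.errstate(invalid="ignore", divide="ignore"):
        impurity = np.where(n_cov > 0, (total - n_cov) / ((s - 1) * n_cov), 0.0)

    keep = (coverage > config.min_coverage) & (impurity < config.max_impurity)
    if not config.require_positive_statistic and not return_statistics:
        return keep

    # per-observation ME log-likelihood of a specific row with m ones:
    # m = 0: log(1 - gamma); m >= 1: log(gamma) + log(m/s)
    #                              + (m-1) log(delta) + (s-m) log(1-delta)
    m = np.arange(s + 1, dtype=float)
    gamma = coverage[None, :]
    delta = np.clip(impurity, 0.0, 1.0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_f = np.where(
            m[:, None] == 0,
            np.log(1 - gamma),
            np.log(gamma)
            + np.log(np.maximum(m[:, None], 1.0) / s)
            + (m[:, None] - 1) * np.log(delta)
            + (s - m[:, None]) * np.log(1 - delta),
        )
    log_f = np.where(np.isnan(log_f), -np.inf, log_f)  # 0*log 0 cases
    # (m-1)*log(delta) with m=1, delta=0 must be 0, not nan
    first = (m[:, None] == 1) & np.broadcast_to(delta == 0, (s + 1, len(coverage)))
    with np.errstate(divide="ignore"):
        log_f = np.where(
            first, np.log(gamma) + np.log(1.0 / s) + (s - 1) * np.log(1 - delta), log_f
        )
    r_me = np.take_along_axis(log_f, row_m.astype(int), axis=0)  # (n, n_subsets)

    p = slab.mean(axis=0)  # (n_subsets, s)
    with np.errstate(divide="ignore"):
        lp = np.where(p > 0, np.log(p), 0.0)
        lq = np.where(p < 1, np.log(1 - p), 0.0)
    r_ind = np.einsum("ncs,cs->nc", slab, lp - lq) + lq.sum(axis=1)[None, :]

    r = r_me - r_ind
    finite = np.isfinite(r).all(axis=0)
    c = 0.5 * (2 - s) * math.log(n)
    sd = r.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (r.sum(axis=0) - c) / (math.sqrt(n) * sd)
    positive = finite & (sd > 0) & (stat > 0)
    mask = keep & positive if config.require_positive_statistic else keep
    if return_statistics:
        return mask, stat
    return mask


def _stage1_mask(
    matrix: AlterationMatrix,
    subsets: list[tuple[int, ...]],
    config: ScreenConfig,
    seed: int,
) -> np.ndarray:
    if config.prefilter_variant is Variant.NO_ERRORS:
        idx = np.asarray(subsets, dtype=np.int64)
        chunk = max(1, int(4e6 / (matrix.n * config.subset_size)))
        masks = [
            _stage1_no_errors_batch(matrix, idx[i : i + chunk], config)
            for i in range(0, idx.shape[0], chunk)
        ]
        return np.concatenate(masks)
    mask = np.zeros(len(subsets), dtype=bool)
    for i, cols in enumerate(subsets):
        sub = matrix.subset(list(cols))
        fit = em_fit(
            sub,
            variant=config.prefilter_variant,
            options=config.em_options,
            fixed=config.fixed_error_rates,
            seed=seed + i,
        )
        if fit.params.coverage <= config.min_coverage:
            continue
        if fit.params.impurity >= config.max_impurity:
            continue
        if config.require_positive_statistic:
            stat, degenerate = me_statistic(sub, fit, fit_independence(sub))
            if degenerate or stat <= 0:
                continue
        mask[i] = True
    return mask


def screen_subsets(
    matrix: AlterationMatrix, config: ScreenConfig, seed: int = 0
) -> ScreenReport:
    """Two-stage exhaustive screen of all gene subsets of a fixed size.

    Stage 1 evaluates every subset with the (cheap) pre-filter variant and
    keeps those passing the coverage/impurity/statistic thresholds. Stage 2
    fits the final variant on the survivors, runs the ME test, adjusts
    p-values over exactly the stage-2 family, and returns the patterns
    that pass the thresholds on the final estimates and the significance
    level, sorted by impurity (ascending) then coverage (descending).
    """
    if config.subset_size > matrix.k:
        raise ValueError("subset_size exceeds the number of genes")
    work = matrix
    if config.top_genes_by_frequency is not None:
        work = matrix.subset(
            _top_frequency_genes(matrix, config.top_genes_by_frequency)
        )
    subsets = list(itertools.combinations(range(work.k), config.subset_size))
    n_stage1 = len(subsets)
    logger.info("stage 1: evaluating %d subsets of size %d", n_stage1, config.subset_size)
    mask = _stage1_mask(work, subsets, config, seed)
    survivors = [subsets[i] for i in np.flatnonzero(mask)]
    logger.info("stage 2: %d subsets passed the pre-filter", len(survivors))

    evaluations: list[tuple[tuple[int, ...], PatternEvaluation]] = []
    p_values: list[float] = []
    for i, cols in enumerate(survivors):
        sub = work.subset(list(cols))
        fit = em_fit(
            sub,
            variant=config.final_variant,
            options=config.em_options,
            fixed=config.fixed_error_rates,
            seed=seed + i,
        )
        ind = fit_independence(sub)
        stat, degenerate = me_statistic(sub, fit, ind)
        from scipy.stats import norm

        p = 1.0 if degenerate else float(norm.sf(stat))
        test = METestResult(
            statistic=stat,
            p_value=p,
            loglik_me=fit.log_likelihood,
            loglik_ind=ind.log_likelihood,
            df_me=config.final_variant.df,
            df_ind=sub.k,
            degenerate=degenerate,
        )
        covered = int((sub.values.sum(axis=1) >= 1).sum())
        evaluations.append(
            (
                cols,
                PatternEvaluation(
                    gene_set=sub.gene_names,
                    me_fit=fit,
                    test=test,
                    weight=dendrix_weight(sub),
                    permutation_p=None,
                    imbalance=imbalance(sub) if covered else None,
                    coverage_count=covered,
                ),
            )
        )
        p_values.append(p)

    results: list[PatternEvaluation] = []
    if evaluations:
        adjusted = bh_adjust(p_values)
        for (cols, ev), adj in zip(evaluations, adjusted):
            params = ev.me_fit.params
            if adj >= config.significance_level:
                continue
            if params.coverage <= config.min_coverage:
                continue
            if params.impurity >= config.max_impurity:
                continue
            sub = work.subset(list(cols))
            perm_p = permutation_test(
                sub, n_permutations=config.n_permutations, seed=seed + hash(cols) % 2**16
            )
            test = METestResult(
                statistic=ev.test.statistic,
                p_value=ev.test.p_value,
                loglik_me=ev.test.loglik_me,
                loglik_ind=ev.test.loglik_ind,
                df_me=ev.test.df_me,
                df_ind=ev.test.df_ind,
                degenerate=ev.test.degenerate,
                adjusted_p=float(adj),
            )
            results.append(
                PatternEvaluation(
                    gene_set=ev.gene_set,
                    me_fit=ev.me_fit,
                    test=test,
                    weight=ev.weight,
                    permutation_p=perm_p,
                    imbalance=ev.imbalance,
                    coverage_count=ev.coverage_count,
                )
            )
    results.sort(
        key=lambda ev: (ev.me_fit.params.impurity, -ev.me_fit.params.coverage)
    )
    return ScreenReport(
        patterns=results,
        n_stage1=n_stage1,
        n_stage2=len(survivors),
        genes_screened=work.gene_names,
    )
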