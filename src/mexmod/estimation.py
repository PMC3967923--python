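"""Parameter estimation for the mutual-exclusivity and independence models.

Three routes are provided:

* ``fit_reduced`` — closed-form maximum-likelihood estimates of coverage
  and impurity when the data are assumed error-free;
* ``fit_independence`` — per-gene marginal frequencies of the null model;
* ``em_fit`` — expectation-maximization for the error-aware variants.
  Observations are grouped by their alteration count m, so the E-step
  computes only k+1 distinct posteriors and each iteration is O(k)
  regardless of the number of patients.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import AlterationMatrix, CountProfile, count_profile
from .model import (
    MEParameters,
    Variant,
    _branch_masses,
    _latent_enumeration,
    dataset_log_likelihood,
)

__all__ = [
    "IndependenceParameters",
    "EMOptions",
    "FitResult",
    "fit_reduced",
    "fit_independence",
    "em_fit",
    "e_step_expectations",
    "class_posterior_expectations",
    "brute_force_posterior",
]

_PROB_FLOOR = 1e-9
_RATE_CEIL = 0.5 - 1e-6


@dataclass(frozen=True)
class IndependenceParameters:
    """Per-gene alteration probabilities of the independence (null) model."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freq)
        if ((freq < 0) | (freq > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def df(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class EMOptions:
    """Initialization and stopping controls for ``em_fit``.

    The educated start seeds coverage/impurity with the reduced-model
    closed forms and the error rates at 1%; random starts draw coverage
    uniformly on (0.05, 0.95) and impurity/error rates on (0.001, 0.3).
    """

    n_random_starts: int = 10
    include_educated_start: bool = True
    max_iterations: int = 2000
    loglik_tolerance: float = 1e-6
    min_iterations: int = 1
    coverage_init_range: tuple[float, float] = (0.05, 0.95)
    rate_init_range: tuple[float, float] = (0.001, 0.3)
    educated_error_init: float = 0.01

    def __post_init__(self) -> None:
        if self.loglik_tolerance <= 0:
            raise ValueError("loglik_tolerance must be positive")
        if self.n_random_starts < 0:
            raise ValueError("n_random_starts must be >= 0")
        if self.n_random_starts == 0 and not self.include_educated_start:
            raise ValueError("at least one start is required")


@dataclass(frozen=True)
class FitResult:
    params: object  # MEParameters or IndependenceParameters
    log_likelihood: float
    n_iterations: int = 0
    converged: bool = True
    start_used: str = "closed_form"
    loglik_trace: tuple[float, ...] = field(default_factory=tuple)

    def to_record(self) -> dict:
        """Flat key/value record for text or JSON serialization."""
        rec: dict = {
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "start_used": self.start_used,
        }
        p = self.params
        if isinstance(p, MEParameters):
            rec.update(
                variant=p.variant.value,
                coverage=p.coverage,
                impurity=p.impurity,
                fp_rate=p.fp_rate,
                fn_rate=p.fn_rate,
            )
        else:
            rec.update(frequencies=list(np.asarray(p.frequencies)))
        return rec


def _as_profile(matrix_or_profile) -> CountProfile:
    if isinstance(matrix_or_profile, AlterationMatrix):
        return count_profile(matrix_or_profile)
    if isinstance(matrix_or_profile, CountProfile):
        return matrix_or_profile
    raise TypeError("expected an AlterationMatrix or CountProfile")


def reduced_mle(profile: CountProfile) -> tuple[float, float]:
    """Closed-form MLEs of (coverage, impurity) in the no-errors model.

    coverage = fraction of rows with >= 1 alteration; impurity =
    (total alterations - covered rows) / ((k - 1) * covered rows).
    Boundary conventions: no covered rows -> impurity 0; k = 1 or all
    covered rows fully altered -> impurity follows the same ratio, with
    impurity := 1 when every covered row carries all k alterations.
    """
    counts, n, k = profile.counts, profile.n, profile.k
    n_cov = int(n - counts[0])
    coverage = n_cov / n
    if n_cov == 0 or k == 1:
        return coverage, 0.0
    total_ones = int((np.arange(k + 1) * counts).sum())
    impurity = (total_ones - n_cov) / ((k - 1) * n_cov)
    return coverage, float(impurity)


def fit_reduced(matrix_or_profile) -> FitResult:
    """Maximum-likelihood fit of the error-free (reduced) ME model."""
    profile = _as_profile(matrix_or_profile)
    coverage, impurity = reduced_mle(profile)
    params = MEParameters(coverage, impurity, variant=Variant.NO_ERRORS)
    return FitResult(
        params=params,
        log_likelihood=dataset_log_likelihood(profile, params),
        start_used="closed_form",
    )


def fit_independence(matrix: AlterationMatrix) -> FitResult:
    """Maximum-likelihood fit of the independence model: per-gene
    frequencies are the column means; the log-likelihood uses the
    convention 0*log 0 = 0."""
    n_j = matrix.values.sum(axis=0).astype(float)
    n = matrix.n
    p = n_j / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_j * np.log(p) + (n - n_j) * np.log(1 - p)
    loglik = float(np.nansum(np.where(np.isfinite(terms), terms, 0.0)))
    return FitResult(
        params=IndependenceParameters(p),
        log_likelihood=loglik,
        start_used="closed_form",
    )


def class_posterior_expectations(
    params: MEParameters, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Posterior expectations of the complete-data sufficient statistics,
    for every count class m = 0..k at once.

    For one observation with m observed 1s, returns the expectations of:
    (a) the coverage indicator, (b) the number of impure true alterations
    among the k-1 non-exclusive genes, (c) the number of false positives,
    (d) the number of false negatives, (e) the number of true alterations
    (= a + b under this latent structure).

    Derivation: condition on the three generative branches (uncovered;
    covered with the exclusive gene observed; covered with the exclusive
    gene flipped). Within a covered branch each non-exclusive gene is
    independently truly altered with posterior probability
    r1 = impurity*(1-fn)/q given it is observed 1, and
    r0 = impurity*fn/(1-q) given it is observed 0, with q the marginal
    observed-alteration probability of a non-exclusive gene.
    """
    m = np.arange(k + 1, dtype=float)
    q = params.observed_impure_rate
    delta, eps, xi = params.impurity, params.fp_rate, params.fn_rate
    w0, wA, wB = _branch_masses(params, k)
    total = w0 + wA + wB

    r1 = delta * (1 - xi) / q if q > 0 else 0.0
    r0 = delta * xi / (1 - q) if q < 1 else 0.0

    # branch A: exclusive gene observed 1; m-1 observed 1s among the others
    bA = (m - 1) * r1 + (k - m) * r0
    fpA = (m - 1) * (1 - r1)
    fnA = (k - m) * r0
    # branch B: exclusive gene observed 0 (one false negative); m observed 1s
    bB = m * r1 + (k - 1 - m) * r0
    fpB = m * (1 - r1)
    fnB = 1 + (k - 1 - m) * r0

    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, (wA + wB) / total, 0.0)
        b = np.where(total > 0, (wA * bA + wB * bB) / total, 0.0)
        c = np.where(total > 0, (w0 * m + wA * fpA + wB * fpB) / total, 0.0)
        d = np.where(total > 0, (wA * fnA + wB * fnB) / total, 0.0)
    e = a + b
    return a, b, c, d, e


def e_step_expectations(
    m: int, k: int, params: MEParameters
) -> tuple[float, float, float, float, float]:
    """E-step expectations for a single observation with m observed 1s."""
    if not 0 <= m <= k:
        raise ValueError(f"m must be in 0..k, got m={m}, k={k}")
    a, b, c, d, e = class_posterior_expectations(params, k)
    return float(a[m]), float(b[m]), float(c[m]), float(d[m]), float(e[m])


def brute_force_posterior(
    observation: Sequence[int], params: MEParameters
) -> tuple[float, float, float, float, float]:
    """The same five expectations by enumerating all latent states weighted
    by their joint probability (oracle for the closed-form E-step; k <= 12)."""
    acc = np.zeros(5)
    total = 0.0
    for w, cov, n_imp, n_fp, n_fn, n_true in _latent_enumeration(observation, params):
        total += w
        acc += w * np.array([cov, n_imp, n_fp, n_fn, n_true], dtype=float)
    if total == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    return tuple(acc / total)  # type: ignore[return-value]


def _clamp(x: float, lo: float = _PROB_FLOOR, hi: float = 1 - _PROB_FLOOR) -> float:
    return float(min(max(x, lo), hi))


def _em_single_start(
    profile: CountProfile,
    start: MEParameters,
    variant: Variant,
    options: EMOptions,
) -> tuple[MEParameters, float, list[float], bool]:
    counts, n, k = profile.counts.astype(float), profile.n, profile.k
    params = start
    trace: list[float] = [dataset_log_likelihood(profile, params)]
    converged = False
    for _ in range(options.max_iterations):
        a, b, c, d, e = class_posterior_expectations(params, k)
        sum_a = float(counts @ a)
        sum_b = float(counts @ b)
        sum_c = float(counts @ c)
        sum_d = float(counts @ d)
        sum_e = float(counts @ e)

        coverage = _clamp(sum_a / n)
        impurity = _clamp(sum_b / ((k - 1) * sum_a)) if k > 1 and sum_a > 0 else _PROB_FLOOR
        fp_rate = params.fp_rate
        fn_rate = params.fn_rate
        if variant in (Variant.FP_ONLY, Variant.FULL):
            denom = k * n - sum_e
            fp_rate = _clamp(sum_c / denom, _PROB_FLOOR, _RATE_CEIL) if denom > 0 else _PROB_FLOOR
        if variant is Variant.FULL:
            fn_rate = _clamp(sum_d / sum_e, _PROB_FLOOR, _RATE_CEIL) if sum_e > 0 else _PROB_FLOOR
        params = MEParameters(
            coverage, impurity, fp_rate, fn_rate, variant=variant
        )
        trace.append(dataset_log_likelihood(profile, params))
        if len(trace) > options.min_iterations and abs(
            trace[-1] - trace[-2]
        ) < options.loglik_tolerance:
            converged = True
            break
    return params, trace[-1], trace, converged


def em_fit(
    matrix_or_profile,
    variant: Variant | str = Variant.FULL,
    options: EMOptions | None = None,
    fixed: MEParameters | dict | None = None,
    seed: int = 0,
) -> FitResult:
    """EM fit of an error-aware ME model variant, best of multiple starts.

    Parameters
    ----------
    variant
        ``known_errors`` (fit coverage/impurity at given error rates),
        ``fp_only`` (additionally fit the false-positive rate, fn = 0) or
        ``full`` (all four parameters).
    fixed
        For ``known_errors``: the known ``fp_rate`` / ``fn_rate`` values,
        as a dict or an ``MEParameters``.
    seed
        Seeds the random restarts; the educated start is deterministic.

    Returns the highest-log-likelihood fit across the educated start and
    ``options.n_random_starts`` random starts (ties broken by start order).
    """
    profile = _as_profile(matrix_or_profile)
    variant = Variant(variant)
    if variant is Variant.NO_ERRORS:
        return fit_reduced(profile)
    options = options or EMOptions()
    k = profile.k

    fixed_fp = fixed_fn = 0.0
    if variant is Variant.KNOWN_ERRORS:
        if fixed is None:
            raise ValueError("known_errors variant requires fixed error rates")
        if isinstance(fixed, MEParameters):
            fixed_fp, fixed_fn = fixed.fp_rate, fixed.fn_rate
        else:
            fixed_fp = float(fixed.get("fp_rate", 0.0))
            fixed_fn = float(fixed.get("fn_rate", 0.0))

    def make(coverage, impurity, fp, fn) -> MEParameters:
        if variant is Variant.KNOWN_ERRORS:
            fp, fn = fixed_fp, fixed_fn
        elif variant is Variant.FP_ONLY:
            fn = 0.0
        return MEParameters(
            _clamp(coverage), _clamp(impurity),
            _clamp(fp, 0.0, _RATE_CEIL), _clamp(fn, 0.0, _RATE_CEIL),
            variant=variant,
        )

    starts: list[tuple[str, MEParameters]] = []
    if options.include_educated_start:
        cov0, imp0 = reduced_mle(profile)
        err0 = options.educated_error_init
        starts.append(("educated", make(cov0, imp0, err0, err0)))
    rng = np.random.default_rng(seed)
    lo_c, hi_c = options.coverage_init_range
    lo_r, hi_r = options.rate_init_range
    for i in range(options.n_random_starts):
        starts.append(
            (
                f"random_{i}",
                make(
                    rng.uniform(lo_c, hi_c),
                    rng.uniform(lo_r, hi_r),
                    rng.uniform(lo_r, hi_r),
                    rng.uniform(lo_r, hi_r),
                ),
            )
        )

    best: FitResult | None = None
    for label, start in starts:
        params, loglik, trace, converged = _em_single_start(
            profile, start, variant, options
        )
        if not np.isfinite(loglik):
            continue
        if best is None or loglik > best.log_likelihood:
            best = FitResult(
                params=params,
                log_likelihood=loglik,
                n_iterations=len(trace) - 1,
                converged=converged,
                start_used=label,
                loglik_trace=tuple(trace),
            )
    if best is None:
        raise RuntimeError("EM failed: every start yielded a -inf log-likelihood")
    return best
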