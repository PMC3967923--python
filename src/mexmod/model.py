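"""Generative mutual-exclusivity (ME) model for binary alteration matrices.

The model describes one patient row of a k-gene pattern. With probability
``coverage`` (gamma) the patient is covered: exactly one gene, chosen
uniformly, carries the exclusive true alteration, and each of the other
k-1 genes is additionally altered with probability ``impurity`` (delta).
An uncovered patient carries no true alterations. The observed row is the
true row passed through a per-entry noise channel: a true 0 is observed
as 1 with probability ``fp_rate`` (epsilon), a true 1 as 0 with
probability ``fn_rate`` (xi).

Because genes are exchangeable, the likelihood of an observation depends
only on its number of 1s, so the whole-dataset likelihood is a function
of the count profile and is evaluated in O(k) after O(k) precomputation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .matrix import AlterationMatrix, CountProfile

__all__ = [
    "Variant",
    "MEParameters",
    "LatentState",
    "observed_count_probabilities",
    "observation_log_likelihoods",
    "dataset_log_likelihood",
    "brute_force_observation_likelihood",
    "simulate_me_dataset",
    "simulate_independence_dataset",
]

_ENUMERATION_BOUND = 12


class Variant(str, Enum):
    """Which parameters of the ME model are free.

    ``no_errors``    coverage + impurity, error rates fixed at zero
    ``known_errors`` coverage + impurity, error rates fixed at given values
    ``fp_only``      coverage + impurity + fp_rate, fn_rate fixed at zero
    ``full``         all four parameters
    """

    NO_ERRORS = "no_errors"
    KNOWN_ERRORS = "known_errors"
    FP_ONLY = "fp_only"
    FULL = "full"

    @property
    def df(self) -> int:
        """Number of free parameters."""
        return {"no_errors": 2, "known_errors": 2, "fp_only": 3, "full": 4}[self.value]


@dataclass(frozen=True)
class MEParameters:
    """Parameters of the generative ME model.

    ``fp_rate`` and ``fn_rate`` are restricted to [0, 0.5): at 0.5 and
    beyond the error channel can relabel 0s and 1s, making the model
    non-identifiable.
    """

    coverage: float
    impurity: float
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    variant: Variant = Variant.NO_ERRORS

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant(self.variant))
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must be in [0, 1], got {self.coverage}")
        if not 0.0 <= self.impurity <= 1.0:
            raise ValueError(f"impurity must be in [0, 1], got {self.impurity}")
        for name, rate in (("fp_rate", self.fp_rate), ("fn_rate", self.fn_rate)):
            if not 0.0 <= rate < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {rate}")
        if self.variant is Variant.NO_ERRORS and (self.fp_rate or self.fn_rate):
            raise ValueError("no_errors variant requires fp_rate = fn_rate = 0")
        if self.variant is Variant.FP_ONLY and self.fn_rate:
            raise ValueError("fp_only variant requires fn_rate = 0")

    @property
    def observed_impure_rate(self) -> float:
        """Probability q that a non-exclusive gene of a covered patient is
        observed altered: q = impurity*(1 - fn) + (1 - impurity)*fp."""
        return self.impurity * (1 - self.fn_rate) + (1 - self.impurity) * self.fp_rate

    def with_rates(self, fp_rate: float | None = None, fn_rate: float | None = None):
        kwargs = {}
        if fp_rate is not None:
            kwargs["fp_rate"] = fp_rate
        if fn_rate is not None:
            kwargs["fn_rate"] = fn_rate
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatentState:
    """Hidden variables of the generative process, one entry per patient.

    ``covered[i]`` is the coverage indicator, ``exclusive_gene[i]`` the
    0-based index of the exclusively altered gene (-1 when uncovered) and
    ``true_alterations`` the error-free alteration matrix.
    """

    covered: np.ndarray
    exclusive_gene: np.ndarray
    true_alterations: np.ndarray

    def __post_init__(self) -> None:
        covered = np.asarray(self.covered, dtype=np.int8)
        excl = np.asarray(self.exclusive_gene, dtype=np.int64)
        true = np.asarray(self.true_alterations, dtype=np.int8)
        object.__setattr__(self, "covered", covered)
        object.__setattr__(self, "exclusive_gene", excl)
        object.__setattr__(self, "true_alterations", true)
        if not ((covered == 1) == (excl >= 0)).all():
            raise ValueError("covered = 1 exactly when an exclusive gene is set")
        rows = np.arange(true.shape[0])
        cov = covered == 1
        if not (true[rows[cov], excl[cov]] == 1).all():
            raise ValueError("exclusive gene must be truly altered when covered")
        if true[~cov].any():
            raise ValueError("uncovered patients must have no true alterations")


def _branch_masses(params: MEParameters, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-mass contributions of the three generative branches for m = 0..k.

    w0: uncovered rows (m observed 1s are all false positives);
    wA: covered rows whose exclusive gene survives the noise (observed 1);
    wB: covered rows whose exclusive gene is flipped to 0 (a false negative).
    """
    m = np.arange(k + 1)
    q = params.observed_impure_rate
    w0 = (1 - params.coverage) * binom.pmf(m, k, params.fp_rate)
    wA = params.coverage * (1 - params.fn_rate) * binom.pmf(m - 1, k - 1, q)
    wB = params.coverage * params.fn_rate * binom.pmf(m, k - 1, q)
    return w0, wA, wB


def observed_count_probabilities(params: MEParameters, k: int) -> np.ndarray:
    """Probability p_m that a patient shows exactly m observed alterations.

    Returns a length k+1 vector summing to 1. The per-observation
    likelihood of a specific binary row with m ones is ``p_m / C(k, m)``
    (the model is exchangeable in the genes).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    w0, wA, wB = _branch_masses(params, k)
    return w0 + wA + wB


def observation_log_likelihoods(params: MEParameters, k: int) -> np.ndarray:
    """log f_m for m = 0..k, the log-likelihood of one specific observed
    row with m ones: log(p_m) - log(C(k, m)). Zero-probability classes
    yield -inf (never an exception)."""
    p = observed_count_probabilities(params, k)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    m = np.arange(k + 1)
    log_binom = (
        np.cumsum(np.concatenate(([0.0], np.log(np.arange(1, k + 1)))))
    )
    log_choose = log_binom[k] - log_binom[m] - log_binom[k - m]
    return logp - log_choose


def dataset_log_likelihood(profile: CountProfile, params: MEParameters) -> float:
    """Log-likelihood of a dataset summarized by its count profile.

    Sum over rows of the per-observation log-likelihood log f_m; evaluated
    as ``sum_m counts[m] * log f_m`` in O(k). Returns -inf when some class
    with positive count has zero probability.
    """
    log_f = observation_log_likelihoods(params, profile.k)
    counts = profile.counts
    mask = counts > 0
    if np.isneginf(log_f[mask]).any():
        return float("-inf")
    return float((counts[mask] * log_f[mask]).sum())


def _latent_enumeration(observation: np.ndarray, params: MEParameters):
    """Yield (weight, covered, n_impure, n_fp, n_fn, n_true) over all latent
    states consistent with the model, for one observed row."""
    o = np.asarray(observation, dtype=np.int64)
    k = o.size
    if k > _ENUMERATION_BOUND:
        raise ValueError(f"enumeration limited to k <= {_ENUMERATION_BOUND}")
    gamma, delta = params.coverage, params.impurity
    eps, xi = params.fp_rate, params.fn_rate

    def channel(z: np.ndarray) -> float:
        # P(o | z) under the per-entry error channel
        p1 = np.where(z == 1, 1 - xi, eps)  # P(O=1 | Z)
        return float(np.prod(np.where(o == 1, p1, 1 - p1)))

    # uncovered: all true alterations zero
    z = np.zeros(k, dtype=np.int64)
    yield (1 - gamma) * channel(z), 0, 0, int(o.sum()), 0, 0
    if gamma == 0:
        return
    # covered: exclusive gene x, impure subset among the rest
    for x in range(k):
        others = [j for j in range(k) if j != x]
        for impure in itertools.product((0, 1), repeat=k - 1):
            z = np.zeros(k, dtype=np.int64)
            z[x] = 1
            z[others] = impure
            s = int(sum(impure))
            prior = gamma / k * delta**s * (1 - delta) ** (k - 1 - s)
            w = prior * channel(z)
            n_fp = int(((z == 0) & (o == 1)).sum())
            n_fn = int(((z == 1) & (o == 0)).sum())
            yield w, 1, s, n_fp, n_fn, 1 + s


def brute_force_observation_likelihood(
    observation: Sequence[int], params: MEParameters
) -> float:
    """Likelihood of one observed row by exhaustive summation over all
    latent states (coverage indicator, exclusive gene, true alterations).

    Test oracle for the closed-form likelihood; k <= 12.
    """
    return float(sum(w for w, *_ in _latent_enumeration(observation, params)))


def simulate_me_dataset(
    params: MEParameters, n: int, k: int, seed: int
) -> tuple[AlterationMatrix, LatentState]:
    """Draw n i.i.d. patient rows from the ME model; returns the observed
    matrix together with the latent state for oracle tests."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    rng = np.random.default_rng(seed)
    covered = (rng.random(n) < params.coverage).astype(np.int8)
    exclusive = np.where(covered == 1, rng.integers(0, k, size=n), -1)
    true = (rng.random((n, k)) < params.impurity).astype(np.int8)
    true[covered == 0] = 0
    rows = np.arange(n)[covered == 1]
    true[rows, exclusive[covered == 1]] = 1
    u = rng.random((n, k))
    observed = np.where(true == 1, u >= params.fn_rate, u < params.fp_rate)
    matrix = AlterationMatrix.from_values(observed.astype(np.int8))
    return matrix, LatentState(covered, exclusive, true)


def simulate_independence_dataset(
    frequencies: Sequence[float], n: int, seed: int
) -> AlterationMatrix:
    """Draw an n x k matrix with independent Bernoulli columns at the
    given per-gene alteration frequencies (the null model)."""
    freq = np.asarray(frequencies, dtype=float)
    if freq.ndim != 1 or freq.size < 1:
        raise ValueError("frequencies must be a non-empty vector")
    if ((freq < 0) | (freq > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = (rng.random((n, freq.size)) < freq).astype(np.int8)
    return AlterationMatrix.from_values(values)
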