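# Methods

## Generative model

A mutually exclusive pattern over k genes is modeled per patient row by
three layers of latent variables: a coverage indicator Y ~ Bernoulli(γ);
given Y = 1, an exclusive gene X uniform on {1..k}; true alterations Z
with Z_X = 1 and, for every other gene independently, Z_j ~ Bernoulli(δ)
(the impurity). Uncovered patients (Y = 0) carry no true alterations;
spurious alterations in those rows are the job of the error channel, not
of impurity. The observation O applies an independent asymmetric binary
channel per entry: P(O=1 | Z=0) = ε, P(O=0 | Z=1) = ξ.

The uniform choice of X makes the model exchangeable in the genes, so the
likelihood of a row depends only on its alteration count m. Writing
q = δ(1−ξ) + (1−δ)ε for the probability that a non-exclusive gene of a
covered patient is *observed* altered, the count-class probability
decomposes over three branches:

    p_m = (1−γ)·Bin(m; k, ε)                      (uncovered)
        + γ(1−ξ)·Bin(m−1; k−1, q)                 (covered, exclusive gene seen)
        + γξ·Bin(m; k−1, q)                       (covered, exclusive gene flipped)

with Bin(·; N, p) the binomial pmf. The probability of one *specific* row
with m ones is p_m / C(k, m); the dataset log-likelihood is
Σ_m n_m · log(p_m / C(k, m)) over the count profile (n₀..n_k). The
per-observation form (rather than the class form, which differs by the
parameter-free constant Σ n_m log C(k,m)) is used everywhere so that ME
and independence log-likelihoods are comparable row by row, which the
Vuong statistic requires. Both forms have the same maximizers.

Every closed form above is certified in the test suite against exhaustive
enumeration of all latent states (all 1 + k·2^(k−1) configurations of
(Y, X, Z)) for k ≤ 6, to 1e-10.

## Estimation

**Error-free (reduced) model.** The MLEs are closed form: γ̂ is the
fraction of rows with at least one alteration, and δ̂ spreads the excess
alterations over the non-exclusive slots of covered rows,
δ̂ = (T − n_cov)/((k−1)·n_cov) with T the total alteration count.
Degenerate inputs: no covered rows → δ̂ := 0; every covered row fully
altered → δ̂ = 1 by the same formula; k = 1 → δ̂ := 0 (no non-exclusive
slots). These estimates are re-verified against a 200-point-per-parameter
grid search on random datasets.

**Independence model.** Per-gene frequency MLEs are the column means,
with the 0·log 0 := 0 convention in the log-likelihood.

**EM for the error-aware variants.** Observations are grouped by count
class, so the E-step evaluates, for each of the k+1 classes, the
posterior expectations of five complete-data sufficient statistics:
the coverage indicator, the number of impure true alterations, of false
positives, of false negatives, and of true alterations. Conditioning on
the three generative branches above, each non-exclusive gene of a covered
row is truly altered with posterior probability r₁ = δ(1−ξ)/q given it is
observed 1 and r₀ = δξ/(1−q) given observed 0, which gives all five
expectations in closed form; the M-step is the ratio of the corresponding
aggregated counts (e.g. ε' = Σ fp / Σ true zeros). Each iteration is O(k)
after the O(n) profile construction. The E-step closed forms are
certified against the enumeration posterior.

Variants: `known_errors` fixes (ε, ξ) at user-supplied values and updates
only (γ, δ); `fp_only` fixes ξ = 0 (motivated by the near
non-identifiability of ξ at realistic sample sizes — see limitations);
`full` updates all four.

Defaults (EMOptions): educated start at the reduced-model estimates with
ε = ξ = 0.01, plus 10 random restarts (coverage ~ U(0.05, 0.95), other
rates ~ U(0.001, 0.3)); at most 2000 iterations; absolute log-likelihood
tolerance 1e-6; best restart wins, ties broken by start order. M-step
estimates are clamped to [1e-9, 1−1e-9] (error rates additionally below
0.5 − 1e-6) to keep the log-likelihood finite; error rates are bounded
below 1/2 throughout because beyond it the channel relabels 0/1 and the
model is non-identifiable (label switching).

## Testing

The ME and independence models are not nested, so they are compared with
Vuong's closeness statistic: with per-row log-likelihood ratios
r_i = log P_ME(row_i) − log P_IND(row_i) at the fitted parameters,

    S = (Σ r_i − C) / (√n · s),

where s is the sample standard deviation of the r_i (n−1 denominator) and
C = ((df_ME − df_IND)/2)·log n is a BIC-type correction for the free
parameter counts (df_ME ∈ {2,3,4} by variant, df_IND = k). An AIC-free
"none" mode is exposed as a switch. Under equal Kullback–Leibler
closeness of the two models to the truth, S is asymptotically N(0,1); the
reported p-value is the upper tail p = 1 − Φ(S), so small p favors mutual
exclusivity and strongly negative statistics map to p ≈ 1. When s = 0
(all rows equally well explained by both models) the test is degenerate
and conservatively reports p = 1.

Note the test is *conservative* when the data truly come from the
independence model: the null then has strictly smaller KL divergence
(zero), S drifts to −∞ with n, and the rejection rate at level α is far
below α. Calibration near α is expected only near the equal-closeness
boundary.

Comparators: the weight 2·(covered rows) − (total alterations) with a
column-permutation test (each column permuted independently, preserving
per-gene frequencies; the total alteration count is permutation-invariant,
so only covered-row counts need to be re-drawn — implemented by placing
each column's 1s on a uniform random row subset). The default p-value is
(1 + #{permuted ≥ observed})/(1 + B); a strict mode (#{permuted >
observed}/B, which can reach exactly 0) is provided. The imbalance of a
gene set is (largest per-gene alteration count)/(covered rows).
Benjamini–Hochberg adjustment delegates to statsmodels.

## Subset screening

`screen_subsets` mirrors the two-stage workflow used on real cohorts:
optionally keep the top-N most frequently altered genes (ties at the
cutoff broken lexicographically), enumerate all C(k, s) subsets, stage-1
pre-filter with the cheap reduced model (estimated coverage > 0.3,
impurity < 0.2, ME statistic > 0 — i.e. the ME model fits at least as
well as independence, not necessarily significantly), stage-2 fit of the
final variant with the ME test, BH adjustment over exactly the stage-2
family, and a final filter on the stage-2 estimates and the adjusted
significance level (default 0.05). Results are sorted by impurity
ascending, then coverage descending. Duplicate columns can first be
collapsed into meta-gene columns (`merge_duplicate_columns`), named by
joining their member genes.

The stage-1 reduced-model path is vectorized over subsets (closed-form
MLEs and the Vuong statistic computed with array operations in chunks),
which makes exhaustive screens of ~2M subsets feasible in seconds; the
batched path is tested for exact agreement with the per-subset path.

## Simulation studies and what they show

The simulators generate exactly the generative process above, returning
the latent state so that tests can compare observed against error-free
quantities. Study conditions follow the published designs where
recoverable: 20 replicates per setting; n ∈ {200, 1000}; k ∈ {3, 5, 8,
10}; null frequencies drawn uniformly per gene (f_max up to 0.5), with an
empirical-resampling mode for realistic frequency spectra.

- *Calibration/power*: on independence data the ME test's rejection rate
  stays at or below the nominal level (conservative, see above); on ME
  data the test gains power with k while the permutation test loses it
  (the weight does not scale with k and impure entries accumulate in
  longer rows). The median-p-decreasing-in-k trend is checked at coverage
  0.5: at higher coverages the k = 3 test is already saturated
  (p ≈ 1e-14) and medians can only hover at the floating-point floor.
- *Error-regime bias*: adding false positives to data fitted with the
  error-free model inflates both estimates — the coverage MLE counts
  nonzero rows, so extra spurious 1s can only raise it, and the excess
  alterations inflate δ̂. Accounting for the known error rates removes
  the bias. Similarly, false negatives lower the observed weight in the
  low-impurity regime; note the direction reverses at high impurity,
  where deleting a 1 from a multi-altered row *raises* the weight by
  removing overlap without losing coverage. The weight-bias study
  therefore uses impurity ∈ {0, 0.05}.
- *Ranking*: datasets with coverage ~ U(0.3, 0.9) and impurity
  ~ U(0, 0.15) (continuous draws, so reference orderings have no ties)
  are ranked (i) by estimated quality — impurity ascending, coverage
  descending, from known-error EM fits — scored against the true-parameter
  ordering, and (ii) by observed weight, scored against the true
  (error-free latent) weight ordering. With false negatives both rankings
  stay accurate; with false positives the observed weight suffers
  systematic inversions that do not shrink with n, while the quality
  ranking's errors are estimation noise that does — pooled over fp ∈
  {0.02, 0.05}, quality ranking is reliably more concordant. At fp = 0.02
  alone the two are within noise of each other at n = 1000.

What passing these simulations does *not* show: the generator draws
i.i.d. patients with a single planted pattern and genes that are
exchangeable within it. Real cohorts have heterogeneous per-gene
frequencies inside true pathways (the model is "tailored for balanced
patterns"), overlapping pathways, subtype structure, and correlated
calling errors — none of which are emulated. Conclusions about real data
rest on the model being a usable approximation, not on these tests.

## Known limitations

- The full 4-parameter variant is weakly identified at realistic sample
  sizes: the false-negative rate is badly estimated below n ≈ 10⁴ and the
  likelihood has a ridge when δ ≈ ε (impure alterations and false
  positives mimic each other); the `fp_only` variant is the practical
  choice and is accurate from n ≈ 1000.
- The ME test's normal reference is asymptotic and conservative away from
  the equal-closeness boundary; no exact small-sample null is provided.
- Subset *search* is exhaustive enumeration with a pre-filter; no
  combinatorial optimization over very large gene universes is attempted.
- No standard errors or priors on the parameters are provided.
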