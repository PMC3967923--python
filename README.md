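# mexmod

Generative modeling and significance testing of **mutual exclusivity** in
binary cancer-alteration matrices.

In large tumor cohorts, genes acting in a common pathway are often altered
in *disjoint* patient subsets: across patients, at most one member of the
set tends to carry a mutation, amplification, or deletion. Detecting such
mutually exclusive patterns is a standard route to grouping candidate
driver genes into pathways. Existing scores — notably the
coverage-minus-overlap weight with a column-permutation test — ignore that
alteration calls contain errors, and false positives in particular can
badly distort pattern ranking.

`mexmod` is for computational biologists who have (or simulate) a binary
patient × gene alteration matrix and want to fit, test, and screen for
mutually exclusive gene sets with observation errors taken into account.

## The model

One patient row over a set of k genes is generated as follows. With
probability γ (**coverage**) the patient is covered: one gene, chosen
uniformly, carries the exclusive alteration, and each of the other k−1
genes is additionally altered with probability δ (**impurity**). Uncovered
patients carry no true alterations. The observed row passes each entry
through an error channel: a true 0 is flipped to 1 with probability ε
(false-positive rate), a true 1 to 0 with probability ξ (false-negative
rate).

Because genes are exchangeable, the likelihood of a row depends only on
its number of observed alterations m, so a dataset is summarized by the
count profile (n₀, …, n_k) and the log-likelihood is evaluated in O(k),
independent of the number of patients. The package provides:

- closed-form maximum-likelihood estimates of (γ, δ) in the error-free
  model: γ̂ = (rows with ≥ 1 alteration)/n,
  δ̂ = (alterations − covered rows)/((k−1) · covered rows);
- an EM algorithm for the error-aware variants (`known_errors`, `fp_only`,
  `full`) whose E-step computes five posterior expectations for only the
  k+1 count classes, so each iteration is O(k);
- the **ME test**: Vuong's non-nested closeness test of the fitted ME
  model against the fitted independence null (each gene altered
  independently at its marginal frequency). The statistic standardizes
  the per-patient log-likelihood ratios with a BIC-type correction for
  the difference in free-parameter counts and is compared against the
  upper tail of N(0, 1);
- the weight/permutation comparators, the imbalance diagnostic,
  Benjamini–Hochberg adjustment, and a two-stage exhaustive subset screen
  (coverage > 0.3, impurity < 0.2, positive ME statistic, then
  significance on BH-adjusted p-values);
- simulators for both models plus scripted power, calibration, ranking,
  and parameter-recovery studies.

## Worked example

```python
from mexmod import (MEParameters, simulate_me_dataset, fit_reduced, em_fit,
                    me_test, permutation_test)

params = MEParameters(coverage=0.6, impurity=0.05, fp_rate=0.05,
                      fn_rate=0.0, variant="fp_only")
matrix, latent = simulate_me_dataset(params, n=1000, k=5, seed=7)

reduced = fit_reduced(matrix)                       # pretends data are clean
known = em_fit(matrix, variant="known_errors",
               fixed={"fp_rate": 0.05, "fn_rate": 0.0}, seed=0)
result = me_test(matrix, variant="known_errors",
                 fixed={"fp_rate": 0.05, "fn_rate": 0.0}, seed=0)
```

Output for this seed:

```
matrix: 1000 patients x 5 genes, 925 alterations
reduced fit:      coverage=0.691 impurity=0.085
known-errors fit: coverage=0.601 impurity=0.046 (17 EM iterations)
ME test: statistic=4.81 p=7.39e-07
permutation test: p=0.001
```

The error-free fit is misled by the 5% false positives — spurious
alterations turn empty rows into apparently covered ones and inflate both
estimates (coverage 0.691, impurity 0.085). Fixing the error rates at
their true values in the EM fit recovers the generating parameters
(0.601 and 0.046 versus the true 0.6 and 0.05). The ME test statistic of
4.81 (upper-tail p ≈ 7×10⁻⁷) says the mutual-exclusivity model describes
these patients far better than independent alterations.

The same steps are available from the shell:

```
mexmod simulate --model me --n 1000 --k 5 --coverage 0.6 --impurity 0.05 \
       --fp-rate 0.05 --seed 7 --out cohort.tsv
mexmod fit cohort.tsv --variant known_errors --fp-rate 0.05
mexmod test cohort.tsv --variant known_errors --fp-rate 0.05
mexmod screen cohort.tsv --subset-size 4 --out patterns.tsv
```

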