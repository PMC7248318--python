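# Methods

## Model and procedure

Let `S = S_maj ∪ S_min` be a labeled tabular dataset with `N` rows, where
the minority class is internally the positive class (label 1) so that
sensitivity always measures minority detection. The estimator is an
AdaBoost.M1 ensemble of `T` depth-limited, weight-aware CART trees with
per-round resampling:

1. Initialize boosting weights `D_{1,n} = 1/N` over all examples and, when
   heuristic under-sampling is on, sampling weights `SW_{1,n} = 1/N_maj`
   over the majority.
2. Each round draws `N_u` majority rows (HUS: weighted by `SW`, without
   replacement; RUS: uniform; `none`: all), generates `N_o` artificial
   minority rows by DOS, and appends them to all original minority rows.
3. A tree is fitted to minimize the weighted misclassification of that
   round set, using boosting weights for real rows; artificial rows get the
   mean boosting weight of the real minority (see design choices).
4. The tree predicts the **full** dataset; `ε_t` is the boosting-weight mass
   it misclassifies, `β_t = ε_t/(1−ε_t)`, vote `α_t = log(1/β_t)`.
5. `D` multiplies correct examples by `β_t` and renormalizes (over original
   examples only). `SW` multiplies sampled-and-correct majority rows by
   `β_t`, sampled-and-misclassified by `1/β_t`, unsampled by 1, and
   renormalizes.
6. The ensemble classifies by the sign of the normalized vote margin
   `(Σ_{t: h_t=min} α_t − Σ_{t: h_t=maj} α_t)/Σ_t α_t`, which is also the
   ranking score used for AUC/AUPRC. Variable importance is
   `VI_p ∝ Σ_t α_t ΔI_G^t(p)`, normalized to sum to 1.

Assumptions: complete cases (the loader rejects or drops missing rows —
imputation is upstream of this package); two classes; at least two minority
examples (DOS needs a variance); DOS treats variables as independent within
the minority class.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_rounds` (T) | 100 | maximum weak classifiers; the conventional budget for this family of methods |
| `n_u` | `n_min + n_o` | majority rows per round; default balances the round sample exactly |
| `n_o` | `n_min` | artificial minority rows per round, so the round's minority set is twice the original |
| `under_sampling` | `hus` | `hus`/`rus`/`none`; the variant lattice (husdos, husboost, rusboost, adaboost) |
| `over_sampling` | `dos` | `dos`/`none` |
| `epsilon_min` | 1e-10 | clamp for perfect rounds; keeps `α_t` finite while letting a perfect tree dominate |
| `tree.max_depth` | 3 | shallow unpruned trees are the standard weak learner; no cost-complexity pruning |
| `artificial_weight` | `mean_minority` | weight of DOS rows inside the tree objective (see below) |

Cross-validation defaults to 10 folds × 10 repeats, stratified. Sampling
sizes are re-resolved from each **training fold's** minority count, never
from the full dataset.

## Design choices where the design was open

- **Weight of artificial examples.** The round objective sums boosting
  weights over the round set, but artificial rows have no boosting weight of
  their own. They receive the mean boosting weight of the real minority
  rows, so DOS scales minority mass without redistributing it; `mean_all`
  is available as a config alternative for sensitivity analysis. Boosting
  weights are only ever defined and updated over original examples.
- **Under-sampling without replacement.** Duplicated majority rows add no
  information; HUS draws sequentially with weight removal.
- **Degenerate rounds.** `ε_t = 0` is clamped to `epsilon_min` and the
  (perfect) tree kept. `ε_t ≥ 0.5` discards the attempt and redraws; after
  10 consecutive failures both weight vectors are reset to uniform once;
  if a further 10 attempts fail the fit stops early (or errors if no tree
  was ever retained). At extreme imbalance these resets are routine: trees
  fitted to balanced round samples can carry weighted error above 0.5 on
  the full data once `D` concentrates.
- **Sampling sizes.** A published line of the protocol reads as if
  `N_u` equals the minority count while its neighbor says the majority
  sample is twice the minority count; both readings are exposed (`n_u`,
  `n_u_factor`) and the default is the balanced one,
  `n_u = n_min + n_o`.
- **Gini form.** Node impurity is the standard squared form
  `1 − Σ_k (share_k)²` with weighted class sums. Per-variable gain totals
  weight each node's impurity decrease by the node's share of total example
  weight, so root splits count more than equal-gain splits deep in the tree.
- **Tree conventions.** Thresholds are midpoints between consecutive
  distinct sorted values; ties at a threshold route left; equal-gain ties
  resolve to the lowest variable index, then the lowest threshold; a tied
  leaf predicts the majority class (conservative for specificity). These
  choices make fits bit-reproducible under a fixed seed.
- **AUPRC interpolation.** Step-wise (average-precision), because linear PR
  interpolation is optimistically biased exactly in the near-zero-prevalence
  regime this package targets. Precision at the zero-recall endpoint is
  taken as 1.
- **DOS truncation.** Generated continuous values are not clipped to the
  observed minority range by default (`clip_to_range=True` enables it);
  a Gaussian KDE can replace the per-variable Gaussian via
  `continuous_model="kde"`. The variance floor `1e-12·(1+μ²)` keeps
  constant variables generable.
- **Stratified CV by default.** With 16–30 minority examples, unstratified
  folds are frequently minority-free, leaving sensitivity undefined;
  stratification is the only protocol under which fold-level metrics are
  always computable. Unstratified splitting remains available and aborts
  with guidance if a test fold has no minority row.

## Synthetic data: what it does and does not emulate

`generate_eism` produces exact class counts, class-shifted unit-variance
Gaussian informative variables (shift `δ` in within-class SD units),
N(0,1) noise variables and per-class Bernoulli binary variables — all
class-conditionally independent. `generate_hr_like` is a 41-variable preset
at 16/7,379 (0.2% prevalence) whose informative variable is an age-like
Gaussian (majority 56.6 ± 11.6, minority 68.8 ± 10.8, about a 1 SD shift)
plus a mildly informative gender share and uninformative habit flags.

The independence is deliberate: it matches DOS's own modeling assumption,
so over-sampling fidelity can be tested in isolation. Real clinical tables
have correlated variables, missingness and non-Gaussian marginals; passing
tests here therefore demonstrate correctness of the algorithms under their
own assumptions, not expected field performance. The known ground truth
yields an equal-prior Bayes log-likelihood-ratio rule whose fresh-sample
G-mean upper-bounds any trained model up to Monte-Carlo noise, which the
tests exploit.

Train and test sets are always generated fresh from the same parameters
rather than split from one sample, which removes split noise from the
evaluation experiments.

## Problem sizes used in tests and the acceptance script

Recovery and null experiments use 20 minority / 2,000 majority with
`δ = 6` (separable) and `δ = 0` (null) over 10 and 20 fresh draws; the
variant comparison uses the generator defaults (δ = 1.5, 2 informative + 8
noise variables) over 20 draws. Cross-validation unit tests use 5 folds and
reduced round budgets; these sizes keep every experiment reproducible on a
single CPU in minutes while leaving the stochastic comparisons enough
replicates to be stable at the tolerances asserted.

## Known limitations

- DOS generates variables independently; correlated minority structure is
  not reproduced (a covariance-aware generator is the natural extension).
- Weighted-vote outputs are not calibrated probabilities.
- One-hot DOS sampling of multi-level categoricals draws the level from the
  fitted proportions, but the tree only sees binary indicator splits.
- Training is sequential over rounds; no parallelism.
- On separable data with majority outliers inside the minority's fitted
  Gaussian tail, the discard/reset policy can leave one or two training
  examples at a persistent ~0.5 vote share, so training G-mean can stall
  marginally below 1 on rare draws.
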