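# Methods

This note documents the statistical models, algorithms and numerical choices
behind `fingertox`, in the spirit of the methods documentation of packages
like `statsmodels` or `msprime`: what is computed, under which assumptions,
and where the genuinely open design decisions were resolved.

## 1. Problem setting

Chemicals are described by binary molecular fingerprint vectors
`x ∈ {0,1}^d` (one bit per structural pattern) and carry activity labels
`y_a ∈ {0,1}` in each of several bioassays, with many labels missing
(inconclusive experiments). Classifiers are trained on exact fingerprints of
structurally identified chemicals. At application time, an unidentified
chemical observed by MS² offers only posterior probabilities `p_j ∈ [0,1]`
that each pattern is present. The package's central operation converts the
posterior vector into an activity score usable with binary-trained models.

## 2. Monte Carlo inference over probabilistic fingerprints

Given a fitted scorer `f : {0,1}^d → [0,1]` and posteriors `p`, the Monte
Carlo estimate is

    ŝ_N = (1/N) Σ_{n=1}^N f(x⁽ⁿ⁾),   x⁽ⁿ⁾_j ~ Bernoulli(p_j) i.i.d.

* `ŝ_N` is an unbiased estimator of `E[f(x)]` with standard error
  `sd(f(x))/√N`; the default `N = 10,000` keeps that error below ~0.005 for
  bounded scores.
* **Enumeration oracle.** For `d ≤ 20` *uncertain* features (those with
  `0 < p_j < 1`; bits at exactly 0 or 1 are forced) the exact expectation
  `Σ_x f(x) Π_j p_j^{x_j}(1-p_j)^{1-x_j}` is computed by full enumeration.
  It is used in tests to verify unbiasedness and the `N^{-1/2}` error decay,
  never as the production path.
* **Degenerate vectors.** If every `p_j ∈ {0,1}` all samples coincide, so the
  prediction is computed from a single model call — exactly, with no
  summation round-off.
* **Common random numbers.** The first `k` rows of an `N`-sample stream equal
  the `k`-sample stream under the same seed, so running means recorded at an
  N-grid of checkpoints are prefix-consistent and convergence curves are
  coherent per chemical. A chemical is flagged by the convergence analysis
  when its thresholded class at any smaller `N` differs from the class at the
  largest `N`.
* **Naive baseline.** Binarise at a fixed threshold (default 0.5, with
  `p = threshold` counting as present) and score once. The disagreement rate
  between the two routes is reported per assay.
* Multi-output models are scored on one shared sample set for all assays
  (cheaper than per-assay resampling; both estimates are unbiased).
* Class rule: `ŝ ≥ 0.5 → active`; the threshold is configurable.

## 3. Synthetic data generator

The generator produces datasets with the statistical structure the analysis
must cope with. Its defaults are the study conditions asserted by the tests.

* **Correlated binary fingerprints.** A latent-Gaussian (copula) scheme:
  features are grouped into blocks; within a block the latent variables share
  pairwise correlation `rho` (one common factor), across blocks they are
  independent. Each latent is thresholded at the normal quantile of a
  per-feature marginal prevalence drawn uniformly from `prevalence_range`
  (default 0.1–0.4, matching the sparsity of real substructure bits). The
  copula was chosen because it gives exact block structure and calibrated
  margins with standard machinery; it does not attempt chemistry-aware
  structure generation.
* **Planted toxicophores.** Each assay's ground truth is a sparse logistic
  model: `sparsity` features (default 5) with weights of magnitude
  `effect_size` (default 2.0, all positive by default), and an intercept
  found by Brent root-finding so that the mean of `sigmoid(w·x + b)` over the
  generated fingerprints equals the target active prevalence within ±0.002.
  Default prevalence 0.05 sits inside the 2–12% range typical of screening
  assays. A `share_fraction` of causal features comes from a global shared
  pool, which induces positive inter-assay label correlation; empirical phi
  is non-decreasing in `share_fraction` (verified at 0, 0.5, 1).
* **Missing labels** are masked completely at random (MCAR) at a per-assay
  rate (default 0.2, in the observed 16–60% range). MCAR is an assumption —
  real inconclusive results are plausibly activity-dependent — and the tests
  therefore say nothing about informative missingness.
* **Duplicates.** A fraction of chemicals is emitted 2–3 times; duplicate
  labels are flipped independently with `flip_prob`, symmetrically in both
  directions (the direction of real conflicts is not characterised). The
  original record is kept verbatim so consensus rules can be verified.
* **Posterior emulator.** Each entry is concordant with the true bit with
  probability `1 − e_j`. A Beta(8,2) draw (shape configurable, sharpened by a
  concentration multiplier) is mapped into the half-interval on the matching
  side of 0.5 for concordant entries and the opposite side for discordant
  ones, producing the bimodal posterior profile of MS²-based fingerprint
  predictors while making the 0.5-threshold error rate exactly `e_j`.
  Defaults: `e_j ~ U(0.01, 0.04)` with 5% "hard" features at `e_j = 0.12`,
  mirroring the observed reliability profile (most features mispredicted for
  <4% of chemicals; the worst, such as benzenamine-type patterns, >12%).
  Infinite concentration is the degenerate noiseless mode (`p` equals the
  bit). The true joint distribution of posteriors is unknown; this Beta
  mixture is a stand-in with exposed parameters.
* **Seeding.** One master seed fans out to stage seeds via
  `sha256("{seed}:{label}") mod 2^31`, so any stage can be regenerated
  independently and every operation is bit-reproducible.

## 4. Data preparation

* **Deduplication.** Per assay: any active replicate ⇒ active. Mixed
  {inactive, missing} resolves to inactive by default, because an
  inconclusive run carries no evidence against an observed inactive; the
  `strict` policy instead keeps it missing. The operation is idempotent.
* **SMARTS fingerprints.** RDKit substructure matching; unparseable SMARTS
  raise a configuration error, unparseable SMILES are dropped with an
  explicit report (never silently zero-filled).
* **Near-zero-variance filter** (caret-compatible): a feature is removed if
  constant, or if its most-/second-most-frequent count ratio exceeds 19
  (= 95/5) *and* its percent of distinct values is below 10. For binary
  features this is "minority prevalence < 5%".
* **Correlation filter.** Exhaustive greedy variant: repeatedly find the
  surviving pair with the largest |Pearson r| above the cutoff and drop the
  member with the larger mean absolute correlation to all remaining features
  (ties: lower column index), recomputing means after each removal. This is
  deterministic and order-independent and guarantees no surviving pair
  exceeds the cutoff; surviving-feature counts are non-decreasing in the
  cutoff (0.7 ≤ 0.8 ≤ 0.9). Variance filtering is applied before correlation
  filtering; Pearson on binary columns is the phi coefficient, and constant
  columns correlate 0 by convention.

## 5. Anticlustered partitioning

Train/test splits and CV folds should *each* look like the whole imbalanced,
sparsely labelled dataset. Anticlustering maximises the diversity objective
(sum over groups of within-group pairwise distances) over balanced
assignments (group sizes differ by ≤1; remainders go to the lowest group
indices):

* items are encoded from labels as active=1, inactive=0, missing=0.5 with
  squared Euclidean distances (the metric and a feature-augmented encoding
  are configurable — labels-only is the default);
* a random balanced start is improved by pairwise exchange: for each item in
  random order, the best swap with any item of another group is accepted if
  it increases the objective (evaluated in O(1) from maintained item-to-group
  distance sums); sweeps stop at `max_sweeps` (default 20) or when no swap
  improves. Accepted swaps never decrease the objective.
* The exchange search can stall in swap-local optima; `n_init` restarts
  (best objective wins) reliably reach the exhaustive optimum on small
  instances (verified against full enumeration at n=8, K=2).
* Distances are held in float64 up to n=4000 and float32 above (memory), and
  the final objective is re-accumulated in float64.
* For the train/test split one of the K=5 groups is chosen uniformly at
  random as the test set; CV uses K=10 with all folds retained.
* **Stratified subsetting** (the "real-life-style" held-out set): subsets of
  size round-half-away-from-zero(`fraction·n`) are redrawn until every
  assay's active/inactive/missing counts are within a per-cell tolerance of
  `round(full-data proportion × size)`; if `max_tries` is exhausted the
  best-scoring draw is returned with a warning rather than failing.

## 6. Models

* **Single-output classifiers**: logistic regression (linear baseline),
  random forest, and gradient boosting — the ensemble families that dominate
  this kind of tabular fingerprint data — selected by grid search over
  user-supplied anticlustered folds with **mean out-of-fold ROC-AUC** (ties:
  first grid point), then refit on the full training data. Rows with a
  missing label for the assay are dropped before training. Tree-ensemble
  scores are the fitted model's class-probability output; probability
  calibration is out of scope.
* **Resampling** (applied to the training portion of each fold only):
  down-sampling (majority subsampled without replacement), up-sampling
  (minority resampled with replacement), and SMOTE (synthetic minority
  points `x_i + u(x_nn − x_i)`, `u ~ U(0,1)`, among `k=5` minority
  neighbours; `k` shrinks with a warning for tiny minorities). SMOTE outputs
  are left continuous in [0,1] — tree models and the network consume them
  directly.
* **Masked loss.** `L = −(1/M) Σ_observed [y log ŷ + (1−y) log(1−ŷ)]` with
  `M` the count of observed cells; missing cells have exactly zero loss and
  zero gradient (checked by finite differences), and `M = 0` defines `L = 0`
  with a warning. With no missing labels it equals plain mean BCE to 1e-12.
* **Multi-output network.** A numpy MLP: ReLU hidden layers (default one
  layer of 64 units — a desk-scale default; widths up to the thousands are
  configurable), one sigmoid output per assay, Adam (lr 1e-3) on the masked
  loss in its numerically stable logit form, L2 weight decay, inverted
  dropout, optional batch normalisation, and early stopping (patience 15) on
  the masked loss of a 10% validation slice carved from the training data by
  the same anticlustering routine. Training is deterministic per seed;
  non-finite losses abort with diagnostics. Assays with no observed
  validation labels contribute no terms to the early-stopping metric.

## 7. Evaluation

* **FPR at TPR ≥ 0.9.** Over the empirical step-function ROC with tied
  scores grouped into a single operating point (no interpolation, no
  optimistic tie-splitting; "score ≥ threshold ⇒ active"), the minimum FPR
  among points reaching the recall target, with the largest such threshold
  reported. No positives (or no negatives) ⇒ NaN with a stated reason.
  Raising the recall target never decreases the returned FPR.
* **ROC-AUC** is the Mann–Whitney statistic (ties counted half);
  **balanced accuracy** is (sensitivity+specificity)/2 at a fixed threshold.
  All metrics exclude missing labels and report `n_evaluated`.
* **Inter-assay correlation** is pairwise phi over jointly observed
  chemicals, with pairs below a minimum overlap reported missing.
* **Permutation importance** (metric drop after within-column shuffling,
  averaged over repeats, ties broken by feature id) is the package's feature
  attribution. It supports the toxicophore-recovery claim — planted causal
  features should rank highly — without exact Shapley values, whose
  per-feature attributions it approximates only in rank terms.

## 8. Problem sizes and verification scope

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen to keep binomial tolerances meaningful: calibration
checks use 5,000–50,000 chemicals; parameter recovery uses n=5000, d=100,
5 causal features of effect 2.0 at 5% prevalence (random-forest held-out
ROC-AUC and permutation-importance recall of planted features, and the
masked net on 3 correlated assays); the Monte Carlo estimator is checked at
N=10,000 against exact enumeration on toy models with ≤12 uncertain
features; the anticluster split reproduces the 5388/1347 partition of 6735
chemicals at K=5. Passing these tests demonstrates internal correctness and
recoverability under the generator's assumptions (MCAR missingness,
independent Bernoulli posteriors, logistic ground truth); it does not certify
performance on real screening data, where feature reliability is
structured, missingness is informative, and toxicophores are neither sparse
nor linear.

## 9. Known limitations

* The posterior emulator treats features as conditionally independent given
  the true bits; real MS²-derived posteriors are correlated through shared
  fragmentation evidence.
* The Monte Carlo estimator also samples features independently; it matches
  the estimand "expectation under independent Bernoulli posteriors", not the
  (unavailable) joint posterior.
* No probability calibration of classifier scores; FPR@TPR and ROC-AUC are
  rank-based and unaffected, but absolute score thresholds are not
  calibrated probabilities.
* Exact Shapley attribution, t-SNE diagnostics, ROSE resampling and the
  wider zoo of single-output learners are intentionally out of scope.
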