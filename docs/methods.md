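# Methods

## Problem setting

The package targets classification of cases described by ordinal/numeric
features when a substantial share of feature values is missing — the situation
typical of clinical symptom tables, where each feature is a severity score
(e.g. coded 1 = absent … 4 = most serious) and different cases are missing
different subsets of features.  The two standard work-arounds each distort the
data: listwise deletion discards every incomplete case (catastrophic when most
cases have at least one hole), and mean imputation fabricates values that add
noise.  The local-validity approach instead trains only on sub-tables that are
genuinely complete, and lets each sub-model vote on a query in proportion to
how much of its feature subset the query actually observes.

## The model

**Mask matrix and patterns.** For a table S = ⟨U, F, g⟩ with missing marker
∗, the mask matrix M ∈ {0,1}^{|U|×|F|} has M_{ij} = 1 iff case i observes
feature j.  Every distinct nonzero row of M defines a *local-validity
pattern* P ⊆ F — the maximal feature set on which its source cases are fully
observed.  Patterns are deliberately not globally maximal and may be nested;
their number is bounded by |U|, so exact enumeration always suffices.  The
*local-validity subset* (LVS) of P is LVS = {x ∈ U : g(x, f) ≠ ∗ ∀f ∈ P};
the projected sub-table LVS × P is complete by construction, and the union of
all LVS covers every case with at least one observed feature.  A case with
every feature missing is rejected at training time and handled by a prior
fallback at prediction time.

**Subset similarity.** Under heavy missingness the number of subsets grows
and the per-subset training sets shrink, so similar subsets are merged.
Similarity between LVS_i and LVS_k (sizes N_i, N_k) is measured on their
shared feature space P_i ∩ P_k by the Gaussian-kernel cross-entropy

    μ_{i,k} = −log( (1 / N_i N_k) Σ_p Σ_q exp(−‖x_p − y_q‖² / 2σ²) )

(natural log, unnormalized kernel, so μ ≥ 0 with μ = 0 for coincident
singletons; larger μ = more dissimilar member clouds), combined with the
membership overlap N_{i,k} = |LVS_i ∩ LVS_k| into

    I(i,k) = μ_{i,k} · log( N_{i,k} / (N_i + N_k) ).

Note the log factor is always ≤ 0 (the overlap cannot exceed either size), so
I ≤ 0 whenever μ > 0.  The formula is implemented as printed; ranking treats
larger I as stronger correlation, with a −∞ sentinel for zero-overlap pairs
so they always rank last.  A consequence worth knowing: the ranking favours
pairs whose clouds nearly coincide (μ → 0 drives I → 0, the maximum), which
is the behaviour the merging step needs.

**Clustering.** Each subset links to its k most similar subsets by I (default
k = 1; ties toward the lower index).  An edge survives only if both endpoints
link each other; connected components of surviving edges become clusters
Ω_k.  A cluster is represented by the *intersection* of its members' patterns
(so its sub-table stays complete) and the *union* of their memberships; a
component whose pattern intersection is empty is split back into singletons.
An optional cap `max_clusters` greedily merges the pair of clusters with
highest inter-cluster I while a merge with a nonempty shared pattern exists;
by default there is no cap.

**Kernel variance σ².** The cross-entropy formulation leaves σ² free.  Two
defaults are used, both median heuristics:

* the standalone pairwise functions use the median squared pairwise distance
  of the pooled shared-feature vectors, with clouds above 64 points thinned
  to an evenly spaced deterministic subset;
* inside a clustering run, each pair's σ² is the sum over its shared features
  of per-feature median squared pairwise differences, with the per-feature
  medians computed once per run (pooled over all subsets, capped at 256
  values per feature).  This prices σ² on the same scale as the pooled
  heuristic — for roughly independent features the squared distance is the
  sum of per-feature squared differences — while avoiding a full pairwise
  median for every one of the O(#subsets²) pairs, which otherwise dominates
  training time.

Both are overridable by an explicit `sigma2`; every frozen numeric test in
the suite passes σ² explicitly, so no expected value depends on the
heuristic.

**Ensemble and decision rule.** One base classifier per cluster is fitted on
the cluster's complete sub-table (default: a fully grown decision tree seeded
per cluster; 1-NN, 3-NN and logistic regression are selectable, or any
scikit-learn classifier).  A single-class cluster becomes a constant scorer.
For a query q the *complete degree* of cluster i is

    λ_i = |P_i ∩ observed(q)| / |P_i|,

and the decision is  Y = argmax_w Σ_i λ_i G_i^w, where G_i^w is cluster i's
class-w probability for the query.  Clusters with λ_i = 1 score the raw
query; clusters with 0 < λ_i < 1 either mean-fill their few missing pattern
features from their own training sub-table (policy `partial`, default) or
abstain (policy `strict`); λ_i = 0 clusters never vote.  If no cluster votes,
the most frequent training class is returned and the prediction is flagged.
Argmax ties break by training-class frequency, then label order.  Because
"complete degree" admits other readings, two alternatives are selectable:
λ_i = N_i|P_i|/(|U||F|) (the cluster's share of the training grid,
`lambda_mode="completeness"`) and an out-of-fold accuracy multiplier per
cluster (`quality_weight=True`).

On a complete table the construction provably collapses: one pattern, one
cluster, λ ≡ 1, and predictions equal the base classifier fitted on the full
table (up to the decision rule on exact probability ties, where scikit-learn's
`predict` breaks by class order instead of frequency).

## Evaluation protocol

Repeated stratified k-fold cross-validation, default ten repeats of 10-fold.
The fold plan depends only on (labels, folds, repeats, seed), so strategies
compared with the same arguments share identical splits.  Everything learned
— deletion, imputation means, patterns, clusters, classifiers — is learned
inside the training folds only.  Accuracy per repeat is correct test
predictions over all test cases; a deletion- or imputation-trained model
facing an incomplete test case mean-fills it with training means (the
`complete_only` option instead restricts the denominator to complete test
cases).  Classes smaller than the fold count trigger a warned fall-back to
non-stratified folds.

## Synthetic data

`make_classification_data` draws class-conditional ordinal features: class c
prefers level index (c + j) mod L on feature j with probability
1/L + (1 − 1/L)·s, the rest uniform.  At s = 0 the classes are
indistinguishable (chance level); at s = 1 levels are deterministic and any
nearest-neighbour rule is perfect.  `inject_mcar` masks exactly
round(α·|U|·|F|) cells uniformly without replacement, independent of values
and labels, re-drawing (bounded at 100 attempts) if a case would lose every
feature; case-level and per-feature-profile masking are also available.
Labels are never maskable.

`make_liver_fixture` emulates a 153-case, 3-class (52/61/40), 40-feature
clinical symptom table on the 1–4 severity scale, then applies a fixed
per-feature missing-percentage profile in which 23 of 40 features have
missing entries (per-feature counts: round-half-away-from-zero of pct·153,
floored at one case for any nonzero percentage, so exactly the 23
profile-positive features end up missing somewhere).  The fixture matches
marginal structure only — class sizes, value coding, per-feature missingness
— and deliberately not the feature correlations of any real cohort; tests
passing on it certify the machinery, not clinical performance.

## Benchmark conditions and problem sizes

The directional benchmark uses separable-but-noisy data: n = 200 cases,
d = 10 features, 3 balanced classes, separation 0.5 (complete-data CV
accuracy of the default tree ≈ 0.77), 20% of cells masked, 10-fold CV per
mask seed, 20 seeds in the test suite and 10 per α in the acceptance script.
The check is one-sided — mean accuracy of local-validity ≥ listwise deletion
up to twice the standard error of the paired difference — because exact
accuracies depend on the (undeposited) original data and on random masks;
the observed margin under these conditions is large (~20 points).

## Numerical and degenerate-input choices

* Missing marker: "*" on disk, NaN in memory; never a numeric code, so it
  cannot collide with ordinal levels.
* Kernel mean underflowing to zero yields μ = +∞ rather than an error.
* μ is clamped at 0 against floating-point drift (the unnormalized kernel
  bounds the mean by 1).
* All orderings (patterns, members, clusters, tie-breaks) are deterministic:
  first-occurrence case order, ascending indices, lowest-index ties.
* Randomness is always drawn from named substreams of a single user seed;
  identical seeds reproduce byte-identical artifacts.

## Known limitations

* The mutual-information ranking is implemented as printed; a variant using
  |log| or an inverted ratio would reverse some preferences and is not
  offered.
* The greedy mutual-link clustering is one faithful reading of an
  underspecified "k-nearest-neighbour" merging step; no spectral or
  hierarchical alternative is provided.
* Mean-filling partially covered queries (policy `partial`) reintroduces a
  little imputation at prediction time; `strict` avoids it at the cost of
  more prior fallbacks.
* The ensemble's probability combination is uncalibrated; combined scores are
  for ranking, not probabilistic interpretation.
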