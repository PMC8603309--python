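# Methods

This note records the scientific and numerical choices behind
`sublocnet`, in the spirit of a model-description appendix: what is
computed, which knobs matter, what the synthetic benchmark does and
does not emulate, and where the design was genuinely open.

## Input model and filtering

Proteins are opaque string identifiers; the caller's network, GMT,
FASTA and label files must share a namespace (no identifier mapping is
attempted). Sequence filtering keeps proteins of 50–5,000 residues
inclusive — *shorter than* 50 and *longer than* 5,000 are excluded —
and drops any sequence containing a residue outside the 20-letter
standard alphabet (B, J, O, U, X, Z, …), each exclusion carrying a
machine-readable reason code. Similarity-based redundancy reduction
(e.g. CD-HIT at 0.7 identity) is deliberately an *external* pre-step:
run it on the FASTA before loading.

Network confidences are stored internally in (0, 1]. STRING-style
files publish integer scores (150–999); `score_scale="thousandths"`
divides by 1,000 at read time. Duplicate undirected pairs keep the
maximum score (deterministic and order-independent); self-edges are
rejected.

## Encoders

**Network features.** The feature vector of a query is its weighted
adjacency row over the fixed node index: feature `net:v` equals the
confidence of the direct interaction with `v`, else 0. A query absent
from the network encodes as all zeros rather than an error, so held-out
proteins can still be scored.

**Enrichment features.** The neighborhood set `PS` includes the query
itself plus all partners above `min_confidence` (default 0: every edge
counts, since interaction confidence already weights the network
features and a second cutoff would be an extra free parameter). The
hypergeometric test is upper-tail (over-representation) and exact via
`scipy.stats.hypergeom.sf`. The background universe defaults to the
network nodes that carry at least one annotation (nodes ∩ union of
catalog members) and is overridable — the benchmark, for instance,
uses all network nodes so that unannotated background proteins dilute
the draws. p-values are floored at 1e-300 before `−log10` to avoid
infinities; terms with no member in the universe score 0 with a logged
warning. Scores are therefore always ≥ 0 and, with K, n, N fixed,
non-decreasing in the overlap k.

**PseAAC.** Layout: 20 amino-acid composition components (plain
frequencies, summing to 1) followed by five blocks of λ sequence-order
factors, one block per property, in the declared order
(codon diversity, electrostatic charge, molecular volume, polarity,
secondary structure — the five Atchley factors). The j-th factor of
property p is the mean squared lag-j difference of the property
profile, with each property table standardized to zero mean and unit
variance over the 20 residues (population SD) so that the five blocks
are scale-free. Block components are `w·θ_j / (1 + w·Σ_j θ_j)` with
w = 0.15 and λ = 50 by default (270 features). Classical single-block
PseAAC folds the composition and order terms into one simplex; the
per-block normalization used here keeps the five properties
independently scaled and the composition block an exact simplex, and
is declared rather than inherited from any particular legacy tool.
Sequences must be strictly longer than λ; the error message names the
minimum.

## Feature selection

**Boruta.** Per iteration, every undecided feature is paired with a
shuffled shadow copy; a random forest (100 trees, depth ≤ 7 — bounded
depth sharpens the real/shadow importance contrast and bounds cost) is
fit on the combined matrix; a feature scores a hit when its importance
exceeds the maximum shadow importance (percentile 100). Decisions use
a two-sided binomial test on the running hit count with a two-step
correction — Benjamini–Hochberg across the features in play, and an
`α/iteration` Bonferroni factor because the same feature is re-tested
every round. Without the second factor any feature whose hit
probability is even slightly above ½ is eventually confirmed, which
inflates false confirmations on pure noise. α = 0.05, up to 100
iterations with early stop. Note that Boruta tests *in-sample*
association: on small samples a noise feature with a large chance
correlation to the labels is genuinely associated in-sample and may be
confirmed; the pure-noise calibration test therefore bounds the
false-confirmation *rate* rather than asserting an always-empty set.

**mRMR.** Continuous features are discretized to three states at
μ ± 1σ per feature (constant features become all-zero). Mutual
information is the plug-in estimate from the empirical joint
distribution, in nats (the base cancels in the argmax). Ranking is
greedy MID: first the feature with maximal I(f; y), then repeatedly
the feature maximizing I(f; y) − mean I(f; s) over the already
selected s. All ties (within 1e-12) break lexicographically on the
feature name, making every ranking bit-reproducible. The quotient
variant (MIQ) is intentionally not offered.

Both methods only ever see original samples: SMOTE synthetics are
created downstream, inside CV training folds.

## IFS, SMOTE and scoring

Subset construction takes nested prefixes of sizes step, 2·step, …;
a remainder prefix is *not* appended (a ranked list of 4,773 features
at step 10 yields exactly 477 subsets; step 1 enables optima at
arbitrary sizes). Cross-validation is stratified 10-fold with seeded
shuffling; classes smaller than the fold count are spread as evenly as
possible (a 3-member class trains in every fold and appears in three
test folds). SMOTE runs in `train_folds_only` mode by default —
oversampling each training split to class parity, leaving test folds
untouched — with a `pre_split` mode (balance first, then fold) kept
for fidelity with workflows that balance the whole dataset up front,
at the cost of synthetic samples appearing in test folds. Each
synthetic sample is `x_i + u·(x_nn − x_i)`, u ~ U(0,1), with `x_nn`
among the `min(k, class_size − 1)` nearest same-class neighbors
(k = 5); singleton classes are duplicated verbatim.

Metrics are computed once on the pooled out-of-fold predictions (a
single confusion matrix, matching the indicator-matrix formulation of
the K-category MCC), not averaged across folds. The MCC denominator
being zero (constant predictor or constant truth) yields 0 by
convention. Classifier defaults: random forest 100 trees; SVM linear
kernel, C = 1, one-vs-one; kNN k = 1 Euclidean; decision tree CART
with Gini impurity and unlimited depth. All are overridable per run;
none is tuned.

Optimum = argmax MCC (ties to the smallest size); compact = smallest
size within 0.03 MCC of the optimum.

## Rule extraction

The interpretive tree is CART/Gini fit on *all* samples (no CV split)
over a chosen feature prefix, by default without SMOTE augmentation
(rules should describe the observed proteins; an augmented mode exists
behind a flag). Each leaf yields one rule; thresholds on a shared
feature are merged to the tightest interval, so a feature contributes
at most one lower and one upper bound per rule. Leaf ties resolve to
the first class in sorted order, identical to the tree's own argmax,
which is what makes the rule set reproduce the tree's predictions
exactly and fire exactly once per point. Thresholds print at 6
significant digits; JSON output keeps full precision.

## Synthetic benchmark

Defaults: 6 classes with geometric size decay 60 → 6 (153 proteins —
a tenth-scale version of the motivating data's 1,487→3 spread, small
enough that the 6-member class stresses the stratified-fold and
SMOTE `k_eff` logic while a full pipeline run stays under a minute);
5 hubs per class; 100 unannotated background nodes; member→own-hub
attachment probability `p_in = 0.3` at confidence U(0.7, 0.99);
member→foreign-hub `p_out = 0.02` at U(0.15, 0.5); 10 terms per class
and 50 noise terms split alternately between the pathway-like and
GO-like catalogs; term hit probability 0.6, noise membership 0.05;
sequence lengths U(100, 500) with per-class residue bias (uniform
blended with a Dirichlet(1) draw).

One deliberate coupling: a member joins its class terms only if it is
attached to at least one own-class hub. Annotation is modeled as
flowing through the interaction module, so *all* class signal —
network and enrichment alike — is carried by within-class
connectivity. This is what makes the null control meaningful: setting
`p_in = p_out` removes every class-informative feature, and the
pipeline's optimum CV MCC collapses toward 0, whereas unconditional
term membership would leak the label through the query's own
membership in `PS ∩ T` regardless of the network. Consequently the
~17% of members that happen to attach to no own-class hub
(`(1−p_in)^5 ≈ 0.17`) are near-featureless and bound the achievable
accuracy; the recovery experiments' MCC ≈ 0.8 reflects that ceiling,
not a classifier limitation.

Randomness uses a single seed expanded into per-component child
streams (network, terms, sequences), so the same seed reproduces
byte-identical output files. The generator is *not* a biological
simulator: it mimics neither STRING's score calibration nor the GO
DAG, and its classes are mutually exclusive, so passing recovery tests
demonstrates that the pipeline recovers planted structure under the
assumed signal model — not performance on real proteomes.

## Problem sizes and runtime choices

Tests and the acceptance script run the full pipeline on the default
benchmark (153 proteins, ~390 features after encoding) with IFS step 5
and three seeds for the stochastic recovery/null claims (majority
vote), keeping a complete run in the tens of seconds on one CPU.
Exhaustive oracle checks (hypergeometric tail, mutual information,
binary-MCC equivalence) run over small enumerable domains (N ≤ 12,
2×2 tables) where exact closed forms exist.

## Known limitations

* Identifier mapping between resources is the caller's problem.
* Enrichment treats annotations as flat sets (no GO-DAG propagation).
* Boruta/mRMR here are faithful re-implementations of the published
  algorithms, not bit-compatible replicas of any specific legacy
  binary; likewise the SVM is a standard solver with the documented
  kernel/C contract, not a specific SMO implementation.
* The hypergeometric background choice materially affects enrichment
  scores; it is explicit and overridable, but there is no
  auto-detection of the "right" universe.
* `pre_split` SMOTE leaks synthetic points into test folds by design;
  use it only to mirror legacy workflows.
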