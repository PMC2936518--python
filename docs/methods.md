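# Methods

## Problem setting

Synthetic-lethal (SL) prediction is a binary classification problem
over unordered gene pairs with two defining difficulties: the positive
class is rare (about 7% of labelled pairs in curated yeast
collections), and no single data source covers all pairs, so feature
values are pervasively missing. The package treats both explicitly:
test sets always keep the true skew, and a missing value is a
first-class marker (NaN) that is never conflated with zero.

## Networks and overlay features

Each data source is a weighted undirected network; edges are stored
under canonical (lexicographically sorted) pair keys, so lookups are
orientation-free, and self-loops are rejected. Duplicate edge entries
in an input file resolve to the weight of largest absolute value — the
strongest evidence, chosen because it is deterministic and
order-independent. Networks meant for overlays should first be
sparsified with per-network thresholds (`w > pos` or `w < neg`); the
thresholds are data-dependent and therefore required configuration
with no defaults.

The overlay of networks W₁ and W₂ scores a pair (A, B) as
max over intermediates C of w₁(A,C)·w₂(C,B), trying both leg
orderings. Three deliberate choices:

* the intermediate C may not be A or B, and the direct A–B edge never
  contributes — direct evidence lives in its own feature, and letting
  it enter the overlay would double-count it;
* products are *signed*: with negatively weighted (e.g. correlation)
  networks the maximum is taken over signed products. Sparsification
  bounds the pathological cases; taking |w| would conflate strong
  negative and strong positive evidence;
* when no intermediate has both legs, the value is missing, not 0.

The SL-independent catalogue pairs all input networks (C(m,2) specs
minus configured exclusions); the SL-dependent catalogue pairs the
known-SL network with each input plus itself. Inside cross-validation
the SL network is rebuilt per fold from the training positives only,
so SL-dependent features never see a test label.

## Direct features

* Pearson co-expression over shared finite samples (≥ 3 required,
  otherwise missing).
* Topological overlap TOM_ij = (l_ij + a_ij)/(min(kᵢ,kⱼ)+1−a_ij),
  l_ij = Σ_k a_ik a_kj over k ∉ {i, j}, computed on |w| so the
  adjacency stays in [0, 1] for signed inputs.
* Group co-membership counts (pathways, complexes, communities) read
  from GMT; unmapped genes count 0.
* Mutual information (nats) of binary phylogenetic profiles from the
  joint 2×2 empirical distribution; constant profiles give 0.
* Sequence-similarity and betweenness-style features are consumed as
  precomputed pair scores (e-values transformed to −log₁₀, capped),
  since their derivation data is outside this package's scope.

## GO semantics

Annotation probabilities are estimated per namespace after propagating
each gene's direct annotations to all ancestors (`is_a` and, by
default, `part_of` links); p(c) is the fraction of annotated genes in
c's namespace whose propagated set contains c, which makes p monotone
child → parent and 1 at each root. Lin similarity uses the minimum
subsumer — the common ancestor of smallest p, where "ancestor"
includes the terms themselves, so a term subsuming the other is its
own subsumer; ties break by term id. Edge cases are pinned down:
identical terms score 1 even when p < 1, and two terms both at p = 1
score 0 (no shared information content).

Gene-pair functional similarity finds, for every term of gene A, the
best Lin match in gene B's set and vice versa, and averages Lin
similarity over the *mutually* best pairs. The aggregation over the
mutual-best set is the arithmetic mean; best-match ties break toward
the higher similarity, then the smaller term id. An empty term set
(after restriction to terms with probabilities) yields a missing
value, not zero — absence of annotation is not evidence of
dissimilarity. The shared-function count uses *propagated*
annotations intersected with a curated term whitelist (supplied as
configuration; counting on raw direct annotations would make the
feature depend on annotation granularity conventions).

## Ranking

Feature discriminative power is the two-sample KS statistic
D = sup |ECDF_pos − ECDF_neg|, with the asymptotic p-value reported
alongside. Missing cells are dropped per feature (pairwise deletion):
ranking describes the data; imputation belongs to the modelling step.
D is invariant under monotone transforms, which makes the ranking
insensitive to feature scaling.

## Learning

Training under-samples negatives to floor(ratio · n_pos), uniformly
without replacement, positives always all retained; the default ratio
is 1 (balanced). Missing values are imputed with per-column means
computed on the (under-sampled) training table only; an all-missing
column falls back to 0 and is flagged. Six base-classifier families
mirror the usual make-up of such ensembles — SVM, feed-forward neural
network, a rule-style learner (implemented as a depth-capped decision
tree, the closest scikit-learn analogue of a sequential-covering rule
inducer), random forest, k-nearest neighbours and an unconstrained
decision tree — all with library-default hyperparameters, plus a
deterministic logistic family for fast runs. Probabilities are clipped
to [10⁻⁶, 1−10⁻⁶] so that hard 0/1 outputs cannot zero out the
products in the combiner.

The combiner is the difference-of-products score
Score = Πpᵢ − Π(1−pᵢ): bounded by [−1, 1], monotone in every pᵢ, and
antisymmetric under p → 1−p. The canonical product-only noisy-AND is
available behind `combiner="product"` for sensitivity analysis. A
useful property observed in the experiments below: when most pᵢ are
small the score is ≈ Σpᵢ − 1, i.e. the combiner behaves additively,
which makes the ensemble ranking robust to individual members that
collapse under class imbalance.

Cross-validation is stratified (guaranteeing both classes in every
fold and skew-preserving test folds), scores every example exactly
once with a model that excludes it, and derives all randomness — fold
assignment, under-sampling, classifier initialisation — from one seed
through named sub-streams. The least-connected split holds out the k
positive pairs of smallest min-degree in the known-SL network,
removes any training positive sharing a gene with them, and uses as
test negatives the negatives fully inside the test-positive gene set.

## Evaluation

AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted 0.5. Precision–recall is computed at
every distinct score with the zero-prediction limit anchored at
precision 1; calls are positive iff score ≥ threshold (ties therefore
count as calls), 0.2 by default.

## Synthetic studies

The generator partitions genes into modules and lets every data source
reflect module structure: dense high-weight within-module edges over a
sparse background (4 networks by default), module-factor expression
(correlation 0.7), module pathways with 5% spurious membership, module
phylogenetic profiles with 15% bit flips, and a complete tree ontology
whose leaves are assigned to modules so module-mates share specific
terms. Labels are planted by raising P(SL | same module) from the
baseline skew q toward 0.5 as signal_strength goes 0 → 1, while the
marginal positive fraction is held exactly at q = 0.071 with a
definition-forced positive count round(q · n_pairs); at
signal_strength 0 labels are independent of all data, an exact null.
The generator emulates module-mediated signal and class skew only: it
does not reproduce real-data properties such as scale-free degree
distributions, study-specific noise, or annotation bias, so passing
tests demonstrate correctness and signal recovery of the machinery,
not field performance on real screens.

Problem sizes used in the shipped experiments, chosen to make the
stochastic quantities stable at desk scale: signal recovery on 2000
pairs (300 genes, signal 0.8); null calibration on 5000 pairs; the
under-sampling-ratio comparison on a 12 000-pair study with 1.2%
positives (so a 50:1 training ratio is drawable from the negative
pool) and a gentler within-module boost (0.2); the positive-set-size
comparison on 20 000 pairs, 1420 positives.

In the ratio experiment the individual base classifiers degrade
markedly from ratio 1 to 50 (SVM and single trees lose 0.10–0.14 AUC,
k-NN 0.05) while the noisy-AND ensemble is largely protected by its
additive small-p regime; the shipped check therefore asserts the weak
form — balanced training is at least as good as 50:1 — rather than a
strict decline.

## Known limitations

* The rule-learner family is approximated by a shallow decision tree;
  no sequential-covering implementation is available in the stack.
* Overlay computation is exact (exhaustive over intermediates), O(min
  neighbourhood) per pair; no indexing for genome-scale all-pairs
  scans is provided.
* Mean imputation is deliberately simple; fold-wise model-based
  imputation would change the SL-dependent comparisons.
* The asymptotic KS p-value is inaccurate for very small samples; D,
  not p, is the ranking key.
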