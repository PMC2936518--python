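# synlet

Prediction of synthetic-lethal (SL) gene pairs from heterogeneous
genomic data.

Two genes are synthetic lethal when deleting either alone is viable but
deleting both kills the cell. SL interactions expose functional
redundancy — parallel pathways, buffering complexes — and are central
to genetic-network biology and to tumour-selective drug-target
discovery. Even in yeast only a small fraction of the ~18 million gene
pairs has been screened, which makes computational ranking of candidate
pairs valuable. `synlet` is a toolkit for researchers who want to train
and evaluate such predictors: it extracts pair features from many data
sources at once, ranks them, trains a classifier ensemble under heavy
class imbalance, and evaluates with skew-preserving cross-validation.

## Method

**Multi-network overlay features.** Every data source (co-expression,
physical interaction, GO functional similarity, …) is treated as an
undirected weighted network with genes as nodes. For two networks *W₁*,
*W₂* the overlay feature of a pair (A, B) is the strongest transitive
link through any third gene C:

    O(W₁, W₂)(A, B) = max_C  w₁(A, C) · w₂(C, B)      (either leg ordering)

with a *missing* value when no intermediate has both legs — a weighted
generalisation of the binary "2-hop" indicator. Direct features
(edge weights, Pearson co-expression, topological overlap, pathway
co-membership, phylogenetic-profile mutual information, BLAST scores)
complete the catalogue. Overlays that include the known SL network
itself are *SL-dependent* and are rebuilt inside cross-validation from
training-fold positives only.

**GO functional similarity.** Per-term annotation probabilities p(c)
are estimated with ancestor propagation; term similarity is Lin's
measure sim(c₁, c₂) = 2 ln p(ms) / (ln p(c₁) + ln p(c₂)) through the
minimum subsumer ms (the common ancestor of smallest p); gene-pair
similarity averages Lin similarity over the mutually-best-matching term
pairs of the two genes' annotation sets.

**Feature ranking.** Each feature's discriminative power is the
two-sample Kolmogorov–Smirnov D-statistic between its SL and non-SL
distributions.

**Ensemble classification.** Negatives are randomly under-sampled to
`ratio` × positives for training only. Six base classifiers (SVM,
neural network, rule learner, random forest, k-NN, decision tree) are
fitted on the same mean-imputed balanced table and combined by a
noisy-AND score

    Score(x) = ∏ᵢ pᵢ(x) − ∏ᵢ (1 − pᵢ(x)) ∈ [−1, 1],

where pᵢ(x) is classifier i's SL probability. Evaluation uses
stratified cross-validation in which test folds keep the true class
skew, ROC/AUC, precision–recall and a configurable call threshold
(0.2 by default).

A seeded synthetic-study generator (`synlet.synthetic`) plants SL
signal through gene modules across every data source, so the entire
pipeline is testable end to end without downloads.

## Worked example

```sh
synlet simulate --out fx --seed 7 --n-pairs 1000 --n-genes 200
# wrote fixture to fx: 200 genes, 1000 pairs (71 SL)
synlet features --fixture fx --out matrix.tsv
# wrote 1000 x 15 feature matrix to matrix.tsv
synlet rank --matrix matrix.tsv --pairs fx/pairs.tsv --out ranking.tsv
#        feature        D      p_value  n_pos  n_neg
#  O(net0, net3) 0.625128 5.205245e-16     50    234
#   coexpression 0.615867 1.272175e-24     71    929
#  O(net0, net2) 0.612311 5.052003e-16     53    221
#  ...
synlet cv --matrix matrix.tsv --pairs fx/pairs.tsv --out scores.tsv --folds 10 --seed 7
# cross-validated AUC: 0.8016 (scores written to scores.tsv)
synlet evaluate --scores scores.tsv --pairs fx/pairs.tsv
# {"auc": 0.8016, "threshold": 0.2, "n_called_sl": 98,
#  "precision_at_threshold": 0.4184, "recall_at_threshold": 0.5775}
```

The ranking shows overlay and co-expression features carrying most of
the planted module signal (D ≈ 0.55–0.63, vanishing KS p-values); the
ensemble recovers the signal with a cross-validated AUC of 0.80 despite
the 7% positive skew, and at the 0.2 score threshold calls 98 pairs SL
with 42% precision at 58% recall.

The same operations are available as library functions
(`synlet.overlay_value`, `synlet.rank_features`, `synlet.cross_validate`,
…) for use in scripts and notebooks.

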