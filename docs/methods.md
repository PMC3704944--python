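# Methods

## Overview

`drugrepo` predicts the therapeutic class of a drug — its ATC level-2 code
(*therapeutic subgroup*, e.g. `L01` antineoplastic agents) — from three
independent kinds of evidence, and then deliberately re-reads the
classifier's stable mistakes as drug-repositioning hypotheses. The premise
is that a drug which is *systematically* assigned to a class other than its
registered one, by a classifier that is otherwise accurate, resembles the
members of that other class in chemistry, targets and transcriptional
response — which is exactly the profile of a repurposing candidate.

The pipeline has five stages:

1. three drug–drug dissimilarity layers;
2. fusion into a joint matrix and a class-size filter;
3. Euclidean embedding by classical multidimensional scaling (cMDS / PCoA);
4. dimension selection by cross-validated SVM error, then a Gaussian-kernel
   multiclass SVM;
5. repeated 90/10 holdout subsampling, accumulating per-drug prediction
   distributions that are converted into scored repositioning records.

## Dissimilarity layers

**Chemical** (`layers.chem_dissimilarity_matrix`). Drugs are compared as
fixed-length binary substructure fingerprints, read as sets of on-bits.
With Jaccard index `JI`, cosine similarity `CS` and Dice coefficient `DC`,

    K_CHEM(i, j) = 1 − (JI + CS + DC) / 3.

The three measures are highly correlated; averaging them smooths their
individual biases (JI penalizes size imbalance hardest, DC least). The
value is 0 iff the fingerprints are identical and 1 iff they are disjoint.
The fingerprint type and length are configuration: any fixed-length binary
vector works, and an optional RDKit backend derives Morgan fingerprints
from a SMILES table.

**Target** (`layers.target_dissimilarity_matrix`). Two components, averaged:
`K_TAR′` applies the chemical formula to each drug's set of target
proteins, and `K_TAR″` is the length (in edges) of the shortest path in a
protein–protein interaction network between any target of one drug and any
target of the other, range-normalized over all drug pairs. The overlap term
is coarse (most drug pairs share no targets at all); the path term restores
granularity by crediting targets that are close in the interactome even
when not identical. Drugs sharing a target get raw distance 0. Targets
absent from the network are ignored during the path search; if no finite
path exists for a pair, the pair receives the longest finite raw distance
observed in the cohort plus one — maximally dissimilar, but finite, so
range normalization stays well defined.

**Expression** (`layers.wsf_dissimilarity_matrix`). Each drug's
transcriptional response is summarized upstream (limma-style) as a p-value
and fold-change sign per gene. Genes are ranked so that significantly
over-expressed genes come first, significantly under-expressed genes last,
and non-significant genes sit in the middle; ties get average ranks. The
pairwise distance is a weighted Spearman's Footrule

    WSF(i, j) = Σ_g |R_i(g) − R_j(g)| · (W_i(g) + W_j(g)) / 2,
    W(g) = 1 − p(g),

range-normalized over the cohort. The weights make the distance dominated
by genes that at least one of the two drugs perturbs significantly; rank
disagreements among noise genes contribute little.

*Ranking key.* The sort key is `−fc_sign · (1 − p)`: over-expressed genes
get negative keys whose magnitude grows with significance, under-expressed
genes the mirror image. A superficially simpler key, `−fc_sign · p`, orders
*high*-p over-expressed genes first and is inconsistent with the intended
semantics ("significant over-expression at the top"); it is retained behind
`rank_key="literal"` so the two conventions can be compared, but the
default is the semantically correct one.

## Fusion and filtering

The joint matrix is the unweighted elementwise mean of the three layers
over the drugs present in all of them. Equal weights are the neutral choice
given no held-out data to tune against; all three layers are on [0, 1]
after range normalization, so the mean is commensurate. Drugs without a
label are dropped, then every class with fewer than `min_class_size`
members (default 8) is removed: smaller classes cannot be stratified into 6
folds and destabilize both the dimension search and the holdout loop.

## Embedding and classification

The fused matrix is a biologically motivated dissimilarity, not a
Euclidean distance, and kernel classifiers applied to it directly perform
poorly. Classical MDS provides the repair: double-center the squared
dissimilarities, `B = −½ J K∘² J`, eigendecompose, and use coordinates
`V₊ Λ₊^½` over the strictly positive eigenvalues. Negative eigenvalues
(the non-Euclidean part of the signal) are discarded rather than corrected
by additive constants; positivity is judged against a relative tolerance of
`1e-9 ×` the largest eigenvalue to absorb floating-point noise around zero.

The classifier is a multiclass SVM with Gaussian kernel
`k(x, y) = exp(−γ‖x−y‖²)` (scikit-learn's `SVC`, one-vs-one voting).
Defaults: `C = 1` and the variance heuristic `γ = 1/(d · var(coords))`;
both are configuration, and nothing in the pipeline tunes them against
outcomes.

**Dimension selection.** For each candidate dimension `i`, the stratified
6-fold cross-validation error of the SVM on the first `i` principal
coordinates is computed with the fold assignment and hyperparameters held
fixed across `i`; the selected dimension is the raw arg-min, ties broken
toward the smaller dimension (no smoothing of the error curve is
attempted). Leading coordinates carry class structure; trailing ones are
mostly noise, so the curve typically falls sharply and then drifts upward.
Stratification is used because unstratified folds can empty an eight-member
class; the folds are seeded for reproducibility.

## From misclassifications to repositioning

`reposition.bootstrap_predict` repeats, for `iterations` rounds (default
10 000; the tests and the acceptance script use 500 at desk scale): sample
90% of the drugs without replacement as the training set, train the SVM,
predict the held-out 10%, and increment each held-out drug's count for the
predicted class. Sampling *without* replacement matches the definition of
the holdout scheme (each training set contains 90% of the drugs); it is
repeated random subsampling rather than a with-replacement bootstrap.
Predictions are accumulated for held-out drugs only, so every count is an
out-of-sample prediction and the same counts support both the accuracy
estimate and the repositioning scores (`accumulate` over all drugs would
mix in-sample predictions into the scores). Training subsets that lose all
but one class are resampled. Drugs never held out by chance receive
targeted extra iterations so every drug has at least one prediction.

For drug `j`, the score of class `i` is `S_ij = counts_j[i] / n_eval_j` —
the frequency of `i` among `j`'s out-of-sample predictions; the scores over
classes form a probability distribution. The most frequent class (ties
broken lexicographically and logged) is the final prediction; the overall
accuracy is the fraction of drugs whose final prediction equals their
label. Every *other* predicted class yields a repositioning record scored
by `S_ij`, with `S = 1` — the drug is reassigned to the same foreign class
in every single iteration that held it out — the strongest evidence level.
Two accuracies are reported: the mode-prediction accuracy above and the
pooled per-prediction holdout accuracy; on a stable cohort they are close,
and both are computed rather than conflated.

## Synthetic cohorts

`synthetic.generate_cohort` produces cohorts with known structure planted
coherently in all three layers, so that every stage — and the
repositioning logic specifically — can be validated against ground truth
without any external database:

* **Chemistry.** Each class has a random fingerprint prototype (bits set
  with density 0.2); members flip each bit independently with probability
  `fp_flip_rate` (default 0.05). Expected within-class Hamming distance is
  `2·L·f·(1−f)`, which the tests check at L = 512.
* **Targets.** The interactome is an Erdős–Rényi graph (default 300
  proteins, edge probability 0.02 → mean degree 6; a Barabási–Albert
  option exists because real interactomes are heavy-tailed). Each class
  owns a connected 6-protein module, grown by randomized breadth-first
  expansion and disjoint from other modules; members draw a random subset
  of their module as targets. Within-class target distances are therefore
  short, between-class ones long.
* **Expression.** Of 1000 genes, each class owns a 30-gene block whose
  p-values are scaled uniform (`p = 0.01·u`, `u ~ U(0,1]` — strictly
  positive, monotone in the scale parameter) with a coherent per-gene
  fold-change direction; all other genes get uniform p-values and random
  signs.
* **Planted repositionings.** A chosen fraction of drugs keeps the label
  of its class but receives all three feature layers from a different
  class; the truth table records each (drug, label class, feature class)
  triple. These drugs are the ground-truth repositioning candidates.

Defaults are 10 classes × 12 drugs — class structure at the scale of the
real application (dozens of classes over a few hundred drugs, min-8
filter), with a gene universe reduced from genome scale to 1000 for
desk-scale runtime. What passing tests show is that the method's machinery
is correct and that planted signal of realistic *shape* is recovered; the
generator does not emulate correlated gene–gene noise, overlapping target
modules, hub-dominated interactomes (unless the BA option is used),
multi-class drugs, or class-imbalanced cohorts, so recovery rates here do
not predict performance on real compendium data.

## Numerical and degenerate-case choices

* Range normalization maps off-diagonal entries through
  `(x − min)/(max − min)`; a degenerate range (all pairs equal) maps to
  all-zero rather than dividing by zero.
* Matrices are validated symmetric within `1e-12` with a zero diagonal,
  and symmetrized (mean of the matrix and its transpose) on construction;
  serialization uses 17 significant digits, so write→read round-trips are
  bit-exact.
* `log_fc = 0` maps to fold-change sign +1 (arbitrary but fixed).
* Similarities of two empty sets are undefined and raise; one empty set
  against a nonempty one yields similarity 0 (the zero-intersection limit,
  with cosine's 0/0 resolved to 0). Drugs missing a layer are excluded
  from that layer and hence from the fused intersection.
* An all-zero dissimilarity matrix has no positive eigenvalues and raises
  a degenerate-embedding error rather than returning an empty embedding.

## Limitations

* No statistical significance is attached to repositioning scores; `S` is
  a stability index, not a p-value.
* The class-size threshold, SVM hyperparameters and layer weights are
  fixed defaults, not optimized; the dimension search is the only
  data-driven model choice.
* Real-data headline numbers (hundreds of drugs, genome-wide expression,
  curated target and interaction databases) are outside what this package
  ships; the synthetic cohorts are analogues in structure, not in scale or
  noise character.
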