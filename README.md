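# drugrepo

Drug repositioning by re-reading a classifier's stable mistakes.

`drugrepo` predicts the therapeutic class of drugs — their WHO ATC level-2
code (*therapeutic subgroup*, e.g. `L01` = antineoplastic agents) — by
fusing three layers of drug–drug dissimilarity:

* **chemical structure**: `K_CHEM = 1 − (JI + CS + DC)/3`, the complemented
  mean of Jaccard, cosine and Dice similarities between binary
  substructure fingerprints;
* **molecular targets**: the mean of the same set measure on target sets
  and the range-normalized shortest-path length between target sets on a
  protein–protein interaction network;
* **gene expression**: a weighted Spearman's Footrule
  `Σ_g |R_i(g) − R_j(g)|·(W_i(g)+W_j(g))/2` between signed-significance
  gene rankings, with weights `W = 1 − p`.

The fused matrix `K̂ = (K_GEX + K_TAR + K_CHEM)/3` is filtered to classes
with ≥ 8 drugs, embedded by classical multidimensional scaling, and
classified with a Gaussian-kernel multiclass SVM whose embedding dimension
is chosen by 6-fold cross-validation. Repeated 90/10 holdout subsampling
then yields, for every drug `j`, a distribution of predicted classes; the
frequency `S_ij` of class `i` among those predictions scores each
alternative class. A drug persistently assigned to a foreign class
(`S = 1` at the extreme) is reported as a repositioning candidate, with the
classifier's overall accuracy vouching for the reliability of its
mistakes.

The package is aimed at computational drug-discovery work: it ships the
complete method plus a synthetic cohort generator that plants known class
structure — and deliberate mislabels — in all three layers, so the whole
pipeline is testable end to end without any external database.

## Worked example

Generate a cohort of 10 classes × 12 drugs in which 6 drugs carry the
features of one class but the label of another, then run the pipeline:

```bash
drugrepo simulate --outdir cohort --seed 7 --mislabel-fraction 0.05
drugrepo run --cohort-dir cohort --iterations 200 --seed 11 \
    --out report.tsv --flows flows.tsv
```

which prints

```json
{
  "n_drugs": 120,
  "n_classes": 10,
  "n_positive_eigenvalues": 64,
  "selected_dimension": 3,
  "cv_error_at_selected": 0.05,
  "mode_prediction_accuracy": 0.95,
  "holdout_accuracy": 0.9454166666666667,
  "n_repositioning_records": 6
}
```

120 drugs survive the class-size filter; the fused matrix has 64 positive
eigenvalues and the cross-validated error is minimized by a 3-dimensional
embedding. 114 of 120 drugs (95%) are assigned their own class; the 6
exceptions are exactly the planted mislabels, and `report.tsv` shows each
reassigned to its true feature class with perfect stability:

```
drug_id  original_atc2  predicted_atc2  score  n_eval  is_confirmation
d000     A01            C01             1      20      0
d019     B01            D01             1      19      0
d061     F01            I01             1      20      0
...
```

`score = 1` means the drug was predicted into the foreign class in every
iteration that held it out — the strongest repositioning evidence the
method produces. `flows.tsv` aggregates the records into a score-weighted
class-to-class edge list for drawing a repositioning flow network.

The same steps are available piecewise (`drugrepo layers`,
`drugrepo integrate`, `drugrepo embed`, `drugrepo select-dim`,
`drugrepo reposition`) and as a Python API (`drugrepo.run_pipeline`).

## Layout

* `src/drugrepo/io.py` — TSV readers/writers for all five input tables and
  bit-exact matrix serialization
* `src/drugrepo/layers.py` — the three dissimilarity layers
* `src/drugrepo/integrate.py` — layer fusion and class-size filtering
* `src/drugrepo/embed.py` — classical MDS, dimension selection, SVM
* `src/drugrepo/reposition.py` — holdout subsampling and scoring
* `src/drugrepo/synthetic.py` — cohort generator with planted structure
* `docs/methods.md` — full description of the model and its assumptions
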