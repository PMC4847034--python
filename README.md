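# qsarforest

Decision Forest consensus modelling for QSAR binary classification, built
around the problem of predicting whether an environmental chemical binds rat
α-fetoprotein (AFP), a serum transport protein that competitively sequesters
estrogens and thereby modulates a chemical's endocrine-disruption potential.
The package is for computational toxicologists and cheminformaticians who
have a table of 2D molecular descriptors (e.g. Mold² output) with binary
activity calls and want a small, interpretable consensus model together with
the validation machinery such models require.

## The model

A **Decision Forest** is a consensus of a fixed, small number of
classification trees (five by default) forced to be *heterogeneous*: tree 1
is fitted on the full descriptor pool, and every descriptor it uses is
removed from the pool before tree 2 is fitted, and so on — no two trees share
a descriptor, and descriptor selection is wrapped inside model construction.
Each tree is CART-style: splits maximize the decrease of the Gini diversity
index `G = 1 − p₁² − p₀²`, a node is split only if it holds at least 10
training chemicals, and after growing, subtrees in the bottom 3 levels are
collapsed whenever that does not increase the number of misclassified
training compounds.

The consensus prediction for a chemical is the mean of the trees' leaf
binder proportions, a continuous `p ∈ [0, 1]`; the chemical is called a
binder when `p ≥ 0.5`, and every call carries a confidence

    confidence = |p − 0.5| / 0.5 ∈ [0, 1],

which stratifies predictions by reliability: calls at high confidence are
empirically far more accurate than calls near the decision boundary.

Model assessment follows the canonical protocol: repeated 5-fold
cross-validation (accuracy, sensitivity, specificity, MCC, balanced
accuracy, fold-averaged then summarized over repeats), a label-permutation
(y-scrambling) null to rule out chance correlation, a 20-bin
confidence/accuracy profile, and informative-descriptor identification —
a descriptor used by more CV models than the top-5% usage frequency of the
permutation background is informative at the 5% level.

Because the original 125-chemical descriptor matrix is not distributed, the
package includes a synthetic generator that reproduces its statistical
shape (125 × 777 with 265 constant columns, 53:72 class balance, 16 planted
informative descriptors, correlated noise blocks) with ground truth, so the
whole pipeline is testable end to end.

## Worked example

The external validation of the published rat-AFP model is reproducible from
the 22 literature chemicals shipped with the package
(`python examples/external_validation.py`):

```
external set: 22 chemicals (17 binders, 5 non-binders)
confusion: TP=7 FN=10 TN=5 FP=0
          accuracy: 0.545
       sensitivity: 0.412
       specificity: 1.000
               mcc: 0.370
 balanced_accuracy: 0.706
```

No non-binder was called a binder (specificity 1.000) while many binders
were missed (sensitivity 0.412), giving a balanced accuracy of 0.706.

On default synthetic data the full pipeline
(`python examples/cross_validation_and_null.py`) prints

```
cross-validation (mean +- sd over 10 repeats):
            accuracy: 0.766 +- 0.028
   balanced_accuracy: 0.764 +- 0.030
permutation null accuracy: 0.511 +- 0.041 over 20 permutations
empirical p-value of the observed accuracy (0.766): 0.048
```

— the signal CV distribution sits well clear of the y-scrambled null, and
the p-value is at the add-one floor for 20 permutations. The other examples
cover training/prediction, the confidence profile and descriptor recovery.

A thin CLI wraps the same functions:

```
qsarforest synth    --out-dir data --seed 0
qsarforest crossval --data data/dataset.csv --out-dir cv --seed 1 --n-repeats 10
qsarforest permtest --data data/dataset.csv --out-dir null --seed 2 --n-permutations 10
qsarforest train    --data data/dataset.csv --out-dir model
qsarforest predict  --data new_chemicals.csv --model model/model.json --out-dir preds
```

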