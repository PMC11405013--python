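# ppihotspots

Prediction of protein–protein-interaction (PPI) **hot-spot residues** from
the *unbound* (free) structure of a protein.

Hot spots are the small set of residues whose mutation substantially
impairs a binding interaction (classically, alanine mutation with
ΔΔG^bind ≥ 2 kcal/mol; more broadly, any mutation curated as disrupting the
interaction). Most predictors need the complex structure; this package
targets the much harder setting where only the free protein is available —
the situation a biologist is usually in before planning mutagenesis.

## What it computes

For each residue *i* of a selected chain, four features:

| feature | meaning | units |
|---|---|---|
| k_C | conservation grade from a homolog alignment (9 = most conserved) | 1..9 |
| aa | amino-acid type | categorical |
| SASA_i | Shrake–Rupley solvent-accessible surface area, probe 1.4 Å | Å² |
| ΔG_i^gas | gas-phase MM energy vs. an extended reference, E^int + E^vdW + E^ele | kcal/mol |

A stacked ensemble (multilayer stacking with repeated k-fold bagging and
greedy F1-maximizing ensemble selection, re-implemented over a scikit-learn
learner registry) maps the features to a hot-spot probability; residues with
probability > 0.5 are called hot spots. Two geometric callers are provided
for comparison and combination: a probe-consensus mode (residues in vdW
contact with the largest consensus site of docked probe clusters) and a
predicted-interface mode (interface residues of a modeled complex, 5 Å
cutoff), plus their union combination and the benchmark metric arithmetic

    sensitivity = TP/(TP+FN)   precision = TP/(TP+FP)
    F1 = 2TP/(2TP+FP+FN)       specificity = TN/(TN+FP)

See `docs/methods.md` for the full model description and its limits.

## Worked example

The classifier is a scikit-learn estimator and composes with sklearn
tooling:

```python
from ppihotspots import (SyntheticSpec, make_labeled_dataset,
                         StackedEnsembleClassifier, permutation_importance)

X, y = make_labeled_dataset(SyntheticSpec(seed=0))   # 2400 labeled residues
model = StackedEnsembleClassifier(
    learners=("gradient-boosted-trees", "random-forest", "logistic"),
    n_layers=2, k_folds=5, n_repeats=1, random_state=0,
).fit(X, y)
print(round(model.validation_f1_, 3))                 # 0.708
print(permutation_importance(model, X, y, n_repeats=3, seed=0).ranking)
# ['k_C', 'sasa', 'e_gas', 'aa']
```

The validation F1 (0.708 here) is the out-of-fold F1 of the selected
ensemble at the 0.5 calling threshold; the permutation ranking recovers the
generator's coefficient ordering (conservation strongest, amino-acid type
weakest once the numeric features are present).

The same operations exist as a CLI (`simulate`, `featurize`, `conserve`,
`sasa`, `energize`, `train`, `crossval`, `predict`, `evaluate`,
`interface`, `ftmap-call`, `combine`). Evaluating a published confusion
table directly:

```console
$ ppihotspots evaluate --counts 278,87,417,136 --out metrics.json
sensitivity=0.67  precision=0.76  f1=0.71  specificity=0.83
```

i.e. of 414 true hot spots 67% are recovered, 76% of calls are correct, and
83% of true non-hot spots are left uncalled.

Every command writes a `.manifest.json` (arguments, seed, version) next to
its output so a run can be replayed.

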