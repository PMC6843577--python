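# hepatoscreen

QSAR classification of drug-induced liver injury (DILI) and a three-channel
computational screen for hepatotoxic ingredients in herbal medicines
(Traditional Chinese Medicines, TCMs).

## Who this is for

Computational toxicologists and cheminformaticians who need to (a) train and
validate binary hepatotoxicity classifiers from molecular fingerprints and 2D
descriptors, and (b) screen the ingredient list of a herbal preparation for
likely hepatotoxicants by combining a trained classifier with curated
evidence sources.

## The method

**Combined classifier.** Compounds carry a binary label (hepatotoxic vs
non-hepatotoxic). Thirteen descriptor families — twelve binary fingerprint
families and one continuous 2D-descriptor block — are computed behind a
pluggable backend (RDKit reference backend included, plus a hashed fallback).
Each family passes a three-stage selection cascade:

1. **Boruta** all-relevant filtering: real features must repeatedly beat the
   best of their shuffled "shadow" copies in random-forest importance;
   confirmation/rejection by Bonferroni-corrected binomial tests.
2. **Correlation pruning** at Pearson |r| > 0.90 (caret-style
   `findCorrelation`: of the worst pair, drop the member with the larger mean
   absolute correlation).
3. **RFE** to a complete ranking (eliminate one least-important feature per
   round until one remains).

Eight learning algorithms (Naive Bayes, RBF-SVM, KNN, a K*-style entropic
instance learner, boosted trees, bagged KNN, a pruned decision tree, random
forest) are then swept over every ranking prefix, k = p…1; the subset
maximizing mean(AUC, ACC/100) defines each learner's best single classifier.
The eight best single classifiers' hard calls become eight binary
meta-features for a Bernoulli Naive Bayes **stacked meta-classifier**, whose
posterior P(hepatotoxic) is thresholded strictly at 0.500.

Performance uses the standard confusion-matrix metrics, with ACC on the
0–100 scale and the rest on 0–1:

    ACC  = 100 · (TP + TN) / N          SE = TP / (TP + FN)
    SP   = TN / (TN + FP)               BACC = (SE + SP) / 2

plus AUC from ROC analysis (ties half-weighted). Cross-validation is
stratified 10-fold with pooled-fold confusion matrices; robustness is
certified by 100-run Y-randomization (label permutation).

**Ingredient screen.** For a herb's ingredient list, three evidence channels
are integrated by union with provenance:

1. the combined classifier (P(hepatotoxic) > 0.500),
2. exact normalized-name matching against a curated herb-induced liver
   injury (HILI) ingredient dictionary,
3. neighbours of the herb in a curated bipartite herb–hepatotoxic-ingredient
   network.

A self-contained case study for *Polygonum multiflorum* Thunb ("He Shou Wu")
ships as package data, including the expected channel memberships.

## Worked example

```python
import hepatoscreen as hs
from hepatoscreen.evaluate import ConfusionMatrix, compute_metrics

# metric arithmetic on a 2191-compound confusion matrix
report = compute_metrics(ConfusionMatrix(tp=768, tn=827, fp=315, fn=281))
print(report.display())

# the He Shou Wu screening case from package data
fx = hs.make_pmt_fixture()
s2 = hs.screen_subgroup2(fx.ingredients, fx.hili)          # HILI dictionary
s3, _ = hs.screen_subgroup3("He Shou Wu", fx.network)      # herb network
result = hs.integrate(fx.expected.subgroup1, s2, s3)
print("union:", len(result.union), "uniques:", result.unique_counts)
print(sorted(result.subgroup3 - result.subgroup1 - result.subgroup2))
```

prints

```
{'ACC': 72.798, 'SE': 0.732, 'SP': 0.724, 'BACC': 0.728, 'TP': 768, 'TN': 827, 'FP': 315, 'FN': 281}
union: 25 uniques: (15, 1, 3)
['chrysarobin', 'emodin dianthrone', 'polygonumnolide c2']
```

The confusion matrix of 1049 positives and 1142 negatives yields accuracy
72.798 %, sensitivity 0.732, specificity 0.724 and balanced accuracy 0.728.
The screen integrates the classifier channel (21 ingredients), the HILI
dictionary (6) and the network lookup (7) into 25 unique hepatotoxicants, of
which 15, 1 and 3 respectively are contributed by a single channel — the
three network-only hits are printed last.

The same workflow is scriptable from the shell:

```bash
hepatoscreen screen --ingredients pmt_ingredients.csv --hili pmt_hili.csv \
    --network pmt_network.tsv --herb "He Shou Wu" --no-classifier --out run/
hepatoscreen pipeline --config my_run.yaml   # featurize → select → sweep → stack → CV
```

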