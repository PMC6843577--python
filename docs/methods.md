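# Methods

This note documents the models, numerical choices and limitations of
`hepatoscreen` the way a maintainer would want them recorded. Everything
stated here is computed by the test suite or `scripts/acceptance.py`;
nothing is asserted beyond what the code demonstrates.

## Problem and data model

The endpoint is binary drug-induced liver injury (DILI): a compound is
hepatotoxic or non-hepatotoxic, with `unknown` allowed for screening inputs.
Compound tables carry an opaque id, a free-text name, an optional SMILES and
a label. Structures are standardized before keying: largest organic fragment
(salt/solvent stripping), charge neutralization, RDKit canonical SMILES as
the deduplication key. This standardization recipe is fixed by this package;
other reasonable recipes (tautomer canonicalization, isotope stripping)
would change keys for a small minority of structures. Unparseable SMILES are
warnings, not errors — name-based screening channels must still cover
structure-less ingredients such as large glycosides.

Name normalization (case-fold, hyphen→space, whitespace collapse) is
deliberately conservative: no synonym resolution, no fuzzy matching. A
dictionary channel built on it reports only exact normalized matches.

## Descriptor families and the backend contract

Thirteen families are declared with their reference widths: FP 1024,
ExtFP 1024, EStateFP 79, GraphFP 1024, MACCSFP 166, PubchemFP 881,
SubFP/SubFPC 307, KRFP/KRFPC 4860, AP2D/APC2D 780 (all binary) and a
continuous 2D-descriptor block (reference width 1444). The calculator is a
contract (`supports` / `featurize_one` / `feature_names`), because the
pipeline's algorithms are backend-agnostic and the historical calculators
(PaDEL, CDK) are JVM tools outside this package's dependency set.

Two backends ship:

* **RDKitBackend** (reference): native electrotopological-state (79) and
  MACCS (166) fingerprints; hashed RDKit path/Morgan/atom-pair/torsion/
  pattern fingerprints folded to the declared widths for the other binary
  families; the full RDKit 2D-descriptor block (~210 descriptors) for the
  continuous family. Count-variant families (SubFPC, KRFPC, APC2D) are
  represented as presence bits; the cascade downstream treats all binary
  families identically, so only the hashing basis differs between a family
  and its count variant.
* **HashedBackend** (fallback): salted SMILES character n-gram hashing plus
  a 16-column constitutional block. It exists so the full pipeline is
  exercisable without a chemistry toolkit; it is not chemically meaningful
  beyond gross composition.

Feature hygiene (`drop_degenerate`): continuous NaNs are imputed by column
median *before* the zero-variance test so that an all-NaN descriptor is
recognized as degenerate. Inside model pipelines, imputation is refit per
training fold (leakage-free); the hygiene-level imputation only gates the
variance filter and correlation analysis.

## Selection cascade

**Boruta.** Per iteration, shuffled shadow copies of all not-yet-rejected
features join the design; a random forest (default 100 trees; tests and the
acceptance script use 10–25 trees for speed) supplies importances; a real
feature scores a hit when it beats the *maximum* shadow importance. Two-sided
binomial tests on hit counts at `alpha` (default 0.05), Bonferroni-corrected
by the number of still-undecided features, confirm or reject. Features still
undecided at the iteration cap (default 100) remain *tentative* and are
treated as not selected — the downstream cascade consumes confirmed features
only. Null behaviour is checked empirically: over label-shuffled runs the
mean confirmed count stays below `alpha·p`.

**Correlation pruning.** The greedy reference algorithm: while any retained
pair exceeds the cutoff (default |r| > 0.90), drop the member of the worst
pair with the larger mean absolute correlation to all other retained
features; on ties, the earlier column is dropped. The post-condition
(max pairwise |r| ≤ cutoff) is asserted on random matrices. The matrix-level
function `find_correlation` is exposed separately because some published
worked examples are stated directly on correlation matrices that no actual
data matrix can realize.

**RFE.** sklearn's RFE with `n_features_to_select=1, step=1` and a seeded
random-forest importance estimator, yielding a complete ranking; rank 1 is
the last survivor. Elimination rounds are recorded (rank p leaves in round 1).

**Subset sweep.** For a ranking over p features, each prefix k = p…1 is
cross-validated with one *fixed* stratified partition shared across k, for
comparability of subset sizes; exactly p evaluations per family and learner.
The chosen k\* maximizes mean(AUC, ACC/100); ACC is rescaled to 0–1 before
averaging because the two metrics are conventionally printed on different
scales and raw averaging would let ACC dominate. Ties break toward smaller
k (parsimony). Learner failures at individual k are recorded and skipped,
not fatal. On the published per-family post-pruning widths this bookkeeping
gives 677 evaluations per learner and 5416 across the eight learners; those
widths ship as package data (`family_selection_widths.csv`) so the
bookkeeping is checkable without the original training set.

## The eight base learners

All learners expose sklearn's estimator API and are deterministic given
their seed. Continuous inputs get per-fold median imputation; distance and
kernel learners additionally get per-fold standardization.

| algorithm | implementation | tuned parameter (default grid) |
|---|---|---|
| naive_bayes | mixed Bernoulli/Gaussian NB (authored here) | — |
| svm_rbf | sklearn SVC, RBF kernel, Platt-calibrated probabilities | C ∈ 2^{−5..5}, γ ∈ 2^{−7..3} |
| knn | sklearn KNeighborsClassifier | K ∈ {1,3,5,7,9} |
| kstar | entropic-blending instance learner (authored here) | B ∈ {1,20,40} |
| adaboost_tree | sklearn AdaBoost over entropy CART | Cf ∈ {0.1,0.25,0.5} |
| bagging_knn | sklearn Bagging over KNN | K ∈ {1,3,5,7,9} |
| decision_tree | entropy CART with cost-complexity pruning | Cf ∈ {0.1,0.25,0.5} |
| random_forest | sklearn RandomForestClassifier | Depth ∈ {0,5,10,20}, 0 = unlimited |

Notable stand-ins, chosen because WEKA-exact ports are out of scope:

* **Mixed Naive Bayes**: columns whose training values are all {0,1} get
  Bernoulli likelihoods (Laplace α=1); the rest Gaussian likelihoods
  (variance smoothing 1e−9); one shared class prior.
* **K\***: the published learner weights instances by transformation
  complexity with a per-attribute blend chosen from a "sphere of influence"
  parameter B. Here each query solves (bisection) for the exponential
  distance scale making the effective neighbour count equal
  1 + (B/100)(n−1): B=0 reduces to 1-NN and B=100 to an unweighted vote, the
  same operational semantics with Euclidean distance standing in for the
  entropic measure.
* **Pruning confidence Cf** maps monotonically onto CART cost-complexity
  pruning, `ccp_alpha = 0.02·(1−Cf)`, preserving "smaller Cf = harder
  pruning"; the constant 0.02 puts the default grid in the regime where
  pruning visibly changes tree size on hundreds-of-compounds data.

Hyperparameter names are validated per algorithm (C, γ > 0; K ≥ 1;
Depth ≥ 0 with 0 = unlimited; 0 < Cf < 1; 0 ≤ B ≤ 100). Grid search scores
every cell with stratified k-fold CV and picks the argmax of
mean(AUC, ACC/100), ties toward the earlier cell in enumeration order.

## The stacked combined classifier

Each of the eight bases is bound to one descriptor family and one feature
subset. Its hard call (P > 0.500, strictly) becomes one binary meta-feature;
a Bernoulli Naive Bayes with Laplace +1 smoothing (eight binary features can
easily produce zero counts in folds) is the meta-model. Two meta-feature
modes:

* `resubstitution`: bases predict their own training compounds — the
  construction described historically, optimistically biased;
* `out_of_fold` (default): training meta-features come from cross-fitted
  base copies, so no base scores a compound it trained on.

Both are provided because the historical description does not disambiguate;
reports record which mode produced them. Meta-features are hard labels, not
probabilities, by design; a probability-input variant is out of scope. The
final label again uses the strict 0.500 threshold; a posterior of exactly
0.500 is non-hepatotoxic.

## Evaluation

Pooled-fold metrics: one confusion matrix over all k test folds (the WEKA
summary convention), not per-fold averages. Stratified partitions are seeded
and recorded for replay; every compound is predicted exactly once by a model
that never trained on it. AUC uses the rank statistic with half credit for
ties (trapezoidal ROC integral). Display rounding is round-half-up at three
decimals with a 9-decimal guard quantization, so decimal midpoints computed
in binary floating point — (0.725+0.720)/2 is stored as 0.722499… — still
round up as decimal arithmetic would (→ 0.723); internal values keep full
precision. Y-randomization permutes labels uniformly (class counts
preserved), reruns the full CV per run, and reports mean ± sd accuracy; on
balanced data the mean sits at 50 within Monte-Carlo tolerance. External
evaluation checks training/external disjointness by structure key and
reports raw cell counts alongside rates, since published rate/denominator
pairs are not always integer-consistent.

## Screening

Channel 1 excludes structure-less ingredients with an explicit notice
(channels 2–3 still cover them). Channel 2 is exact normalized-name
intersection with the HILI dictionary. Channel 3 returns the herb node's
neighbours; an unknown herb yields an empty set plus a notice, not an error.
Integration is a union with per-ingredient provenance and per-channel unique
counts; it is commutative and idempotent in its set arguments. Hierarchical
clustering of ingredient feature rows uses Euclidean distance with average
linkage by default — the linkage is a recorded parameter, because cluster
counts at a given cut depend on it and no single choice is canonical.

## Synthetic generator

`make_classification_set` plants three feature blocks: informative
(continuous: means ±effect/2 per class at unit variance; binary: bit
probability 0.5 ± gap/2), redundant (a parent plus calibrated Gaussian noise
or bit flips hitting the target correlation, default ρ = 0.95 — straddling
the 0.90 pruning cutoff from above), and label-independent noise. Class
balance is exact by construction; generation is byte-deterministic under a
fixed seed. What it does *not* emulate: real descriptor distributions
(heavy tails, block correlation across families, bit sparsity), label noise,
and applicability-domain structure. Passing tests on this generator
demonstrate the machinery's correctness and calibration, not field
performance on real chemistry.

Default study conditions used by the tests and the acceptance script:
n = 60–200 compounds, 1–5 informative features, effect sizes 1.5–3 (chosen
so that signal recovery is unambiguous for calibrated selectors while null
runs stay null), 20–50 repetitions for calibration properties, 5-fold CV at
these sample sizes (10-fold remains the default for real data). The
importance forest is shrunk to 10–25 trees in repeated-run properties; this
trades a little selection power for run time and does not affect the null
calibration being tested.

## The He Shou Wu fixture

The 25-ingredient membership table of the three channels, the herb's star
network (7 edges) and the 6-name HILI subset ship as package data, making
the case study a self-contained regression test: channels of size 21/6/7,
union 25, unique contributions 15/1/3. The query ingredient table holds the
22 ingredients present in the herb's ingredient list (the three network-only
hits are deliberately absent from it); SMILES are included for the
anthraquinone/flavonoid/small-acid subset and deliberately omitted for six
obscure ingredients to exercise the structure-less path. The fixture's
channel-1 memberships are recorded data, replayed through stub bases when a
test or the acceptance script needs the classifier channel without the
original training set.

## Known limitations

* The historical descriptor calculator (PaDEL 2.21) is not reproduced
  bit-for-bit; family widths beyond EStateFP/MACCSFP are emulated by
  hashing. Models trained with different backends are not interchangeable.
* The full-dataset reproduction (combined-classifier CV accuracy ≈ 72.8,
  Y-randomization ≈ 50.85) requires the original curated training set,
  which is not redistributable with the package; the corresponding test
  documents the expected file location and fails until it is provided.
* K\* and C4.5-style pruning are behavioural stand-ins (documented above),
  not ports; per-dataset agreement with WEKA is not guaranteed.
* No applicability-domain estimation, no synonym resolution in name
  matching, no 3D descriptors.
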