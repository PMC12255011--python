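# Methods

`maap` classifies the functional activity of a ligand at a GPCR-A17 receptor
into three classes — antagonist (0), agonist (1), allosteric modulator (2) —
from a per-pair feature vector that concatenates the ligand's 2-D molecular
descriptors (a Mold2-style table), the receptor's protein-language-model
embedding, and optionally the pair's binding affinity (Ki, nM). This note
records the model, the procedural choices that were genuinely open, and what
the synthetic fixtures do and do not demonstrate.

## Curation

**Ki replicate deduplication.** Public bioactivity sources report several Ki
measurements for one ligand-receptor complex. The replicates are z-scored
against their own mean μ and standard deviation σ, values with |z| strictly
greater than 1 are discarded, and the survivor with |z| closest to zero (the
value closest to the mean) is retained as the single representative.

Choices where the procedure was open:

- σ is the population standard deviation (denominator N); the sample
  convention is available via `ddof=1`.
- The comparison is strict (|z| > 1 removes) with a 1e-9 numerical guard.
  The guard matters: a duplicate pair has z exactly ±1, and without it float
  rounding flags one of the two values nondeterministically.
- |z| ties (again the duplicate pair is the canonical case) break toward the
  smaller Ki, then first occurrence, so output is deterministic and invariant
  to input order and to unit rescaling.
- z-scores are computed once; survivors are not re-scored iteratively.
- A structural fact worth knowing: population z-scores satisfy Σz² = n, so
  any non-degenerate replicate set of n ≥ 3 values has max |z| > 1 — the
  strict threshold removes at least one value from *every* such set, not only
  from sets containing gross outliers. This is a property of the method, not
  of an implementation.

**Label conflicts.** Sources can disagree on the functional class of a pair.
Literature re-review cannot be automated, so the resolution policy is explicit:
`error` (default — surfacing conflicts is safer than silently voting),
`majority` (ties keep the earliest row's label), or `priority_file`.

**Zero-variance filtering.** Descriptor columns constant over the curated
dataset are removed before splitting (tolerance exactly 0.0); embedding
columns are exempt by scope. The filter is idempotent and errors if it would
remove an entire role.

## Splitting

Two-stage protocol. First an *independent ligand validation* holdout:
~10% of pairs built from whole ligand groups, so none of its ligands appears
on any receptor in the remaining data — this measures generalisation to novel
compounds. The remainder is split 80/10/10 into train / internal-validation /
test, stratified by class with largest-remainder per-class allocation
(proportions within one record per split).

All sizes use one rounding rule — round-half-up(fraction × n), clamped to
[1, n−1] — which reproduces the reference protocol's printed sizes exactly
(6,919 → 692 + 6,227 → 4,981/623/623; 4,274 → 427 + 3,847 → 3,077/385/385).
Ligand-group allocation is greedy over a seeded random ligand order with one
final swap pass toward the target count; any residual deviation is recorded
in the split manifest.

**Scaffold audit.** Chemical-series diversity per split is summarised over
Bemis-Murcko scaffolds: counts, unique/total ratio, Shannon entropy
H = −Σ pᵢ log₂ pᵢ and its normalisation H/log₂M (defined 0 at M = 1), novelty
of one split's scaffold set against another, and an overlap score defined
here as the Pearson correlation of relative-frequency vectors over the
scaffold union (undefined → NaN when a vector is constant). Acyclic molecules
share one empty-scaffold class, the standard convention.

## Models

Six learner families are registered (XGBoost, LightGBM, random forest, kNN,
logistic regression, and an optional MLP); the core pipeline uses the three
tree ensembles. Hyperparameter search is a seeded random search over spaces
declared in `search_spaces.yaml`, maximising macro F1 — the unweighted mean
of per-class F1, chosen because the class mix (~53/27/20%) makes accuracy
misleading. The default objective is mean macro F1 over stratified 3-fold CV
of the training split, which leaves the internal-validation split untouched
for the blending stage; scoring on the internal-validation split directly is
available via `objective_mode="holdout"`. The default budget is desk-scale
(50 trials); `--paper-budget` selects the reference protocol's 800.

**Blending.** The three tuned base learners fit on the training split. Their
predicted class probabilities on the internal-validation split form nine
meta-feature columns (model-major, class-minor), appended to the original
features; a metamodel of one of the same families — reusing its tuned
hyperparameters — trains on this widened matrix with the internal-validation
labels (1,649 → 1,658 columns for the full variant, 1,637 → 1,646 with Ki).
Meta-probability columns are not re-standardised (they are already bounded);
original columns keep the train-fitted scaler. Prediction appends the base
probabilities the same way; the label is the argmax with ties resolved to the
lowest class index. Guards enforce that the metamodel never sees training
rows at fit time and that train/internal-validation indices never overlap.
This is single-holdout blending, not k-fold stacking.

**Standardisation.** Zero-mean unit-variance scaling with parameters fitted
on the training split only (a flag allows fitting on all rows); columns
constant on the training rows get scale 1 and are flagged. The Ki column
enters in raw nM by default with an optional log10 transform.

**Evaluation.** All metrics derive from one-vs-rest confusion counts:
recall TP/(TP+FN), precision TP/(TP+FP), F1, specificity TN/(TN+FP), FPR
FP/(FP+TN), macro-averaged; one-vs-rest AUC uses the Mann-Whitney rank
statistic per class. Empty cells (0/0) are reported as 0 with a warning so
degenerate splits still produce deterministic reports. The implementation is
written directly from the formulas; scikit-learn serves as an independent
cross-check in the test suite only.

**Baselines.** Two deliberately simple references: (i) a frequency-aware
random classifier drawing each test pair's label from its receptor's training
class frequencies (global prior for unseen receptors), with the closed-form
expected accuracy Σ_c p_c q_c aggregated by test support; (ii) a per-receptor
1-nearest-neighbour on Morgan fingerprints (radius 2, 2048 bits, Tanimoto
similarity), same-receptor search with global fallback, similarity ties
resolved by majority label then lowest class. Both definitions are this
package's interpretation — fingerprint settings, k = 1 and tie rules are
config-overridable defaults.

## Synthetic data

The generator produces the three input tables plus a ground-truth record, at
a scale a workstation handles: 21 receptors, 400 ligands, 1,200 pairs
(≈1/6 of the reference dataset), 60 descriptors of which 8 are exactly
constant, 64 embedding dimensions, class mix 3,677/1,870/1,372 ≈
0.531/0.270/0.198.

**What it emulates.** Multi-source rows with replicate Ki measurements and
gross (×10) outliers; occasional conflicting labels; constant descriptor
columns; receptor-specific embedding centroids; class imbalance; and a class
signal that depends jointly on ligand and receptor — one ligand can be an
agonist at one receptor and an antagonist at another.

**Label model.** Each ligand has an archetype, expressed as a ±2 mean-shift
sign pattern on 6 informative descriptor dimensions (noise sd 1); each
receptor has a Gaussian embedding centroid. Bilinear scores between the
archetype patterns and the receptor's selected embedding dimensions rate
every (receptor, archetype) cell per class. A global archetype → class base
map honours largest-remainder quotas on the class mix, and each receptor
swaps the one archetype pair its bilinear scores favour most. Labels are
drawn from softmax(log(mix) + signal_strength × onehot(assigned class)):
signal 0 is the bare class mix, the default 40 is near-deterministic.

Two properties of this construction are load-bearing for the test suite:

- *Receptor neutrality.* Because every receptor keeps the same class
  composition, per-receptor label marginals approximate the global mix, so
  the frequency baseline stays at class-mix chance (Σp·q ≈ 0.38 on the
  preset) while the planted interaction signal is fully learnable — the gap
  between baseline and model is attributable to the joint signal alone.
- *Exact outlier bookkeeping.* Clean replicate sets have exactly two
  measurements (z = ±1, never flagged under the strict rule); outlier-bearing
  sets have 3-4 replicates with one ×10 value, which is always the single
  flagged value. The curation report's outlier count therefore equals the
  planted count exactly, giving the tests a sharp oracle. Replicate noise
  (0.1 log10 units) is kept well below the pair-level affinity spread
  (0.4 log10 units) and the 1-unit class separation of the Ki means.

**What it does not emulate.** The SMILES are parseable templates grouped into
scaffold families so scaffold code paths run, but their chemistry carries no
signal; descriptors are not Mold2 semantics and embeddings are not language-
model geometry; there is no assay noise structure, no related-ligand
correlation, and archetypes are far cleaner than real chemotype structure.
Passing the recovery tests shows the pipeline's plumbing, splitting hygiene,
tuning and blending machinery work end to end — it says nothing about
real-data accuracy.

## Numerical choices and degenerate inputs

- Population (ddof 0) standard deviations throughout, matching the scaler.
- dedup_ki: single values and zero-spread groups return the common value; if
  every value is flagged, the one with minimal |z| among the originals wins.
- Scaler: columns constant on training rows map to exactly 0.
- Metrics: 0/0 cells → 0 with a RuntimeWarning; AUC skips classes absent
  from y_true and macro-averages the rest.
- Argmax tie-breaks always resolve to the lowest class index.
- Feature matrices persist as TSV (%.17g) plus a JSON manifest; loading uses
  round-trip float parsing and refuses a file whose header disagrees with
  its manifest.

## Known limitations

- The tuning harness is an in-house seeded random search; it reproduces the
  contract (trial budget, stratified 3-fold CV, macro-F1 objective, full
  trial log) but not any specific TPE-style sampler's trajectory.
- The scaffold overlap score is one reasonable definition (Pearson over the
  union); strongly negative values are hard to obtain under it for large
  scaffold sets, and other definitions exist.
- Blending uses a single internal-validation holdout; with small validation
  splits the metamodel can overfit — the package warns rather than switching
  to out-of-fold stacking, which is deliberately out of scope.
- Desk-scale defaults (tuning budget, synthetic preset sizes) are chosen for
  iteration speed; reference-scale runs need `--paper-budget 800` and a real
  dataset.
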