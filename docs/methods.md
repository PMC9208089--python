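# Methods

`panmoiety` re-implements, as a tested pipeline, an analysis that asks which
chemical moieties make a compound a *pan-kinase-family inhibitor*: active
against at least half the member kinases of a family rather than against a
single kinase.  The pipeline has five stages — curation, featurization,
classification, attribution, analysis — plus a synthetic data generator that
plants known "driver" moieties so every stage can be held to ground truth.

## Curation

Bioactivity records come in two dialects: IC50 in nM (ChEMBL-style binding
assays) and pKi (profiling-panel style).  A record is **positive** when
IC50 < 500 nM or pKi > 6.3; both inequalities are strict, so a value exactly
at the threshold is negative.  Replicates of one kinase–compound pair are
resolved by voting: **active** when the positive fraction strictly exceeds
0.8, **inactive** when strictly below 0.2, otherwise **ambiguous** and the
pair is discarded.  The inclusive ambiguous band [0.2, 0.8] follows from
reading the published cutoffs as strict; a pair measured four-positive,
one-negative (fraction 0.8) is therefore discarded, not active.

A compound is an **active family inhibitor** (label 1) when it is called
active on at least half the family's M_f members.  Two conventions were
genuinely open and are exposed as options:

* `family_threshold` — with odd M_f, "half" is read as ceil(M_f/2)
  (default): 1 active call of 3 members is less than half.  `floor` gives
  the permissive reading.
* `inactive_scope` — compounds never tested against any member of a family
  are excluded from that family's dataset (default `tested`) rather than
  labeled 0 (`all`).  The denominator of the half-rule is always M_f:
  untested members count as not inhibited.

Families are retained for modelling when they have ≥ 250 labeled compounds,
≥ 2 member kinases, and (optionally) at least one member with a crystal
structure.  ChEMBL-style quality filters (relation "=", binding assay "B",
confidence 9) are applied at read time when those columns are present.

## Featurization

Each compound is a 238-bit presence/absence vector: 204 functional-group
features in the style of the Checkmol descriptor set plus 34 ring moieties
grouped by their typical interaction with the kinase ATP pocket
(3 electrostatic, 13 hydrogen-bonding, 10 hydrogen-bonding+vdW, 8 vdW).
Matching is RDKit SMARTS substructure search on the sanitized molecule, so
the vector is independent of the input atom ordering.  The bundled
dictionary carries working SMARTS for the ring moieties and the common
functional groups (pyridine is `f-224`, pyrimidine `f-225`, ether `f-37`,
the amine variants `f-47`–`f-54`, aromatic halogens `f-67`/`f-69`, amides
`f-82`/`f-87`, …); bit-exact parity with the external Checkmol program is
deliberately not promised — entries that only Checkmol perceives are named
placeholders that always report 0, and users who need them can load a
precomputed matrix with `load_feature_matrix`.

## Classifier

One feed-forward network per family maps the moiety vector to the
probability of being an active family inhibitor.  Defaults follow the tuned
configuration: hidden widths 1024/768/512/256, ReLU, batch normalization
after each linear map (before the activation), dropout 0.2 after the
activation, sigmoid output; Adam with learning rate 0.001 and batch size
32 on mean binary cross entropy; stratified 80/20 train/validation splits.
Epoch budget and stopping are unstated in the source analysis: the default
is at most 100 epochs with early stopping on validation loss (patience 10),
restoring the best-validation parameters.  Stratified rather than plain
random splitting prevents empty-class validation sets for imbalanced
families.  Experiments are repeated (`n_repeats`, default 100) with
independently derived seeds for split and initialization; metrics are
averaged.

The net is a compact numpy implementation (`panmoiety.nn`), exact-gradient
checked in the test suite against finite differences, and deterministic
given its seed.

Evaluation reports confusion counts at threshold 0.5, accuracy, Matthews
correlation (0 returned when a denominator factor vanishes), and ROC AUC by
the trapezoidal rule.  A historical half-sum variant (TPR+FPR)/2 appears in
some write-ups as "AUC"; it is not an area under any curve and is reported
separately as `auc_half_sum` for transparency, never used for selection.

## Shapley attribution

The trained classifier `f` is explained per compound by Shapley values over
the feature coalitional game with the **interventional** value function:
for a coalition S, features outside S are replaced by the corresponding
values of each background row and predictions averaged; `phi_0` is the mean
prediction over the background.  Two estimators:

* `shapley_exact` — full 2^M enumeration with the standard
  |S|!(M−|S|−1)!/M! weights; the oracle for M ≤ 12.
* `shapley_sampled` / `explain_dataset` — permutation Monte Carlo.  Each
  ordering contributes the telescoping marginal contributions from the
  empty to the full coalition, so `phi_0 + Σ phi_j = f(x)` holds exactly for
  any number of permutations; sampling error lives only in how the total is
  split.

Three numerical choices matter for dataset-level scoring and were validated
against the enumeration oracle:

1. **Content-keyed permutations.**  Each sample's orderings are seeded from
   the global seed plus a hash of its own feature values.  Duplicate rows
   receive identical attributions, while distinct rows draw independent
   orderings, so the truncated-permutation bias decorrelates across the
   dataset instead of shifting every sample's phi the same way (a shared
   permutation set does exactly that, and the shift does not shrink with
   sample count).
2. **Antithetic pairs.**  Odd orderings are the reverses of their
   predecessors, cancelling most position bias at no extra cost.
3. **Product-of-marginals background.**  The background is a deterministic
   binary matrix whose column means equal the dataset's feature
   prevalences (each column's count of ones is exact, positions seeded).
   A small random row subsample instead injects two nuisance terms —
   binomial noise in its column means and accidental feature
   co-occurrence — that propagate directly into per-feature scores.

Large masked-prediction batches may run in float32 (the pipeline does);
the ~1e-6 effect on phi is far below anything the class-contrast scores
resolve.  The standalone estimators stay in float64 and keep the 1e-9
efficiency guarantee.

## Importance score and selection

Per family, feature j's importance is the mean Shapley value over active
compounds minus the mean over inactive compounds.  Scores are standardized
into z-scores across the 238-feature axis (the reference population for z
is a per-family choice; standardizing across features matches selecting
"features that stand out within this model").  A feature is **selected**
when z > 1.96, ranked by score, truncated to the top 15; ties break by
feature id.  When several repeat models are supplied, phi is averaged
across models before scoring, damping initialization idiosyncrasies.

## Downstream analysis

* **Odds ratios** per feature from the 2×2 presence-vs-label table,
  (a·d)/(b·c), with Haldane–Anscombe +0.5 on all four cells when any cell
  is zero (flagged).  The Pearson r between importance scores and odds
  ratios over the selected features is the external-consistency check; the
  pipeline computes both statistics on the same compound subset, since
  computing them on different subsamples decorrelates their sampling noise
  and randomizes the sign when the selected features have near-equal
  association strengths.
* **Cross-family clustering** on the union of selected features:
  average-linkage agglomeration on 1 − Pearson r between family score
  vectors; family order is name-sorted for deterministic ties.
* **Moiety tagging**: a union feature is *common* when selected in at
  least ⌈0.75 × n_families⌉ families (configurable — the notion of
  "most families" is qualitative in the source analysis), *specific* to a
  family when selected there and in at most one family overall, otherwise
  *remainder*.
* **Occurrence**: for a moiety group and a ligand set, 100 × the fraction
  of ligands containing each moiety, averaged over the group.

## Synthetic data generator

The generator emulates the *statistical* shape of the curated compendium,
not its chemistry: there are no SMILES, compounds are binary feature
vectors directly.  Structure: a kinome of groups → families → kinases;
every feature bit i.i.d. Bernoulli(background_prevalence) — planted drivers
are no more prevalent than background, they act only through activity; a
logistic activity model per kinase–compound pair,
p = sigmoid(intercept + driver_effect × k), where k counts the drivers of
that kinase's family present in the compound.  Drivers come in three tiers:
common to all families, shared within one group, and family-specific.  The
group tier exists because common + family-specific drivers alone give every
family pair an identical expected profile overlap, leaving hierarchical
clustering nothing group-level to recover.  Replicates per tested pair are
uniform in `replicate_range`, split between IC50 and pKi records by
`assay_mix`; values land on the correct side of the curation thresholds
(log-uniform IC50 on (10, 500) / (500, 50000) nM, uniform pKi on
(6.3, 9) / (3, 6.3)) and flip sides with probability `label_noise`.
Randomness is hierarchical: each compound and pair derives its own stream
from the one seed, so enlarging the compound set leaves earlier draws
untouched.

What the generator does **not** emulate: realistic chemistry (feature
correlations from actual substructure nesting, e.g. quinoline implying
benzene), heterogeneous per-feature prevalences, assay-specific error
structure, or compounds tested on overlapping kinase panels.  Passing the
synthetic recovery tests therefore shows the pipeline's statistical
machinery is sound — not that the biology of any real compendium would
yield the same moieties.

### The bundled benchmark (`panmoiety.study`)

Four groups × two families (2–4 kinases each), 1,000 compounds, 60
features, 2 common + 1 group + 3 family-specific drivers per family,
saturated effects (intercept −50, effect +100: activity is exactly the OR
of the family's drivers), label noise 0.  Background prevalence is 0.25:
an identifiability analysis using *exact* enumerated Shapley values of the
true OR function (independent of the estimators) shows that with 1,000
compounds and 60 features the per-driver z-scores have irreducible spread
from the realized driver co-occurrence pattern, and at prevalences ≤ 0.15
the weakest driver sits too close to the 1.96 selection line for single-
driver recovery to be a fair expectation of any estimator; at 0.25 the
worst-case driver z is comfortably above it.  Pipeline sizing for a single
CPU: hidden (64, 32), 5 repeats, ≤ 60 epochs, attribution over 6 antithetic
permutations × 100 background rows on a 500-compound stratified subset,
averaged over 2 repeat models.

## Known limitations

* The 204 functional-group SMARTS are best-effort, not Checkmol-parity;
  analyses that depend on exact Checkmol bits must import Checkmol output.
* The numpy network trains single-threaded; the default 1024/768/512/256
  architecture at 100 repeats is sized for a framework, not for this
  implementation — use the benchmark-scale settings for experimentation.
* Permutation attribution cost grows as samples × permutations ×
  background × features; the defaults trade variance for runtime and are
  the knob to turn first on real data.
* `select_top_features` errors on zero score variance (z undefined) rather
  than guessing; constant-output models must be caught upstream.
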