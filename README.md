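# panmoiety

Moiety preferences of pan-kinase-family inhibitors: curation of
kinase–compound bioactivity into family-level inhibitor datasets, 238-bit
binary moiety fingerprints, one deep classifier per kinase family, and
Shapley-value attribution that contrasts active against inactive compounds
to find the moieties a family's inhibitors rely on.

## The problem

Inhibiting a single kinase often triggers compensatory upregulation of its
relatives; a *pan-family* inhibitor — one active against at least half of a
kinase family's M_f members — sidesteps that.  Given heterogeneous assay
tables (IC50 in nM, pKi), `panmoiety`:

1. **Curates** records into binary family-inhibitor labels: a record is
   positive iff IC50 < 500 nM or pKi > 6.3; replicates of a kinase–compound
   pair vote (> 80% positive → active, < 20% → inactive, otherwise
   discarded); a compound is a family inhibitor (label 1) iff active on
   ≥ M_f/2 members; families with ≥ 250 compounds and ≥ 2 kinases are kept.
2. **Featurizes** compounds as 238 binary moiety bits (204 functional-group
   features + 34 ring moieties, SMARTS matching via RDKit).
3. **Classifies** per family with a feed-forward net (default
   238→1024→768→512→256→1, ReLU, batch norm, dropout 0.2, Adam, binary
   cross entropy) over repeated stratified 80/20 splits, reporting
   ACC / ROC-AUC / MCC.
4. **Explains** the model with Shapley values φ_j (exact enumeration for
   ≤ 12 features, permutation sampling otherwise; efficiency
   φ₀ + Σφ_j = f(x) holds exactly), and scores each feature by

   ```
   importance_j = mean(φ_j | active) − mean(φ_j | inactive)
   ```

   selecting the top 15 features with z > 1.96 per family.
5. **Analyzes** selections across families: odds-ratio validation
   (OR = a·d/b·c with Haldane–Anscombe correction, Pearson r against the
   importance scores), hierarchical clustering of families on 1 − r of
   their importance profiles, tagging of moieties as *common* (selected in
   most families) versus *family-specific*, and moiety occurrence
   percentages in ligand sets.

A seeded synthetic generator plants known driver moieties behind a logistic
activity model so the whole pipeline can be validated against ground truth
without any external downloads.

## Worked example

Run the bundled synthetic benchmark — 4 kinase groups × 2 families,
1,000 compounds, 60 moiety features, with 2 common drivers, 1 driver per
group, and 3 family-specific drivers per family, at saturated effect sizes:

```python
from panmoiety.study import benchmark_config, benchmark_spec
from panmoiety.pipeline import run_full_pipeline

bundle = run_full_pipeline(benchmark_config(seed=1))
print(bundle["summary"][["group", "family", "n_active", "n_inactive", "ratio"]])
for family, m in bundle["metrics"].items():
    print(f"{family}: ACC={m['mean']['ACC']:.3f}  r={m['shap_or_pearson_r']:.2f}")
print("common moieties:", bundle["grouping"].common)
print("G1F1-specific:", bundle["grouping"].specific["G1F1"])
```

On one CPU this takes a few minutes and prints (seed 1):

```
  group family  n_active  n_inactive  ratio
0    G1   G1F1       826         174   4.75
1    G1   G1F2       820         180   4.56
2    G2   G2F1       825         175   4.71
3    G2   G2F2       834         166   5.02
4    G3   G3F1       829         171   4.85
5    G3   G3F2       833         167   4.99
6    G4   G4F1       826         174   4.75
7    G4   G4F2       851         149   5.71
G1F1: ACC=0.996  r=0.88
G1F2: ACC=0.992  r=0.93
G2F1: ACC=0.993  r=0.97
G2F2: ACC=0.986  r=0.86
G3F1: ACC=0.977  r=0.81
G3F2: ACC=0.993  r=0.84
G4F1: ACC=0.998  r=0.83
G4F2: ACC=0.981  r=0.80
common moieties: ['f-1', 'f-2']
G1F1-specific: ['f-7', 'f-9', 'f-8']
```

Reading the output: each family's classifier separates planted actives
from inactives almost perfectly (mean validation ACC ≈ 0.99 over 5
repeats); the two planted common drivers `f-1`/`f-2` are tagged *common*
because they are selected (z > 1.96, top-15) in nearly every family; each
family's three specific drivers are recovered as *specific* to it; and the
positive Pearson r per family says the Shapley-selected moieties also
separate the classes by plain odds ratios.  The same structure drives the
clustering: families sharing a group driver merge before cross-group
merges.

The CLI wraps the same stages:

```bash
panmoiety all --config examples/synthetic_benchmark.yaml --outdir out
panmoiety simulate --config examples/synthetic_benchmark.yaml --outdir data
panmoiety curate --bioactivity data/bioactivity.csv --catalog data/catalog.csv --outdir curated
panmoiety featurize --smiles compounds.csv --out features.csv
```

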