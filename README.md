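# cpqsar

Uncertainty-aware QSAR screening for endocrine-activity endpoints.

High-throughput bioassay datasets for receptor-mediated molecular
initiating events (estrogen, androgen, thyroid, PPAR, PXR, … agonism
and antagonism) are severely imbalanced: actives typically make up
0.8–24 % of a curated endpoint. A plain random-forest classifier
trained on such data is specific but insensitive, and gives no
per-compound measure of whether a screened chemical is inside the
model's applicability domain at all. `cpqsar` addresses both problems
with **Mondrian inductive conformal prediction (ICP)** wrapped around
random-forest QSAR models, and builds a complete screening and
prioritization workflow on top of it:

- **curation** — SMILES standardization (largest organic fragment,
  charge neutralization, canonicalization), RDKit 2-D descriptors,
  replicate-label aggregation by a ≥ 2/3 majority vote, and a 0.3 %
  active-ratio endpoint filter;
- **conformal engine** — class-conditional calibration tables,
  p-values, four-way class assignment, validity/efficiency;
- **training protocols** — stratified 5-fold cross-validation with a
  60/20/20 train/calibration/test layout, 200-tree Gini forests, and
  five classical imbalance protocols (naive, equal-size under-sampling,
  duplication over-sampling, SMOTE, ROSE) for comparison;
- **screening battery** — apply many endpoint models to a library,
  classify at a tunable significance, select high-confidence hits,
  flag out-of-domain compounds;
- **prioritization** — binary bioactivity fingerprints from conformal
  p-values, Tanimoto ranking against reference endocrine disruptors
  (e.g. bisphenol A, DEHP), t-SNE embedding of p-value profiles and
  consensus clusters;
- **synthetic data** — imbalanced Gaussian descriptor datasets and a
  full 23-endpoint battery fixture with planted ground truth, so every
  stage is testable without downloading assay data.

## The model

For a binary endpoint, a forest is trained on 60 % of the data and its
predicted class probability is used as the *conformity score*. The
held-out calibration split (20 %) is ranked per class (the *Mondrian*
condition): the active table holds the active-class probabilities of
the true actives, the inactive table the inactive-class probabilities
of the true inactives. A new compound with conformity score *s* for a
class receives the p-value

```
p = (#{calibration scores of that class ≤ s} + 1) / (n + 1)
```

With significance level ε, every class with p ≥ ε enters the
prediction set, giving four outcomes: `active`, `inactive`, `both`
(indistinguishable at ε) or `empty` (out of domain). Under
exchangeability the per-class error rate is at most ε — regardless of
the imbalance — which is the class-balancing property the package is
built around. *Validity* is the per-class fraction of prediction sets
containing the truth; *efficiency* the fraction of single-label
predictions. Calibration is repeated (default 10 iterations per fold)
and p-values are combined by the componentwise median.

## Worked example

```python
from cpqsar import GeneratorConfig, make_endpoint_dataset, run_cp_protocol

cfg = GeneratorConfig(n_compounds=800, active_fraction=0.1, seed=42)
dataset = make_endpoint_dataset(cfg, "demo-endpoint")
run = run_cp_protocol(dataset, n_iterations=10, seed=42)

rep = run.reports[0.2]
print(f"endpoint: {dataset.endpoint_name}  "
      f"(n={dataset.n_compounds}, {100*dataset.active_ratio:.1f}% active)")
print(f"validity   active={rep.validity_active:.3f}  "
      f"inactive={rep.validity_inactive:.3f}")
print(f"efficiency active={rep.efficiency_active:.3f}  "
      f"inactive={rep.efficiency_inactive:.3f}")
print(f"AUC={rep.auc:.3f}  coverage={rep.coverage:.3f}  MCC={rep.mcc:.3f}")
```

prints

```
endpoint: demo-endpoint  (n=800, 10.0% active)
validity   active=0.887  inactive=0.842
efficiency active=0.925  inactive=0.938
AUC=0.919  coverage=0.936  MCC=0.565
```

At ε = 0.2 the model keeps both per-class error rates below 20 %
(validity ≥ 0.8) even though only 10 % of the compounds are active,
while still giving a single label to ~94 % of the test compounds
(coverage). For comparison tables across the classical imbalance
protocols use `run_protocol_comparison`; the conformal rows report
metrics on single-label predictions and, separately, with
`both`/`empty` compounds force-labelled by the larger p-value.

A full command-line pipeline is available too:

```
cpqsar make-fixture --preset table1 --seed 1 --out fixture/
cpqsar train --data fixture/AhR_activation --eps 0.1,0.15,0.2,0.25,0.3 --seed 1 --out models/
cpqsar screen --models models/ --library library.csv --eps 0.2 --strict 0.8 --ood 0.2 --out results/
cpqsar prioritize --matrix results/pvalues.csv --reference REF-A --seed 1 --out prio/
```

### Balanced predictive values

The metrics panel includes prevalence-normalized predictive values.
With per-class rates sens = TP/(TP+FN) and spec = TN/(TN+FP), each true
class is rescaled to equal mass before the ratio:

```
balanced PPV = sens / (sens + (1 − spec))
balanced NPV = spec / (spec + (1 − sens))
```

i.e. the PPV/NPV that would be observed on a test set with balanced
classes but the same per-class error rates.

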