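# Methods

## Mondrian inductive conformal prediction

The package's core is a class-conditional (Mondrian) inductive
conformal predictor for binary bioactivity endpoints. The conformity
score of a compound for a class is the random forest's predicted
probability for that class; equivalently the nonconformity is one minus
that probability. Calibration compounds are split by their true class
and each class's scores are sorted into its own calibration table, so
the p-value of a test compound is computed against compounds of that
class only. This is what makes the error guarantee *per class*: for
exchangeable data the probability that the true class's p-value falls
below ε is at most ε, for actives and inactives separately, no matter
how rare the actives are. That distribution-free guarantee — not the
forest's accuracy — is what the validity tests assert.

**p-value convention.** The unsmoothed rank formula
`p = (#{s ≤ score} + 1) / (n + 1)` is the default: ties count in the
numerator, the `+1` correction keeps p in (0, 1], and the result is
deterministic. A smoothed variant with a seeded uniform tie-break is
available (`p_value(..., smoothed=True, rng=...)`); it makes true-class
p-values exactly uniform but introduces randomness into predictions,
which is the wrong trade for a screening tool. The unsmoothed form is
slightly conservative, which only tightens the error guarantee.

**Class assignment.** A class enters the prediction set when its
p-value is ≥ ε (inclusive boundary). The four outcomes — single label,
`both`, `empty` — are a pure function of (p1, p0, ε), so prediction
sets are nested: raising ε can only shrink them.

**Repeated calibration.** Within each cross-validation fold the 80 %
non-test pool is re-partitioned 60/20 (train/calibration, i.e. 75/25 of
the pool) with a fresh seed for each of 10 iterations; each iteration
contributes a (p1, p0) pair per test compound and the pairs are
combined by the componentwise median. The median is robust,
permutation-invariant and stays in (0, 1]. It does not carry a formal
finite-sample guarantee (a median of valid p-values is not
automatically valid), but across the simulation conditions used here
the aggregated per-class error stays within three binomial standard
errors of ε, which the acceptance suite checks explicitly. For battery
screening, a trained endpoint model stores every fold × iteration
(forest, calibration-tables) unit and aggregates over all of them by
the same median; aggregation per fold is available by building a model
from a single fold's units.

## Training protocol

Stratified 5-fold cross-validation; per fold 20 % test, and the rest
split 60/20 as above. Forests use the Gini criterion with 200 trees and
a fixed seed; probabilities are tree-vote fractions. Descriptors are
fed to the forests unscaled (forests are invariant to monotone feature
transforms); standardization (train-part mean/variance) is applied only
inside neighbour-based resampling.

Imbalance protocols compared against conformal prediction:

- *naive* — no correction (control);
- *undersample* — majority class randomly reduced to exactly the
  minority size;
- *oversample_dup* — minority duplicated (sampling real rows with
  replacement) up to the majority size;
- *smote* — synthetic minority compounds interpolated uniformly between
  a minority compound and one of its 5 nearest minority neighbours
  (Euclidean on standardized descriptors; interpolation is affine, so
  interpolating raw coordinates is equivalent);
- *rose* — both classes topped up with smoothed-bootstrap draws
  (Gaussian kernel, per-class per-feature Silverman bandwidth
  `(4/((d+2)n))^(1/(d+4)) · σ`) to a balanced sample of twice the
  original size. This is a reimplementation from the method's
  description; unlike the R original, which emits a fully synthetic
  sample, original rows are retained and only the top-up is synthetic.

**Metrics.** Classical metrics come from the confusion matrix;
balanced PPV/NPV rescale each true-class row to equal mass first (see
README for the closed forms). For conformal models the classical panel
is computed on single-label predictions only, with *coverage* reporting
their fraction; a second variant includes `both`/`empty` compounds by
force-labelling them with the larger p-value (ties → inactive), since a
confusion matrix needs a hard label and the framework itself does not
supply one for those outcomes. AUC always uses p1 (or the active-class
probability for classical protocols) over all compounds. Degenerate
denominators yield `None` rather than NaN.

## Curation rules

Replicate activity calls are resolved by a ≥ 2/3 majority: active
(inactive) iff at least two thirds of the replicates agree, else the
compound is excluded. Inconclusive replicates stay in the denominator
by default — the conservative reading, since it makes the threshold
harder to reach — with `drop_inconclusive=True` removing them before
the vote. The comparison is done in integers (`3·count ≥ 2·n`) so the
exact-2/3 boundary is inclusive. An endpoint is retained iff its
active ratio is ≥ 0.003 (inclusive: real batteries retain endpoints
at 0.77–0.78 %, so the boundary must not exclude them).

Structure standardization is deliberately minimal: largest organic
fragment (salt stripping), charge neutralization where a proton
add/remove suffices, RDKit canonicalization. It is idempotent. It is
*not* a full QSAR-ready standardization workflow (no tautomer
canonicalization, no normalization of exotic functional groups); for
production use on real inventories a dedicated standardizer should be
run first. Descriptors are the full RDKit 2-D physicochemical set
(about 210, release-dependent); the descriptor list is written into
every model artifact and checked at screening time, so a library is
always featurized with exactly the training set's descriptor order.
Non-finite descriptor values are replaced by 0.0 and flagged on the
record.

## Screening and prioritization

Screening a library against a battery yields a compounds × endpoints
grid of (p1, p0). Derived views:

- assignment grid at any ε;
- high-confidence selection at a strict level (default 0.8): active iff
  p1 > 0.8 and p0 ≤ 0.8 — strict inequality on the selecting p-value,
  so a compound exactly at the threshold is not selected;
- out-of-domain: both p-values strictly below 0.2 — the compound is
  insufficiently conformal to either class and the model abstains;
- per-endpoint summary with the fold difference between the predicted
  active percentage and the training prevalence, plus a variant
  multiplied by the endpoint's balanced PPV (an estimate of the
  *true-positive* share of the predicted actives). Both are reported
  because the discount for expected false positives can be composed in
  more than one defensible way.

Bioactivity fingerprints set bit j when p1 > p0 on endpoint j (ties →
0; the bit records which p-value is larger, not any class assignment).
Tanimoto similarity is `c/(a+b−c)` over on-bits, 0 by convention (with
a warning) when both fingerprints are empty; hits against a reference
use a 0.8 cutoff and are ordered by similarity with ties broken by
compound id. The t-SNE embedding consumes the concatenated (p1, p0)
profile by default (p1-only by flag) via scikit-learn's TSNE with PCA
initialisation and a fixed seed. The cluster around a reference is the
DBSCAN density-connected component containing it, with `min_samples=4`
and eps set adaptively to 3 × the median distance to the 4th nearest
neighbour — t-SNE output has no meaningful absolute scale, so a fixed
eps would be arbitrary; the factor 3 absorbs cluster fringes while
staying well below between-cluster gaps in practice. The consensus list
is the intersection of the Tanimoto hits and the embedding cluster,
reference excluded.

## Synthetic data

The generator emulates the *statistical* shape of curated qHTS
endpoints — severe imbalance, a tunable signal — not their chemistry:
features are multivariate Gaussians (spherical by default, optional
exchangeable correlation 0.3), classes differ by a mean shift of
`separation` pooled standard deviations along the all-ones direction,
and the active count is exactly `round(n · active_fraction)`. Defaults
(n = 2000, 4 % active — near the battery's median prevalence —
20 features) define the benchmark endpoint used throughout the tests
and the acceptance script. The default separation of 3.0 was chosen so
that the 200-tree forest operates at a test AUC near 0.9 under this
imbalance, a realistic strength for a good qHTS QSAR model (the
ideal-observer AUC at that separation is higher, ≈ 0.98; forests on 20
noisy features do not reach it). `separation_for_auc` gives the
ideal-observer inversion `d = √2 · Φ⁻¹(AUC)` when an exact Bayes-level
difficulty is wanted instead.

The battery fixture builds 23 endpoints at the reference prevalence
spectrum (0.77–24.25 %), each separating along its own descriptor axis
in a shared space, plus a disjoint screening library whose per-compound
activity profile over all endpoints is known, two reference compounds
with prescribed complementary profiles (≥ 10 on-bits each, so any
profile within Hamming distance 2 is guaranteed Tanimoto ≥ 0.8), and
planted near-duplicates of each reference. Replicate tables corrupt
binary ground truth with independent inconclusive and flip noise.

Because features are Gaussian, passing tests demonstrate the
*framework* properties — per-class error control, domain flagging,
fingerprint recovery — under exchangeability; they do not demonstrate
descriptor-specific behaviour of real chemical inventories (activity
cliffs, correlated descriptor blocks, assay noise structure,
cytotoxicity interference).

## Problem sizes and numerical choices

The test suite and acceptance script run the benchmark endpoint at
n = 2000 with 5 folds × 10 iterations × 200 trees (50 forests, under a
minute on one CPU); distribution-free coverage checks use a balanced
n = 3000 dataset with a single calibration (≥ 500 test compounds per
class, so binomial three-standard-error bands are a few percent wide).
Stochastic assertions fix every seed and allow three (occasionally
four) standard errors. Determinism contracts (same seed ⇒ identical
splits, forests, p-values, embeddings) are asserted bit-exactly.

Known limitations: the median across calibration iterations lacks a
formal validity proof (checked empirically instead); ROSE here is an
approximation of the R package; the standardizer is minimal; conformal
guarantees are marginal per class, not conditional on chemical
subfamilies.
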