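"""Cross-validated training with imbalance-handling protocols and metrics.

Implements the comparison backbone: stratified 5-fold splits with a
60/20/20 train/calibration/test layout, 200-tree Gini random forests,
five classical imbalance protocols (naive control, equal-size
under-sampling, duplication over-sampling, SMOTE, ROSE) plus Mondrian
conformal prediction with repeated calibration sampling, and the binary
metrics panel (accuracy, balanced accuracy, sensitivity, specificity,
balanced PPV/NPV, MCC, AUC, coverage, per-class validity/efficiency).

Conformal metrics are computed on single-label predictions only
(coverage < 1); a second, full-coverage variant forces a point label by
the larger p-value so it can sit in the same table as the classical
protocols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .chemistry import AssayDataset
from .conformal import (
    ConformalResult,
    MondrianICP,
    aggregate_iterations,
    efficiency,
    validity,
)

logger = logging.getLogger(__name__)

PROTOCOLS = ("naive", "undersample", "oversample_dup", "smote", "rose", "cp")

#: Significance grid used for conformal model assessment.
DEFAULT_EPS_GRID = (0.1, 0.15, 0.2, 0.25, 0.3)


@dataclass(frozen=True)
class SplitPlan:
    """5-fold stratified plan with a 60/20/20 train/calibration/test layout."""

    n_folds: int = 5
    train_frac: float = 0.6
    calib_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.calib_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if abs(self.test_frac - 1.0 / self.n_folds) > 1e-9:
            raise ValueError(
                "test_frac must equal 1/n_folds so test sets tile the data"
            )


def split_stratified(
    y: Sequence[int], plan: SplitPlan
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-fold disjoint (train, calibration, test) index triples.

    Test sets across folds partition the data; within each fold the
    non-test pool is split train/calibration, stratified throughout so
    each part preserves the class ratio to within one compound.
    """
    y = np.asarray(y, dtype=int)
    for label in (0, 1):
        n_c = int((y == label).sum())
        if n_c < plan.n_folds:
            raise ValueError(
                f"class {label} has only {n_c} members; cannot stratify "
                f"into {plan.n_folds} folds"
            )
    skf = StratifiedKFold(
        n_splits=plan.n_folds, shuffle=True, random_state=plan.seed
    )
    calib_share = plan.calib_frac / (plan.train_frac + plan.calib_frac)
    folds = []
    for k, (pool_idx, test_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        train_idx, calib_idx = train_test_split(
            pool_idx,
            test_size=calib_share,
            stratify=y[pool_idx],
            random_state=plan.seed * 1000 + k,
        )
        folds.append(
            (np.sort(train_idx), np.sort(calib_idx), np.sort(test_idx))
        )
    return folds


def train_forest(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_trees: int = 200,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a Gini random forest (200 trees by default), deterministic by seed."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


# ---------------------------------------------------------------------------
# Imbalance resampling
# ---------------------------------------------------------------------------

def resample(
    X: np.ndarray,
    y: np.ndarray,
    protocol: str,
    seed: int = 0,
    *,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance a training part according to one of the five protocols.

    naive            unchanged control.
    undersample      majority randomly reduced to the exact minority size.
    oversample_dup   minority duplicated (with replacement) to majority size.
    smote            minority grown to majority size with synthetic points
                     interpolated between a compound and one of its
                     ``k_neighbors`` nearest same-class neighbours
                     (Euclidean on standardized descriptors).
    rose             both classes topped up with kernel-smoothed bootstrap
                     samples (Gaussian kernel, Silverman bandwidth per
                     class) to a balanced set of twice the original size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if protocol == "naive":
        return X, y
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if idx1.size == 0 or idx0.size == 0:
        raise ValueError("both classes must be present")
    min_idx, maj_idx = (idx1, idx0) if idx1.size <= idx0.size else (idx0, idx1)

    if protocol == "undersample":
        keep_maj = rng.choice(maj_idx, size=min_idx.size, replace=False)
        keep = np.concatenate([min_idx, keep_maj])
        return X[keep], y[keep]

    if protocol == "oversample_dup":
        extra = rng.choice(min_idx, size=maj_idx.size - min_idx.size,
                           replace=True)
        keep = np.concatenate([np.arange(len(y)), extra])
        return X[keep], y[keep]

    if protocol == "smote":
        return _smote(X, y, min_idx, maj_idx, k_neighbors, rng)

    if protocol == "rose":
        return _rose(X, y, idx0, idx1, rng)

    raise ValueError(f"unknown protocol {protocol!r}")


def _smote(X, y, min_idx, maj_idx, k, rng):
    if min_idx.size < k + 1:
        raise ValueError(
            f"SMOTE needs at least {k + 1} minority compounds to find "
            f"{k} neighbours; got {min_idx.size}"
        )
    n_new = maj_idx.size - min_idx.size
    if n_new <= 0:
        return X, y
    # Neighbour search on standardized features; interpolation is affine,
    # so interpolating in the raw space gives the same synthetic points.
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z_min = (X[min_idx] - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z_min)
    _, neigh = nn.kneighbors(Z_min)  # column 0 is the point itself
    base = rng.integers(0, min_idx.size, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    partner = neigh[base, pick]
    u = rng.uniform(size=(n_new, 1))
    X_new = X[min_idx[base]] + u * (X[min_idx[partner]] - X[min_idx[base]])
    y_new = np.full(n_new, y[min_idx[0]])
    return np.vstack([X, X_new]), np.concatenate([y, y_new])


def _rose(X, y, idx0, idx1, rng):
    """Smoothed-bootstrap enlargement: balanced output of size 2n.

    Original rows are kept; each class is topped up to n (the original
    total) with bootstrap draws jittered by a Gaussian kernel whose
    per-feature bandwidth follows Silverman's multivariate rule for the
    class, an approximation of the conditional-kernel-density sampler.
    """
    n_total = len(y)
    parts_X, parts_y = [X], [y]
    d = X.shape[1]
    for idx in (idx0, idx1):
        n_c = idx.size
        n_new = n_total - n_c
        if n_new <= 0:
            continue
        sd = X[idx].std(axis=0, ddof=1)
        h = ((4.0 / ((d + 2.0) * n_c)) ** (1.0 / (d + 4.0))) * sd
        boot = rng.choice(idx, size=n_new, replace=True)
        noise = rng.normal(size=(n_new, d)) * h
        parts_X.append(X[boot] + noise)
        parts_y.append(np.full(n_new, y[idx[0]]))
    return np.vstack(parts_X), np.concatenate(parts_y)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Binary panel; fields that cannot be computed are None ('missing')."""

    accuracy: float | None = None
    balanced_accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    balanced_ppv: float | None = None
    balanced_npv: float | None = None
    mcc: float | None = None
    auc: float | None = None
    coverage: float = 1.0
    validity_active: float | None = None
    validity_inactive: float | None = None
    efficiency_active: float | None = None
    efficiency_inactive: float | None = None
    epsilon: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(
    tp: int, fn: int, fp: int, tn: int
) -> dict[str, float | None]:
    """Classical panel from confusion counts (rows = true classes).

    Balanced PPV/NPV rescale each true-class row to unit mass before the
    predictive-value ratio, i.e. they are the PPV/NPV of a hypothetical
    balanced test set with the same per-class error rates:
        bPPV = sens / (sens + (1 - spec)),
        bNPV = spec / (spec + (1 - sens)).
    """
    n = tp + fn + fp + tn
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    out: dict[str, float | None] = {
        "accuracy": _safe_div(tp + tn, n),
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": None,
        "balanced_ppv": None,
        "balanced_npv": None,
        "mcc": None,
    }
    if sens is not None and spec is not None:
        out["balanced_accuracy"] = (sens + spec) / 2.0
        out["balanced_ppv"] = _safe_div(sens, sens + (1.0 - spec))
        out["balanced_npv"] = _safe_div(spec, spec + (1.0 - sens))
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if mcc_den > 0:
        out["mcc"] = float(tp * tn - fp * fn) / mcc_den
    return out


def evaluate_binary(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Metrics panel for hard binary predictions (coverage 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    rep = MetricsReport(**metrics_from_confusion(tp, fn, fp, tn))
    if scores is not None and len(np.unique(y_true)) == 2:
        rep.auc = float(roc_auc_score(y_true, np.asarray(scores)))
    return rep


def evaluate_conformal(
    results: Sequence[ConformalResult],
    y_true: Sequence[int],
    epsilon: float,
    *,
    include_unclassified: bool = False,
) -> MetricsReport:
    """Metrics panel for conformal predictions at one significance level.

    Default: classical metrics use single-label predictions only and
    coverage reports their fraction.  With ``include_unclassified`` every
    compound is force-labelled by its larger p-value (ties -> inactive),
    mirroring a full-coverage comparison against classical protocols.
    AUC always uses p1 over all compounds.
    """
    y_true = np.asarray(y_true, dtype=int)
    assigns = np.array([r.assignment_at(epsilon) for r in results])
    p1 = np.array([r.p1 for r in results])
    single = (assigns == "active") | (assigns == "inactive")
    coverage = float(single.mean()) if len(results) else 0.0
    if include_unclassified:
        mask = np.ones(len(results), dtype=bool)
        y_pred = (np.array([r.p1 > r.p0 for r in results])).astype(int)
        y_pred[single] = (assigns[single] == "active").astype(int)
        rep_coverage = 1.0
    else:
        mask = single
        y_pred = (assigns == "active").astype(int)
        rep_coverage = coverage
    if mask.any():
        rep = evaluate_binary(y_true[mask], y_pred[mask])
    else:
        rep = MetricsReport()
    rep.coverage = rep_coverage
    rep.epsilon = epsilon
    if len(np.unique(y_true)) == 2:
        rep.auc = float(roc_auc_score(y_true, p1))
    val = validity(results, y_true, epsilon)
    eff = efficiency(results, epsilon, y_true)
    rep.validity_active = val["active"]
    rep.validity_inactive = val["inactive"]
    rep.efficiency_active = eff["active"]
    rep.efficiency_inactive = eff["inactive"]
    return rep


def evaluate(predictions, labels, epsilon: float | None = None, **kw) -> MetricsReport:
    """Dispatching front door: conformal results or hard labels."""
    if len(predictions) and isinstance(predictions[0], ConformalResult):
        if epsilon is None:
            raise ValueError("conformal evaluation needs a significance level")
        return evaluate_conformal(predictions, labels, epsilon, **kw)
    return evaluate_binary(labels, predictions, **kw)


# ---------------------------------------------------------------------------
# Conformal training protocol (5 folds x repeated calibration sampling)
# ---------------------------------------------------------------------------

@dataclass
class EndpointModel:
    """Trained conformal battery member: fold x iteration ICP ensemble.

    ``predict_p`` aggregates the per-model (p1, p0) by the componentwise
    median over every stored fold x iteration model.
    """

    endpoint_name: str
    descriptor_names: list[str]
    icps: list[MondrianICP]
    eps_grid: tuple[float, ...] = DEFAULT_EPS_GRID
    seed: int = 0
    training_active_ratio: float | None = None
    balanced_ppv: float | None = None

    def predict_p(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.descriptor_names):
            raise ValueError(
                f"descriptor mismatch: model {self.endpoint_name} expects "
                f"{len(self.descriptor_names)} features, got {X.shape[1]}"
            )
        p1s = np.stack([icp.predict_p(X)[0] for icp in self.icps])
        p0s = np.stack([icp.predict_p(X)[1] for icp in self.icps])
        return np.median(p1s, axis=0), np.median(p0s, axis=0)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "EndpointModel":
        return joblib.load(Path(path))


@dataclass
class CPRunResult:
    """Pooled cross-validated conformal predictions for one endpoint."""

    endpoint_name: str
    p1: np.ndarray  # aligned with dataset rows; median over iterations
    p0: np.ndarray
    y: np.ndarray
    model: EndpointModel
    reports: dict[float, MetricsReport] = field(default_factory=dict)

    @property
    def results(self) -> list[ConformalResult]:
        return [ConformalResult(a, b) for a, b in zip(self.p1, self.p0)]


def run_cp_protocol(
    dataset: AssayDataset,
    *,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    n_folds: int = 5,
    n_iterations: int = 10,
    n_trees: int = 200,
    seed: int = 0,
) -> CPRunResult:
    """Mondrian ICP with repeated calibration sampling, cross-validated.

    Per fold, 20 % of the data is held out as test; the remaining pool
    is re-partitioned 60/20 (train/calibration, i.e. 75/25 of the pool)
    with a fresh seed for each of ``n_iterations`` iterations.  Each
    iteration trains a forest, calibrates it per class, and scores the
    fold's test set; the iteration (p1, p0) are combined per compound by
    the componentwise median.  Test sets tile the data, so the pooled
    output covers every compound exactly once.
    """
    plan = SplitPlan(n_folds=n_folds, seed=seed)
    folds = split_stratified(dataset.y, plan)
    n = dataset.n_compounds
    p1_all = np.full(n, np.nan)
    p0_all = np.full(n, np.nan)
    icps: list[MondrianICP] = []
    rng = np.random.default_rng(seed)
    for k, (train_idx, calib_idx, test_idx) in enumerate(folds):
        pool = np.concatenate([train_idx, calib_idx])
        pairs_per_compound = [[] for _ in range(test_idx.size)]
        for it in range(n_iterations):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            tr, ca = train_test_split(
                pool,
                test_size=0.25,
                stratify=dataset.y[pool],
                random_state=sub_seed,
            )
            forest = train_forest(
                dataset.X[tr], dataset.y[tr], n_trees=n_trees, seed=sub_seed
            )
            icp = MondrianICP.calibrate(
                forest, dataset.X[ca], dataset.y[ca]
            )
            icps.append(icp)
            p1, p0 = icp.predict_p(dataset.X[test_idx])
            for i in range(test_idx.size):
                pairs_per_compound[i].append((p1[i], p0[i]))
        for i, t in enumerate(test_idx):
            p1_all[t], p0_all[t] = aggregate_iterations(pairs_per_compound[i])
    result = CPRunResult(
        endpoint_name=dataset.endpoint_name,
        p1=p1_all,
        p0=p0_all,
        y=dataset.y.copy(),
        model=EndpointModel(
            endpoint_name=dataset.endpoint_name,
            descriptor_names=list(dataset.descriptor_names),
            icps=icps,
            eps_grid=tuple(eps_grid),
            seed=seed,
            training_active_ratio=dataset.active_ratio,
        ),
    )
    for eps in eps_grid:
        result.reports[eps] = evaluate_conformal(
            result.results, dataset.y, eps
        )
    rep02 = result.reports.get(0.2)
    if rep02 is not None:
        result.model.balanced_ppv = rep02.balanced_ppv
    return result


# ---------------------------------------------------------------------------
# Full protocol comparison
# ---------------------------------------------------------------------------

def run_protocol_comparison(
    dataset: AssayDataset,
    protocols: Sequence[str] = PROTOCOLS,
    *,
    epsilon: float = 0.2,
    n_folds: int = 5,
    n_iterations: int = 10,
    n_trees: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Average test-set metrics per imbalance protocol.

    Classical protocols train on the resampled 80 % pool (train +
    calibration merged) and predict the held-out 20 % at the 0.5
    majority-vote threshold; reports are averaged over folds.  The
    conformal protocol is reported twice: on single-label predictions
    (coverage < 1) and with 'both'/'empty' compounds force-labelled by
    the larger p-value (coverage 1).
    """
    plan = SplitPlan(n_folds=n_folds, seed=seed)
    folds = split_stratified(dataset.y, plan)
    rows = []
    for protocol in protocols:
        if protocol == "cp":
            run = run_cp_protocol(
                dataset,
                eps_grid=(epsilon,),
                n_folds=n_folds,
                n_iterations=n_iterations,
                n_trees=n_trees,
                seed=seed,
            )
            single = run.reports[epsilon]
            full = evaluate_conformal(
                run.results, dataset.y, epsilon, include_unclassified=True
            )
            rows.append({"protocol": "cp", **single.to_dict()})
            rows.append({"protocol": "cp_full", **full.to_dict()})
            continue
        fold_reports = []
        for k, (train_idx, calib_idx, test_idx) in enumerate(folds):
            pool = np.concatenate([train_idx, calib_idx])
            Xr, yr = resample(
                dataset.X[pool], dataset.y[pool], protocol,
                seed=seed * 100 + k,
            )
            forest = train_forest(Xr, yr, n_trees=n_trees, seed=seed + k)
            prob = forest.predict_proba(dataset.X[test_idx])[:, 1]
            rep = evaluate_binary(
                dataset.y[test_idx], (prob >= 0.5).astype(int), scores=prob
            )
            fold_reports.append(rep.to_dict())
        rows.append({"protocol": protocol, **_mean_reports(fold_reports)})
    return pd.DataFrame(rows)


def _mean_reports(reports: list[dict]) -> dict:
    out = {}
    for key in reports[0]:
        vals = [r[key] for r in reports if r[key] is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out
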