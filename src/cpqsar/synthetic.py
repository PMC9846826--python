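"""Synthetic imbalanced descriptor data with known ground truth.

Real qHTS curation yields severely imbalanced two-class datasets (active
fractions between roughly 0.8 % and 24 % across the nuclear-receptor
battery modeled here).  This module emulates that regime with two
multivariate Gaussian classes in a surrogate descriptor space whose
separation — the distance between class means in pooled-σ units — is a
single tunable knob, so classifier difficulty is controlled exactly.
It also builds a full 23-endpoint battery fixture with a shared
screening library and planted reference compounds, and noisy replicate
label tables to exercise the curation vote.

Gaussian features stand in for real descriptors so that class
separation is controllable; a small set of real SMILES structures is
bundled for the chemistry tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chemistry import AssayDataset

#: Active/Data set (%) for the 23 retained receptor-activity endpoints
#: (receptor, molecular initiating event, percent active), the prevalence
#: landscape the generator emulates.
BATTERY_PREVALENCES: list[tuple[str, str, float]] = [
    ("AhR", "activation", 10.94),
    ("AR", "agonism", 3.00),
    ("AR", "antagonism", 6.28),
    ("CAR", "agonism", 11.80),
    ("CAR", "antagonism", 2.49),
    ("ER-alpha", "agonism", 4.42),
    ("ER-alpha", "antagonism", 4.23),
    ("FXR", "agonism", 1.16),
    ("FXR", "antagonism", 2.60),
    ("GR", "agonism", 2.04),
    ("GR", "antagonism", 4.70),
    ("PPAR-delta", "agonism", 1.02),
    ("PPAR-delta", "antagonism", 0.77),
    ("PPAR-gamma", "agonism", 2.56),
    ("PPAR-gamma", "antagonism", 4.90),
    ("PR", "agonism", 1.46),
    ("PR", "antagonism", 12.01),
    ("PXR", "agonism", 24.25),
    ("RAR", "agonism", 5.04),
    ("RAR", "antagonism", 9.53),
    ("RXR", "agonism", 2.61),
    ("TR-beta", "antagonism", 4.65),
    ("VDR3", "antagonism", 0.78),
]

#: 20 real structures (common industrial chemicals, plasticizers,
#: phenols, drugs) bundled for structure-handling tests.
TOY_SMILES: list[tuple[str, str]] = [
    ("BPA", "CC(C)(c1ccc(O)cc1)c1ccc(O)cc1"),
    ("BPB", "CCC(C)(c1ccc(O)cc1)c1ccc(O)cc1"),
    ("DEHP", "CCCCC(CC)COC(=O)c1ccccc1C(=O)OCC(CC)CCCC"),
    ("DBP", "CCCCOC(=O)c1ccccc1C(=O)OCCCC"),
    ("DEP", "CCOC(=O)c1ccccc1C(=O)OCC"),
    ("methoxychlor", "COc1ccc(C(c2ccc(OC)cc2)C(Cl)(Cl)Cl)cc1"),
    ("ethanol", "CCO"),
    ("phenol", "Oc1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("benzoic_acid", "O=C(O)c1ccccc1"),
    ("nonylphenol", "CCCCCCCCCc1ccc(O)cc1"),
    ("triclosan", "Oc1cc(Cl)ccc1Oc1ccc(Cl)cc1Cl"),
    ("atrazine", "CCNc1nc(Cl)nc(NC(C)C)n1"),
    ("dieldrin", "ClC1=C(Cl)C2(Cl)C3C4CC(C5OC45)C3C1(Cl)C2(Cl)Cl"),
    ("estradiol", "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O"),
    ("genistein", "O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12"),
]


def separation_for_auc(auc: float) -> float:
    """Class-mean distance (pooled-σ units) whose ideal-observer AUC is ``auc``.

    For two spherical Gaussians at Mahalanobis distance d the optimal
    AUC is Phi(d / sqrt(2)); invert for d.
    """
    if not 0.5 < auc < 1.0:
        raise ValueError("auc must be in (0.5, 1)")
    return float(np.sqrt(2.0) * norm.ppf(auc))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic endpoint dataset."""

    n_compounds: int = 2000
    n_features: int = 20
    active_fraction: float = 0.04
    #: Class-mean distance in pooled-σ units.  The default 3.0 puts a
    #: 200-tree random forest at a test AUC near 0.9 under the default
    #: imbalance; the ideal-observer AUC would be Phi(3/sqrt(2)) ≈ 0.983.
    separation: float = 3.0
    covariance: str = "spherical"  # or "correlated"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must be in (0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.covariance not in ("spherical", "correlated"):
            raise ValueError("covariance must be 'spherical' or 'correlated'")


def _covariance_matrix(config: GeneratorConfig) -> np.ndarray:
    f = config.n_features
    if config.covariance == "spherical":
        return np.eye(f)
    # Exchangeable correlation 0.3 off-diagonal: unit marginal variance,
    # nontrivial principal axes, still positive definite for any f.
    cov = np.full((f, f), 0.3)
    np.fill_diagonal(cov, 1.0)
    return cov


def make_endpoint_dataset(
    config: GeneratorConfig, endpoint_name: str = "synthetic"
) -> AssayDataset:
    """Two Gaussian classes with exact active count round(n * fraction).

    Class means sit at ±separation/2 along the all-ones direction, so
    the Mahalanobis distance between them equals ``separation`` for the
    spherical covariance (for the correlated option the same Euclidean
    mean distance is used; the effective separation is then smaller
    along correlated directions).
    """
    n_active = int(round(config.n_compounds * config.active_fraction))
    if n_active == 0:
        raise ValueError(
            "active_fraction rounds to zero actives; increase n_compounds"
        )
    n_inactive = config.n_compounds - n_active
    rng = np.random.default_rng(config.seed)
    f = config.n_features
    direction = np.ones(f) / np.sqrt(f)
    offset = (config.separation / 2.0) * direction
    cov = _covariance_matrix(config)
    X_act = rng.multivariate_normal(offset, cov, size=n_active,
                                    method="cholesky")
    X_inact = rng.multivariate_normal(-offset, cov, size=n_inactive,
                                      method="cholesky")
    X = np.vstack([X_act, X_inact])
    y = np.concatenate([np.ones(n_active, int), np.zeros(n_inactive, int)])
    order = rng.permutation(config.n_compounds)
    X, y = X[order], y[order]
    ids = [f"{endpoint_name}-{i:05d}" for i in range(config.n_compounds)]
    names = [f"d{j:03d}" for j in range(f)]
    return AssayDataset(endpoint_name, ids, X, y, names)


# ---------------------------------------------------------------------------
# Battery fixture: 23 endpoints, shared library, planted references
# ---------------------------------------------------------------------------

@dataclass
class BatteryFixture:
    """A full synthetic screening battery with known ground truth."""

    datasets: list[AssayDataset]
    library_ids: list[str]
    library_X: np.ndarray
    library_profiles: np.ndarray  # (n_library, n_endpoints) true activity bits
    reference_ids: list[str]
    descriptor_names: list[str] = field(default_factory=list)

    @property
    def endpoint_names(self) -> list[str]:
        return [d.endpoint_name for d in self.datasets]


def make_battery_fixture(
    n_endpoints: int = 23,
    prevalence_list: Sequence[float] | None = None,
    *,
    n_train_per_endpoint: int = 600,
    n_library: int = 300,
    n_near_duplicates: int = 5,
    separation: float = 3.0,
    seed: int = 0,
) -> BatteryFixture:
    """Build per-endpoint training sets plus a disjoint screening library.

    Each endpoint e separates along its own descriptor axis: actives are
    shifted by ``separation`` on feature e, inactives centred at zero.
    Library compounds carry a known activity profile (one bit per
    endpoint) realised the same way, so their expected conformal
    behaviour is known.  Two designated reference compounds get
    prescribed profiles, each with ``n_near_duplicates`` planted
    neighbours whose profiles differ in at most 2 bits.
    """
    if prevalence_list is None:
        prevalence_list = [p / 100.0 for _, _, p in
                           BATTERY_PREVALENCES[:n_endpoints]]
    if len(prevalence_list) != n_endpoints:
        raise ValueError("prevalence_list length must equal n_endpoints")
    rng = np.random.default_rng(seed)
    n_features = n_endpoints  # one signal axis per endpoint
    names = [f"d{j:03d}" for j in range(n_features)]
    if n_endpoints <= len(BATTERY_PREVALENCES):
        endpoint_names = [f"{r}_{mie}" for r, mie, _ in
                          BATTERY_PREVALENCES[:n_endpoints]]
    else:
        endpoint_names = [f"endpoint{j:02d}" for j in range(n_endpoints)]

    datasets = []
    for e, (name, prev) in enumerate(zip(endpoint_names, prevalence_list)):
        n_active = max(1, int(round(n_train_per_endpoint * prev)))
        n_inactive = n_train_per_endpoint - n_active
        X = rng.normal(size=(n_train_per_endpoint, n_features))
        y = np.zeros(n_train_per_endpoint, int)
        y[:n_active] = 1
        X[:n_active, e] += separation
        order = rng.permutation(n_train_per_endpoint)
        X, y = X[order], y[order]
        ids = [f"{name}-{i:05d}" for i in range(n_train_per_endpoint)]
        datasets.append(AssayDataset(name, ids, X, y, names))

    # Screening library: random profiles at the endpoint prevalences.
    prof = (rng.uniform(size=(n_library, n_endpoints))
            < np.asarray(prevalence_list)).astype(int)
    # Two references with prescribed, distinctive profiles.
    # Each reference keeps >= 10 on-bits so a profile within Hamming
    # distance 2 is guaranteed Tanimoto >= 0.8 ((a-2)/a with a >= 10).
    ref_a = np.zeros(n_endpoints, int)
    ref_a[::2] = 1  # active on the even-indexed endpoints
    ref_b = np.zeros(n_endpoints, int)
    ref_b[1::2] = 1  # complementary profile: the odd-indexed endpoints
    profiles = [prof, ref_a[None, :], ref_b[None, :]]
    ids = [f"LIB-{i:05d}" for i in range(n_library)] + ["REF-A", "REF-B"]
    for tag, ref in (("A", ref_a), ("B", ref_b)):
        for k in range(n_near_duplicates):
            dup = ref.copy()
            n_flip = int(rng.integers(0, 3))  # Hamming distance <= 2
            flip = rng.choice(n_endpoints, size=n_flip, replace=False)
            dup[flip] ^= 1
            profiles.append(dup[None, :])
            ids.append(f"DUP-{tag}{k}")
    profiles = np.vstack(profiles)
    X_lib = rng.normal(size=(profiles.shape[0], n_features))
    X_lib += separation * profiles
    return BatteryFixture(
        datasets=datasets,
        library_ids=ids,
        library_X=X_lib,
        library_profiles=profiles,
        reference_ids=["REF-A", "REF-B"],
        descriptor_names=names,
    )


# ---------------------------------------------------------------------------
# Replicate label tables
# ---------------------------------------------------------------------------

def make_replicate_table(
    truth_labels: Sequence[int],
    n_replicates: int = 3,
    flip_rate: float = 0.0,
    inconclusive_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy per-compound replicate labels from binary ground truth.

    Each replicate is independently Inconclusive with probability
    ``inconclusive_rate``; otherwise it reports the true label flipped
    with probability ``flip_rate``.  Returns a frame with columns
    compound_id, truth, replicates (';'-joined) for the curation reader.
    """
    for name, r in (("flip_rate", flip_rate),
                    ("inconclusive_rate", inconclusive_rate)):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    y = np.asarray(truth_labels, dtype=int)
    rows = []
    for i, truth in enumerate(y):
        reps = []
        for _ in range(n_replicates):
            if rng.uniform() < inconclusive_rate:
                reps.append("Inconclusive")
                continue
            lab = truth if rng.uniform() >= flip_rate else 1 - truth
            reps.append("Active" if lab == 1 else "Inactive")
        rows.append(
            {
                "compound_id": f"C{i:05d}",
                "truth": "Active" if truth == 1 else "Inactive",
                "replicates": ";".join(reps),
            }
        )
    return pd.DataFrame(rows)
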