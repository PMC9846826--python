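"""Battery screening: apply trained conformal models to a library.

A screening battery is a list of trained endpoint models sharing one
descriptor space.  Screening a library yields a compounds x endpoints
grid of conformal p-value pairs (p1 for active, p0 for inactive), from
which class assignments at any significance level, high-confidence
selections at a strict level, out-of-domain flags and per-endpoint
summaries (including the predicted-vs-expected actives fold difference)
are derived without re-running the models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conformal import assign_class
from .protocols import EndpointModel


@dataclass
class PValueMatrix:
    """Compounds x endpoints grids of conformal p-values, all in (0, 1]."""

    compound_ids: list[str]
    endpoint_names: list[str]
    p1: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        shape = (len(self.compound_ids), len(self.endpoint_names))
        if self.p1.shape != shape or self.p0.shape != shape:
            raise ValueError(
                f"p-value grids must have shape {shape}; got "
                f"{self.p1.shape} / {self.p0.shape}"
            )
        for name, grid in (("p1", self.p1), ("p0", self.p0)):
            if np.any(~np.isfinite(grid)) or grid.min() <= 0 or grid.max() > 1:
                raise ValueError(f"{name} entries must lie in (0, 1]")

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, cid in enumerate(self.compound_ids):
            for j, ep in enumerate(self.endpoint_names):
                rows.append(
                    {"compound": cid, "endpoint": ep,
                     "p1": self.p1[i, j], "p0": self.p0[i, j]}
                )
        return pd.DataFrame(rows)

    @staticmethod
    def from_long_frame(frame: pd.DataFrame) -> "PValueMatrix":
        wide1 = frame.pivot(index="compound", columns="endpoint", values="p1")
        wide0 = frame.pivot(index="compound", columns="endpoint", values="p0")
        return PValueMatrix(
            compound_ids=list(wide1.index),
            endpoint_names=list(wide1.columns),
            p1=wide1.to_numpy(),
            p0=wide0.to_numpy(),
        )


def screen(
    battery: Sequence[EndpointModel],
    library_X: np.ndarray,
    compound_ids: Sequence[str] | None = None,
) -> PValueMatrix:
    """Aggregated (p1, p0) per compound x endpoint across the battery.

    Every model's descriptor list must match the library featurization
    (same length and order); a mismatch is a hard error raised by the
    model itself.
    """
    if len(battery) == 0:
        raise ValueError("battery is empty")
    library_X = np.asarray(library_X, dtype=float)
    names = [m.endpoint_name for m in battery]
    if compound_ids is None:
        compound_ids = [f"lib-{i:05d}" for i in range(library_X.shape[0])]
    ref = battery[0].descriptor_names
    for m in battery[1:]:
        if m.descriptor_names != ref:
            raise ValueError(
                f"battery models disagree on descriptors "
                f"({m.endpoint_name} vs {battery[0].endpoint_name})"
            )
    p1 = np.empty((library_X.shape[0], len(battery)))
    p0 = np.empty_like(p1)
    for j, model in enumerate(battery):
        p1[:, j], p0[:, j] = model.predict_p(library_X)
    return PValueMatrix(list(compound_ids), names, p1, p0)


def classify_matrix(matrix: PValueMatrix, epsilon: float) -> np.ndarray:
    """Elementwise four-way assignment grid at significance ``epsilon``."""
    out = np.empty(matrix.p1.shape, dtype=object)
    for i in range(matrix.p1.shape[0]):
        for j in range(matrix.p1.shape[1]):
            out[i, j] = assign_class(matrix.p1[i, j], matrix.p0[i, j], epsilon)
    return out


def high_confidence_selection(
    matrix: PValueMatrix, eps_strict: float = 0.8
) -> dict[str, dict[str, set[str]]]:
    """Strict-threshold selections per endpoint.

    A compound is a high-confidence active on an endpoint when its p1
    strictly exceeds ``eps_strict`` while p0 does not; symmetrically for
    inactives.  The strict inequality means a p-value exactly at the
    threshold is not selected.
    """
    if not 0.5 < eps_strict <= 1.0:
        raise ValueError("eps_strict must be in (0.5, 1]")
    ids = np.array(matrix.compound_ids)
    out: dict[str, dict[str, set[str]]] = {}
    for j, ep in enumerate(matrix.endpoint_names):
        act = (matrix.p1[:, j] > eps_strict) & (matrix.p0[:, j] <= eps_strict)
        inact = (matrix.p0[:, j] > eps_strict) & (matrix.p1[:, j] <= eps_strict)
        out[ep] = {
            "active": set(ids[act]),
            "inactive": set(ids[inact]),
        }
    return out


def out_of_domain(
    matrix: PValueMatrix, threshold: float = 0.2
) -> dict[str, set[str]]:
    """Compounds with both p-values strictly below ``threshold`` per endpoint.

    Such compounds are insufficiently conformal to either class: the
    model has no basis to speak about them (applicability-domain flag).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ids = np.array(matrix.compound_ids)
    out = {}
    for j, ep in enumerate(matrix.endpoint_names):
        mask = (matrix.p1[:, j] < threshold) & (matrix.p0[:, j] < threshold)
        out[ep] = set(ids[mask])
    return out


def summarize(
    matrix: PValueMatrix,
    epsilon: float = 0.2,
    training_prevalences: dict[str, float] | None = None,
    balanced_ppv: dict[str, float] | None = None,
    *,
    eps_strict: float = 0.8,
    ood_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-endpoint screening summary.

    Percentages of active / inactive / unclassified assignments at
    ``epsilon`` (summing to 100), high-confidence counts at
    ``eps_strict``, out-of-domain counts, and — when training
    prevalences are supplied — the fold difference between the predicted
    active fraction and the training active fraction, plus a variant
    discounted by the endpoint's balanced PPV (the expected
    true-positive share of the predicted actives).
    """
    assigns = classify_matrix(matrix, epsilon)
    hc = high_confidence_selection(matrix, eps_strict)
    ood = out_of_domain(matrix, ood_threshold)
    n = len(matrix.compound_ids)
    rows = []
    for j, ep in enumerate(matrix.endpoint_names):
        col = assigns[:, j]
        pct_active = 100.0 * float((col == "active").sum()) / n
        pct_inactive = 100.0 * float((col == "inactive").sum()) / n
        pct_uncl = 100.0 - pct_active - pct_inactive
        row = {
            "endpoint": ep,
            "pct_active": pct_active,
            "pct_inactive": pct_inactive,
            "pct_unclassified": pct_uncl,
            "n_high_confidence_active": len(hc[ep]["active"]),
            "n_high_confidence_inactive": len(hc[ep]["inactive"]),
            "n_out_of_domain": len(ood[ep]),
            "fold_difference": None,
            "fold_difference_ppv_adjusted": None,
        }
        if training_prevalences is not None:
            prev_pct = 100.0 * training_prevalences.get(ep, 0.0)
            if prev_pct > 0:
                row["fold_difference"] = pct_active / prev_pct
                if balanced_ppv is not None and balanced_ppv.get(ep):
                    row["fold_difference_ppv_adjusted"] = (
                        pct_active * balanced_ppv[ep] / prev_pct
                    )
        rows.append(row)
    return pd.DataFrame(rows)
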