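"""Mondrian (class-conditional) inductive conformal prediction.

The conformity score of a compound for a class is the random forest's
predicted probability for that class.  Calibration is Mondrian: the
active table holds the active-class probabilities of the true actives in
the calibration split, the inactive table the inactive-class
probabilities of the true inactives.  A test compound's p-value for a
class is the (+1-corrected) fraction of calibration scores of that class
at or below its own score,

    p = (#{s in table : s <= score} + 1) / (n + 1),

so p is never exactly 0 and true-class p-values are (super-)uniform
under exchangeability, per class.  At a significance level epsilon the
prediction set contains every class whose p-value is >= epsilon, giving
the four-way outcome {active, inactive, both, empty}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

ASSIGNMENTS = ("active", "inactive", "both", "empty")


class CalibrationError(ValueError):
    """Raised when a calibration table cannot be built or is empty."""


@dataclass
class CalibrationTable:
    """Sorted conformity scores of calibration compounds of one class."""

    class_label: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.sort(np.asarray(self.scores, dtype=float))
        if scores.size == 0:
            raise CalibrationError(
                f"no calibration compounds for class {self.class_label!r}"
            )
        if scores.min() < 0.0 or scores.max() > 1.0:
            raise CalibrationError("conformity scores must lie in [0, 1]")
        self.scores = scores

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class ConformalResult:
    """Conformal p-values for one compound: p1 (active), p0 (inactive)."""

    p1: float
    p0: float

    def assignment_at(self, epsilon: float) -> str:
        return assign_class(self.p1, self.p0, epsilon)


def build_calibration(
    prob_active: Sequence[float], true_labels: Sequence[int]
) -> tuple[CalibrationTable, CalibrationTable]:
    """Build the (active, inactive) calibration tables.

    ``prob_active`` is the model's active-class probability for each
    calibration compound; ``true_labels`` are binary (1 = active).  The
    inactive table stores the complement ``1 - prob_active`` for the true
    inactives, i.e. the model's inactive-class probability.
    """
    p = np.asarray(prob_active, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must be aligned")
    active = CalibrationTable("active", p[y == 1])
    inactive = CalibrationTable("inactive", 1.0 - p[y == 0])
    return active, inactive


def p_value(
    conformity: float | np.ndarray,
    table: CalibrationTable,
    *,
    smoothed: bool = False,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """Rank a conformity score in a calibration table as a p-value.

    Unsmoothed (default): ties count in the numerator, so the p-value is
    ``(#{s <= conformity} + 1) / (n + 1)`` — deterministic, in (0, 1].
    The smoothed variant breaks ties uniformly at random (requires
    ``rng``), yielding exactly uniform p-values under exchangeability.
    """
    scores = table.scores
    n = scores.size
    c = np.asarray(conformity, dtype=float)
    n_le = np.searchsorted(scores, c, side="right")
    if smoothed:
        if rng is None:
            raise ValueError("smoothed p-values need an rng for tie-breaks")
        n_lt = np.searchsorted(scores, c, side="left")
        ties = n_le - n_lt
        u = rng.uniform(size=c.shape if c.shape else None)
        p = (n_lt + u * (ties + 1)) / (n + 1)
    else:
        p = (n_le + 1) / (n + 1)
    if np.ndim(conformity) == 0:
        return float(p)
    return p


def assign_class(p1: float, p0: float, epsilon: float) -> str:
    """Four-way class assignment at significance ``epsilon``.

    A class enters the prediction set when its p-value is >= epsilon
    (inclusive boundary).  Exactly one of active / inactive / both /
    empty holds for any (p1, p0, epsilon).
    """
    for name, v in (("p1", p1), ("p0", p0), ("epsilon", epsilon)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    in_active = p1 >= epsilon
    in_inactive = p0 >= epsilon
    if in_active and in_inactive:
        return "both"
    if in_active:
        return "active"
    if in_inactive:
        return "inactive"
    return "empty"


def aggregate_iterations(
    pairs: Iterable[tuple[float, float]]
) -> tuple[float, float]:
    """Combine (p1, p0) pairs from repeated calibration samplings.

    Componentwise median: robust, permutation-invariant, and stays in
    (0, 1] because every input component does.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one (p1, p0) pair")
    med = np.median(arr, axis=0)
    return float(med[0]), float(med[1])


# ---------------------------------------------------------------------------
# Validity / efficiency
# ---------------------------------------------------------------------------

def _assignments(results: Sequence[ConformalResult], epsilon: float) -> list[str]:
    return [r.assignment_at(epsilon) for r in results]


def validity(
    results: Sequence[ConformalResult],
    true_labels: Sequence[int],
    epsilon: float,
) -> dict[str, float | None]:
    """Per-class fraction of prediction sets containing the true class.

    'both' always contains the true class and counts correct; 'empty'
    never does and counts wrong.  A class with no members yields None.
    """
    y = np.asarray(true_labels, dtype=int)
    if len(results) != y.size:
        raise ValueError("results and labels must be aligned")
    assigns = np.array(_assignments(results, epsilon))
    out: dict[str, float | None] = {}
    for cls, label in (("active", 1), ("inactive", 0)):
        mask = y == label
        if not mask.any():
            out[cls] = None
            continue
        contained = (assigns[mask] == cls) | (assigns[mask] == "both")
        out[cls] = float(contained.mean())
    return out


def efficiency(
    results: Sequence[ConformalResult],
    epsilon: float,
    true_labels: Sequence[int] | None = None,
) -> dict[str, float | None]:
    """Fraction of compounds receiving a single-label prediction.

    With ``true_labels`` the fraction is reported per true class (keys
    'active'/'inactive'); without, overall (key 'overall').
    """
    if len(results) == 0:
        raise ValueError("no results")
    assigns = np.array(_assignments(results, epsilon))
    single = (assigns == "active") | (assigns == "inactive")
    if true_labels is None:
        return {"overall": float(single.mean())}
    y = np.asarray(true_labels, dtype=int)
    out: dict[str, float | None] = {}
    for cls, label in (("active", 1), ("inactive", 0)):
        mask = y == label
        out[cls] = float(single[mask].mean()) if mask.any() else None
    return out


# ---------------------------------------------------------------------------
# A fitted Mondrian ICP: one classifier + one calibration pass
# ---------------------------------------------------------------------------

@dataclass
class MondrianICP:
    """A trained probabilistic classifier with its calibration tables."""

    model: object  # exposes predict_proba; active class is column 1
    active_table: CalibrationTable
    inactive_table: CalibrationTable

    @classmethod
    def calibrate(cls, model, X_cal, y_cal) -> "MondrianICP":
        prob = model.predict_proba(X_cal)[:, 1]
        act, inact = build_calibration(prob, y_cal)
        return cls(model, act, inact)

    def predict_p(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(p1, p0) arrays for the rows of X."""
        prob = self.model.predict_proba(X)[:, 1]
        p1 = p_value(prob, self.active_table)
        p0 = p_value(1.0 - prob, self.inactive_table)
        return np.asarray(p1), np.asarray(p0)

    def predict_results(self, X) -> list[ConformalResult]:
        p1, p0 = self.predict_p(X)
        return [ConformalResult(a, b) for a, b in zip(p1, p0)]
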