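"""Reading, standardizing, labeling and featurizing chemical datasets.

This module implements the data-curation front end of the screening
toolkit: parsing compound tables (CSV / .smi), a minimal structure
standardization step (canonicalize, keep the largest organic fragment,
neutralize simple charges), RDKit 2-D physicochemical descriptor
calculation, replicate-label aggregation by a two-thirds majority vote,
and the active-ratio dataset filter used to decide whether an assay
endpoint carries enough actives to be modeled at all.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Replicate label vocabulary as it appears in qHTS activity summaries.
ACTIVE, INACTIVE, INCONCLUSIVE = "Active", "Inactive", "Inconclusive"

#: Sentinel substituted for non-finite descriptor values (and recorded in
#: the record's ``flags``) so downstream matrices are always finite.
NONFINITE_SENTINEL = 0.0

#: Minimum fraction of actives for an endpoint to be retained (0.3 %).
DEFAULT_MIN_ACTIVE_RATIO = 0.003

#: Majority threshold for the replicate vote.
MAJORITY_THRESHOLD = 2.0 / 3.0


class StructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a structure."""


class ConfigurationError(ValueError):
    """Raised for malformed inputs such as missing mandatory columns."""


def descriptor_names() -> list[str]:
    """Names of the full RDKit 2-D descriptor set, in canonical order."""
    return [name for name, _ in Descriptors._descList]


@dataclass
class CompoundRecord:
    """One chemical structure with identity, descriptors and raw labels."""

    compound_id: str
    smiles_raw: str
    smiles_standard: str | None = None
    descriptors: np.ndarray | None = None
    replicate_labels: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.descriptors is not None:
            self.descriptors = np.asarray(self.descriptors, dtype=float)


@dataclass
class AssayDataset:
    """Labeled descriptor data for one endpoint (receptor + mode).

    ``y`` is a binary vector (1 = active, 0 = inactive) aligned with the
    rows of the descriptor matrix ``X`` and with ``compound_ids``.
    """

    endpoint_name: str
    compound_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    descriptor_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if len(self.compound_ids) != self.X.shape[0]:
            raise ValueError("compound_ids length does not match X")
        if self.X.shape[1] != len(self.descriptor_names):
            raise ValueError("descriptor_names length does not match X")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValueError("labels must be binary 0/1")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def active_ratio(self) -> float:
        return float(np.count_nonzero(self.y == 1)) / len(self.y)


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    active_ratio: float
    min_active_ratio: float

    @property
    def reason(self) -> str:
        rel = "≥" if self.keep else "<"
        return (
            f"active_ratio {self.active_ratio:.4f} {rel} "
            f"cutoff {self.min_active_ratio:.4f}"
        )


# ---------------------------------------------------------------------------
# Structure standardization
# ---------------------------------------------------------------------------

_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles_raw: str) -> str:
    """Return a canonical SMILES for the largest, neutralized fragment.

    The step is deliberately minimal: salt/counter-ion stripping via the
    largest organic fragment, charge neutralization where adding or
    removing a proton suffices, and RDKit canonicalization.  It is
    idempotent: standardizing an already-standard SMILES returns the
    same string.

    Raises
    ------
    StructureError
        If ``smiles_raw`` is empty or does not parse.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise StructureError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles_raw!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def compute_descriptors(smiles_standard: str) -> tuple[np.ndarray, list[str]]:
    """Full RDKit 2-D descriptor vector for one standardized structure.

    Returns the vector (fixed length, order of :func:`descriptor_names`)
    and a list of flags naming descriptors whose raw value was non-finite
    and was replaced by :data:`NONFINITE_SENTINEL`.
    """
    mol = Chem.MolFromSmiles(smiles_standard)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles_standard!r}")
    values = Descriptors.CalcMolDescriptors(mol)
    names = descriptor_names()
    vec = np.empty(len(names), dtype=float)
    flags: list[str] = []
    for i, name in enumerate(names):
        v = float(values[name])
        if not np.isfinite(v):
            flags.append(f"nonfinite:{name}")
            v = NONFINITE_SENTINEL
        vec[i] = v
    return vec, flags


# ---------------------------------------------------------------------------
# Table reading
# ---------------------------------------------------------------------------

def read_compound_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    compute_features: bool = False,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Read a compound table from CSV or a .smi file.

    ``column_map`` names the mandatory ``id`` and ``smiles`` columns and
    optionally a ``labels`` column holding ``;``-separated replicate
    labels.  Structures that fail standardization are collected into the
    returned rejects report (columns: row, compound_id, smiles, reason)
    rather than silently dropped.
    """
    path = Path(path)
    if path.suffix.lower() in {".smi", ".smiles"}:
        frame = _read_smi(path)
        column_map = {"id": "id", "smiles": "smiles"}
    else:
        frame = pd.read_csv(path, dtype=str)
        if column_map is None:
            column_map = {"id": "id", "smiles": "smiles"}
    for role in ("id", "smiles"):
        col = column_map.get(role)
        if col is None or col not in frame.columns:
            raise ConfigurationError(
                f"column for {role!r} ({col!r}) not found in {path.name}; "
                f"available: {list(frame.columns)}"
            )
    if frame.empty:
        warnings.warn(f"{path.name} contains no rows", stacklevel=2)

    label_col = column_map.get("labels")
    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        cid = str(row[column_map["id"]])
        smiles = str(row[column_map["smiles"]])
        try:
            std = standardize_structure(smiles)
        except StructureError as exc:
            rejects.append(
                {"row": row_no, "compound_id": cid, "smiles": smiles,
                 "reason": str(exc)}
            )
            continue
        labels: list[str] = []
        if label_col is not None and label_col in frame.columns:
            raw = row[label_col]
            if isinstance(raw, str) and raw.strip():
                labels = [t.strip() for t in raw.split(";") if t.strip()]
        rec = CompoundRecord(cid, smiles, std, replicate_labels=labels)
        if compute_features:
            try:
                rec.descriptors, rec.flags = compute_descriptors(std)
            except StructureError as exc:  # pragma: no cover - defensive
                rec.flags.append(f"descriptor_failure:{exc}")
                logger.warning("descriptor failure for %s: %s", cid, exc)
        records.append(rec)
    rejects_df = pd.DataFrame(
        rejects, columns=["row", "compound_id", "smiles", "reason"]
    )
    return records, rejects_df


def _read_smi(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"row{i}"
        rows.append({"id": cid, "smiles": smiles})
    return pd.DataFrame(rows, columns=["id", "smiles"])


# ---------------------------------------------------------------------------
# Replicate aggregation and endpoint filtering
# ---------------------------------------------------------------------------

def aggregate_replicates(
    replicate_labels: Sequence[str],
    *,
    drop_inconclusive: bool = False,
) -> str:
    """Resolve replicate activity calls by a >= 2/3 majority vote.

    Returns ``"active"`` (resp. ``"inactive"``) when at least two thirds
    of the replicates agree on Active (resp. Inactive); otherwise
    ``"excluded"``.  By default Inconclusive replicates stay in the
    denominator, which makes the vote harder to win (the conservative
    reading); ``drop_inconclusive=True`` removes them before voting.
    """
    if len(replicate_labels) == 0:
        raise ValueError("replicate label list must be non-empty")
    labels = list(replicate_labels)
    bad = set(labels) - {ACTIVE, INACTIVE, INCONCLUSIVE}
    if bad:
        raise ValueError(f"unknown replicate labels: {sorted(bad)}")
    if drop_inconclusive:
        labels = [l for l in labels if l != INCONCLUSIVE]
        if not labels:
            return "excluded"
    n = len(labels)
    n_active = labels.count(ACTIVE)
    n_inactive = labels.count(INACTIVE)
    # >= 2/3 compared via integers (3*count >= 2*n) to dodge float edges.
    if 3 * n_active >= 2 * n:
        return "active"
    if 3 * n_inactive >= 2 * n:
        return "inactive"
    return "excluded"


def filter_assay(
    dataset: AssayDataset,
    min_active_ratio: float = DEFAULT_MIN_ACTIVE_RATIO,
) -> FilterDecision:
    """Keep an endpoint iff its active ratio is >= the cutoff (inclusive)."""
    if dataset.n_compounds == 0:
        raise ValueError("dataset is empty")
    decision = FilterDecision(
        keep=dataset.active_ratio >= min_active_ratio,
        active_ratio=dataset.active_ratio,
        min_active_ratio=min_active_ratio,
    )
    logger.info("filter_assay %s: %s", dataset.endpoint_name, decision.reason)
    return decision


# ---------------------------------------------------------------------------
# Dataset archive
# ---------------------------------------------------------------------------

def save_dataset(dataset: AssayDataset, out_dir: str | Path) -> Path:
    """Write an endpoint dataset as CSV + descriptor matrix + metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"compound_id": dataset.compound_ids, "label": dataset.y}
    ).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(
        dataset.X, columns=dataset.descriptor_names
    ).to_csv(out / "descriptors.csv", index=False)
    import rdkit

    meta = {
        "endpoint_name": dataset.endpoint_name,
        "n_compounds": dataset.n_compounds,
        "active_ratio": dataset.active_ratio,
        "descriptor_names": dataset.descriptor_names,
        "rdkit_version": rdkit.__version__,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return out


def load_dataset(in_dir: str | Path) -> AssayDataset:
    """Read back a dataset archive written by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "metadata.json").read_text())
    labels = pd.read_csv(in_dir / "labels.csv")
    X = pd.read_csv(in_dir / "descriptors.csv").to_numpy(dtype=float)
    return AssayDataset(
        endpoint_name=meta["endpoint_name"],
        compound_ids=[str(c) for c in labels["compound_id"]],
        X=X,
        y=labels["label"].to_numpy(dtype=int),
        descriptor_names=meta["descriptor_names"],
    )
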