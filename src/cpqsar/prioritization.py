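"""Prioritization of library compounds against reference disruptors.

Two complementary similarity routes operate on the screened p-value
matrix rather than on chemical structure:

* a binary *bioactivity fingerprint* per compound — one bit per
  endpoint, set when p1 > p0 — compared by Tanimoto coefficient against
  a reference compound's fingerprint;
* a 2-D t-SNE embedding of the full conformal p-value profiles, with a
  density-based cluster extracted around the reference.

The consensus of the two routes (compounds that are both Tanimoto hits
and members of the reference's embedding cluster) is the prioritized
candidate list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .screening import PValueMatrix


def fingerprint(p1_row: Sequence[float], p0_row: Sequence[float]) -> np.ndarray:
    """Binary bioactivity fingerprint: bit_j = 1 iff p1_j > p0_j.

    The bit expresses which p-value is larger, not a class assignment at
    any significance level.  Ties give bit 0.
    """
    p1 = np.asarray(p1_row, dtype=float)
    p0 = np.asarray(p0_row, dtype=float)
    if p1.shape != p0.shape:
        raise ValueError("p1 and p0 rows must be aligned")
    return (p1 > p0).astype(int)


def fingerprint_matrix(matrix: PValueMatrix) -> np.ndarray:
    """Fingerprints for every compound, rows aligned with the matrix."""
    return (matrix.p1 > matrix.p0).astype(int)


def tanimoto(fp_a: Sequence[int], fp_b: Sequence[int]) -> float:
    """Tanimoto coefficient c / (a + b - c) over on-bits.

    Two all-zero fingerprints have an empty union; by convention the
    coefficient is 0 (with a warning), although identical all-inactive
    profiles are arguably similar.
    """
    a = np.asarray(fp_a, dtype=int)
    b = np.asarray(fp_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    on_a = int(a.sum())
    on_b = int(b.sum())
    shared = int((a & b).sum())
    union = on_a + on_b - shared
    if union == 0:
        warnings.warn(
            "both fingerprints are all-zero; Tanimoto reported as 0",
            stacklevel=2,
        )
        return 0.0
    return shared / union


def rank_by_tanimoto(
    fingerprints: np.ndarray,
    compound_ids: Sequence[str],
    reference_fp: Sequence[int],
    cutoff: float = 0.8,
) -> pd.DataFrame:
    """Hits with Tanimoto >= cutoff, sorted by similarity.

    Ties are broken by compound id for a deterministic order; exact
    profile matches (T = 1) are flagged.
    """
    fingerprints = np.asarray(fingerprints, dtype=int)
    ref = np.asarray(reference_fp, dtype=int)
    if fingerprints.shape[1] != ref.shape[0]:
        raise ValueError("fingerprint battery sizes differ")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cid, fp in zip(compound_ids, fingerprints):
            t = tanimoto(fp, ref)
            if t >= cutoff:
                rows.append(
                    {"compound": cid, "tanimoto": t,
                     "exact_profile_match": t == 1.0}
                )
    frame = pd.DataFrame(
        rows, columns=["compound", "tanimoto", "exact_profile_match"]
    )
    return frame.sort_values(
        ["tanimoto", "compound"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass
class Embedding2D:
    """Planar t-SNE coordinates of p-value profiles."""

    compound_ids: list[str]
    coords: np.ndarray  # (n, 2)
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.compound_ids), 2):
            raise ValueError("one (x, y) pair per compound required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound": self.compound_ids,
             "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )


def embed(
    matrix: PValueMatrix,
    *,
    perplexity: float = 30.0,
    seed: int = 0,
    features: str = "p1_and_p0",
) -> Embedding2D:
    """t-SNE of conformal p-value profiles into the plane.

    The default feature vector concatenates p1 and p0 per endpoint
    (2 x battery size); ``features='p1_only'`` uses p1 alone.
    Deterministic given the seed.
    """
    if features == "p1_and_p0":
        X = np.hstack([matrix.p1, matrix.p0])
    elif features == "p1_only":
        X = matrix.p1
    else:
        raise ValueError("features must be 'p1_and_p0' or 'p1_only'")
    n = X.shape[0]
    if n <= perplexity:
        raise ValueError(
            f"perplexity {perplexity} requires more than {int(perplexity)} "
            f"compounds; got {n}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(X)
    return Embedding2D(
        compound_ids=list(matrix.compound_ids),
        coords=coords,
        perplexity=perplexity,
        seed=seed,
    )


def cluster_around(
    embedding: Embedding2D,
    reference_id: str,
    *,
    min_samples: int = 4,
    eps: float | None = None,
) -> set[str]:
    """Density-connected cluster of the embedding containing the reference.

    DBSCAN on the planar coordinates; when ``eps`` is not given it is
    set adaptively to 3 x the median distance to the
    ``min_samples``-th nearest neighbour, so the scale-free t-SNE output
    needs no manual tuning (the factor is generous enough to absorb
    cluster fringes while staying far below between-cluster gaps).
    If the reference is density noise, the returned set is the
    singleton {reference_id}.
    """
    ids = list(embedding.compound_ids)
    if reference_id not in ids:
        raise KeyError(f"reference {reference_id!r} not in embedding")
    X = embedding.coords
    if eps is None:
        nn = NearestNeighbors(n_neighbors=min_samples + 1).fit(X)
        dists, _ = nn.kneighbors(X)
        eps = 3.0 * float(np.median(dists[:, min_samples]))
        if eps <= 0:  # all points coincide
            eps = 1e-9
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
    ref_label = labels[ids.index(reference_id)]
    if ref_label == -1:
        return {reference_id}
    return {cid for cid, lab in zip(ids, labels) if lab == ref_label}


def consensus(
    tsne_members: set[str],
    tanimoto_hits: set[str],
    reference_id: str | None = None,
) -> set[str]:
    """Compounds selected by both similarity routes (reference excluded)."""
    out = set(tsne_members) & set(tanimoto_hits)
    if reference_id is not None:
        out.discard(reference_id)
    return out
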