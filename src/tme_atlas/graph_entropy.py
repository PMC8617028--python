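"""Patient mixability as Shannon entropy over kNN neighborhoods.

For each cell *i*, the k = 80 nearest neighbors (Euclidean distance in a
low-dimensional embedding, self excluded) define a patient composition
p_i^d (fraction of neighbors from patient d, d = 1..D, summing to 1);
the mixability is

    H_i = - sum_d  p_i^d * log2 p_i^d        (0 * log 0 := 0)

so H_i = 0 for a patient-pure neighborhood and H_i = log2 D for a
perfectly uniform one. Cohorts larger than 25,000 cells are subsampled
uniformly first; neighbors are computed within the subsample.

Neighbor search is exact (all pairwise distances, chunked) with distance
ties broken by ascending cell index so results are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger("tme_atlas")


@dataclass
class NeighborGraph:
    """Exact kNN over an embedding; ``indices[i]`` are cell i's neighbors."""

    embedding: pd.DataFrame  # cells x d
    k: int
    indices: np.ndarray  # cells x k int

    @property
    def cell_ids(self) -> pd.Index:
        return self.embedding.index


def subsample_cells(
    cell_ids, n: int = 25_000, seed: int = 0
) -> list[str]:
    """Uniform without-replacement subsample; returns all if n >= size."""
    if n <= 0:
        raise ValueError("n must be positive")
    ids = list(cell_ids)
    if n >= len(ids):
        logger.info("subsample target %d >= %d cells; returning all", n, len(ids))
        return ids
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(pick)]


def build_knn(embedding: pd.DataFrame, k: int = 80, chunk: int = 2_048) -> NeighborGraph:
    """Exact k nearest neighbors by Euclidean distance, self excluded.

    Ties at equal distance break by ascending cell index. Raises on NaN
    coordinates or k >= number of cells.
    """
    X = embedding.to_numpy(dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    if not np.isfinite(X).all():
        raise ValueError("embedding contains non-finite coordinates")
    indices = np.empty((n, k), dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = cdist(X[lo:hi], X)
        rows = np.arange(lo, hi)
        d[np.arange(hi - lo), rows] = np.inf  # exclude self
        # Full sort on (distance, index) so boundary ties resolve by index.
        idx = np.broadcast_to(np.arange(n), d.shape)
        order = np.lexsort((idx, d), axis=1)
        indices[lo:hi] = order[:, :k]
    return NeighborGraph(embedding=embedding, k=k, indices=indices)


def neighborhood_entropy(
    graph: NeighborGraph, patient_labels: pd.Series
) -> pd.DataFrame:
    """Per-cell patient-composition entropy in bits.

    Returns a table with H (bits), the dominant neighbor patient, and
    one fraction column per patient. 0 <= H <= log2(D) always.
    """
    labels = patient_labels.reindex(graph.cell_ids)
    if labels.isna().any():
        bad = labels.index[labels.isna()][0]
        raise KeyError(f"cell {bad!r} has no patient label")
    patients = sorted(labels.unique())
    code = labels.map({p: i for i, p in enumerate(patients)}).to_numpy()
    neigh = code[graph.indices]  # cells x k
    D = len(patients)
    counts = np.zeros((len(labels), D), dtype=np.int64)
    for d in range(D):
        counts[:, d] = (neigh == d).sum(axis=1)
    p = counts / graph.k
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    H = -terms.sum(axis=1)
    out = pd.DataFrame({"H": H}, index=graph.cell_ids)
    out["dominant_patient"] = [patients[i] for i in np.argmax(counts, axis=1)]
    for i, pat in enumerate(patients):
        out[f"p_{pat}"] = p[:, i]
    return out


def entropy_summary(
    entropy: pd.DataFrame,
    group_labels: pd.Series,
    n_bins: int = 40,
    h_max: float | None = None,
) -> pd.DataFrame:
    """Per-group mean/median entropy plus a fixed-grid histogram density."""
    groups = group_labels.reindex(entropy.index)
    if h_max is None:
        h_max = max(float(entropy["H"].max()), 1e-12)
    edges = np.linspace(0.0, h_max, n_bins + 1)
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        h = entropy.loc[idx, "H"].to_numpy()
        hist, _ = np.histogram(h, bins=edges, density=True)
        rows.append(
            {
                "group": g,
                "n_cells": len(h),
                "mean_H": float(h.mean()),
                "median_H": float(np.median(h)),
                "density": hist.tolist(),
            }
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def mixability(
    embedding: pd.DataFrame,
    patient_labels: pd.Series,
    k: int = 80,
    subsample: int = 25_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsample, build the kNN graph and compute per-cell entropy."""
    keep = subsample_cells(embedding.index, subsample, seed)
    graph = build_knn(embedding.loc[keep], k=k)
    return neighborhood_entropy(graph, patient_labels)
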