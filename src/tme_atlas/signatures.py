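"""Gene-set scoring, marker ranking, cross-dataset signature comparison,
origin label transfer, and druggable-gene intersection.

A gene-set score is the plain per-cell mean of log-normalized expression
over the set genes present in the matrix (no background-control
subtraction). Marker genes are ranked one-vs-rest with a Wilcoxon
rank-sum test (normal approximation with tie correction) and
Benjamini-Hochberg adjustment within each group; log2 fold changes use a
1e-9 pseudocount. Origin transfer assigns each query cell the reference
centroid with the highest Spearman correlation over shared marker genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import DrugGeneTable, GeneSetCollection

logger = logging.getLogger("tme_atlas")

LOG2FC_PSEUDOCOUNT = 1e-9


# ---------------------------------------------------------------------------
# Gene-set scores
# ---------------------------------------------------------------------------


def score_gene_set(norm: pd.DataFrame, gene_set, name: str = "set") -> pd.Series:
    """Per-cell mean log-normalized expression over the set's genes.

    Genes absent from the matrix are dropped (logged); zero overlap is
    an error naming the set.
    """
    genes = [g for g in gene_set if g in norm.columns]
    missing = len(list(gene_set)) - len(genes)
    if not genes:
        raise KeyError(f"gene set {name!r} shares no genes with the matrix")
    if missing:
        logger.info("gene set %s: %d gene(s) absent from matrix", name, missing)
    return norm[genes].mean(axis=1).rename(name)


def score_gene_sets(norm: pd.DataFrame, collection: GeneSetCollection) -> pd.DataFrame:
    """Score every set in a collection; columns are set names."""
    return pd.DataFrame(
        {name: score_gene_set(norm, collection[name], name) for name in collection}
    )


def scale_scores_01(scores: pd.Series) -> pd.Series:
    """Min-max scale to [0, 1]; a constant vector maps to all zeros."""
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        warnings.warn("constant score vector scaled to all zeros", stacklevel=2)
        return pd.Series(0.0, index=scores.index, name=scores.name)
    return (scores - lo) / (hi - lo)


def score_correlation(score_a: pd.Series, score_b: pd.Series) -> float:
    """Pearson correlation between two per-cell score vectors."""
    a, b = score_a.align(score_b, join="inner")
    if len(a) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("zero-variance score vector")
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])


# ---------------------------------------------------------------------------
# Marker ranking
# ---------------------------------------------------------------------------


def rank_marker_genes(norm: pd.DataFrame, group_labels: pd.Series) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table per group.

    Columns: group, gene_id, log2fc, p, p_adj, rank. P values use the
    normal approximation with tie correction and continuity correction;
    BH adjustment is applied within each group. Ranking is by p, then
    |log2fc| descending, then gene id.
    """
    labels = group_labels.reindex(norm.index)
    if labels.isna().any():
        raise KeyError("every cell needs a group label")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for one-vs-rest ranking")
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with < 2 cells: {small.index.tolist()}")

    X = norm.to_numpy(dtype=float)
    n = X.shape[0]
    ranks = scipy.stats.rankdata(X, axis=0)
    # Tie correction term sum(t^3 - t) per gene.
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)

    frames = []
    for g in groups:
        in_g = (labels == g).to_numpy()
        n1 = int(in_g.sum())
        n2 = n - n1
        rank_sum = ranks[in_g].sum(axis=0)
        U = rank_sum - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (U - mu - np.sign(U - mu) * 0.5) / sigma
        p = np.where(sigma > 0, 2 * scipy.stats.norm.sf(np.abs(z)), 1.0)
        p = np.minimum(p, 1.0)
        mean_in = X[in_g].mean(axis=0)
        mean_out = X[~in_g].mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            log2fc = np.log2(
                (mean_in + LOG2FC_PSEUDOCOUNT) / (mean_out + LOG2FC_PSEUDOCOUNT)
            )
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        tbl = pd.DataFrame(
            {
                "group": g,
                "gene_id": norm.columns,
                "log2fc": log2fc,
                "p": p,
                "p_adj": p_adj,
            }
        )
        tbl = tbl.sort_values(
            by=["p", "log2fc", "gene_id"],
            ascending=[True, False, True],
            key=lambda s: s.abs() if s.name == "log2fc" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        tbl["rank"] = np.arange(1, len(tbl) + 1)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


def filter_degs(
    marker_table: pd.DataFrame,
    min_log2fc: float = 0.2,
    max_padj: float = 0.05,
) -> list[str]:
    """Genes with log2FC strictly above and adjusted P strictly below cutoffs."""
    hit = (marker_table["log2fc"] > min_log2fc) & (marker_table["p_adj"] < max_padj)
    return sorted(marker_table.loc[hit, "gene_id"].unique())


def expressed_genes(norm: pd.DataFrame, min_frac: float = 0.10) -> list[str]:
    """Genes with nonzero values in at least ``min_frac`` of the cells."""
    frac = (norm > 0).mean(axis=0)
    return sorted(frac.index[frac >= min_frac])


# ---------------------------------------------------------------------------
# Cross-dataset aggregation
# ---------------------------------------------------------------------------


def top_markers(marker_table: pd.DataFrame, group: str, top_n: int) -> list[str]:
    """The group's top-n marker gene ids in rank order."""
    sub = marker_table[marker_table["group"] == group].sort_values("rank")
    return sub["gene_id"].head(top_n).tolist()


def aggregate_profiles(
    norm_by_dataset: dict[str, pd.DataFrame],
    group_labels_by_dataset: dict[str, pd.Series],
    marker_tables: dict[str, pd.DataFrame],
    top_n: int = 50,
) -> pd.DataFrame:
    """Mean expression of the union of top-n markers, per dataset group.

    Rows are the union of every group's top-n signature genes restricted
    to genes present in all datasets; columns are "dataset:group". Used
    to compare cell populations across cohorts by correlation.
    """
    shared = None
    for norm in norm_by_dataset.values():
        cols = set(norm.columns)
        shared = cols if shared is None else shared & cols
    signature: set[str] = set()
    for ds, table in marker_tables.items():
        for g in sorted(table["group"].unique()):
            signature.update(top_markers(table, g, top_n))
    genes = sorted(signature & shared)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} shared signature genes (< 3)")
    cols = {}
    for ds, norm in norm_by_dataset.items():
        labels = group_labels_by_dataset[ds].reindex(norm.index)
        for g in sorted(labels.unique()):
            cols[f"{ds}:{g}"] = norm.loc[labels == g, genes].mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def profile_correlation(profile: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of aggregated profiles (groups x groups)."""
    if profile.shape[1] < 2:
        raise ValueError("need at least two groups")
    if profile.shape[0] < 3:
        raise ValueError("need at least three shared genes")
    return profile.corr(method="pearson")


# ---------------------------------------------------------------------------
# Origin label transfer
# ---------------------------------------------------------------------------


def transfer_labels(
    query_norm: pd.DataFrame, reference_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Assign each query cell the most Spearman-similar reference centroid.

    ``reference_profiles`` is genes x types (mean expression per
    reference type). Similarity is Spearman correlation over the shared
    genes, making the call invariant to monotone per-cell transforms of
    the query. Ties resolve to the lexicographically first label and are
    flagged.
    """
    if reference_profiles.shape[1] < 2:
        raise ValueError("need at least two reference types")
    shared = [g for g in reference_profiles.index if g in query_norm.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes (< 3)")
    Q = query_norm[shared].to_numpy(dtype=float)
    R = reference_profiles.loc[shared].to_numpy(dtype=float)
    qr = scipy.stats.rankdata(Q, axis=1)
    rr = scipy.stats.rankdata(R, axis=0)
    qz = qr - qr.mean(axis=1, keepdims=True)
    rz = rr - rr.mean(axis=0, keepdims=True)
    qn = np.linalg.norm(qz, axis=1, keepdims=True)
    rn = np.linalg.norm(rz, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (qz @ rz) / (qn * rn)
    sim = np.nan_to_num(sim, nan=0.0)
    types = list(reference_profiles.columns)  # column order; argmax → first max
    order = np.argsort(types)
    sim_sorted = sim[:, order]
    best = np.argmax(sim_sorted, axis=1)
    best_sim = sim_sorted[np.arange(len(sim)), best]
    tie = (np.isclose(sim_sorted, best_sim[:, None])).sum(axis=1) > 1
    labels = [types[order[i]] for i in best]
    out = pd.DataFrame(
        {"predicted_type": labels, "similarity": best_sim, "tie": tie},
        index=query_norm.index,
    )
    for j, t in enumerate(types):
        out[f"sim_{t}"] = sim[:, j]
    return out


# ---------------------------------------------------------------------------
# Druggable-gene intersection
# ---------------------------------------------------------------------------


def druggable_intersection(
    marker_table: pd.DataFrame,
    drug_table: DrugGeneTable,
    top_n: int = 100,
    exclude_categories: set[str] = frozenset({"druggable genome"}),
) -> pd.DataFrame:
    """Intersect each group's top-n markers with druggable-gene categories.

    Rows of the interaction table whose category is excluded (by default
    the sequence/structure-predicted "druggable genome" catch-all) are
    dropped before intersection. A gene annotated in several categories
    appears once per category.
    """
    drugs = drug_table.frame
    drugs = drugs[~drugs["category"].isin(set(exclude_categories))]
    rows = []
    for g in sorted(marker_table["group"].unique()):
        top = set(top_markers(marker_table, g, top_n))
        hit = drugs[drugs["gene_id"].isin(top)]
        for r in hit.itertuples(index=False):
            rows.append({"group": g, "gene_id": r.gene_id, "category": r.category})
    out = pd.DataFrame(rows, columns=["group", "gene_id", "category"])
    return out.sort_values(["group", "category", "gene_id"]).reset_index(drop=True)


def druggable_counts(intersection: pd.DataFrame) -> pd.DataFrame:
    """Gene counts per group per category from an intersection table."""
    if intersection.empty:
        return pd.DataFrame(columns=["group", "category", "n_genes"])
    out = (
        intersection.groupby(["group", "category"])["gene_id"]
        .nunique()
        .rename("n_genes")
        .reset_index()
    )
    return out
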