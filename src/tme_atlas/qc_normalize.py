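"""Cell quality control, library-size normalization, HVG selection and
covariate residualization.

The QC cascade removes cells with fewer than 2000 UMIs or fewer than 500
detected genes, cells with more than 20% mitochondrial counts, and
doublet-like cells with more than 70,000 UMIs or more than 10,000
detected genes. All rules use strict inequalities for removal, so cells
sitting exactly on a boundary are kept. The kept set is the conjunction
of all rules and does not depend on application order; sequential
attrition counts are reported separately because per-rule removal counts
do depend on order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix

logger = logging.getLogger("tme_atlas")

#: Order in which the filtration rules are applied when reporting
#: sequential attrition: depth/complexity first, mito second, doublet last.
RULE_ORDER = ("min_umi", "min_genes", "max_pct_mito", "max_umi", "max_genes")


@dataclass
class QCThresholds:
    """Cell-filtration cutoffs; removal is strict on every bound."""

    min_umi: int = 2_000
    min_genes: int = 500
    max_pct_mito: float = 20.0
    max_umi: int = 70_000
    max_genes: int = 10_000

    def __post_init__(self) -> None:
        if self.min_umi > self.max_umi:
            raise ValueError("min_umi exceeds max_umi")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes exceeds max_genes")
        if not 0 <= self.max_pct_mito <= 100:
            raise ValueError("max_pct_mito must lie in [0, 100]")


@dataclass
class CellQC:
    """Per-cell QC metrics plus per-rule pass flags."""

    table: pd.DataFrame  # total_umi, n_genes_detected, pct_mito[, pct_hsp]
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def kept(self) -> pd.Series:
        flags = apply_rules(self.table, self.thresholds)
        return flags.all(axis=1)


def compute_cell_qc(
    cm: CountMatrix, hsp_genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-cell totals, detected-gene counts and mitochondrial fraction.

    ``pct_mito`` is 100 x (mitochondrial counts / total counts); cells
    with zero total get pct_mito = 0 (they fail the depth rule anyway).
    If ``hsp_genes`` is None, heat-shock-protein content is computed from
    genes whose id starts with "HSP" (with a warning) when any exist.
    """
    counts = sp.csr_matrix(cm.counts)
    total = np.asarray(counts.sum(axis=1)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito_mask = cm.gene_meta["is_mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito_counts / np.maximum(total, 1), 0.0)
    out = pd.DataFrame(
        {
            "total_umi": total.astype(np.int64),
            "n_genes_detected": n_genes.astype(np.int64),
            "pct_mito": pct_mito,
        },
        index=pd.Index(cm.cell_ids, name="cell_id"),
    )
    if hsp_genes is None:
        hsp_mask = np.array([str(g).startswith("HSP") for g in cm.gene_ids])
        if hsp_mask.any():
            warnings.warn(
                "no HSP gene list supplied; using prefix match 'HSP'",
                stacklevel=2,
            )
    else:
        hsp_mask = np.isin(cm.gene_ids.astype(str), np.asarray(hsp_genes, dtype=str))
    if hsp_mask.any():
        hsp_counts = np.asarray(counts[:, hsp_mask].sum(axis=1)).ravel()
        out["pct_hsp"] = np.where(
            total > 0, 100.0 * hsp_counts / np.maximum(total, 1), 0.0
        )
    return out


def apply_rules(qc: pd.DataFrame, t: QCThresholds) -> pd.DataFrame:
    """Boolean pass flag per cell per rule (True = rule satisfied)."""
    return pd.DataFrame(
        {
            "min_umi": qc["total_umi"] >= t.min_umi,
            "min_genes": qc["n_genes_detected"] >= t.min_genes,
            "max_pct_mito": qc["pct_mito"] <= t.max_pct_mito,
            "max_umi": qc["total_umi"] <= t.max_umi,
            "max_genes": qc["n_genes_detected"] <= t.max_genes,
        },
        index=qc.index,
    )


def filter_cells(qc: pd.DataFrame, t: QCThresholds | None = None) -> list[str]:
    """Ids of cells passing every rule (order-free conjunction)."""
    t = t or QCThresholds()
    flags = apply_rules(qc, t)
    return flags.index[flags.all(axis=1)].tolist()


def sequential_attrition(qc: pd.DataFrame, t: QCThresholds | None = None) -> pd.DataFrame:
    """Cells removed per rule when rules are applied in the stated order.

    The final kept count equals :func:`filter_cells`'s (conjunction), but
    the per-rule removal attribution depends on order.
    """
    t = t or QCThresholds()
    flags = apply_rules(qc, t)
    alive = pd.Series(True, index=qc.index)
    rows = []
    for rule in RULE_ORDER:
        removed = int((alive & ~flags[rule]).sum())
        alive &= flags[rule]
        rows.append({"rule": rule, "removed": removed, "remaining": int(alive.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_log(
    cm: CountMatrix | sp.spmatrix,
    target_sum: float | None = None,
) -> pd.DataFrame:
    """Library-size normalize each cell to ``target_sum`` then log1p.

    ``target_sum`` defaults to the median of per-cell totals (over cells
    with nonzero totals). Zero-total cells are left all-zero with a
    warning. Returns a dense cells x genes DataFrame of natural-log
    values.
    """
    if isinstance(cm, CountMatrix):
        counts = cm.counts
        index = pd.Index(cm.cell_ids, name="cell_id")
        columns = pd.Index(cm.gene_ids, name="gene_id")
    else:
        counts = sp.csr_matrix(cm)
        index = pd.RangeIndex(counts.shape[0])
        columns = pd.RangeIndex(counts.shape[1])
    totals = np.asarray(counts.sum(axis=1), dtype=float).ravel()
    if target_sum is None:
        nonzero = totals[totals > 0]
        if nonzero.size == 0:
            raise ValueError("all cells have zero counts")
        target_sum = float(np.median(nonzero))
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} zero-total cell(s) left all-zero",
            stacklevel=2,
        )
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals), where=totals > 0
    )
    scaled = sp.diags(scale) @ counts
    dense = np.log1p(np.asarray(scaled.todense()))
    return pd.DataFrame(dense, index=index, columns=columns)


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------


def select_hvg(norm: pd.DataFrame, n_top: int = 2_000, n_bins: int = 20) -> list[str]:
    """Rank genes by dispersion z-score within mean-expression bins.

    Dispersion is variance/mean of the log-normalized values; genes are
    binned into ``n_bins`` equal-occupancy bins of mean expression and
    the dispersion is z-scored within each bin. Ties break by gene id
    for determinism. If ``n_top`` exceeds the gene count, all genes are
    returned with a warning.
    """
    means = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(means > 0, var / means, 0.0)
    dispersion = pd.Series(dispersion, index=norm.columns)
    try:
        bins = pd.qcut(means.rank(method="first"), q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=means.index)
    z = pd.Series(0.0, index=dispersion.index)
    for _, idx in dispersion.groupby(bins).groups.items():
        vals = dispersion.loc[idx]
        sd = vals.std(ddof=1)
        if sd > 0:
            z.loc[idx] = (vals - vals.mean()) / sd
        # constant-dispersion bin: z stays 0
    if n_top > len(z):
        warnings.warn(
            f"n_top={n_top} exceeds {len(z)} genes; returning all", stacklevel=2
        )
        n_top = len(z)
    # z ties (e.g. singleton bins) break by raw dispersion, then gene id.
    order = sorted(z.index, key=lambda g: (-z[g], -dispersion[g], str(g)))
    return list(order[:n_top])


# ---------------------------------------------------------------------------
# Covariate regression
# ---------------------------------------------------------------------------


def regress_out(norm: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize each gene on the covariates (OLS with intercept).

    Collinear covariate columns are dropped with a warning naming them
    (detected by rank-revealing QR on the design matrix).
    """
    if len(norm) < 2:
        raise ValueError("need at least 2 cells to regress")
    cov = covariates.reindex(norm.index)
    if cov.isna().any().any() or not np.isfinite(cov.to_numpy(dtype=float)).all():
        raise ValueError("covariates must be finite for every cell")
    X = np.column_stack([np.ones(len(norm)), cov.to_numpy(dtype=float)])
    names = ["intercept", *cov.columns]
    # Drop columns that do not increase the design rank (greedy, in order).
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate {names[j]!r}", stacklevel=2)
            logger.info("regress_out dropped collinear covariate %s", names[j])
    Xk = X[:, keep]
    Y = norm.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    resid = Y - Xk @ beta
    return pd.DataFrame(resid, index=norm.index, columns=norm.columns)
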