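"""Expression-inferred copy-number profiles and malignant-cell calling.

Relative expression (log-normalized, centered on a nonmalignant
baseline, clipped) is smoothed with a moving average of 101 genes along
each chromosome; the mean baseline profile is then subtracted from every
cell so the nonmalignant karyotype sits at zero. A per-cell CNV score
(mean squared profile) and a baseline-quantile threshold turn the
profile into a malignant/nonmalignant call.

The window length and the +/-3 clip are the referenced tool's documented
defaults; both are configurable. Windows shrink at chromosome ends so
the profile keeps one value per gene, and never span chromosomes.
Denoising and HMM segmentation are intentionally absent: the profile is
a smoothed relative-expression proxy, not an absolute copy number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


@dataclass
class CNVProfile:
    """Cells x genomic-position smoothed relative-expression matrix."""

    matrix: pd.DataFrame  # cells x genes, genes ordered by (chrom, start)
    gene_order: pd.DataFrame  # chrom, start per profiled gene, in order
    window_size: int
    clip_limit: float
    baseline_cell_ids: list[str]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.gene_order["chrom"]))


def relative_expression(
    norm: pd.DataFrame,
    baseline_ids: list[str],
    clip_limit: float = 3.0,
) -> pd.DataFrame:
    """Center each gene on its baseline-cell mean and clip.

    ``baseline_ids`` are nonmalignant (stromal/immune) cells defining the
    normal-karyotype reference. Values are clipped to
    ``[-clip_limit, +clip_limit]`` on the centered log scale.
    """
    baseline_ids = list(baseline_ids)
    if not baseline_ids:
        raise ValueError("baseline_ids must be nonempty")
    missing = set(baseline_ids) - set(norm.index)
    if missing:
        raise KeyError(f"baseline cells not in matrix: {sorted(missing)[:5]}")
    center = norm.loc[baseline_ids].mean(axis=0)
    return (norm - center).clip(-clip_limit, clip_limit)


def order_genes(gene_meta: pd.DataFrame) -> pd.DataFrame:
    """Placed genes ordered by chromosome then start; unplaced dropped."""
    placed = gene_meta[gene_meta["chrom"].notna()].copy()
    placed["start"] = placed["start"].astype(np.int64)
    return placed.sort_values(
        ["chrom", "start"], kind="mergesort"
    )[["chrom", "start"]]


def moving_average_cnv(
    centered: pd.DataFrame,
    gene_meta: pd.DataFrame,
    baseline_ids: list[str],
    window_size: int = 101,
    clip_limit: float = 3.0,
) -> CNVProfile:
    """Smooth centered expression along the genome and re-zero on baseline.

    For each cell and each gene position the profile is the mean of the
    centered values in a ``window_size``-gene window centered there,
    truncated (shrunk) at chromosome ends. The mean profile over the
    baseline cells is then subtracted from all cells, so baseline
    profiles average to zero per position.
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError("window_size must be odd and >= 3")
    order = order_genes(gene_meta)
    genes = [g for g in order.index if g in centered.columns]
    if not genes:
        raise ValueError("no placed genes present in the expression matrix")
    order = order.loc[genes]
    X = centered[genes].to_numpy(dtype=float)

    smoothed = np.empty_like(X)
    col = 0
    for chrom, block in order.groupby("chrom", sort=False):
        n = len(block)
        smoothed[:, col : col + n] = _moving_average(X[:, col : col + n], window_size)
        col += n

    out = pd.DataFrame(smoothed, index=centered.index, columns=genes)
    baseline_ids = list(baseline_ids)
    if not baseline_ids:
        raise ValueError("baseline_ids must be nonempty")
    baseline_mean = out.loc[baseline_ids].mean(axis=0)
    out = out - baseline_mean
    return CNVProfile(
        matrix=out,
        gene_order=order,
        window_size=window_size,
        clip_limit=clip_limit,
        baseline_cell_ids=baseline_ids,
    )


def _moving_average(X: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edge windows."""
    n = X.shape[1]
    half = w // 2
    csum = np.zeros((X.shape[0], n + 1))
    np.cumsum(X, axis=1, out=csum[:, 1:])
    pos = np.arange(n)
    lo = np.maximum(pos - half, 0)
    hi = np.minimum(pos + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def score_and_call(
    profile: CNVProfile, threshold_quantile: float = 0.95
) -> pd.DataFrame:
    """Mean-squared-profile CNV score and baseline-quantile malignant call.

    A cell is called malignant when its score exceeds the
    ``threshold_quantile`` of the baseline cells' scores. By
    construction at the default quantile at least 95% of baseline cells
    are called nonmalignant.
    """
    baseline = [c for c in profile.baseline_cell_ids if c in profile.matrix.index]
    if not baseline:
        raise ValueError("no baseline cells present in profile")
    scores = (profile.matrix.to_numpy() ** 2).mean(axis=1)
    scores = pd.Series(scores, index=profile.matrix.index, name="cnv_score")
    cutoff = float(np.quantile(scores.loc[baseline], threshold_quantile))
    return pd.DataFrame(
        {
            "cnv_score": scores,
            "malignant_call": scores > cutoff,
        }
    )


def chromosome_summary(profile: CNVProfile, cell_groups: pd.Series) -> pd.DataFrame:
    """Mean profile per chromosome per cell group (for reporting)."""
    rows = []
    for chrom, block in profile.gene_order.groupby("chrom", sort=False):
        sub = profile.matrix[block.index]
        for group, ids in cell_groups.groupby(cell_groups).groups.items():
            ids = [i for i in ids if i in sub.index]
            rows.append(
                {
                    "chrom": chrom,
                    "group": group,
                    "mean_profile": float(sub.loc[ids].to_numpy().mean()),
                    "n_cells": len(ids),
                }
            )
    return pd.DataFrame(rows)


def infer_cnv(
    cm: CountMatrix,
    norm: pd.DataFrame,
    baseline_ids: list[str],
    window_size: int = 101,
    clip_limit: float = 3.0,
    threshold_quantile: float = 0.95,
) -> tuple[CNVProfile, pd.DataFrame]:
    """Convenience wrapper: center, smooth, score and call in one step."""
    centered = relative_expression(norm, baseline_ids, clip_limit)
    profile = moving_average_cnv(
        centered, cm.gene_meta, baseline_ids, window_size, clip_limit
    )
    calls = score_and_call(profile, threshold_quantile)
    return profile, calls
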