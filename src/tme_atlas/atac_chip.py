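"""scATAC fragment processing and histone-mark promoter classification.

Fragments are reduced to Tn5 insertion events (one at the fragment start
and one at ``end - 1``, both 0-based, weighted by the fragment's count),
aggregated into a cells x 2.5 kb-window matrix, binarized, TF-IDF
weighted, and embedded by truncated SVD (latent semantic indexing, first
component dropped by default as depth-correlated). Cell QC applies the
five standard rules: fragments-in-peaks within [1000, 20000], FRiP >
0.10, TSS enrichment > 2, blacklist ratio < 0.05, nucleosome signal < 4.

TF-IDF uses term frequency x inverse document frequency
``idf_f = ln(1 + n_cells / n_cells_with_feature_f)`` on the binarized
matrix. Gene activity counts insertions in the gene body extended 2 kb
upstream of the TSS, strand-aware. Active promoters are genes with an
H3K4me3 peak within 1000 bp of the TSS that overlaps an H3K27ac peak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg

from .io_formats import FragmentSet, GenomicInterval

logger = logging.getLogger("tme_atlas")


# ---------------------------------------------------------------------------
# Insertions and the window matrix
# ---------------------------------------------------------------------------


def insertions_from_fragments(frags: FragmentSet) -> pd.DataFrame:
    """Expand fragments to per-position insertion events.

    Each fragment contributes two insertion sites — its start and
    ``end - 1`` — each weighted by the fragment's count, so per-cell
    insertion totals are exactly twice the summed fragment counts.
    """
    f = frags.frame
    left = f[["chrom", "start", "barcode", "count"]].rename(columns={"start": "pos"})
    right = f[["chrom", "barcode", "count"]].copy()
    right["pos"] = f["end"] - 1
    out = pd.concat([left, right[left.columns]], ignore_index=True)
    return out.rename(columns={"count": "weight"})


@dataclass
class WindowMatrix:
    """Cells x genomic-window insertion counts."""

    matrix: sp.csr_matrix
    cell_ids: np.ndarray
    windows: list[GenomicInterval]
    window_size: int
    binarized: bool = False

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def binarize(self) -> "WindowMatrix":
        b = self.matrix.copy()
        b.data = np.ones_like(b.data)
        return WindowMatrix(
            b.tocsr(), self.cell_ids, self.windows, self.window_size, binarized=True
        )


def build_window_matrix(
    frags: FragmentSet,
    chrom_sizes: dict[str, int],
    window_size: int = 2_500,
) -> WindowMatrix:
    """Count insertion events per cell per tiling window.

    Windows tile each chromosome as ``[i*w, (i+1)*w)`` with the last
    window truncated at the chromosome end. A fragment extending beyond
    its chromosome is an error naming the record.
    """
    f = frags.frame
    missing = set(f["chrom"]) - set(chrom_sizes)
    if missing:
        raise KeyError(f"chrom sizes missing for {sorted(missing)}")
    for row in f.itertuples():
        if row.end > chrom_sizes[row.chrom]:
            raise ValueError(
                f"fragment {row.chrom}:{row.start}-{row.end} ({row.barcode}) "
                f"exceeds chromosome size {chrom_sizes[row.chrom]}"
            )
    chroms = sorted(chrom_sizes)
    windows: list[GenomicInterval] = []
    offset: dict[str, int] = {}
    for c in chroms:
        offset[c] = len(windows)
        size = chrom_sizes[c]
        n_win = -(-size // window_size)
        for i in range(n_win):
            windows.append(
                GenomicInterval(c, i * window_size, min((i + 1) * window_size, size))
            )

    ins = insertions_from_fragments(frags)
    cell_ids = np.asarray(sorted(ins["barcode"].unique()), dtype=object)
    cell_index = {b: i for i, b in enumerate(cell_ids)}
    rows = ins["barcode"].map(cell_index).to_numpy()
    cols = (
        ins["chrom"].map(offset).to_numpy() + (ins["pos"] // window_size).to_numpy()
    )
    mat = sp.coo_matrix(
        (ins["weight"].to_numpy(), (rows, cols)),
        shape=(len(cell_ids), len(windows)),
    ).tocsr()
    return WindowMatrix(mat, cell_ids, windows, window_size)


# ---------------------------------------------------------------------------
# Interval overlap helpers (merged-interval searchsorted)
# ---------------------------------------------------------------------------


def _merge_intervals(intervals) -> dict[str, np.ndarray]:
    """Merge per chromosome; returns chrom -> (n, 2) array of [start, end)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    return merged


def _overlaps_any(
    chrom: np.ndarray, start: np.ndarray, end: np.ndarray, merged: dict[str, np.ndarray]
) -> np.ndarray:
    """Boolean: does [start, end) overlap any merged interval by >= 1 bp."""
    hit = np.zeros(len(chrom), dtype=bool)
    for c, ivs in merged.items():
        mask = chrom == c
        if not mask.any():
            continue
        s, e = start[mask], end[mask]
        # interval j overlaps iff ivs[j,0] < e and ivs[j,1] > s for some j
        idx = np.searchsorted(ivs[:, 0], e, side="left") - 1
        ok = (idx >= 0) & (np.take(ivs[:, 1], np.clip(idx, 0, None)) > s)
        hit[np.flatnonzero(mask)] = ok
    return hit


# ---------------------------------------------------------------------------
# Cell QC
# ---------------------------------------------------------------------------

ATAC_QC_RULES = (
    "fragments_in_peaks",
    "frip",
    "tss_enrichment",
    "blacklist_ratio",
    "nucleosome_signal",
)


def atac_cell_qc(
    frags: FragmentSet,
    peaks,
    tss: pd.Series | None,
    blacklist=(),
    min_fragments: int = 1_000,
    max_fragments: int = 20_000,
    min_frip: float = 0.10,
    min_tss_enrichment: float = 2.0,
    max_blacklist_ratio: float = 0.05,
    max_nucleosome_signal: float = 4.0,
    disable_rules: set[str] = frozenset(),
) -> pd.DataFrame:
    """Per-cell scATAC QC metrics and the joint keep decision.

    ``tss`` maps gene id -> (chrom, position) rows of a DataFrame or a
    Series of "chrom:pos" strings; pass None only with the
    ``tss_enrichment`` rule disabled. TSS enrichment is the
    position-averaged insertion coverage in +/-500 bp of the TSSs over
    the mean coverage in the two 100 bp flanks at +/-(900-1000) bp (flank
    floored at 0.1 to guard empty flanks). Nucleosome signal is
    (# fragments of 147-294 bp) / (# fragments < 147 bp), denominator
    floored at 1.
    """
    f = frags.frame
    if tss is None and "tss_enrichment" not in disable_rules:
        raise ValueError("no TSS positions given; disable the tss_enrichment rule")
    chrom = f["chrom"].to_numpy(dtype=object)
    start = f["start"].to_numpy()
    end = f["end"].to_numpy()
    weight = f["count"].to_numpy()
    barcode = f["barcode"].to_numpy(dtype=object)

    peak_merged = _merge_intervals(peaks)
    in_peak = _overlaps_any(chrom, start, end, peak_merged)
    bl_merged = _merge_intervals(blacklist) if len(list(blacklist)) else {}
    in_bl = (
        _overlaps_any(chrom, start, end, bl_merged)
        if bl_merged
        else np.zeros(len(f), dtype=bool)
    )

    tbl = pd.DataFrame(
        {
            "barcode": barcode,
            "weight": weight,
            "in_peak": np.where(in_peak, weight, 0),
            "in_blacklist": np.where(in_bl, weight, 0),
            "length": end - start,
        }
    )
    g = tbl.groupby("barcode", sort=True)
    total = g["weight"].sum()
    fip = g["in_peak"].sum()
    bl = g["in_blacklist"].sum()
    mono = tbl.assign(
        w=np.where((tbl["length"] >= 147) & (tbl["length"] < 295), weight, 0)
    ).groupby("barcode", sort=True)["w"].sum()
    sub = tbl.assign(w=np.where(tbl["length"] < 147, weight, 0)).groupby(
        "barcode", sort=True
    )["w"].sum()

    qc = pd.DataFrame(
        {
            "total_fragments": total,
            "fragments_in_peaks": fip,
            "frip": fip / total,
            "blacklist_ratio": bl / total,
            "nucleosome_signal": mono / np.maximum(sub, 1),
        }
    )
    qc.index.name = "barcode"

    if tss is not None:
        qc["tss_enrichment"] = _tss_enrichment(frags, tss)
    else:
        qc["tss_enrichment"] = np.nan

    flags = pd.DataFrame(index=qc.index)
    flags["fragments_in_peaks"] = (qc["fragments_in_peaks"] >= min_fragments) & (
        qc["fragments_in_peaks"] <= max_fragments
    )
    flags["frip"] = qc["frip"] > min_frip
    flags["tss_enrichment"] = qc["tss_enrichment"] > min_tss_enrichment
    flags["blacklist_ratio"] = qc["blacklist_ratio"] < max_blacklist_ratio
    flags["nucleosome_signal"] = qc["nucleosome_signal"] < max_nucleosome_signal
    for rule in disable_rules:
        flags[rule] = True
    qc["kept"] = flags.all(axis=1)
    for rule in ATAC_QC_RULES:
        qc[f"pass_{rule}"] = flags[rule]
    return qc


def _tss_enrichment(
    frags: FragmentSet,
    tss: pd.DataFrame | pd.Series,
    center_half: int = 500,
    flank_inner: int = 900,
    flank_outer: int = 1_000,
    flank_floor: float = 0.1,
) -> pd.Series:
    """Flank-ratio TSS enrichment per barcode."""
    if isinstance(tss, pd.Series):
        parts = tss.str.split(":", expand=True)
        tss = pd.DataFrame(
            {"chrom": parts[0], "pos": parts[1].astype(int)}, index=tss.index
        )
    ins = insertions_from_fragments(frags)
    center_w = np.zeros(len(ins))
    flank_w = np.zeros(len(ins))
    pos = ins["pos"].to_numpy()
    for _, row in tss.iterrows():
        on = (ins["chrom"] == row["chrom"]).to_numpy()
        delta = np.abs(pos - int(row["pos"]))
        center_w += np.where(on & (delta <= center_half), ins["weight"], 0)
        flank_w += np.where(
            on & (delta >= flank_inner) & (delta <= flank_outer), ins["weight"], 0
        )
    n_tss = len(tss)
    tmp = pd.DataFrame(
        {"barcode": ins["barcode"], "center": center_w, "flank": flank_w}
    )
    g = tmp.groupby("barcode", sort=True).sum(numeric_only=True)
    center_positions = (2 * center_half + 1) * n_tss
    flank_positions = 2 * (flank_outer - flank_inner + 1) * n_tss
    center_mean = g["center"] / center_positions
    flank_mean = g["flank"] / flank_positions
    return center_mean / flank_mean.clip(lower=flank_floor)


# ---------------------------------------------------------------------------
# TF-IDF and LSI
# ---------------------------------------------------------------------------


def tfidf_transform(wm: WindowMatrix) -> tuple[sp.csr_matrix, np.ndarray]:
    """TF-IDF weight a binarized window matrix.

    Term frequency divides each cell's row by its total; inverse document
    frequency is ``ln(1 + n_cells / n_cells_containing_feature)``.
    All-zero cells are dropped with a warning; all-zero features get a
    feature-sum floor of 1 and are flagged in the returned mask. Returns
    (weighted matrix, all-zero-feature mask); cell order of the input is
    preserved minus dropped cells.
    """
    if not wm.binarized:
        raise ValueError("tfidf_transform expects a binarized matrix")
    X = wm.matrix.tocsr().astype(float)
    cell_tot = np.asarray(X.sum(axis=1)).ravel()
    zero_cells = cell_tot == 0
    if zero_cells.any():
        warnings.warn(
            f"dropping {int(zero_cells.sum())} all-zero cell(s) before TF-IDF",
            stacklevel=2,
        )
        X = X[~zero_cells]
        cell_tot = cell_tot[~zero_cells]
    n_cells = X.shape[0]
    feat_tot = np.asarray(X.sum(axis=0)).ravel()
    zero_feats = feat_tot == 0
    idf = np.log1p(n_cells / np.maximum(feat_tot, 1.0))
    tf = sp.diags(1.0 / cell_tot) @ X
    out = tf @ sp.diags(idf)
    return out.tocsr(), zero_feats


@dataclass
class LsiEmbedding:
    """Truncated-SVD cell embedding with singular values."""

    coordinates: pd.DataFrame  # cells x retained components
    singular_values: np.ndarray  # all computed components, descending
    drop_first: bool


def lsi(
    tfidf: sp.spmatrix,
    cell_ids,
    n_components: int = 30,
    drop_first: bool = True,
    seed: int = 0,
) -> LsiEmbedding:
    """Latent semantic indexing: truncated SVD of the TF-IDF matrix.

    The cell embedding is U*S; with ``drop_first`` the first (depth-
    correlated) component is discarded, keeping components 2..K. Signs
    follow the convention that each component's largest-magnitude feature
    loading is positive, making the embedding deterministic.
    """
    X = sp.csr_matrix(tfidf)
    if n_components >= min(X.shape):
        raise ValueError(
            f"n_components={n_components} must be < min{X.shape}"
        )
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(X.shape))
    U, S, Vt = scipy.sparse.linalg.svds(X, k=n_components, v0=v0)
    order = np.argsort(S)[::-1]
    U, S, Vt = U[:, order], S[order], Vt[order]
    for j in range(n_components):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    emb = U * S
    start = 1 if drop_first else 0
    cols = [f"LSI{j + 1}" for j in range(start, n_components)]
    coords = pd.DataFrame(
        emb[:, start:], index=pd.Index(list(cell_ids), name="cell_id"), columns=cols
    )
    return LsiEmbedding(coordinates=coords, singular_values=S, drop_first=drop_first)


# ---------------------------------------------------------------------------
# Gene activity
# ---------------------------------------------------------------------------


def gene_activity(
    frags: FragmentSet,
    gene_annotation: pd.DataFrame,
    upstream: int = 2_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-cell insertion counts in gene body + upstream promoter region.

    The region is the gene body extended ``upstream`` bp 5' of the TSS
    (strand-aware), clamped at 0 and at the chromosome end when sizes are
    given. Unplaced genes are excluded.
    """
    ann = gene_annotation[gene_annotation["chrom"].notna()]
    ins = insertions_from_fragments(frags)
    barcodes = np.asarray(sorted(ins["barcode"].unique()), dtype=object)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    out = np.zeros((len(barcodes), len(ann)), dtype=np.int64)
    by_chrom = {c: sub.sort_values("pos") for c, sub in ins.groupby("chrom")}
    for j, (gene, row) in enumerate(ann.iterrows()):
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            continue
        start, end = int(row["start"]), int(row["end"])
        if row["strand"] == "+":
            lo, hi = start - upstream, end
        else:
            lo, hi = start, end + upstream
        lo = max(lo, 0)
        if chrom_sizes is not None:
            hi = min(hi, chrom_sizes[row["chrom"]])
        pos = sub["pos"].to_numpy()
        a, b = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "left")
        if a == b:
            continue
        hit = sub.iloc[a:b]
        for bc, w in hit.groupby("barcode")["weight"].sum().items():
            out[bc_index[bc], j] += w
    return pd.DataFrame(
        out,
        index=pd.Index(barcodes, name="cell_id"),
        columns=pd.Index(ann.index, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# Active promoters and co-accessibility network
# ---------------------------------------------------------------------------


def tss_positions(gene_annotation: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware TSS (chrom, pos) per placed gene."""
    ann = gene_annotation[gene_annotation["chrom"].notna()]
    pos = np.where(
        ann["strand"] == "+", ann["start"].astype(int), ann["end"].astype(int) - 1
    )
    return pd.DataFrame({"chrom": ann["chrom"], "pos": pos}, index=ann.index)


def _interval_point_distance(start: int, end: int, point: int) -> int:
    """Distance from a half-open interval to a point (0 if inside)."""
    if point < start:
        return start - point
    if point >= end:
        return point - end + 1
    return 0


def active_promoters(
    h3k4me3,
    h3k27ac,
    tss: pd.DataFrame,
    max_dist: int = 1_000,
) -> list[str]:
    """Genes whose promoter carries both activation marks.

    A gene is active iff some H3K4me3 peak lies within ``max_dist`` bp of
    its TSS (interval-to-point distance) and that peak overlaps an
    H3K27ac peak by at least 1 bp. Monotone in ``max_dist``.
    """
    k27_merged = _merge_intervals(h3k27ac)
    # Precompute which H3K4me3 peaks carry acetylation.
    k4 = list(h3k4me3)
    if k4:
        chrom = np.asarray([p.chrom for p in k4], dtype=object)
        start = np.asarray([p.start for p in k4])
        end = np.asarray([p.end for p in k4])
        has_ac = _overlaps_any(chrom, start, end, k27_merged) if k27_merged else np.zeros(len(k4), bool)
    active = []
    for gene, row in tss.iterrows():
        for i, peak in enumerate(k4):
            if peak.chrom != row["chrom"] or not has_ac[i]:
                continue
            if _interval_point_distance(peak.start, peak.end, int(row["pos"])) <= max_dist:
                active.append(str(gene))
                break
    return active


def correlation_network(
    activity: pd.DataFrame, threshold: float = 0.15
) -> pd.DataFrame:
    """Pairwise Pearson edges over gene activity profiles.

    Edges with r below ``threshold`` are removed; zero-variance genes are
    excluded with a warning. Returns an undirected edge list
    (gene_a, gene_b, r) with gene_a < gene_b.
    """
    if len(activity) < 3:
        raise ValueError("need at least 3 cells")
    var = activity.var(axis=0, ddof=0)
    dead = var.index[var == 0].tolist()
    if dead:
        warnings.warn(f"excluding zero-variance gene(s): {dead[:5]}", stacklevel=2)
        activity = activity.drop(columns=dead)
    if activity.shape[1] < 2:
        raise ValueError("need at least 2 varying genes")
    corr = activity.corr(method="pearson")
    rows = []
    genes = list(corr.columns)
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            r = float(corr.loc[ga, gb])
            if r >= threshold:
                rows.append({"gene_a": ga, "gene_b": gb, "r": r})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
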