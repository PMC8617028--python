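"""Synthetic multi-patient cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a droplet-based tumor
cohort: negative-binomial UMI counts with per-patient depth factors,
disjoint marker programs per cell type, arm-level copy-number segments in
malignant cells only, a mitochondrial count fraction, doublet-like cells
with inflated totals, per-cell-type accessible windows in ATAC fragments,
and histone-mark peaks around a known subset of TSSs. Every planted
effect is recorded in :class:`SyntheticTruth` so downstream recovery can
be quantified.

All randomness flows through a single ``numpy.random.Generator`` seeded
from the design; a fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io_formats import (
    CountMatrix,
    FragmentSet,
    GenomicInterval,
)

# Cell-type vocabulary of the default cohort. "malignant" carries the CNV;
# the two TAM subsets carry disjoint marker programs (recruited/"Mo" vs
# resident/"Mg" origin); the rest are stroma/immune baseline.
DEFAULT_CELL_TYPES = (
    "malignant",
    "TAM_Mo",
    "TAM_Mg",
    "Tcell",
    "fibroblast",
    "endothelial",
)

DEFAULT_SUBTYPES = ("SE", "EPN", "AEP")


def default_genome(n_genes: int = 200, mito_genes: int = 8) -> pd.DataFrame:
    """A tiny two-chromosome annotation plus a mitochondrial contig.

    Genes are 1 kb bodies spaced 10 kb apart, split evenly between chr1
    and chr22 (chr22 hosts the default planted CNV segment), with
    ``mito_genes`` genes on chrMT.
    """
    rows = []
    n_nuclear = n_genes - mito_genes
    per_chrom = n_nuclear // 2
    for chrom, n in (("chr1", n_nuclear - per_chrom), ("chr22", per_chrom)):
        for i in range(n):
            start = 10_000 * (i + 1)
            rows.append((f"{chrom}_g{i:03d}", chrom, start, start + 1_000,
                         "+" if i % 2 == 0 else "-"))
    for i in range(mito_genes):
        start = 500 * (i + 1)
        rows.append((f"MT_g{i}", "chrMT", start, start + 400, "+"))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    ann = ann.set_index("gene_id")
    ann["is_mito"] = ann["chrom"] == "chrMT"
    return ann


@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    fold: float
    applies_to: str = "malignant"

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("CNV fold must be positive")


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort.

    Defaults model a 15-patient cohort over three tumor subtypes with a
    chr22 loss (fold 0.5) planted in malignant cells, disjoint 10-gene
    fold-3 marker programs for the TAM/T/fibroblast subsets, a 5%
    mitochondrial count fraction, and 1% doublet-like cells with
    inflated totals.
    """

    n_patients: int = 15
    subtypes: tuple[str, ...] = ()
    n_cells_per_patient: int = 200
    proportions: dict[str, float] = field(default_factory=dict)
    gene_annotation: pd.DataFrame | None = None
    base_mean: float = 25.0
    dispersion: float = 2.0
    cnv_segments: list[CNVSegment] = field(default_factory=list)
    # Default programs are kept to a small fraction of the toy genome
    # (10 of ~200 genes), mirroring real transcriptomes where cell-type
    # programs are tiny relative to the genome the CNV average runs over.
    marker_programs: dict[str, tuple[list[str], float]] = field(default_factory=dict)
    program_size: int = 10
    program_fold: float = 3.0
    mito_fraction: float = 0.05
    libsize_sigma: float = 0.25
    patient_sigma: float = 0.10
    doublet_fraction: float = 0.01
    doublet_factor: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_annotation is None:
            self.gene_annotation = default_genome()
        if not self.subtypes:
            reps = -(-self.n_patients // len(DEFAULT_SUBTYPES))
            self.subtypes = tuple(
                (DEFAULT_SUBTYPES * reps)[: self.n_patients]
            )
        if len(self.subtypes) != self.n_patients:
            raise ValueError("one subtype per patient required")
        if not self.proportions:
            self.proportions = {
                "malignant": 0.40,
                "TAM_Mo": 0.15,
                "TAM_Mg": 0.15,
                "Tcell": 0.12,
                "fibroblast": 0.10,
                "endothelial": 0.08,
            }
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"cell-type proportions sum to {total}, not 1")
        if self.dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if not self.cnv_segments:
            self.cnv_segments = [
                CNVSegment("chr22", 0, 2_000_000, fold=0.5, applies_to="malignant")
            ]
        if not self.marker_programs:
            self.marker_programs = self._default_programs()

    def _default_programs(self) -> dict[str, tuple[list[str], float]]:
        # Disjoint blocks of chr1 genes (away from the planted chr22 CNV),
        # one per non-malignant cell type; endothelial cells stay
        # program-free baseline so the default fits the toy genome.
        ann = self.gene_annotation
        chr1 = [g for g in ann.index if ann.loc[g, "chrom"] == "chr1"]
        programs: dict[str, tuple[list[str], float]] = {}
        offset = 0
        for ct in DEFAULT_CELL_TYPES[1:-1]:
            genes = chr1[offset : offset + self.program_size]
            if len(genes) < self.program_size:
                raise ValueError("genome too small for default marker programs")
            programs[ct] = (genes, self.program_fold)
            offset += self.program_size
        return programs


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated cohort."""

    cell_meta: pd.DataFrame  # index cell_id: patient, subtype, cell_type, malignant, doublet
    gene_programs: dict[str, list[str]]
    cnv_segments: list[CNVSegment]
    design: CohortDesign
    gene_means: pd.Series | None = None  # realized per-gene base means
    embedding_centroids: pd.DataFrame | None = None
    active_genes: list[str] = field(default_factory=list)
    type_windows: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_meta.index.to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _gene_means(design: CohortDesign, rng: np.random.Generator) -> pd.Series:
    """Per-gene base means with the mitochondrial share fixed by design."""
    ann = design.gene_annotation
    means = pd.Series(
        rng.lognormal(mean=0.0, sigma=0.6, size=len(ann)) , index=ann.index
    )
    means *= design.base_mean / means.mean()
    mito = ann["is_mito"].to_numpy()
    if mito.any():
        f = design.mito_fraction
        nuclear_total = means[~mito].sum()
        means[mito] = nuclear_total * f / (1 - f) / mito.sum()
    return means


def generate_cohort(design: CohortDesign) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a cohort of negative-binomial UMI counts with planted effects.

    Counts for cell *c*, gene *g* follow NB with mean
    ``base_mean_g x patient_factor x program_fold x cnv_fold x libsize_c``
    and a single shared dispersion. CNV folds apply only to genes inside
    a designed segment and to cells whose type matches ``applies_to``.
    """
    rng = np.random.default_rng(design.seed)
    ann = design.gene_annotation
    gene_ids = ann.index.to_numpy(dtype=object)
    base = _gene_means(design, rng).to_numpy()

    # Per-gene fold matrix per cell type (programs + CNV).
    types = list(design.proportions)
    type_fold = {ct: np.ones(len(gene_ids)) for ct in types}
    gene_pos = pd.Index(ann.index)
    for ct, (genes, fold) in design.marker_programs.items():
        if ct not in type_fold:
            continue
        idx = gene_pos.get_indexer(genes)
        if (idx < 0).any():
            raise ValueError(f"program gene absent from annotation for {ct!r}")
        type_fold[ct][idx] *= fold
    for seg in design.cnv_segments:
        in_seg = (
            (ann["chrom"] == seg.chrom)
            & (ann["start"] < seg.end)
            & (ann["end"] > seg.start)
        ).to_numpy()
        for ct in types:
            if ct == seg.applies_to:
                type_fold[ct][in_seg] *= seg.fold

    patient_factor = rng.lognormal(0.0, design.patient_sigma, design.n_patients)

    cell_rows = []
    count_blocks = []
    theta = design.dispersion
    for p in range(design.n_patients):
        patient = f"P{p + 1:02d}"
        subtype = design.subtypes[p]
        n = design.n_cells_per_patient
        # Deterministic type allocation: largest-remainder on proportions.
        alloc = _allocate(design.proportions, n)
        for ct, n_ct in alloc.items():
            if n_ct == 0:
                continue
            lib = rng.lognormal(0.0, design.libsize_sigma, n_ct)
            doublet = rng.random(n_ct) < design.doublet_fraction
            lib = lib * np.where(doublet, design.doublet_factor, 1.0)
            mean = (
                base[None, :]
                * type_fold[ct][None, :]
                * patient_factor[p]
                * lib[:, None]
            )
            # NB via gamma-Poisson mixture with shape theta.
            lam = rng.gamma(shape=theta, scale=mean / theta)
            block = rng.poisson(lam)
            count_blocks.append(sp.csr_matrix(block))
            for j in range(n_ct):
                cell_rows.append(
                    {
                        "patient": patient,
                        "subtype": subtype,
                        "cell_type": ct,
                        "malignant": ct == "malignant",
                        "doublet": bool(doublet[j]),
                    }
                )

    counts = sp.vstack(count_blocks).tocsr()
    cell_meta = pd.DataFrame(cell_rows)
    cell_meta.index = pd.Index(
        [f"cell{i:05d}" for i in range(len(cell_meta))], name="cell_id"
    )

    gene_meta = ann.copy()
    cm = CountMatrix(
        counts,
        cell_meta.index.to_numpy(dtype=object),
        gene_ids,
        cell_meta[["patient", "subtype", "cell_type", "malignant"]].copy(),
        gene_meta,
    )
    truth = SyntheticTruth(
        cell_meta=cell_meta,
        gene_programs={ct: genes for ct, (genes, _) in design.marker_programs.items()},
        cnv_segments=list(design.cnv_segments),
        design=design,
        gene_means=pd.Series(base, index=ann.index),
    )
    return cm, truth


def _allocate(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n cells to types."""
    raw = {ct: p * n for ct, p in proportions.items()}
    alloc = {ct: int(np.floor(v)) for ct, v in raw.items()}
    short = n - sum(alloc.values())
    order = sorted(raw, key=lambda ct: (raw[ct] - alloc[ct], ct), reverse=True)
    for ct in order[:short]:
        alloc[ct] += 1
    return alloc


def expected_log_expression(
    mean: float, dispersion: float, scale: float = 1.0, q: float = 1e-10
) -> float:
    """E[log1p(scale * X)] for X ~ NB(mean, dispersion), by pmf summation.

    Used as the analytic expectation when checking that a planted CNV
    fold is recovered by the moving-average profile. The sum is truncated
    at the 1 - q quantile of the NB.
    """
    theta = dispersion
    p = theta / (theta + mean)
    dist = scipy.stats.nbinom(theta, p)
    kmax = int(dist.ppf(1 - q)) + 1
    k = np.arange(kmax + 1)
    return float(np.sum(dist.pmf(k) * np.log1p(scale * k)))


def expected_type_totals(design: CohortDesign, gene_means: pd.Series) -> dict[str, float]:
    """Expected per-cell total counts per cell type (unit depth factor)."""
    ann = design.gene_annotation
    totals = {}
    for ct in design.proportions:
        t = float(gene_means.sum())
        if ct in design.marker_programs:
            genes, fold = design.marker_programs[ct]
            t += (fold - 1) * float(gene_means[genes].sum())
        for seg in design.cnv_segments:
            if seg.applies_to == ct:
                in_seg = ann.index[
                    (ann["chrom"] == seg.chrom)
                    & (ann["start"] < seg.end)
                    & (ann["end"] > seg.start)
                ]
                t += (seg.fold - 1) * float(gene_means[in_seg].sum())
        totals[ct] = t
    return totals


def expected_centered_shift(
    truth: SyntheticTruth,
    target_sum: float,
    genes,
    cell_type: str = "malignant",
    n_quad: int = 15,
) -> pd.Series:
    """Analytic expectation of the baseline-centered log expression.

    For each gene, computes E[log1p(s * X)] for a ``cell_type`` cell
    minus the baseline mixture (all other types, weighted by their
    design proportions), where X is the designed negative binomial and
    ``s = target_sum / (depth * type_total)``. The per-cell depth factor
    (library x patient, jointly lognormal) is integrated out by
    Gauss-Hermite quadrature. This is the expected interior value of a
    CNV profile over those genes before moving-average smoothing.
    """
    design = truth.design
    m = truth.gene_means
    ann = design.gene_annotation
    sigma = float(np.hypot(design.libsize_sigma, design.patient_sigma))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    depth = np.exp(sigma * nodes)
    w = weights / weights.sum()
    totals = expected_type_totals(design, m)

    def gene_fold(gene: str, ct: str) -> float:
        fold = 1.0
        if ct in design.marker_programs:
            gs, f = design.marker_programs[ct]
            if gene in gs:
                fold *= f
        row = ann.loc[gene]
        for seg in design.cnv_segments:
            if (
                seg.applies_to == ct
                and row["chrom"] == seg.chrom
                and row["start"] < seg.end
                and row["end"] > seg.start
            ):
                fold *= seg.fold
        return fold

    def e_val(mg: float, fold: float, total: float) -> float:
        vals = [
            expected_log_expression(
                L * mg * fold, design.dispersion, target_sum / (L * total)
            )
            for L in depth
        ]
        return float(np.dot(w, vals))

    base_types = [ct for ct in design.proportions if ct != cell_type]
    bw = np.array([design.proportions[ct] for ct in base_types])
    bw = bw / bw.sum()
    out = {}
    for g in genes:
        e_query = e_val(m[g], gene_fold(g, cell_type), totals[cell_type])
        e_base = sum(
            wt * e_val(m[g], gene_fold(g, ct), totals[ct])
            for wt, ct in zip(bw, base_types)
        )
        out[g] = e_query - e_base
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------


def generate_embedding(
    truth: SyntheticTruth,
    spread: float = 1.0,
    seed: int = 0,
    regime: str = "mixed",
) -> pd.DataFrame:
    """Gaussian-blob 2-D coordinates standing in for a UMAP embedding.

    ``regime="separated"`` places one centroid per patient (cells of a
    patient cluster alone → low neighborhood entropy);
    ``regime="mixed"`` places one centroid per cell type shared by all
    patients (patients interleave → high entropy).
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if regime not in ("separated", "mixed"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    meta = truth.cell_meta
    key = meta["patient"] if regime == "separated" else meta["cell_type"]
    groups = sorted(key.unique())
    # Centroids on a wide circle so blobs are far apart relative to spread.
    radius = 50.0 * max(1.0, spread)
    angles = 2 * np.pi * np.arange(len(groups)) / len(groups)
    centroids = pd.DataFrame(
        {
            "x": radius * np.cos(angles),
            "y": radius * np.sin(angles),
        },
        index=pd.Index(groups, name="group"),
    )
    coords = centroids.loc[key.to_numpy(), ["x", "y"]].to_numpy()
    coords = coords + rng.normal(0.0, spread, size=coords.shape)
    out = pd.DataFrame(coords, columns=["x", "y"], index=meta.index)
    truth.embedding_centroids = centroids
    return out


# ---------------------------------------------------------------------------
# ATAC fragments and ChIP peaks
# ---------------------------------------------------------------------------


def generate_fragments(
    truth: SyntheticTruth,
    windows_per_type: int = 4,
    genome: dict[str, int] | None = None,
    seed: int = 0,
    window_size: int = 2_500,
    fragments_per_cell: int = 400,
    noise: float = 0.1,
) -> FragmentSet:
    """Fragments concentrated in per-cell-type windows plus uniform noise.

    Each cell type is assigned ``windows_per_type`` disjoint
    ``window_size`` windows; a fragment lands in one of its cell's
    windows with probability ``1 - noise`` and uniformly on the genome
    otherwise. Fragment lengths are drawn sub-nucleosomal (most) or
    mono-nucleosomal so the standard QC ratios behave realistically.
    ``windows_per_type=0`` yields pure-noise fragments.
    """
    if genome is None:
        genome = {"chr1": 1_000_000, "chr22": 1_000_000}
    if any(size <= 0 for size in genome.values()):
        raise ValueError("chromosome sizes must be positive")
    rng = np.random.default_rng(seed)
    meta = truth.cell_meta
    types = sorted(meta["cell_type"].unique())
    chroms = sorted(genome)

    # Assign disjoint windows round-robin across chromosomes.
    type_windows: dict[str, list[GenomicInterval]] = {ct: [] for ct in types}
    slot = 0
    for ct in types:
        for _ in range(windows_per_type):
            chrom = chroms[slot % len(chroms)]
            w = slot // len(chroms)
            start = w * window_size
            if start + window_size > genome[chrom]:
                raise ValueError("genome too small for requested windows")
            type_windows[ct].append(
                GenomicInterval(chrom, start, start + window_size)
            )
            slot += 1
    truth.type_windows = type_windows

    chrom_arr = np.asarray(chroms, dtype=object)
    sizes = np.asarray([genome[c] for c in chroms])
    size_p = sizes / sizes.sum()

    rows: list[tuple[str, int, int, str, int]] = []
    for cell_id, ct in meta["cell_type"].items():
        n = fragments_per_cell
        wins = type_windows[ct]
        in_window = (
            rng.random(n) < (1 - noise) if wins else np.zeros(n, dtype=bool)
        )
        # Mixture of sub-nucleosomal and mono-nucleosomal lengths.
        mono = rng.random(n) < 0.15
        lengths = np.where(
            mono,
            rng.integers(160, 290, n),
            rng.integers(50, 140, n),
        )
        which_win = rng.integers(0, max(len(wins), 1), n)
        which_chrom = rng.choice(len(chroms), size=n, p=size_p)
        for i in range(n):
            length = int(lengths[i])
            if in_window[i]:
                w = wins[which_win[i]]
                lo, hi = w.start, max(w.start + 1, w.end - length)
                chrom = w.chrom
            else:
                chrom = chrom_arr[which_chrom[i]]
                lo, hi = 0, max(1, genome[chrom] - length)
            start = int(rng.integers(lo, hi))
            rows.append((chrom, start, start + length, str(cell_id), 1))
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "barcode", "count"]
    )
    return FragmentSet(frame)


def generate_chip_peaks(
    gene_annotation: pd.DataFrame,
    active_genes: list[str],
    seed: int = 0,
    peak_width: int = 600,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Histone-mark peaks realizing a designed active-promoter gene list.

    Every active gene gets an H3K4me3 peak whose interval lies within
    1000 bp of its TSS and overlaps an H3K27ac peak. Inactive genes get
    at most one of the marks near the TSS, or a peak placed distally, so
    they fail the joint rule by construction.
    """
    rng = np.random.default_rng(seed)
    index = set(gene_annotation.index)
    for g in active_genes:
        if g not in index:
            raise ValueError(f"active gene {g!r} absent from annotation")
    active = set(active_genes)
    k4: list[GenomicInterval] = []
    k27: list[GenomicInterval] = []
    for gene_id, row in gene_annotation.iterrows():
        if row["chrom"] == "chrMT" or pd.isna(row["chrom"]):
            continue
        tss = int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1
        if gene_id in active:
            offset = int(rng.integers(-500, 500))
            s = max(0, tss + offset - peak_width // 2)
            k4.append(GenomicInterval(row["chrom"], s, s + peak_width, name=str(gene_id)))
            s27 = max(0, s + int(rng.integers(-peak_width // 2, peak_width // 2)))
            k27.append(GenomicInterval(row["chrom"], s27, s27 + peak_width))
        else:
            mode = rng.integers(0, 3)
            if mode == 0:
                # H3K4me3 near TSS, no acetylation anywhere close.
                s = max(0, tss - peak_width // 2)
                k4.append(GenomicInterval(row["chrom"], s, s + peak_width))
            elif mode == 1:
                # H3K27ac alone near TSS.
                s = max(0, tss - peak_width // 2)
                k27.append(GenomicInterval(row["chrom"], s, s + peak_width))
            else:
                # Both marks, but 5 kb away from any TSS neighborhood.
                s = tss + 5_000
                k4.append(GenomicInterval(row["chrom"], s, s + peak_width))
                k27.append(GenomicInterval(row["chrom"], s, s + peak_width))
    return k4, k27
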