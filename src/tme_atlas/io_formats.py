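"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates inside the package are 0-based half-open
``[start, end)`` (the 10x/UCSC convention used by BED and fragments
files). Converters at the boundary are the only place 1-based data may
enter; none of the readers below perform coordinate shifts.

Mitochondrial genes are identified by contig name (configurable, default
``chrMT`` with ``MT``/``chrM`` accepted as aliases), never by gene-symbol
prefix.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("tme_atlas")

#: Contig names accepted as the mitochondrial genome when the configured
#: name is any one of them.
MITO_ALIASES = frozenset({"chrMT", "MT", "chrM", "chrmt", "mt", "chrm"})

CELL_META_COLUMNS = ("patient", "subtype", "cluster")
GENE_META_COLUMNS = ("chrom", "start", "end", "strand", "is_mito", "is_hsp")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse cells × genes UMI count matrix with per-axis metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, cells in rows.
    cell_ids, gene_ids
        Unique string identifiers for rows / columns.
    cell_meta
        Table indexed by cell id; recognised columns are ``patient``,
        ``subtype`` and ``cluster`` but arbitrary extra columns survive.
    gene_meta
        Table indexed by gene id with locus columns ``chrom``, ``start``,
        ``end``, ``strand`` plus boolean ``is_mito`` (and optionally
        ``is_hsp``). Genes without annotation carry ``chrom`` = NA and are
        flagged unplaced; they stay in expression analyses but are
        excluded from CNV and gene-activity computations.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        _check_unique(self.cell_ids, "cell id")
        _check_unique(self.gene_ids, "gene id")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        self.gene_meta = self.gene_meta.reindex(self.gene_ids)
        if "is_mito" not in self.gene_meta.columns:
            self.gene_meta["is_mito"] = False
        self.gene_meta["is_mito"] = self.gene_meta["is_mito"].astype("boolean").fillna(False).astype(bool)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def placed_mask(self) -> np.ndarray:
        """Boolean mask over genes that carry a genomic location."""
        return self.gene_meta["chrom"].notna().to_numpy()

    def subset_cells(self, keep_ids) -> "CountMatrix":
        idx = pd.Index(self.cell_ids).get_indexer(list(keep_ids))
        if (idx < 0).any():
            missing = [c for c, i in zip(keep_ids, idx) if i < 0]
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return CountMatrix(
            self.counts[idx],
            self.cell_ids[idx],
            self.gene_ids,
            self.cell_meta.iloc[idx],
            self.gene_meta,
        )


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentSet:
    """Tn5 fragment records as a table (chrom, start, end, barcode, count).

    Duplicate (chrom, start, end, barcode) rows are summed on load.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        needed = ["chrom", "start", "end", "barcode", "count"]
        missing = [c for c in needed if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fragment table lacks columns {missing}")
        f = self.frame
        if len(f):
            if (f["end"] <= f["start"]).any():
                bad = f[f["end"] <= f["start"]].index[0]
                raise ValueError(f"fragment end <= start at row {bad}")
            if (f["count"] < 1).any():
                raise ValueError("fragment count must be >= 1")
        self.frame = (
            f.groupby(["chrom", "start", "end", "barcode"], as_index=False, sort=True)[
                "count"
            ]
            .sum()
            .astype({"start": np.int64, "end": np.int64, "count": np.int64})
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_count(self) -> int:
        return int(self.frame["count"].sum())

    def barcode_totals(self) -> pd.Series:
        """Total fragment count per barcode."""
        return self.frame.groupby("barcode")["count"].sum()

    def barcodes(self) -> np.ndarray:
        return np.asarray(sorted(self.frame["barcode"].unique()), dtype=object)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class DrugGeneTable:
    """Druggable-gene interaction rows (gene, category, optional drug)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene_id", "category"):
            if col not in self.frame.columns:
                raise ValueError(f"drug table lacks column {col!r}")
        if "drug" not in self.frame.columns:
            self.frame["drug"] = pd.NA
        self.frame = self.frame.drop_duplicates(
            subset=["gene_id", "category"]
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}(s): {dup[:5]}")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def mito_contig_names(configured: str = "chrMT") -> frozenset[str]:
    """The set of contig names treated as mitochondrial.

    If the configured name is one of the common aliases, all aliases are
    accepted; otherwise only the configured name matches.
    """
    if configured in MITO_ALIASES:
        return MITO_ALIASES
    return frozenset({configured})


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_count_matrix(
    mtx_path,
    barcodes_path,
    features_path,
    gene_annotation_path=None,
    mito_contig: str = "chrMT",
) -> CountMatrix:
    """Load a MatrixMarket UMI matrix with barcode/feature sidecars.

    The MTX file is genes × cells (CellRanger layout) when its row count
    matches the features file; cells × genes is also accepted. Genes
    absent from the annotation table are retained but left unplaced.
    """
    mat = scipy.io.mmread(str(mtx_path))
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    _check_unique(barcodes, "cell id")
    _check_unique(features, "gene id")
    mat = sp.coo_matrix(mat)
    if mat.shape == (len(features), len(barcodes)):
        mat = mat.T
    elif mat.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"(cells={len(barcodes)}, genes={len(features)}) nor its transpose"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("count matrix contains non-integer values")
    counts = sp.csr_matrix(mat).astype(np.int64)

    gene_meta = pd.DataFrame(
        index=pd.Index(features, name="gene_id"),
        columns=list(GENE_META_COLUMNS),
        dtype=object,
    )
    if gene_annotation_path is not None:
        ann = read_gene_annotation(gene_annotation_path, mito_contig=mito_contig)
        known = ann.index.intersection(gene_meta.index)
        for col in ("chrom", "start", "end", "strand", "is_mito"):
            gene_meta.loc[known, col] = ann.loc[known, col]
        unplaced = len(gene_meta) - len(known)
        if unplaced:
            logger.info("%d gene(s) lack annotation and stay unplaced", unplaced)
    gene_meta["is_mito"] = gene_meta["is_mito"].astype("boolean").fillna(False).astype(bool)

    cell_meta = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    return CountMatrix(counts, barcodes, features, cell_meta, gene_meta)


def _read_id_column(path) -> np.ndarray:
    with _open_text(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def read_gene_annotation(path, mito_contig: str = "chrMT") -> pd.DataFrame:
    """Gene annotation TSV with header gene_id, chrom, start, end, strand.

    Coordinates are expected 0-based half-open already. ``is_mito`` is
    derived from the contig name.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    needed = {"gene_id", "chrom", "start", "end", "strand"}
    missing = needed - set(ann.columns)
    if missing:
        raise FormatError(f"gene annotation lacks columns {sorted(missing)}")
    _check_unique(ann["gene_id"], "gene id")
    if (ann["start"] < 0).any():
        raise FormatError("gene annotation has negative start")
    if (ann["end"] <= ann["start"]).any():
        raise FormatError("gene annotation has end <= start")
    bad_strand = ~ann["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"bad strand value(s): {ann.loc[bad_strand, 'strand'].unique().tolist()}"
        )
    ann = ann.set_index("gene_id")
    ann["is_mito"] = ann["chrom"].isin(mito_contig_names(mito_contig))
    return ann


def read_fragments(path) -> FragmentSet:
    """Parse a 5-column fragments TSV (optionally gzipped).

    Columns: chrom, start, end, barcode, count. ``#`` comment lines are
    skipped. Malformed lines raise with their line number.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            chrom, start_s, end_s, barcode, count_s = parts
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
            if count < 1:
                raise FormatError(f"{path}:{lineno}: count {count} < 1")
            rows.append((chrom, start, end, barcode, count))
    if not rows:
        warnings.warn(f"no fragment records in {path}", stacklevel=2)
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "barcode", "count"]
    )
    if frame.empty:
        frame = frame.astype(
            {"chrom": object, "start": np.int64, "end": np.int64,
             "barcode": object, "count": np.int64}
        )
    return FragmentSet(frame)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = (
                float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            )
            strand = parts[5] if len(parts) > 5 else None
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(repr(iv.score) if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT set {parts[0]!r} has zero genes"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: GMT set {name!r} has zero genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_drug_table(path) -> DrugGeneTable:
    """Read a TSV of (gene_id, category[, drug]) druggable-gene rows."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return DrugGeneTable(frame)


def write_table(obj, path) -> None:
    """Write a table-like object as headered TSV.

    Accepts a DataFrame, Series, FragmentSet or DrugGeneTable; every
    writer in the package emits TSV with a header row.
    """
    if isinstance(obj, FragmentSet):
        frame = obj.frame
    elif isinstance(obj, DrugGeneTable):
        frame = obj.frame
    elif isinstance(obj, pd.Series):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    frame.to_csv(path, sep="\t", index=not isinstance(frame.index, pd.RangeIndex))


def write_count_matrix(cm: CountMatrix, out_dir) -> None:
    """Write a CountMatrix as MTX + barcodes/features TSV + annotation TSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), cm.counts.T.tocoo())
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{b}\n" for b in cm.cell_ids)
    with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
        fh.writelines(f"{g}\n" for g in cm.gene_ids)
    placed = cm.gene_meta[cm.gene_meta["chrom"].notna()]
    ann = placed[["chrom", "start", "end", "strand"]].copy()
    ann.index.name = "gene_id"
    ann.to_csv(os.path.join(out_dir, "genes.tsv"), sep="\t")
    cm.cell_meta.to_csv(os.path.join(out_dir, "cell_meta.tsv"), sep="\t")


def write_fragments(frags: FragmentSet, path) -> None:
    """Write fragments as a 5-column TSV (gzipped if path ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for row in frags.frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.barcode}\t{row.count}\n")
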