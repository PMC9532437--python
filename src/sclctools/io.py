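"""Shared data model and on-disk formats.

The pipeline's universal input is a sparse gene x cell UMI count matrix
(Matrix Market exchange format) with sidecar TSVs for gene ids, cell
barcodes and per-cell metadata, a gene annotation table giving genomic
position (chromosome, 0-based start), GMT gene-set collections, and
real-valued bulk expression matrices.  Everything in memory is 0-based;
MTX files are 1-based per the Matrix Market standard.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "ExprMatrix",
    "GeneAnnotation",
    "GeneSetCollection",
    "BulkMatrix",
    "FormatError",
    "DEFAULT_CHROMOSOMES",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
]

#: Default chromosome ordering (human autosomes then sex chromosomes).
DEFAULT_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        dupes = pd.Series(ids).value_counts()
        bad = dupes[dupes > 1].index[0]
        raise FormatError(f"duplicate {what} id: {bad!r}")


@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix with cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    cell_meta
        Table indexed by cell id.  Conventional columns are ``patient``,
        ``tissue`` (``PT`` primary tumor, ``NAT`` normal adjacent tissue,
        ``RT`` relapsed tumor) and ``label`` (cluster / cell type); extra
        columns are preserved.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix is {self.counts.shape} but got {len(self.gene_ids)} "
                f"gene ids and {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                bad = int(np.argmax(data < 0))
                raise FormatError(f"negative count {data[bad]} in matrix")
            if not np.all(data == np.floor(data)):
                bad = int(np.argmax(data != np.floor(data)))
                raise FormatError(f"non-integer count {data[bad]} in matrix")
        self.counts = self.counts.astype(np.int64)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index.name = "cell_id"
            unknown = set(self.cell_meta.index) - set(self.cell_ids)
            if unknown:
                raise FormatError(f"metadata rows for unknown cells: {sorted(unknown)[:3]}")
            # align to cell order; cells without a meta row get NaNs
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def total_umis(self) -> np.ndarray:
        """Total UMI count per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one UMI, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )


@dataclass
class ExprMatrix:
    """Dense real-valued gene x cell expression matrix (e.g. log-normalized)."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match ids")

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class GeneAnnotation:
    """Genomic location per gene: chromosome name and 0-based start.

    Only the total order induced by (chromosome rank, start, gene_id)
    matters downstream; strand is intentionally ignored.  Genes on
    chromosomes outside ``chromosomes`` sort last and are excluded from
    CNV inference.
    """

    table: pd.DataFrame  # columns gene_id, chromosome, start
    chromosomes: tuple = DEFAULT_CHROMOSOMES

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"annotation needs columns {sorted(required)}")
        self.table = self.table.copy()
        self.table["chromosome"] = self.table["chromosome"].astype(str)
        self.table["start"] = self.table["start"].astype(np.int64)
        if (self.table["start"] < 0).any():
            raise FormatError("negative gene start in annotation")
        _check_unique(self.table["gene_id"].to_numpy(), "annotation gene")

    def chrom_rank(self) -> dict:
        return {c: i for i, c in enumerate(self.chromosomes)}

    def ordered(self, gene_ids=None) -> pd.DataFrame:
        """Annotation rows sorted by (chromosome rank, start, gene_id).

        Genes on undeclared chromosomes are dropped.  If ``gene_ids`` is
        given the result is restricted to those genes; unannotated genes
        are silently excluded (the caller decides whether to warn).
        """
        tab = self.table
        if gene_ids is not None:
            tab = tab[tab["gene_id"].isin(set(gene_ids))]
        rank = self.chrom_rank()
        tab = tab[tab["chromosome"].isin(rank)]
        key = tab["chromosome"].map(rank)
        return (
            tab.assign(_rank=key)
            .sort_values(["_rank", "start", "gene_id"], kind="mergesort")
            .drop(columns="_rank")
            .reset_index(drop=True)
        )

    @classmethod
    def read_tsv(cls, path, chromosomes=DEFAULT_CHROMOSOMES) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}), chromosomes)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class GeneSetCollection:
    """Named, ordered collection of non-empty gene sets."""

    sets: dict  # name -> list of gene ids (deduplicated, order preserved)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
        self.sets = {k: list(v) for k, v in self.sets.items()}

    def __getitem__(self, name):
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class BulkMatrix:
    """Real-valued gene x sample bulk expression with sample metadata."""

    values: pd.DataFrame  # genes in rows, samples in columns
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise FormatError("bulk matrix contains non-finite values")
        _check_unique(self.values.columns.to_numpy(), "sample")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)

    @property
    def samples(self):
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path, meta_path=None) -> "BulkMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else None
        return cls(values, meta)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def _read_id_column(path, what: str) -> np.ndarray:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise FormatError(f"{path}: 0 {what}s")
    return np.asarray(ids, dtype=object)


def read_counts(matrix_path, genes_path, barcodes_path, meta_path=None) -> CountMatrix:
    """Read an MTX count matrix plus gene/barcode TSVs (and optional metadata).

    Raises :class:`FormatError` on dimension mismatches, duplicate ids,
    or negative / non-integer entries, naming the offending record.
    """
    genes = _read_id_column(genes_path, "gene")
    cells = _read_id_column(barcodes_path, "cell")
    mat = scipy.io.mmread(matrix_path)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{matrix_path}: matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars "
            f"declare {len(genes)} genes x {len(cells)} cells"
        )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"patient": str})
    return CountMatrix(counts=mat, gene_ids=genes, cell_ids=cells, cell_meta=meta)


def write_counts(cm: CountMatrix, out_dir) -> dict:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + meta.tsv under ``out_dir``.

    ``read_counts`` inverts this exactly on counts, ids and metadata.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "meta": os.path.join(out_dir, "meta.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(cm.counts), field="integer")
    with open(paths["genes"], "w") as fh:
        fh.writelines(f"{g}\n" for g in cm.gene_ids)
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(f"{c}\n" for c in cm.cell_ids)
    cm.cell_meta.to_csv(paths["meta"], sep="\t")
    return paths


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...).

    Duplicate member ids within a set are deduplicated preserving first
    occurrence; a duplicate set name or a line with fewer than three
    fields is a :class:`FormatError` carrying the line number.
    """
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(f for f in fields[2:] if f))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
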