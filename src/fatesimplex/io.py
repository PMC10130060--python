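"""Readers and writers for the on-disk formats the pipeline touches.

Integer count matrices round-trip bit-exactly through MatrixMarket files.
Row/column ordering is never silently changed: expression matrices keep the
barcode/feature order of the input files, simplex coordinate tables are
written barcode-sorted, and arrow tables are written in row-major bin order.
Gzip compression is handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)

#: significant digits used for floating-point TSV output
FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class FragmentRecord:
    """One (possibly duplicated) sequenced fragment, 0-based half-open."""

    contig: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")
        if self.count < 1:
            raise ValueError(f"fragment duplicate count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class GeneInterval:
    """Genomic span of one gene, 0-based half-open, stranded."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: `start` on the + strand, `end - 1` on the - strand."""
        return self.start if self.strand == "+" else self.end - 1


def _open_text(path: Path | str, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# expression bundles (MTX per layer + features/barcodes TSV)
# ---------------------------------------------------------------------------

LAYER_FILES = {"total": "total.mtx", "spliced": "spliced.mtx", "unspliced": "unspliced.mtx"}


def write_expression(adata: AnnData, outdir: Path | str) -> None:
    """Write an expression bundle as one MTX per layer plus features/barcodes TSV.

    Matrices are stored cells x genes. Integer matrices use the MTX integer
    field so the round trip is bit exact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices = {"total": adata.X}
    for name in ("spliced", "unspliced"):
        if name in adata.layers:
            matrices[name] = adata.layers[name]
    for name, mat in matrices.items():
        m = sp.coo_matrix(mat)
        field = "integer" if np.issubdtype(m.dtype, np.integer) else "real"
        scipy.io.mmwrite(str(outdir / LAYER_FILES[name]), m, field=field)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    if "cluster" in adata.obs:
        adata.obs["cluster"].rename_axis("barcode").to_csv(outdir / "labels.tsv", sep="\t")


def read_expression(indir: Path | str) -> AnnData:
    """Read a bundle written by :func:`write_expression` (or equivalent files).

    The stored orientation may be either cells x genes or genes x cells; it is
    normalized to cells x genes using the features/barcodes lengths. Raises on
    a dimension mismatch or duplicate barcodes.
    """
    indir = Path(indir)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcodes.tsv")

    def load(fname: str) -> sp.csr_matrix:
        m = sp.csr_matrix(scipy.io.mmread(str(indir / fname)))
        if m.shape == (len(barcodes), len(features)):
            return m
        if m.shape == (len(features), len(barcodes)):
            return m.T.tocsr()
        raise ValueError(
            f"{fname}: matrix shape {m.shape} matches neither "
            f"(cells={len(barcodes)}, genes={len(features)}) nor its transpose"
        )

    X = load(LAYER_FILES["total"])
    layers = {}
    for name in ("spliced", "unspliced"):
        p = indir / LAYER_FILES[name]
        if p.exists():
            layers[name] = load(LAYER_FILES[name])
    adata = AnnData(X=X, layers=layers)
    adata.obs_names = barcodes
    adata.var_names = features
    labels = indir / "labels.tsv"
    if labels.exists():
        lab = pd.read_csv(labels, sep="\t", index_col=0)
        adata.obs["cluster"] = lab.reindex(adata.obs_names).iloc[:, 0].astype(str).values
    return adata


# ---------------------------------------------------------------------------
# gene annotation (BED6 / GTF)
# ---------------------------------------------------------------------------


def read_gene_annotation(path: Path | str, dialect: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED6 (0-based half-open, verbatim) or GTF.

    GTF coordinates (1-based closed) are converted to 0-based half-open as
    ``[start - 1, end)``; only ``gene`` feature records are used. Records with
    an unknown strand are rejected with a warning; for duplicated gene ids the
    first record is retained and a warning logged.
    """
    dialect = dialect.lower()
    if dialect not in ("bed", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    intervals: list[GeneInterval] = []
    seen: set[str] = set()

    def add(gene_id: str, contig: str, start: int, end: int, strand: str) -> None:
        if strand not in ("+", "-"):
            logger.warning("gene %s: unknown strand %r, record rejected", gene_id, strand)
            return
        if gene_id in seen:
            logger.warning("duplicate gene_id %s: first record retained", gene_id)
            return
        seen.add(gene_id)
        intervals.append(GeneInterval(gene_id, contig, start, end, strand))

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 6:
                    raise ValueError(f"BED6 line with {len(fields)} fields: {line!r}")
                contig, start, end, name, _score, strand = fields[:6]
                add(name, contig, int(start), int(end), strand)
            else:  # gtf
                if len(fields) < 9:
                    raise ValueError(f"GTF line with {len(fields)} fields: {line!r}")
                contig, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                if feature != "gene":
                    continue
                gene_id = _gtf_attr(attrs, "gene_id")
                add(gene_id, contig, int(start) - 1, int(end), strand)
    return intervals


def _gtf_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    raise ValueError(f"GTF attributes missing {key}: {attrs!r}")


def write_gene_annotation_bed(intervals: Iterable[GeneInterval], path: Path | str) -> None:
    """Write intervals as BED6 (0-based half-open)."""
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# fragments (5-column TSV dialect)
# ---------------------------------------------------------------------------


def write_fragments(fragments: Iterable[FragmentRecord], path: Path | str) -> None:
    """Write fragments as 5-column TSV: contig, start, end, barcode, count."""
    with _open_text(path, "wt") as fh:
        for fr in fragments:
            fh.write(f"{fr.contig}\t{fr.start}\t{fr.end}\t{fr.barcode}\t{fr.count}\n")


def read_fragments(path: Path | str) -> list[FragmentRecord]:
    """Read a 5-column fragments TSV (gzip allowed by extension)."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, start, end, barcode, count = line.split("\t")[:5]
            out.append(FragmentRecord(contig, int(start), int(end), barcode, int(count)))
    return out


# ---------------------------------------------------------------------------
# simplex coordinate / arrow tables
# ---------------------------------------------------------------------------


def write_simplex_outputs(coords, arrows, outdir: Path | str) -> tuple[Path, Path]:
    """Write ``coords.tsv`` (barcode-sorted) and ``arrows.tsv`` (row-major bins).

    ``coords`` is a :class:`~fatesimplex.simplex.SimplexCoordinates`; ``arrows``
    a :class:`~fatesimplex.velocity.BinnedArrowField` (may be None to skip).
    Returns the two paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coords_path = outdir / "coords.tsv"
    fate_cols = [f"w_{f}" for f in coords.fate_names]
    df = pd.DataFrame(coords.barycentric, columns=fate_cols)
    df.insert(0, "barcode", list(coords.barcodes))
    df["x"] = coords.cartesian[:, 0]
    df["y"] = coords.cartesian[:, 1]
    df = df.sort_values("barcode", kind="stable")
    df.to_csv(coords_path, sep="\t", index=False, float_format=FLOAT_FORMAT)

    arrows_path = outdir / "arrows.tsv"
    if arrows is not None:
        adf = arrows.to_frame()
        adf.to_csv(arrows_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    else:
        pd.DataFrame(
            columns=["bin_id", "bin_x", "bin_y", "n_cells", "len_fate1", "len_fate2", "len_fate3"]
        ).to_csv(arrows_path, sep="\t", index=False)
    return coords_path, arrows_path


def read_simplex_coords(path: Path | str) -> pd.DataFrame:
    """Read a coords.tsv back as a DataFrame indexed by barcode."""
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_velocity_graph(graph: sp.spmatrix, path: Path | str) -> None:
    """Write a sparse velocity graph as (i, j, w) triplets."""
    coo = sp.coo_matrix(graph)
    df = pd.DataFrame({"i": coo.row, "j": coo.col, "w": coo.data})
    df.sort_values(["i", "j"]).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_velocity_graph(path: Path | str, n_cells: int) -> sp.csr_matrix:
    """Read an (i, j, w) triplet TSV back into an n x n sparse matrix."""
    df = pd.read_csv(path, sep="\t")
    return sp.csr_matrix((df["w"], (df["i"], df["j"])), shape=(n_cells, n_cells))


def write_truth(truth, path: Path | str, barcodes: Sequence[str], fate_names: Sequence[str]) -> None:
    """Write simulation ground truth as TSV (one row per cell)."""
    df = pd.DataFrame(truth.true_barycentric, columns=[f"w_{f}" for f in fate_names])
    df.insert(0, "barcode", list(barcodes))
    df["destined_fate"] = ["" if f is None else f for f in truth.destined_fate]
    df["apex_label"] = truth.apex_label
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
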