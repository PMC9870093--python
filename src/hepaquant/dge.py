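"""Digital gene expression (DGE) matrix container and file formats.

A DGE matrix is genes x barcodes with non-negative integer UMI counts.
Two on-disk dialects are supported: the dense Drop-Seq
``DigitalExpression`` TSV (first column ``GENE``, one column per
barcode) and MatrixMarket triplets with ``genes.tsv`` / ``barcodes.tsv``
sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["DGEMatrix", "read_dge_tsv", "write_dge_tsv", "read_dge_mtx", "write_dge_mtx"]


@dataclass
class DGEMatrix:
    """Genes x barcodes integer UMI count matrix with identifiers."""

    genes: list[str]
    barcodes: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if np.any(self.counts < 0):
            raise ValueError("UMI counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("UMI counts must be integral")
            self.counts = rounded.astype(np.int64)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcode identifiers must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def barcode_totals(self) -> pd.Series:
        """Total UMI count per barcode."""
        return pd.Series(self.counts.sum(axis=0), index=self.barcodes, name="total")

    def select_barcodes(self, barcodes) -> "DGEMatrix":
        """Subset to the given barcodes, in the given order."""
        idx = {b: i for i, b in enumerate(self.barcodes)}
        missing = [b for b in barcodes if b not in idx]
        if missing:
            raise KeyError(f"barcodes not in matrix: {missing[:5]}")
        cols = [idx[b] for b in barcodes]
        return DGEMatrix(list(self.genes), list(barcodes), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.barcodes)


def write_dge_tsv(m: DGEMatrix, path) -> None:
    """Write the dense Drop-Seq DigitalExpression dialect (GENE + barcodes)."""
    df = m.to_frame()
    df.index.name = "GENE"
    df.to_csv(path, sep="\t")


def read_dge_tsv(path) -> DGEMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DGEMatrix(list(df.index), list(df.columns), df.to_numpy())


def write_dge_mtx(m: DGEMatrix, mtx_path) -> None:
    """Write MatrixMarket triplets plus genes.tsv / barcodes.tsv sidecars."""
    mtx_path = Path(mtx_path)
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(m.counts))
    mtx_path.with_name("genes.tsv").write_text("\n".join(m.genes) + "\n")
    mtx_path.with_name("barcodes.tsv").write_text("\n".join(m.barcodes) + "\n")


def read_dge_mtx(mtx_path) -> DGEMatrix:
    mtx_path = Path(mtx_path)
    counts = scipy.io.mmread(str(mtx_path)).toarray()
    genes = mtx_path.with_name("genes.tsv").read_text().splitlines()
    barcodes = mtx_path.with_name("barcodes.tsv").read_text().splitlines()
    return DGEMatrix(genes, barcodes, counts)
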