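"""Sparse genes x barcodes UMI count matrix with CellRanger-style triplet I/O.

The on-disk layout is the familiar MatrixMarket triplet: ``matrix.mtx`` with
genes as rows and barcodes as columns, next to ``features.tsv`` and
``barcodes.tsv`` listing the row and column labels in order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.io
import scipy.sparse as sp


class UMICountMatrix:
    """Deduplicated UMI counts per (gene, barcode), stored sparse."""

    def __init__(self, gene_ids: list[str], barcodes: list[str], counts: sp.spmatrix):
        counts = sp.csr_matrix(counts, dtype=np.int64)
        if counts.shape != (len(gene_ids), len(barcodes)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(barcodes)} barcodes"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative counts")
        self.gene_ids = list(gene_ids)
        self.barcodes = list(barcodes)
        self.counts = counts
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self._barcode_pos = {b: j for j, b in enumerate(self.barcodes)}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_triplets(
        cls,
        gene_ids: list[str],
        barcodes: list[str],
        triplets: Mapping[tuple[str, str], int] | Iterable[tuple[str, str, int]],
    ) -> "UMICountMatrix":
        gpos = {g: i for i, g in enumerate(gene_ids)}
        bpos = {b: j for j, b in enumerate(barcodes)}
        if isinstance(triplets, Mapping):
            items = ((g, b, c) for (g, b), c in triplets.items())
        else:
            items = iter(triplets)
        rows, cols, data = [], [], []
        for g, b, c in items:
            rows.append(gpos[g])
            cols.append(bpos[b])
            data.append(c)
        counts = sp.coo_matrix(
            (data, (rows, cols)), shape=(len(gene_ids), len(barcodes)), dtype=np.int64
        )
        return cls(gene_ids, barcodes, counts.tocsr())

    # -- basic queries -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def get(self, gene_id: str, barcode: str) -> int:
        i = self._gene_pos.get(gene_id)
        j = self._barcode_pos.get(barcode)
        if i is None or j is None:
            return 0
        return int(self.counts[i, j])

    def total(self) -> int:
        return int(self.counts.sum())

    def barcode_totals(self) -> np.ndarray:
        """Total UMIs per barcode (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_barcodes(self, barcodes: Iterable[str]) -> "UMICountMatrix":
        keep = [b for b in barcodes if b in self._barcode_pos]
        idx = [self._barcode_pos[b] for b in keep]
        return UMICountMatrix(self.gene_ids, keep, self.counts[:, idx])

    def hstack(self, other: "UMICountMatrix") -> "UMICountMatrix":
        """Append the columns of another matrix over the same gene list."""
        if other.gene_ids != self.gene_ids:
            raise ValueError("gene lists differ")
        overlap = set(self.barcodes) & set(other.barcodes)
        if overlap:
            raise ValueError(f"{len(overlap)} barcode(s) present in both matrices")
        return UMICountMatrix(
            self.gene_ids,
            self.barcodes + other.barcodes,
            sp.hstack([self.counts, other.counts], format="csr"),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, UMICountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.barcodes == other.barcodes
            and (self.counts != other.counts).nnz == 0
        )

    # -- I/O -----------------------------------------------------------------

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "matrix.mtx", self.counts.tocoo(), field="integer")
        (outdir / "features.tsv").write_text("".join(g + "\n" for g in self.gene_ids))
        (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in self.barcodes))

    @classmethod
    def from_dir(cls, indir) -> "UMICountMatrix":
        indir = Path(indir)
        counts = scipy.io.mmread(indir / "matrix.mtx").tocsr()
        genes = (indir / "features.tsv").read_text().splitlines()
        barcodes = (indir / "barcodes.tsv").read_text().splitlines()
        return cls(genes, barcodes, counts)
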