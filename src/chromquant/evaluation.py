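"""Accuracy metrics: log2-cpm RMSE against truth, mixture concordance, recall.

UMI counts are compared on the log2 counts-per-million scale with a 0.5
offset added to counts before the log (library sizes stay offset-free raw
column totals).  Mixture concordance checks whether pseudo-bulk expression of
an A/B mixture matches the ratio-weighted combination of the pure samples'
cpm profiles — a truth-free accuracy check borrowed from mixture benchmark
designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cellcalling import CallResult
from .matrix import UMICountMatrix

log = logging.getLogger("chromquant")

DEFAULT_OFFSET = 0.5


@dataclass
class ExpressionMatrixLog:
    """Dense genes x cells matrix of log2-cpm values."""

    gene_ids: list[str]
    barcodes: list[str]
    values: np.ndarray
    offset: float
    libsizes: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("log matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite log2-cpm values")


def log2_cpm(matrix: UMICountMatrix, offset: float = DEFAULT_OFFSET) -> ExpressionMatrixLog:
    """log2((count + offset) / libsize * 1e6) with raw column totals as libsize.

    Cells with zero library size are excluded with a warning.
    """
    counts = matrix.to_dense().astype(float)
    libsizes = counts.sum(axis=0)
    keep = libsizes > 0
    if not keep.all():
        log.warning("excluding %d cell(s) with zero library size", int((~keep).sum()))
    counts = counts[:, keep]
    libsizes = libsizes[keep]
    values = np.log2((counts + offset) / libsizes * 1e6)
    barcodes = [b for b, k in zip(matrix.barcodes, keep) if k]
    return ExpressionMatrixLog(list(matrix.gene_ids), barcodes, values, offset, libsizes)


def _aligned_log_values(
    est: UMICountMatrix,
    truth: UMICountMatrix,
    offset: float,
    include_missing: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Truth-aligned log2-cpm arrays for est and truth.

    Cells present in truth but absent from est are scored as all-zero
    columns; their log2-cpm uses the offset-inclusive library size
    (n_genes * offset), the flat minimal-expression profile.  With
    ``include_missing=False`` they are dropped instead.
    """
    if est.gene_ids != truth.gene_ids:
        gene_ids = truth.gene_ids
        est = UMICountMatrix.from_triplets(
            gene_ids,
            est.barcodes,
            (
                (g, b, est.get(g, b))
                for g in gene_ids
                for b in est.barcodes
                if est.get(g, b)
            ),
        )
    shared = [b for b in truth.barcodes if b in set(est.barcodes)]
    missing = [b for b in truth.barcodes if b not in set(est.barcodes)]
    if not shared:
        raise ValueError("no overlapping cells between estimate and truth")
    t_log = log2_cpm(truth, offset)
    t_cols = {b: j for j, b in enumerate(t_log.barcodes)}
    e_log = log2_cpm(est.subset_barcodes(shared), offset)
    e_cols = {b: j for j, b in enumerate(e_log.barcodes)}
    use_missing = missing if include_missing else []
    n_genes = len(truth.gene_ids)
    est_mat = np.empty((n_genes, len(shared) + len(use_missing)))
    truth_mat = np.empty_like(est_mat)
    flat = np.log2(offset / (n_genes * offset) * 1e6)
    j = 0
    for b in shared:
        est_mat[:, j] = e_log.values[:, e_cols[b]]
        truth_mat[:, j] = t_log.values[:, t_cols[b]]
        j += 1
    for b in use_missing:
        est_mat[:, j] = flat
        truth_mat[:, j] = t_log.values[:, t_cols[b]]
        j += 1
    return est_mat, truth_mat


def rmse(
    est: UMICountMatrix | ExpressionMatrixLog,
    truth: UMICountMatrix | ExpressionMatrixLog,
    offset: float = DEFAULT_OFFSET,
    include_missing: bool = True,
) -> float:
    """Root mean square error over all matched (gene, cell) entries.

    Count matrices are converted to log2-cpm and matched on the truth's
    barcodes and genes; log matrices are compared as-is and must already be
    matched.
    """
    if isinstance(est, ExpressionMatrixLog) and isinstance(truth, ExpressionMatrixLog):
        if est.values.shape != truth.values.shape:
            raise ValueError("log matrices are not matched")
        diff = est.values - truth.values
        return float(np.sqrt(np.mean(diff**2)))
    est_mat, truth_mat = _aligned_log_values(est, truth, offset, include_missing)
    return float(np.sqrt(np.mean((est_mat - truth_mat) ** 2)))


def _pseudobulk_cpm(matrix: UMICountMatrix, offset: float) -> np.ndarray:
    pooled = matrix.gene_totals().astype(float)
    libsize = pooled.sum()
    if libsize <= 0:
        raise ValueError("empty sample")
    return (pooled + offset) / libsize * 1e6


def mixture_concordance(
    mat_a: UMICountMatrix,
    mat_b: UMICountMatrix,
    mat_mix: UMICountMatrix,
    ratio: float,
    offset: float = DEFAULT_OFFSET,
) -> float:
    """Concordance RMSE between an observed and a predicted in-silico mixture.

    Per gene, pseudo-bulk cpm profiles of the pure samples are combined as
    ratio * cpmA + (1 - ratio) * cpmB on the cpm scale, log2-transformed and
    compared with the observed mixture's log2 pseudo-bulk cpm.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    if not (mat_a.gene_ids == mat_b.gene_ids == mat_mix.gene_ids):
        raise ValueError("gene lists differ between samples")
    cpm_a = _pseudobulk_cpm(mat_a, offset)
    cpm_b = _pseudobulk_cpm(mat_b, offset)
    cpm_mix = _pseudobulk_cpm(mat_mix, offset)
    predicted = np.log2(ratio * cpm_a + (1.0 - ratio) * cpm_b)
    observed = np.log2(cpm_mix)
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def cell_recall(called: CallResult | set[str], truth_barcodes: set[str]) -> float:
    """Fraction of ground-truth cells present in the called set."""
    if not truth_barcodes:
        raise ValueError("empty truth barcode set")
    called_set = called.called if isinstance(called, CallResult) else called
    return len(called_set & truth_barcodes) / len(truth_barcodes)
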