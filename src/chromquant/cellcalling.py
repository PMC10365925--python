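"""Two-stage cell calling: bootstrap UMI cutoff, ambient profile, rescue.

Stage one bootstraps the per-barcode total-UMI distribution to fix a
cutoff: in each resample the 99th percentile of the top ``expected_cells``
totals is divided by 10, and the cutoff is the mean over resamples; barcodes
at or above it are high-confidence cells.  Stage two estimates the ambient
RNA profile from barcodes deep down the rank curve.  Stage three rescues
sub-cutoff barcodes whose expression deviates from the ambient profile: a
Monte-Carlo multinomial goodness-of-fit p-value per candidate, controlled
with Benjamini-Hochberg across candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .matrix import UMICountMatrix

log = logging.getLogger("chromquant")


@dataclass
class CallParams:
    expected_cells: int = 3000
    bootstrap_reps: int = 100
    quantile: float = 0.99
    divisor: float = 10.0
    # barcode-rank window (1-based, descending totals) for ambient estimation
    ambient_rank_range: tuple[int, int] = (10_000, 100_000)
    min_rescue_total: int = 10
    rescue_mc_iters: int = 10_000
    fdr_threshold: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if self.divisor <= 1.0:
            raise ValueError("divisor must be > 1")


@dataclass
class CallResult:
    high_confidence: set[str]
    rescued: set[str]
    ambient_profile: np.ndarray  # per-gene proportions, sums to 1
    threshold: float

    @property
    def called(self) -> set[str]:
        return self.high_confidence | self.rescued


def bootstrap_threshold(
    totals: np.ndarray, p: CallParams, rng: np.random.Generator
) -> float:
    """Bootstrap total-UMI cutoff for high-confidence cells.

    Each of ``bootstrap_reps`` same-size resamples with replacement
    contributes quantile(top expected_cells totals) / divisor; the cutoff is
    their mean.
    """
    totals = np.sort(np.asarray(totals))  # sort: invariant to barcode order
    nonzero = totals[totals > 0]
    if len(nonzero) == 0:
        raise ValueError("no barcode with a positive total")
    expected = p.expected_cells
    if len(nonzero) < expected:
        log.warning(
            "only %d nonzero barcodes < expected_cells=%d; lowering",
            len(nonzero),
            expected,
        )
        expected = len(nonzero)
    n = len(totals)
    reps = np.empty(p.bootstrap_reps)
    for r in range(p.bootstrap_reps):
        sample = totals[rng.integers(0, n, size=n)]
        top = np.partition(sample, n - expected)[n - expected :]
        reps[r] = np.quantile(top, p.quantile) / p.divisor
    return float(reps.mean())


def estimate_ambient(matrix: UMICountMatrix, p: CallParams) -> np.ndarray:
    """Ambient RNA profile from low-rank barcodes, with add-one smoothing.

    Sums gene counts over barcodes ranked (descending total) within
    ``ambient_rank_range`` clipped to the available barcodes, adds one
    pseudocount per gene and normalises to proportions.
    """
    totals = matrix.barcode_totals()
    order = np.argsort(-totals, kind="stable")
    lo, hi = p.ambient_rank_range
    window = order[lo - 1 : hi]
    n_genes = len(matrix.gene_ids)
    if len(window) == 0:
        log.warning("ambient rank window is empty; falling back to a uniform profile")
        return np.full(n_genes, 1.0 / n_genes)
    pooled = np.asarray(matrix.counts[:, window].sum(axis=1)).ravel().astype(float)
    pooled += 1.0
    return pooled / pooled.sum()


def _multinomial_loglik(counts: np.ndarray, log_p: np.ndarray) -> np.ndarray:
    """Multinomial log-pmf for rows of ``counts`` under fixed proportions."""
    counts = np.atleast_2d(counts)
    totals = counts.sum(axis=1)
    return (
        gammaln(totals + 1)
        - gammaln(counts + 1).sum(axis=1)
        + counts @ log_p
    )


def rescue_barcodes(
    matrix: UMICountMatrix,
    ambient_profile: np.ndarray,
    threshold: float,
    p: CallParams,
    rng: np.random.Generator,
) -> set[str]:
    """Rescue sub-cutoff barcodes whose profiles deviate from ambient RNA.

    Candidates (total below the cutoff but at least ``min_rescue_total``)
    get a Monte-Carlo p-value: the fraction of multinomial draws with the
    candidate's total under the ambient proportions whose log-likelihood is
    <= the observed one, with the add-one correction (r+1)/(N+1).  BH-adjusted
    p-values below ``fdr_threshold`` are rescued.
    """
    totals = matrix.barcode_totals()
    cand_idx = np.nonzero((totals < threshold) & (totals >= p.min_rescue_total))[0]
    if len(cand_idx) == 0:
        return set()
    log_p = np.log(ambient_profile)
    dense = np.asarray(matrix.counts[:, cand_idx].todense()).T.astype(np.int64)
    obs_ll = _multinomial_loglik(dense, log_p)
    pvals = np.empty(len(cand_idx))
    for total in np.unique(totals[cand_idx]):
        sel = totals[cand_idx] == total
        null = rng.multinomial(int(total), ambient_profile, size=p.rescue_mc_iters)
        null_ll = np.sort(_multinomial_loglik(null, log_p))
        r = np.searchsorted(null_ll, obs_ll[sel], side="right")
        pvals[sel] = (r + 1) / (p.rescue_mc_iters + 1)
    adjusted = false_discovery_control(pvals, method="bh")
    rescued_idx = cand_idx[adjusted < p.fdr_threshold]
    return {matrix.barcodes[i] for i in rescued_idx}


def call_cells(
    matrix: UMICountMatrix,
    p: CallParams | None = None,
    rng: np.random.Generator | None = None,
) -> CallResult:
    """Compose the three stages into a cell-calling result."""
    p = p or CallParams()
    rng = rng if rng is not None else np.random.default_rng(p.rng_seed)
    totals = matrix.barcode_totals()
    threshold = bootstrap_threshold(totals, p, rng)
    high = {b for b, t in zip(matrix.barcodes, totals) if t >= threshold}
    ambient = estimate_ambient(matrix, p)
    rescued = rescue_barcodes(matrix, ambient, threshold, p, rng)
    rescued -= high
    return CallResult(high, rescued, ambient, threshold)


def write_cells_tsv(result: CallResult, matrix: UMICountMatrix, path) -> None:
    """Called barcodes with totals and status (high_confidence | rescued)."""
    totals = dict(zip(matrix.barcodes, matrix.barcode_totals()))
    with open(path, "wt") as fh:
        fh.write("barcode\ttotal\tstatus\n")
        for b in sorted(result.high_confidence):
            fh.write(f"{b}\t{totals.get(b, 0)}\thigh_confidence\n")
        for b in sorted(result.rescued):
            fh.write(f"{b}\t{totals.get(b, 0)}\trescued\n")


def simulate_ambient_background(
    gene_ids: list[str],
    n_droplets: int,
    rng: np.random.Generator,
    profile: np.ndarray | None = None,
    mean_total: float = 8.0,
    barcode_pool: list[str] | None = None,
) -> tuple[UMICountMatrix, np.ndarray]:
    """Synthetic ambient-only droplets for validating the calling stages.

    Droplet totals are 1 + Poisson(mean_total - 1) and gene identities are
    multinomial draws from ``profile`` (default: a geometric-decay profile
    over genes, mimicking the skew of ambient RNA).  Returns the droplet
    matrix (columns ``bg%06d`` unless a barcode pool is given) and the
    profile used.
    """
    g = len(gene_ids)
    if profile is None:
        profile = 0.7 ** np.arange(g)
        profile = profile / profile.sum()
    totals = 1 + rng.poisson(max(mean_total - 1.0, 0.0), size=n_droplets)
    cols = np.vstack([rng.multinomial(int(t), profile) for t in totals]).T
    if barcode_pool is not None:
        if len(barcode_pool) < n_droplets:
            raise ValueError("barcode pool smaller than n_droplets")
        barcodes = list(barcode_pool[:n_droplets])
    else:
        barcodes = [f"bg{i:06d}" for i in range(n_droplets)]
    import scipy.sparse as sp

    mat = UMICountMatrix(gene_ids, barcodes, sp.csr_matrix(cols))
    return mat, profile
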