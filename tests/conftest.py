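"""Shared fixtures: synthetic reference data and two end-to-end runs.

The heavyweight session fixtures (a noise-free 200-cell run and a
default-noise 500-cell run with ambient background) are shared between the
property and acceptance tests so each simulation is paid for once.
"""

from __future__ import annotations

import numpy as np
import pytest

import chromquant as cq
from chromquant.quantifier import read_pairs_from_records

FIXTURE_SEED = 101


@pytest.fixture(scope="session")
def ref():
    """Small random reference: 25 disjoint single-exon genes, 600 barcodes."""
    genome, catalogue, whitelist = cq.build_fixture(
        FIXTURE_SEED, n_genes=25, genome_size=70_000, n_barcodes=600
    )
    return genome, catalogue, whitelist


@pytest.fixture(scope="session")
def aligner(ref):
    genome, catalogue, _ = ref
    index = cq.build_kmer_index(genome, 16)
    return cq.Aligner(genome, catalogue, index)


def noise_free_params(n_cells: int) -> cq.SimParams:
    return cq.SimParams(
        n_cells=n_cells,
        snp_rate=0.0,
        indel_rate=0.0,
        frag_dist_sd=0.0,
        sequencing_errors=False,
    )


@pytest.fixture(scope="session")
def noise_free_run(ref, aligner):
    """200-cell noise-free simulation, quantified end to end."""
    genome, catalogue, whitelist = ref
    params = noise_free_params(200)
    rng = np.random.default_rng(2001)
    records, truth, profiles = cq.simulate(genome, catalogue, whitelist, params, rng)
    wl = cq.BarcodeWhitelist(whitelist)
    matrix, stats = cq.quantify_reads(read_pairs_from_records(records), aligner, wl)
    return {
        "records": records,
        "truth": truth,
        "profiles": profiles,
        "matrix": matrix,
        "stats": stats,
    }


@pytest.fixture(scope="session")
def noisy_run(ref, aligner):
    """500 cells at default noise plus 20,000 ambient-only droplets, called."""
    genome, catalogue, _ = ref
    rng = np.random.default_rng(8001)
    whitelist = cq.random_whitelist(21_000, 16, rng)
    params = cq.SimParams(n_cells=500)
    records, truth, profiles = cq.simulate(genome, catalogue, whitelist, params, rng)
    wl = cq.BarcodeWhitelist(whitelist)
    matrix, stats = cq.quantify_reads(read_pairs_from_records(records), aligner, wl)
    matrix_raw, _ = cq.quantify_reads(
        read_pairs_from_records(records), aligner, wl, barcode_mode="raw"
    )
    cell_barcodes = {p.barcode for p in profiles}
    unused = [b for b in whitelist if b not in cell_barcodes]
    background, ambient_profile = cq.simulate_ambient_background(
        matrix.gene_ids, 20_000, rng, barcode_pool=unused
    )
    full = matrix.hstack(background.subset_barcodes(
        [b for b in background.barcodes if b not in set(matrix.barcodes)]
    ))
    call_params = cq.CallParams(expected_cells=500, rng_seed=8002)
    result = cq.call_cells(full, call_params, np.random.default_rng(8002))
    return {
        "records": records,
        "truth": truth,
        "profiles": profiles,
        "matrix": matrix,
        "matrix_raw": matrix_raw,
        "stats": stats,
        "full_matrix": full,
        "call_result": result,
        "truth_barcodes": cell_barcodes,
        "ambient_profile": ambient_profile,
    }
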