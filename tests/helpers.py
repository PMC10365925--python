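"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np

from chromquant.reference import GeneCatalogue, Genome, encode_seq


def brute_force_align(read: str, genome: Genome, catalogue: GeneCatalogue):
    """Exhaustive ungapped alignment over both strands of every chromosome.

    Scores matched - mismatched at every fully-contained offset; ties prefer
    gene-overlapping locations, then (chromosome order, position, strand '+'
    first) — the same tie rules as the aligner.  Returns
    (chrom, position, strand, score) or None when the genome is shorter than
    the read everywhere.
    """
    L = len(read)
    fwd = encode_seq(read)
    rev = np.where(fwd < 4, 3 - fwd, 4)[::-1]
    best = None
    for ci, (chrom, seq) in enumerate(genome.sequences.items()):
        codes = genome.codes(chrom)
        if len(codes) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        for strand, query in (("+", fwd), ("-", rev)):
            neq = (windows != query) | (windows >= 4) | (query >= 4)
            mm = neq.sum(axis=1)
            scores = L - 2 * mm
            for pos in np.nonzero(scores == scores.max())[0]:
                pos = int(pos)
                overlap = bool(catalogue.overlapping_genes(chrom, pos, pos + L))
                key = (-int(scores[pos]), not overlap, ci, pos, strand)
                if best is None or key < best[0]:
                    best = (key, (chrom, pos, strand, int(scores[pos])))
    return None if best is None else best[1]


def brute_force_distance1(observed: str, whitelist) -> list[str]:
    """All whitelist members at Hamming distance exactly 1 (linear scan)."""
    out = []
    for b in whitelist:
        if len(b) == len(observed) and sum(x != y for x, y in zip(b, observed)) == 1:
            out.append(b)
    return sorted(out)


def brute_force_umi_components(umis: list[str]) -> int:
    """Connected components of the Hamming-distance-<=1 graph via BFS."""
    n = len(umis)
    seen = [False] * n
    comps = 0
    for i in range(n):
        if seen[i]:
            continue
        comps += 1
        stack = [i]
        seen[i] = True
        while stack:
            u = stack.pop()
            for v in range(n):
                if not seen[v] and sum(x != y for x, y in zip(umis[u], umis[v])) <= 1:
                    seen[v] = True
                    stack.append(v)
    return comps


def brute_force_kmer_positions(seq: str, kmer: str) -> list[int]:
    """All occurrence positions of kmer in seq by naive scan."""
    k = len(kmer)
    return [i for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer]


def pairwise_min_hamming(barcodes: list[str]) -> int:
    codes = np.array([[ord(c) for c in b] for b in barcodes], dtype=np.uint8)
    best = codes.shape[1]
    n = len(codes)
    step = 256
    for i in range(0, n, step):
        chunk = codes[i : i + step]
        d = (chunk[:, None, :] != codes[None, :, :]).sum(axis=2)
        for r in range(len(chunk)):
            d[r, i + r] = codes.shape[1]  # ignore self
        best = min(best, int(d.min()))
    return best
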