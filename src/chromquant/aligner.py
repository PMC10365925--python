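"""Seed-and-vote read alignment, sensitised for short 3'-tag reads.

Up to 15 evenly spaced seeds per read are looked up in the genome k-mer
index; seed hits that imply the same read-start location (within a small
indel window) pool into candidate locations, and every candidate with at
least one vote is kept.  Candidates are then fully extended and scored as
matched bases minus mismatched bases, with at most one indel inferred from
disagreeing seed offsets.  Score ties prefer the location overlapping an
annotated gene; remaining ties break on (chromosome order, position, strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

import numpy as np

from .reference import (
    GeneCatalogue,
    Genome,
    KmerIndex,
    encode_seq,
    revcomp,
)

log = logging.getLogger("chromquant")


@dataclass
class AlignerParams:
    n_seeds: int = 15
    seed_k: int = 16
    min_votes: int = 1
    max_indel: int = 16  # also the candidate pooling window
    max_candidates: int = 8  # extension cap, best by votes
    min_score: int = 16  # alignments scoring below this are unmapped


@dataclass(frozen=True)
class Seed:
    read_offset: int
    kmer: str


@dataclass
class CandidateLocation:
    chrom: str
    position: int  # implied read-start coordinate (may be negative near edges)
    strand: str
    votes: int
    # seed support as (read offset in the strand-oriented query, implied start)
    support: list[tuple[int, int]] = field(default_factory=list, repr=False)


@dataclass
class AlignmentRecord:
    read_id: str
    mapped: bool
    chrom: str | None = None
    position: int | None = None
    strand: str | None = None
    matched: int = 0
    mismatched: int = 0
    indels: list[tuple[int, int, str]] = field(default_factory=list)  # (read pos, len, type)
    gene_overlap: bool = False
    votes: int = 0
    ref_span: int = 0
    clip_left: int = 0
    clip_right: int = 0

    @property
    def score(self) -> int:
        return self.matched - self.mismatched


# ---------------------------------------------------------------------------
# Seeds


@lru_cache(maxsize=None)
def _seed_offsets_cached(read_length: int, n_seeds: int, k: int) -> tuple[int, ...]:
    if read_length < k:
        return ()
    if n_seeds == 1 or read_length == k:
        return (0,)
    span = read_length - k
    seen: list[int] = []
    for i in range(n_seeds):
        o = round(i * span / (n_seeds - 1))
        if not seen or o != seen[-1]:
            seen.append(o)
    return tuple(seen)


def seed_offsets(read_length: int, n_seeds: int, k: int) -> list[int]:
    """Evenly spaced seed offsets round(i*(L-k)/(n-1)), deduplicated."""
    return list(_seed_offsets_cached(read_length, n_seeds, k))


@lru_cache(maxsize=8)
def _kmer_weights(k: int) -> np.ndarray:
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)


def extract_seeds(read: str, n_seeds: int = 15, k: int = 16) -> list[Seed]:
    """Up to ``n_seeds`` N-free seeds spread evenly across the read."""
    seeds = []
    for o in seed_offsets(len(read), n_seeds, k):
        kmer = read[o : o + k]
        if "N" not in kmer:
            seeds.append(Seed(o, kmer))
    return seeds


# ---------------------------------------------------------------------------
# Voting


def _pool(starts: np.ndarray, seed_ords: np.ndarray, max_indel: int):
    """Cluster implied starts within ±max_indel; yield (modal start, votes, support)."""
    if starts.min() == starts.max():  # unanimous seeds, the common case
        yield int(starts[0]), len(set(seed_ords.tolist())), []
        return
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    seed_ords = seed_ords[order]
    breaks = np.nonzero(np.diff(starts) > max_indel)[0] + 1
    for chunk_starts, chunk_ords in zip(
        np.split(starts, breaks), np.split(seed_ords, breaks)
    ):
        vals, counts = np.unique(chunk_starts, return_counts=True)
        modal = int(vals[np.argmax(counts)])  # ties -> smallest start
        votes = len(set(chunk_ords.tolist()))
        support = list(zip(chunk_ords.tolist(), chunk_starts.tolist()))
        yield modal, votes, support


def _candidates_for_query(
    query_codes: np.ndarray,
    strand: str,
    index: KmerIndex,
    params: AlignerParams,
) -> list[CandidateLocation]:
    k = params.seed_k
    offsets = seed_offsets(len(query_codes), params.n_seeds, k)
    if not offsets:
        return []
    offs = np.asarray(offsets)
    windows = query_codes[offs[:, None] + np.arange(k)[None, :]].astype(np.int64)
    valid = (windows < 4).all(axis=1)
    packed = windows @ _kmer_weights(k)
    all_starts: list[np.ndarray] = []
    all_ords: list[np.ndarray] = []
    for i in np.nonzero(valid)[0]:
        hits = index.lookup_packed(int(packed[i]))
        if len(hits) == 0:
            continue
        all_starts.append(hits - int(offs[i]))
        all_ords.append(np.full(len(hits), i, dtype=np.int64))
    if not all_starts:
        return []
    starts = np.concatenate(all_starts)
    seed_ords = np.concatenate(all_ords)
    out = []
    for modal, votes, support in _pool(starts, seed_ords, params.max_indel):
        if votes < params.min_votes:
            continue
        chrom, local = index.global_to_chrom(modal)
        chrom_lo, _ = index.chrom_bounds(chrom)
        local_support = [(int(offs[o]), int(s - chrom_lo)) for o, s in support]
        out.append(CandidateLocation(chrom, local, strand, votes, local_support))
    return out


def vote(
    seeds: Sequence[Seed],
    index: KmerIndex,
    read_length: int,
    params: AlignerParams | None = None,
) -> list[CandidateLocation]:
    """Pool seed hits on both strands into voted candidate locations.

    Forward seeds imply start = hit - offset; the reverse strand is queried
    with the reverse-complemented seeds at their mirrored offsets.
    """
    params = params or AlignerParams()
    out: list[CandidateLocation] = []
    for strand in "+-":
        all_starts, all_ords = [], []
        for i, seed in enumerate(seeds):
            if strand == "+":
                offset, kmer = seed.read_offset, seed.kmer
            else:
                offset = read_length - params.seed_k - seed.read_offset
                kmer = revcomp(seed.kmer)
            hits = [index.chrom_bounds(c)[0] + p for c, p in index.lookup(kmer)]
            if not hits:
                continue
            all_starts.append(np.asarray(hits, dtype=np.int64) - offset)
            all_ords.append(np.full(len(hits), i, dtype=np.int64))
        if not all_starts:
            continue
        starts = np.concatenate(all_starts)
        seed_ords = np.concatenate(all_ords)
        for modal, votes, support in _pool(starts, seed_ords, params.max_indel):
            if votes < params.min_votes:
                continue
            chrom, local = index.global_to_chrom(modal)
            lo, _ = index.chrom_bounds(chrom)
            out.append(
                CandidateLocation(
                    chrom, local, strand, votes, [(o, int(s - lo)) for o, s in support]
                )
            )
    return out


# ---------------------------------------------------------------------------
# Extension and final selection


def _ungapped(query: np.ndarray, gcodes: np.ndarray, s: int):
    """Score an ungapped placement at start s, soft-clipping past chrom ends."""
    L = len(query)
    n = len(gcodes)
    lo, hi = max(0, s), min(n, s + L)
    if hi <= lo:
        return None
    q = query[lo - s : hi - s]
    g = gcodes[lo:hi]
    neq = (q != g) | (q >= 4) | (g >= 4)
    mm = int(neq.sum())
    clipped = L - (hi - lo)
    matched = L - clipped - mm
    return {
        "score": matched - mm,
        "matched": matched,
        "mismatched": mm,
        "indels": [],
        "position": lo,
        "ref_span": hi - lo,
        "clip_left": lo - s,
        "clip_right": (s + L) - hi,
    }


def _one_indel(query: np.ndarray, gcodes: np.ndarray, s1: int, s2: int):
    """Best single-indel placement: read prefix at s1, suffix shifted to s2.

    The split point is chosen to minimise total mismatches via prefix/suffix
    mismatch sums.  Inserted read bases count as neither matched nor
    mismatched.  Returns None when the window would need clipping.
    """
    L = len(query)
    n = len(gcodes)
    d = s2 - s1  # >0 deletion from the read's view, <0 insertion
    ins = max(0, -d)
    if d == 0 or abs(d) > L:
        return None
    if s1 < 0 or s2 < 0 or s1 + L > n or s2 + L > n:
        return None
    g1 = gcodes[s1 : s1 + L]
    g2 = gcodes[s2 : s2 + L]
    neq1 = (query != g1) | (query >= 4) | (g1 >= 4)
    neq2 = (query != g2) | (query >= 4) | (g2 >= 4)
    pre = np.concatenate([[0], np.cumsum(neq1)])  # pre[i] = mm of read[:i] at s1
    suf = np.concatenate([np.cumsum(neq2[::-1])[::-1], [0]])  # suf[j] = mm of read[j:] at s2
    i_max = L - ins
    totals = pre[: i_max + 1] + suf[ins : ins + i_max + 1]
    i = int(np.argmin(totals))
    mm = int(totals[i])
    matched = L - ins - mm
    if d > 0:
        indel = (i, d, "D")
        ref_span = L + d
    else:
        indel = (i, ins, "I")
        ref_span = L - ins
    return {
        "score": matched - mm,
        "matched": matched,
        "mismatched": mm,
        "indels": [indel],
        "position": s1,
        "ref_span": ref_span,
        "clip_left": 0,
        "clip_right": 0,
    }


def _score_candidate(query: np.ndarray, gcodes: np.ndarray, cand: CandidateLocation):
    """Best placement for one candidate: ungapped at the modal start, plus a
    single-indel attempt when the seed support disagrees about the start."""
    best = _ungapped(query, gcodes, cand.position)
    starts = {s for _, s in cand.support}
    if len(starts) >= 2:
        by_offset = sorted(cand.support)
        s1 = by_offset[0][1]  # start implied by the leftmost seed
        s2 = by_offset[-1][1]  # start implied by the rightmost seed
        alt = _one_indel(query, gcodes, s1, s2)
        if alt is not None and (best is None or alt["score"] > best["score"]):
            best = alt
    return best


def finalize_alignment(
    read_id: str,
    read: str,
    candidates: Sequence[CandidateLocation],
    genome: Genome,
    catalogue: GeneCatalogue,
    params: AlignerParams | None = None,
) -> AlignmentRecord:
    """Extend the top-voted candidates and pick the best-scoring location.

    Score = matched - mismatched.  Ties prefer gene-overlapping locations,
    then (chromosome order, position, strand).  Best score < min_score is
    reported unmapped.
    """
    params = params or AlignerParams()
    query_fwd = encode_seq(read)
    chrom_order = {c: i for i, c in enumerate(genome.sequences)}
    return _select_best(
        read_id, query_fwd, candidates, genome, catalogue, params, chrom_order
    )


def _select_best(
    read_id: str,
    query_fwd: np.ndarray,
    candidates: Sequence[CandidateLocation],
    genome: Genome,
    catalogue: GeneCatalogue,
    params: AlignerParams,
    chrom_order: dict[str, int],
) -> AlignmentRecord:
    if not candidates:
        return AlignmentRecord(read_id, mapped=False)
    ranked = sorted(
        candidates, key=lambda c: (-c.votes, chrom_order[c.chrom], c.position, c.strand)
    )[: params.max_candidates]
    query_rev = None
    results = []
    for cand in ranked:
        if cand.strand == "+":
            query = query_fwd
        else:
            if query_rev is None:
                query_rev = np.where(query_fwd < 4, 3 - query_fwd, 4)[::-1]
            query = query_rev
        placed = _score_candidate(query, genome.codes(cand.chrom), cand)
        if placed is None:
            continue
        overlap = bool(
            catalogue.overlapping_genes(
                cand.chrom, placed["position"], placed["position"] + placed["ref_span"]
            )
        )
        results.append((placed, overlap, cand))
    if not results:
        return AlignmentRecord(read_id, mapped=False)
    results.sort(
        key=lambda t: (
            -t[0]["score"],
            not t[1],
            chrom_order[t[2].chrom],
            t[0]["position"],
            t[2].strand,
        )
    )
    placed, overlap, cand = results[0]
    if placed["score"] < params.min_score:
        return AlignmentRecord(read_id, mapped=False)
    return AlignmentRecord(
        read_id,
        mapped=True,
        chrom=cand.chrom,
        position=placed["position"],
        strand=cand.strand,
        matched=placed["matched"],
        mismatched=placed["mismatched"],
        indels=placed["indels"],
        gene_overlap=overlap,
        votes=cand.votes,
        ref_span=placed["ref_span"],
        clip_left=placed["clip_left"],
        clip_right=placed["clip_right"],
    )


# ---------------------------------------------------------------------------
# High-level aligner


class Aligner:
    """Seed-and-vote aligner bound to one genome, catalogue and k-mer index."""

    def __init__(
        self,
        genome: Genome,
        catalogue: GeneCatalogue,
        index: KmerIndex,
        params: AlignerParams | None = None,
    ):
        self.genome = genome
        self.catalogue = catalogue
        self.index = index
        self.params = params or AlignerParams()
        if self.index.k != self.params.seed_k:
            raise ValueError(
                f"index k={index.k} does not match seed_k={self.params.seed_k}"
            )
        self._chrom_order = {c: i for i, c in enumerate(genome.sequences)}

    def align(self, read_id: str, read: str) -> AlignmentRecord:
        p = self.params
        k = p.seed_k
        if len(read) < k:
            return AlignmentRecord(read_id, mapped=False)
        codes = encode_seq(read)
        rc = np.where(codes < 4, 3 - codes, 4)[::-1]
        offsets = _seed_offsets_cached(len(read), p.n_seeds, k)
        offs = np.asarray(offsets)
        win = offs[:, None] + np.arange(k)[None, :]
        windows = np.concatenate([codes[win], rc[win]]).astype(np.int64)
        valid = (windows < 4).all(axis=1)
        packed = windows @ _kmer_weights(k)
        # one batched binary search for all seeds on both strands
        skmers = self.index._sorted_kmers
        lo = skmers.searchsorted(packed, side="left")
        hi = skmers.searchsorted(packed, side="right")
        n_seeds = len(offsets)
        rows = np.nonzero(valid & (hi > lo))[0]
        candidates: list[CandidateLocation] = []
        if len(rows) == 0:
            return AlignmentRecord(read_id, mapped=False)
        # gather all hit positions for all seeds at once
        counts = hi[rows] - lo[rows]
        cum = np.concatenate([[0], np.cumsum(counts)])
        flat = np.arange(cum[-1]) - np.repeat(cum[:-1], counts) + np.repeat(lo[rows], counts)
        positions = self.index._sorted_pos[flat]
        row_of_hit = np.repeat(rows, counts)
        seed_of_hit = row_of_hit % n_seeds
        implied = positions - offs[seed_of_hit]
        fwd_mask = row_of_hit < n_seeds
        for strand, mask in (("+", fwd_mask), ("-", ~fwd_mask)):
            if not mask.any():
                continue
            starts = implied[mask]
            seed_ords = seed_of_hit[mask]
            for modal, votes, support in _pool(starts, seed_ords, p.max_indel):
                if votes < p.min_votes:
                    continue
                chrom, local = self.index.global_to_chrom(modal)
                chrom_lo, _ = self.index.chrom_bounds(chrom)
                candidates.append(
                    CandidateLocation(
                        chrom,
                        local,
                        strand,
                        votes,
                        [(int(offs[o]), int(s - chrom_lo)) for o, s in support],
                    )
                )
        return _select_best(
            read_id, codes, candidates, self.genome, self.catalogue, p, self._chrom_order
        )

    def align_reads(self, reads: Iterable[tuple[str, str]]) -> Iterator[AlignmentRecord]:
        for read_id, seq in reads:
            yield self.align(read_id, seq)


# ---------------------------------------------------------------------------
# SAM output


def _cigar(rec: AlignmentRecord, read_length: int) -> str:
    parts = []
    if rec.clip_left:
        parts.append(f"{rec.clip_left}S")
    core = read_length - rec.clip_left - rec.clip_right
    if rec.indels:
        pos, length, kind = rec.indels[0]
        if kind == "D":
            parts.append(f"{pos}M{length}D{core - pos}M")
        else:
            parts.append(f"{pos}M{length}I{core - pos - length}M")
    else:
        parts.append(f"{core}M")
    if rec.clip_right:
        parts.append(f"{rec.clip_right}S")
    return "".join(parts)


def write_sam(records: Iterable[AlignmentRecord], reads: dict[str, str], genome: Genome, path) -> None:
    """Minimal valid SAM text output (header + one line per read)."""
    with open(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, seq in genome.sequences.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for rec in records:
            seq = reads[rec.read_id]
            if not rec.mapped:
                fh.write(f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            flag = 16 if rec.strand == "-" else 0
            out_seq = revcomp(seq) if rec.strand == "-" else seq
            cigar = _cigar(rec, len(seq))
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.chrom}\t{rec.position + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{out_seq}\t*\tNM:i:{rec.mismatched}\n"
            )
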