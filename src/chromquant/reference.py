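"""Reference handling: genome sequences, gene models, and the seed k-mer index.

The genome is held as plain uppercase strings over {A,C,G,T,N}; gene models
are exon-interval unions in 0-based half-open coordinates with an explicit
transcriptional 3' terminus, which the 3'-biased read simulator anchors on.
The k-mer index maps every fully determined (N-free) k-mer to the sorted list
of its genomic occurrences and is the structure the seed-and-vote aligner
votes against.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger("chromquant")

DEFAULT_SEED_K = 16

# base -> 2-bit code; anything else (incl. N) -> 4
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
CODE_BASE = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return "".join(CODE_BASE[c] for c in codes)


def _open_text(path) -> Iterator[str]:
    """Open plain or gzipped text transparently (sniffed by magic bytes)."""
    with open(path, "rb") as raw:
        magic = raw.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Genome


class Genome:
    """Uppercase chromosome sequences with cached 2-bit-ish code arrays."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome has no sequences")
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
        self.sequences = sequences
        self._codes: dict[str, np.ndarray] = {}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def codes(self, chrom: str) -> np.ndarray:
        """Numeric codes for one chromosome, computed once and cached."""
        arr = self._codes.get(chrom)
        if arr is None:
            arr = encode_seq(self.sequences[chrom])
            self._codes[chrom] = arr
        return arr


def load_fasta(path) -> Genome:
    """Read a (possibly gzipped) FASTA file into a :class:`Genome`.

    The chromosome name is the header token before the first whitespace.
    Lowercase is folded to uppercase and any character outside {A,C,G,T,N}
    becomes N.  Duplicate names and empty files are hard errors.
    """
    sequences: dict[str, str] = {}
    handle = _open_text(path)
    try:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if name in sequences:
                raise ValueError(f"duplicate chromosome name {name!r} in {path}")
            seq = _NON_ACGTN.sub("N", str(record.seq).upper())
            sequences[name] = seq
    finally:
        handle.close()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


# ---------------------------------------------------------------------------
# Gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene as the union of its exons on one strand of one chromosome.

    ``exons`` are sorted, non-overlapping, half-open [start, end) intervals.
    ``three_prime_pos`` is the genomic coordinate of the transcriptional
    3'-most base: the last base for '+' genes, the first for '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon [{s},{e}) in {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"unsorted/overlapping exons in {self.gene_id}")
            prev_end = e
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        """Genomic (unspliced) span of the gene."""
        return self.end - self.start

    @property
    def three_prime_pos(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


class GeneCatalogue:
    """Gene models indexed for exon-overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                tree.addi(s, e, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> set[str]:
        """Genes with at least one exon base inside [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def overlap_bases(self, gene_id: str, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the gene's exon union."""
        g = self.genes[gene_id]
        if g.chrom != chrom:
            return 0
        total = 0
        for s, e in g.exons:
            total += max(0, min(e, end) - max(s, start))
        return total

    def subset(self, gene_ids: Iterable[str]) -> "GeneCatalogue":
        return GeneCatalogue(self.genes[g] for g in gene_ids)

    def write_gtf(self, path) -> None:
        """Write one ``exon`` feature per merged exon (1-based closed coords)."""
        with open(path, "wt") as fh:
            for g in self.genes.values():
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\tchromquant\texon\t{s + 1}\t{e}\t.\t"
                        f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
                    )


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def load_gtf(path, genome: Genome, min_gene_length: int = 0) -> GeneCatalogue:
    """Build a :class:`GeneCatalogue` from the ``exon`` features of a GTF file.

    GTF's 1-based closed coordinates are converted to 0-based half-open, and
    overlapping exons of a gene are merged to their union (transcript-level
    structure is deliberately collapsed).  Genes on chromosomes missing from
    ``genome`` are skipped with a warning; exons without a ``gene_id``
    attribute are a hard error.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    skipped_chroms: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise ValueError(f"{path}:{lineno}: exon feature without gene_id")
            gene_id = m.group(1)
            if chrom not in genome:
                skipped_chroms.add(chrom)
                exons.pop(gene_id, None)
                meta[gene_id] = ("", "")
                continue
            s, e = int(start) - 1, int(end)
            if meta.get(gene_id, (chrom, strand)) not in ((chrom, strand), ("", "")):
                raise ValueError(
                    f"{path}:{lineno}: gene {gene_id} spans chromosomes/strands"
                )
            if meta.get(gene_id) == ("", ""):
                continue  # gene already dropped for unknown chromosome
            meta[gene_id] = (chrom, strand)
            exons.setdefault(gene_id, []).append((s, e))
    if skipped_chroms:
        log.warning(
            "skipped genes on %d chromosome(s) absent from genome: %s",
            len(skipped_chroms),
            ", ".join(sorted(skipped_chroms)),
        )
    genes = []
    for gene_id, ivs in exons.items():
        chrom, strand = meta[gene_id]
        model = GeneModel(gene_id, chrom, strand, merge_intervals(ivs))
        if model.span < min_gene_length:
            log.warning("dropping gene %s: span %d < %d", gene_id, model.span, min_gene_length)
            continue
        genes.append(model)
    return GeneCatalogue(genes)


def three_prime_sequence(
    gene: GeneModel, genome: Genome, distance: int, length: int
) -> str:
    """Genomic (unspliced) sequence near a gene's 3' end, transcript-oriented.

    The returned window's 3'-most base sits ``distance`` bases upstream of the
    gene's ``three_prime_pos``; minus-strand genes return the reverse
    complement.  The window is clipped to the gene's genomic span (truncated
    sequence returned); a distance beyond the span yields "".
    """
    if distance < 0 or length < 1:
        raise ValueError("distance must be >= 0 and length >= 1")
    seq = genome.sequences[gene.chrom]
    if gene.strand == "+":
        hi = gene.three_prime_pos - distance + 1  # exclusive
        if hi <= gene.start:
            return ""
        lo = max(gene.start, hi - length)
        return seq[lo:hi]
    lo = gene.three_prime_pos + distance
    if lo >= gene.end:
        return ""
    hi = min(gene.end, lo + length)
    return revcomp(seq[lo:hi])


# ---------------------------------------------------------------------------
# K-mer index


class KmerIndex:
    """Map from N-free k-mer to all its genomic occurrence positions.

    Internally k-mers are 2-bit packed integers and occurrences are stored as
    sorted per-chromosome position arrays, which is what the aligner's voting
    step consumes directly.
    """

    def __init__(self, k: int, genome: Genome):
        if not (8 <= k <= 24):
            raise ValueError(f"seed length k={k} outside [8, 24]")
        self.k = k
        self.chrom_names: list[str] = list(genome.sequences)
        self._chrom_index = {c: i for i, c in enumerate(self.chrom_names)}
        # concatenated coordinates: chrom i occupies [starts[i], starts[i+1])
        self.starts = np.zeros(len(self.chrom_names) + 1, dtype=np.int64)
        kmer_chunks, pos_chunks = [], []
        for i, chrom in enumerate(self.chrom_names):
            codes = genome.codes(chrom)
            self.starts[i + 1] = self.starts[i] + len(codes)
            kmers, positions = _rolling_kmers(codes, k)
            kmer_chunks.append(kmers)
            pos_chunks.append(positions + self.starts[i])
        all_kmers = np.concatenate(kmer_chunks)
        all_pos = np.concatenate(pos_chunks)
        order = np.argsort(all_kmers, kind="stable")  # stable keeps positions sorted
        self._sorted_kmers = all_kmers[order]
        self._sorted_pos = all_pos[order]

    def lookup_packed(self, kmer_code: int) -> np.ndarray:
        """Occurrences of a 2-bit packed k-mer as global (concatenated) positions."""
        lo = np.searchsorted(self._sorted_kmers, kmer_code, side="left")
        hi = np.searchsorted(self._sorted_kmers, kmer_code, side="right")
        return self._sorted_pos[lo:hi]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Occurrences of a k-mer string as (chromosome, position) pairs."""
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != k={self.k}")
        codes = encode_seq(kmer)
        if (codes >= 4).any():
            return []
        packed = 0
        for c in codes:
            packed = (packed << 2) | int(c)
        return [self.global_to_chrom(p) for p in self.lookup_packed(packed)]

    def global_to_chrom(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        return self.chrom_names[i], int(gpos - self.starts[i])

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        i = self._chrom_index[chrom]
        return int(self.starts[i]), int(self.starts[i + 1])


def _rolling_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All N-free k-mers of one chromosome as packed ints + their positions."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    packed = np.zeros(m, dtype=np.int64)
    for j in range(k):
        packed = (packed << 2) | codes[j : j + m].astype(np.int64)
    bad = (codes >= 4).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    clean = (cum[k:] - cum[:-k]) == 0
    positions = np.nonzero(clean)[0].astype(np.int64)
    return packed[positions], positions


def build_kmer_index(genome: Genome, k: int = DEFAULT_SEED_K) -> KmerIndex:
    """Index every N-free k-mer position of the genome (see :class:`KmerIndex`)."""
    return KmerIndex(k, genome)
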