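"""Barcode correction, gene assignment and UMI deduplication.

Observed cell barcodes are matched against the chemistry whitelist allowing
one base mismatch (ambiguous corrections are rejected).  Mapped reads are
assigned to the gene whose exon union they overlap most (featureCounts-style
largestOverlap; exact ties are discarded as ambiguous).  Within each
(gene, cell), UMIs at Hamming distance <= 1 collapse to single molecules
(single-linkage components), and a UMI claimed by several genes of one cell
is kept only by the gene with the most supporting reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .aligner import Aligner, AlignmentRecord
from .matrix import UMICountMatrix
from .reference import GeneCatalogue, _open_text

log = logging.getLogger("chromquant")

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Barcode whitelist


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


class BarcodeWhitelist:
    """Fixed-length barcode set with Hamming-distance-1 correction."""

    def __init__(self, barcodes: Iterable[str]):
        self.barcodes = frozenset(barcodes)
        if not self.barcodes:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"barcodes of mixed lengths: {sorted(lengths)}")
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    @classmethod
    def from_file(cls, path) -> "BarcodeWhitelist":
        with _open_text(path) as fh:
            return cls(line.strip() for line in fh if line.strip())

    def distance1_members(self, observed: str) -> list[str]:
        """All whitelist barcodes at Hamming distance exactly 1 from observed."""
        found = []
        for i, orig in enumerate(observed):
            prefix, suffix = observed[:i], observed[i + 1 :]
            for b in _BASES:
                if b == orig:
                    continue
                cand = prefix + b + suffix
                if cand in self.barcodes:
                    found.append(cand)
        return found


def correct_barcode(observed: str, wl: BarcodeWhitelist) -> str | None:
    """Whitelist-correct one observed barcode; None means the read is dropped.

    Exact members pass through; otherwise a unique distance-1 whitelist
    barcode is adopted, and zero or multiple candidates reject the read.
    """
    if len(observed) != wl.length:
        return None
    if observed in wl:
        return observed
    candidates = wl.distance1_members(observed)
    if len(candidates) == 1:
        return candidates[0]
    return None


# ---------------------------------------------------------------------------
# Gene assignment


def assign_to_gene(aln: AlignmentRecord, catalogue: GeneCatalogue) -> tuple[str | None, str]:
    """featureCounts-style assignment of one mapped read to a gene.

    Returns (gene_id, "assigned"), (None, "no_feature") or (None, "ambiguous").
    Among several overlapping genes, the largest exon-union overlap wins;
    exact ties are ambiguous.
    """
    if not aln.mapped:
        raise ValueError("cannot assign an unmapped read")
    start, end = aln.position, aln.position + aln.ref_span
    hits = catalogue.overlapping_genes(aln.chrom, start, end)
    if not hits:
        return None, "no_feature"
    if len(hits) == 1:
        return next(iter(hits)), "assigned"
    overlaps = {
        g: catalogue.overlap_bases(g, aln.chrom, start, end) for g in hits
    }
    best = max(overlaps.values())
    winners = [g for g, v in overlaps.items() if v == best]
    if len(winners) == 1:
        return winners[0], "assigned"
    return None, "ambiguous"


# ---------------------------------------------------------------------------
# UMI collapsing


def collapse_umis(umi_read_counts: Mapping[str, int]) -> list[tuple[str, int]]:
    """Collapse UMIs at Hamming distance <= 1 into single-molecule components.

    Returns one (representative, summed reads) pair per connected component
    of the distance-1 graph (single linkage).  The representative is the
    member with the most reads, ties broken lexicographically.
    """
    umis = sorted(umi_read_counts)
    n = len(umis)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if hamming(umis[i], umis[j]) <= 1:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(umis[i])
    out = []
    for members in groups.values():
        rep = min(members, key=lambda u: (-umi_read_counts[u], u))
        out.append((rep, sum(umi_read_counts[u] for u in members)))
    out.sort(key=lambda t: t[0])
    return out


def resolve_multigene_umis(
    table: Mapping[tuple[str, str], int]
) -> dict[tuple[str, str], int]:
    """Resolve UMI representatives claimed by several genes of one barcode.

    ``table`` maps (umi representative, gene_id) -> supporting reads.  Each
    representative is kept only under the gene with the most reads (ties:
    lexicographically smallest gene_id); each surviving pair counts one UMI.
    """
    by_umi: dict[str, list[tuple[str, int]]] = {}
    for (umi, gene_id), reads in table.items():
        by_umi.setdefault(umi, []).append((gene_id, reads))
    winners: dict[tuple[str, str], int] = {}
    for umi, claims in by_umi.items():
        gene_id, _ = min(claims, key=lambda t: (-t[1], t[0]))
        winners[(umi, gene_id)] = 1
    return winners


# ---------------------------------------------------------------------------
# Matrix assembly


@dataclass(frozen=True)
class ReadAssignment:
    barcode: str  # whitelist-corrected
    umi: str
    gene_id: str
    read_id: str


@dataclass
class QuantStats:
    """Per-stage read accounting; reads_in = rejected + unmapped + unassigned + assigned."""

    reads_in: int = 0
    barcode_rejected: int = 0
    unmapped: int = 0
    unassigned: int = 0
    assigned: int = 0

    def check(self) -> None:
        total = self.barcode_rejected + self.unmapped + self.unassigned + self.assigned
        if total != self.reads_in:
            raise AssertionError(f"accounting mismatch: {total} != {self.reads_in}")


def build_matrix(
    assignments: Iterable[ReadAssignment],
    catalogue: GeneCatalogue,
) -> UMICountMatrix:
    """Deduplicated UMI counts from corrected, gene-assigned reads.

    Rows are all catalogue genes; columns are the barcodes with at least one
    assigned read, in sorted order.
    """
    # (barcode, gene) -> umi -> reads
    nested: dict[str, dict[str, dict[str, int]]] = {}
    for a in assignments:
        per_gene = nested.setdefault(a.barcode, {})
        per_umi = per_gene.setdefault(a.gene_id, {})
        per_umi[a.umi] = per_umi.get(a.umi, 0) + 1
    barcodes = sorted(nested)
    triplets: list[tuple[str, str, int]] = []
    for barcode in barcodes:
        table: dict[tuple[str, str], int] = {}
        for gene_id, umi_counts in nested[barcode].items():
            for rep, reads in collapse_umis(umi_counts):
                table[(rep, gene_id)] = table.get((rep, gene_id), 0) + reads
        gene_counts: dict[str, int] = {}
        for (_umi, gene_id), inc in resolve_multigene_umis(table).items():
            gene_counts[gene_id] = gene_counts.get(gene_id, 0) + inc
        for gene_id, count in gene_counts.items():
            triplets.append((gene_id, barcode, count))
    return UMICountMatrix.from_triplets(catalogue.gene_ids(), barcodes, triplets)


def quantify_reads(
    read_pairs: Iterable[tuple[str, str, str]],
    aligner: Aligner,
    whitelist: BarcodeWhitelist,
    umi_length: int = 12,
    barcode_mode: str = "correct",
) -> tuple[UMICountMatrix, QuantStats]:
    """Full quantification: (read_id, R1, R2) triples -> UMI count matrix.

    ``barcode_mode``: "correct" applies one-mismatch whitelist correction,
    "exact" keeps exact whitelist members only, and "raw" accepts any
    observed barcode unfiltered (a deliberately degraded mode used to gauge
    the value of correction).
    """
    if barcode_mode not in ("correct", "exact", "raw"):
        raise ValueError(f"unknown barcode_mode {barcode_mode!r}")
    stats = QuantStats()
    assignments: list[ReadAssignment] = []
    catalogue = aligner.catalogue
    for read_id, r1, r2 in read_pairs:
        stats.reads_in += 1
        observed = r1[: whitelist.length]
        umi = r1[whitelist.length : whitelist.length + umi_length]
        if barcode_mode == "correct":
            barcode = correct_barcode(observed, whitelist)
        elif barcode_mode == "exact":
            barcode = observed if observed in whitelist else None
        else:
            barcode = observed
        if barcode is None:
            stats.barcode_rejected += 1
            continue
        aln = aligner.align(read_id, r2)
        if not aln.mapped:
            stats.unmapped += 1
            continue
        gene_id, _status = assign_to_gene(aln, catalogue)
        if gene_id is None:
            stats.unassigned += 1
            continue
        stats.assigned += 1
        assignments.append(ReadAssignment(barcode, umi, gene_id, read_id))
    stats.check()
    return build_matrix(assignments, catalogue), stats


def read_pairs_from_records(records) -> Iterator[tuple[str, str, str]]:
    """Adapt simulator ReadRecords to the (read_id, R1, R2) triples."""
    for rec in records:
        yield rec.read_id, rec.r1_seq, rec.r2_seq
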