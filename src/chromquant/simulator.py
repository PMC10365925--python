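"""Chromium-style 3'-biased scRNA-seq read simulator with ground truth.

Per cell, the number of expressed genes, UMIs per gene and reads per UMI are
drawn from Gamma distributions (defaults Gamma(4.5, 550), Gamma(1, 6) and
Gamma(2, 2), rounded to counts and clamped at 1).  Each UMI corresponds to one
cDNA molecule: a genomic window of the read length whose 3'-most base lies
Normal(350, 30) bases upstream of the gene's 3' terminus.  Biological variants
(SNPs at 9e-4/base, short indels at 1e-4/base) are planted once per molecule,
and per-read substitution errors are driven by a per-cycle Phred profile that
decays toward the 3' end of the read.  Reads follow the Chromium layout:
R1 = 16-base cell barcode + 12-base UMI, R2 = 90-base cDNA, I1 = 8-base sample
index.  The planted UMI counts form the ground-truth matrix used downstream
for accuracy evaluation.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .matrix import UMICountMatrix
from .reference import GeneCatalogue, GeneModel, Genome, three_prime_sequence

log = logging.getLogger("chromquant")

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Parameters and quality model


@dataclass
class SimParams:
    """Simulation settings; the defaults define the standard study conditions."""

    n_cells: int = 10_000
    genes_per_cell_gamma: tuple[float, float] = (4.5, 550.0)
    umis_per_gene_gamma: tuple[float, float] = (1.0, 6.0)
    reads_per_umi_gamma: tuple[float, float] = (2.0, 2.0)
    frag_dist_mean: float = 350.0
    frag_dist_sd: float = 30.0
    snp_rate: float = 0.0009
    indel_rate: float = 0.0001
    read2_length: int = 90
    barcode_length: int = 16
    umi_length: int = 12
    sample_index: str = "ACGTACGT"
    sequencing_errors: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        for rate in (self.snp_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        for k, theta in (
            self.genes_per_cell_gamma,
            self.umis_per_gene_gamma,
            self.reads_per_umi_gamma,
        ):
            if k <= 0 or theta <= 0:
                raise ValueError("Gamma parameters must be > 0")

    def min_simulatable_span(self) -> int:
        """Smallest gene span that gives the fragment window a feasible placement.

        The 3' distance is effectively bounded by mean + 4 sd, so a gene must
        accommodate that distance plus the read itself.
        """
        return self.read2_length + int(round(self.frag_dist_mean + 4 * self.frag_dist_sd))


@dataclass
class QualityModel:
    """Per-cycle Phred profile, linearly decaying toward the 3' end of a read.

    The substitution probability at cycle i is 10^(-q_i/10) with q_i the
    (integer) score written to the FASTQ quality string, so emitted qualities
    and injected errors are consistent by construction.
    """

    q_start: float = 37.0
    q_end: float = 25.0

    def __post_init__(self):
        if self.q_end > self.q_start:
            raise ValueError("quality profile must be non-increasing toward 3'")
        self._cache: dict[int, tuple[np.ndarray, np.ndarray, str]] = {}

    def _entry(self, length: int) -> tuple[np.ndarray, np.ndarray, str]:
        ent = self._cache.get(length)
        if ent is None:
            if length == 1:
                q = np.array([round(self.q_start)])
            else:
                q = np.rint(np.linspace(self.q_start, self.q_end, length)).astype(int)
            probs = np.power(10.0, -q / 10.0)
            qual = "".join(chr(33 + int(v)) for v in q)
            ent = (q, probs, qual)
            self._cache[length] = ent
        return ent

    def profile(self, length: int) -> np.ndarray:
        return self._entry(length)[0]

    def error_probs(self, length: int) -> np.ndarray:
        return self._entry(length)[1]

    def qual_string(self, length: int) -> str:
        return self._entry(length)[2]


# ---------------------------------------------------------------------------
# Cell profiles


@dataclass
class CellProfile:
    """Planted truth for one cell: expressed genes, UMIs per gene, reads per UMI.

    ``reads_per_umi`` is flat over all UMIs of the cell; the UMIs of
    ``expressed_genes[i]`` occupy the slice starting at
    ``sum(umis_per_gene[:i])``.
    """

    barcode: str
    expressed_genes: list[str]
    umis_per_gene: list[int]
    reads_per_umi: list[int]

    def __post_init__(self):
        if len(self.expressed_genes) != len(set(self.expressed_genes)):
            raise ValueError("expressed_genes contains duplicates")
        if len(self.expressed_genes) != len(self.umis_per_gene):
            raise ValueError("umis_per_gene misaligned with expressed_genes")
        if sum(self.umis_per_gene) != len(self.reads_per_umi):
            raise ValueError("reads_per_umi misaligned with umis_per_gene")
        if any(u < 1 for u in self.umis_per_gene) or any(r < 1 for r in self.reads_per_umi):
            raise ValueError("UMI and read counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return sum(self.reads_per_umi)


class ReadRecord(NamedTuple):
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    i1_seq: str
    i1_qual: str


@dataclass
class GroundTruth:
    """Planted UMI counts plus per-read provenance."""

    matrix: UMICountMatrix
    # read_id -> (barcode, umi, gene_id, chrom, origin_start, strand)
    per_read: dict[str, tuple[str, str, str, str, int, str]] = field(default_factory=dict)


def raw_gamma(params_pair: tuple[float, float], size: int, rng: np.random.Generator) -> np.ndarray:
    """Raw (pre-rounding) Gamma(shape k, scale theta) draws."""
    k, theta = params_pair
    return rng.gamma(k, theta, size)


def _gamma_count(params_pair: tuple[float, float], size: int, rng: np.random.Generator) -> np.ndarray:
    """Gamma draws rounded to the nearest integer and clamped at 1."""
    return np.maximum(1, np.rint(raw_gamma(params_pair, size, rng)).astype(np.int64))


def simulatable_genes(catalogue: GeneCatalogue, params: SimParams) -> GeneCatalogue:
    """Restrict a catalogue to genes long enough for the 3'-window placement."""
    min_span = params.min_simulatable_span()
    keep = [g.gene_id for g in catalogue if g.span >= min_span]
    dropped = len(catalogue) - len(keep)
    if dropped:
        log.warning("excluding %d gene(s) too short for fragment placement", dropped)
    if not keep:
        raise ValueError(f"no gene reaches the minimum simulatable span of {min_span}")
    return catalogue.subset(keep)


def draw_cell_profiles(
    params: SimParams,
    catalogue: GeneCatalogue,
    whitelist: Sequence[str],
    rng: np.random.Generator,
) -> list[CellProfile]:
    """Draw per-cell expression structure from the Gamma model.

    Per cell: N ~ Gamma(genes_per_cell) rounded and capped at the catalogue
    size; N distinct genes uniformly without replacement; per gene
    max(1, round(Gamma(umis_per_gene))) UMIs; per UMI
    max(1, round(Gamma(reads_per_umi))) reads.  Cell barcodes are sampled
    without replacement from the whitelist.
    """
    if len(catalogue) == 0:
        raise ValueError("gene catalogue is empty")
    if len(whitelist) < params.n_cells:
        raise ValueError(
            f"whitelist has {len(whitelist)} barcodes < n_cells={params.n_cells}"
        )
    gene_ids = np.array(catalogue.gene_ids())
    bc_idx = rng.choice(len(whitelist), size=params.n_cells, replace=False)
    n_genes = _gamma_count(params.genes_per_cell_gamma, params.n_cells, rng)
    n_genes = np.minimum(n_genes, len(gene_ids))
    profiles = []
    for c in range(params.n_cells):
        n = int(n_genes[c])
        genes = gene_ids[rng.choice(len(gene_ids), size=n, replace=False)]
        umis = _gamma_count(params.umis_per_gene_gamma, n, rng)
        reads = _gamma_count(params.reads_per_umi_gamma, int(umis.sum()), rng)
        profiles.append(
            CellProfile(
                barcode=str(whitelist[bc_idx[c]]),
                expressed_genes=[str(g) for g in genes],
                umis_per_gene=[int(u) for u in umis],
                reads_per_umi=[int(r) for r in reads],
            )
        )
    return profiles


def truth_matrix_from_profiles(
    profiles: Iterable[CellProfile], catalogue: GeneCatalogue
) -> UMICountMatrix:
    """Planted UMI counts per (gene, barcode) as a sparse matrix."""
    profiles = list(profiles)
    barcodes = [p.barcode for p in profiles]
    triplets = []
    for p in profiles:
        for g, u in zip(p.expressed_genes, p.umis_per_gene):
            triplets.append((g, p.barcode, u))
    return UMICountMatrix.from_triplets(catalogue.gene_ids(), barcodes, triplets)


# ---------------------------------------------------------------------------
# Fragments, variants, sequencing errors


def _sample_distance(gene: GeneModel, params: SimParams, rng: np.random.Generator, length: int) -> int:
    """3' distance d ~ Normal(mean, sd), resampled until the window fits the gene."""
    max_d = gene.span - length
    if max_d < 0:
        raise ValueError(f"gene {gene.gene_id} shorter than the read length")
    for _ in range(1000):
        d = int(round(rng.normal(params.frag_dist_mean, params.frag_dist_sd)))
        if 0 <= d <= max_d:
            return d
    raise ValueError(f"no feasible fragment placement for gene {gene.gene_id}")


def sample_fragment(
    gene: GeneModel,
    genome: Genome,
    params: SimParams,
    rng: np.random.Generator,
    length: int | None = None,
) -> tuple[str, tuple[str, int, int, str]]:
    """Draw one 3'-biased fragment window from a gene.

    Returns the transcript-oriented sequence and its genomic forward-strand
    interval as (chrom, start, end, strand).
    """
    length = params.read2_length if length is None else length
    d = _sample_distance(gene, params, rng, length)
    seq = three_prime_sequence(gene, genome, d, length)
    if gene.strand == "+":
        hi = gene.three_prime_pos - d + 1
        origin = (gene.chrom, hi - len(seq), hi, "+")
    else:
        lo = gene.three_prime_pos + d
        origin = (gene.chrom, lo, lo + len(seq), "-")
    return seq, origin


def plant_variants(
    sequence: str, params: SimParams, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, str, str]]]:
    """Plant germline-style variants into a biological sequence.

    Per base: substitution with probability ``snp_rate`` (to a uniformly
    chosen different base) and indel initiation with probability
    ``indel_rate`` (insertion or deletion at equal odds, length uniform in
    1-3).  Returns the mutated sequence and a list of
    (type, position, ref, alt) records; positions refer to the input sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    variants: list[tuple[str, int, str, str]] = []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    actg = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        base_idx[b] = i
    # substitutions, vectorised; N positions are left untouched
    snp_mask = (rng.random(n) < params.snp_rate) & (base_idx[arr] >= 0)
    snp_pos = np.nonzero(snp_mask)[0]
    if len(snp_pos):
        shift = rng.integers(1, 4, size=len(snp_pos))
        new_codes = (base_idx[arr[snp_pos]].astype(np.int64) + shift) % 4
        for p, c in zip(snp_pos, new_codes):
            variants.append(("snp", int(p), sequence[p], _BASES[int(c)]))
        arr[snp_pos] = actg[new_codes]
    mutated = arr.tobytes().decode("ascii")
    # indels, sparse enough for a plain loop
    indel_pos = np.nonzero(rng.random(n) < params.indel_rate)[0]
    if len(indel_pos) == 0:
        return mutated, variants
    pieces = []
    cursor = 0
    for p in indel_pos:
        p = int(p)
        if p < cursor:  # swallowed by a previous deletion
            continue
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # insertion after base p
            ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=length))
            pieces.append(mutated[cursor : p + 1])
            pieces.append(ins)
            cursor = p + 1
            variants.append(("ins", p, "", ins))
        else:  # deletion of [p, p+length)
            length = min(length, n - p)
            pieces.append(mutated[cursor:p])
            cursor = p + length
            variants.append(("del", p, sequence[p : p + length], ""))
    pieces.append(mutated[cursor:])
    return "".join(pieces), variants


def apply_sequencing_errors(
    read: str, qm: QualityModel, rng: np.random.Generator
) -> tuple[str, str]:
    """Inject per-cycle substitution errors at probability 10^(-q_i/10).

    Returns the erroneous read and its Phred+33 quality string.
    """
    n = len(read)
    probs = qm.error_probs(n)
    qual = qm.qual_string(n)
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        base_idx[b] = i
    mask = (rng.random(n) < probs) & (base_idx[arr] >= 0)
    pos = np.nonzero(mask)[0]
    if len(pos):
        shift = rng.integers(1, 4, size=len(pos))
        new_codes = (base_idx[arr[pos]].astype(np.int64) + shift) % 4
        arr[pos] = np.frombuffer(b"ACGT", dtype=np.uint8)[new_codes]
        return arr.tobytes().decode("ascii"), qual
    return read, qual


# ---------------------------------------------------------------------------
# Read assembly


def _umi_to_str(umi_code: int, length: int) -> str:
    out = []
    for i in range(length - 1, -1, -1):
        out.append(_BASES[(umi_code >> (2 * i)) & 3])
    return "".join(out)


def _umi_hamming(a: int, b: int, length: int) -> int:
    d = a ^ b
    n = 0
    for _ in range(length):
        if d & 3:
            n += 1
        d >>= 2
    return n


def _draw_umi(
    rng: np.random.Generator,
    umi_length: int,
    cell_umis: set[int],
    gene_umis: list[int],
) -> int:
    """Draw a UMI distinct within the cell and Hamming-separated within the gene.

    Resampling keeps planted molecules unambiguous: no exact duplicate within
    a cell and no distance-<=1 pair within a (gene, cell), so deduplication
    can recover the planted counts exactly when sequencing is error-free.
    """
    space = 4**umi_length
    while True:
        u = int(rng.integers(0, space))
        if u in cell_umis:
            continue
        if any(_umi_hamming(u, v, umi_length) <= 1 for v in gene_umis):
            continue
        return u


def assemble_reads(
    profiles: Sequence[CellProfile],
    catalogue: GeneCatalogue,
    genome: Genome,
    params: SimParams,
    rng: np.random.Generator,
    quality: QualityModel | None = None,
) -> tuple[list[ReadRecord], GroundTruth]:
    """Turn cell profiles into Chromium-layout reads plus ground truth.

    Each UMI is one molecule: a single 3'-biased fragment is sampled and its
    variants planted once, shared by all reads of that UMI; sequencing errors
    are injected per read into every segment (I1, R1 and R2 alike).
    """
    qm = quality or QualityModel()
    slack = 12  # extra 5' bases so deletions cannot shorten the read
    records: list[ReadRecord] = []
    truth = GroundTruth(matrix=truth_matrix_from_profiles(profiles, catalogue))
    serial = 0
    for profile in profiles:
        cell_umis: set[int] = set()
        umi_cursor = 0
        for gene_id, n_umis in zip(profile.expressed_genes, profile.umis_per_gene):
            gene = catalogue[gene_id]
            gene_umis: list[int] = []
            for _ in range(n_umis):
                u = _draw_umi(rng, params.umi_length, cell_umis, gene_umis)
                cell_umis.add(u)
                gene_umis.append(u)
                umi_str = _umi_to_str(u, params.umi_length)
                n_reads = profile.reads_per_umi[umi_cursor]
                umi_cursor += 1
                # one molecule: one fragment, one set of planted variants
                d = _sample_distance(gene, params, rng, params.read2_length)
                window = three_prime_sequence(
                    gene, genome, d, params.read2_length + slack
                )
                if params.snp_rate > 0 or params.indel_rate > 0:
                    window, _ = plant_variants(window, params, rng)
                cdna = window[-params.read2_length :]
                if gene.strand == "+":
                    hi = gene.three_prime_pos - d + 1
                    origin_start = hi - params.read2_length
                else:
                    origin_start = gene.three_prime_pos + d
                r1_clean = profile.barcode + umi_str
                for _ in range(n_reads):
                    read_id = f"r{serial:08d}"
                    serial += 1
                    if params.sequencing_errors:
                        r1, q1 = apply_sequencing_errors(r1_clean, qm, rng)
                        r2, q2 = apply_sequencing_errors(cdna, qm, rng)
                        i1, qi1 = apply_sequencing_errors(params.sample_index, qm, rng)
                    else:
                        r1, q1 = r1_clean, qm.qual_string(len(r1_clean))
                        r2, q2 = cdna, qm.qual_string(len(cdna))
                        i1, qi1 = params.sample_index, qm.qual_string(len(params.sample_index))
                    records.append(ReadRecord(read_id, r1, q1, r2, q2, i1, qi1))
                    truth.per_read[read_id] = (
                        profile.barcode,
                        umi_str,
                        gene_id,
                        gene.chrom,
                        origin_start,
                        gene.strand,
                    )
    return records, truth


def simulate(
    genome: Genome,
    catalogue: GeneCatalogue,
    whitelist: Sequence[str],
    params: SimParams,
    rng: np.random.Generator | None = None,
    quality: QualityModel | None = None,
) -> tuple[list[ReadRecord], GroundTruth, list[CellProfile]]:
    """Full simulation: profiles -> reads + ground truth on simulatable genes."""
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    usable = simulatable_genes(catalogue, params)
    profiles = draw_cell_profiles(params, usable, whitelist, rng)
    records, truth = assemble_reads(profiles, usable, genome, params, rng, quality)
    return records, truth, profiles


# ---------------------------------------------------------------------------
# FASTQ / provenance output


def write_fastq(records: Iterable[ReadRecord], outdir) -> dict[str, Path]:
    """Write R1/R2/I1 gzipped FASTQ files (4-line records, Phred+33)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {tag: outdir / f"{tag}.fastq.gz" for tag in ("R1", "R2", "I1")}
    with gzip.open(paths["R1"], "wt", compresslevel=2) as f1, gzip.open(
        paths["R2"], "wt", compresslevel=2
    ) as f2, gzip.open(paths["I1"], "wt", compresslevel=2) as fi:
        for rec in records:
            f1.write(f"@{rec.read_id}\n{rec.r1_seq}\n+\n{rec.r1_qual}\n")
            f2.write(f"@{rec.read_id}\n{rec.r2_seq}\n+\n{rec.r2_qual}\n")
            fi.write(f"@{rec.read_id}\n{rec.i1_seq}\n+\n{rec.i1_qual}\n")
    return paths


def write_provenance(truth: GroundTruth, path) -> None:
    """Per-read provenance TSV: read_id, barcode, umi, gene, chrom, pos, strand."""
    with open(path, "wt") as fh:
        fh.write("read_id\tbarcode\tumi\tgene_id\tchrom\torigin_start\tstrand\n")
        for read_id, row in truth.per_read.items():
            fh.write(read_id + "\t" + "\t".join(str(v) for v in row) + "\n")
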