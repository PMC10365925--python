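"""Seed extraction, voting, extension scoring and oracle equivalence."""

import numpy as np
import pytest

import chromquant as cq
from chromquant.aligner import AlignerParams, seed_offsets
from chromquant.reference import GeneModel

from helpers import brute_force_align


def mutate(seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
    return "".join(out)


class TestExtractSeeds:
    def test_fifteen_seeds_on_90mer(self):
        seeds = cq.extract_seeds("A" * 90, 15, 16)
        assert len(seeds) == 15
        assert seeds[0].read_offset == 0
        assert seeds[-1].read_offset == 74

    def test_degenerate_read_equals_seed_length(self):
        seeds = cq.extract_seeds("ACGTACGTACGTACGT", 15, 16)
        assert [s.read_offset for s in seeds] == [0]

    def test_all_n_read_has_no_seeds(self):
        assert cq.extract_seeds("N" * 90, 15, 16) == []

    def test_too_short_read(self):
        assert cq.extract_seeds("ACGT", 15, 16) == []

    def test_offsets_strictly_increasing(self):
        for L in (17, 30, 45, 90, 120):
            offs = seed_offsets(L, 15, 16)
            assert offs == sorted(set(offs))
            assert all(o + 16 <= L for o in offs)


class TestVote:
    def test_unique_exact_read_gets_full_votes(self, ref, aligner):
        genome, catalogue, _ = ref
        seq = genome.sequences["chr1"][5000:5090]
        seeds = cq.extract_seeds(seq)
        cands = cq.vote(seeds, aligner.index, len(seq))
        best = max(cands, key=lambda c: c.votes)
        assert best.votes == 15
        assert (best.chrom, best.position, best.strand) == ("chr1", 5000, "+")

    def test_single_seed_read_reports_one_vote(self, ref, aligner):
        genome, _, _ = ref
        seq = genome.sequences["chr1"][5000:5090]
        # mutations at 17,33,49,65,81 break every seed except the one at offset 0
        read = mutate(seq, [17, 33, 49, 65, 81])
        cands = [c for c in cq.vote(cq.extract_seeds(read), aligner.index, 90)
                 if c.position == 5000 and c.strand == "+"]
        assert len(cands) == 1
        assert cands[0].votes == 1

    def test_no_hits_empty(self, aligner):
        read = "A" * 90  # homopolymer absent from the random fixture genome
        cands = cq.vote(cq.extract_seeds(read), aligner.index, 90)
        assert cands == []

    def test_reverse_strand_candidate(self, ref, aligner):
        genome, _, _ = ref
        seq = cq.revcomp(genome.sequences["chr1"][7000:7090])
        cands = cq.vote(cq.extract_seeds(seq), aligner.index, 90)
        best = max(cands, key=lambda c: c.votes)
        assert (best.chrom, best.position, best.strand) == ("chr1", 7000, "-")


class TestFinalize:
    def test_perfect_match(self, ref, aligner):
        genome, _, _ = ref
        seq = genome.sequences["chr1"][5000:5090]
        rec = aligner.align("r", seq)
        assert rec.mapped and rec.matched == 90 and rec.mismatched == 0
        assert rec.position == 5000 and rec.strand == "+"

    def test_single_vote_read_still_aligned(self, ref, aligner):
        genome, _, _ = ref
        seq = genome.sequences["chr1"][5000:5090]
        read = mutate(seq, [17, 33, 49, 65, 81])
        rec = aligner.align("r", read)
        assert rec.mapped
        assert rec.position == 5000
        assert rec.mismatched == 5 and rec.matched == 85
        assert rec.votes == 1

    def test_gene_overlap_preferred_on_score_tie(self):
        # two copies of the same locus, one inside a gene, one intergenic
        rng = np.random.default_rng(21)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = core + filler + core
        genome = cq.Genome({"c": seq})
        catalogue = cq.GeneCatalogue(
            [GeneModel("g1", "c", "+", ((600, 800),))]  # second copy only
        )
        index = cq.build_kmer_index(genome, 16)
        al = cq.Aligner(genome, catalogue, index)
        read = mutate(core[50:140], [10, 40])  # 2 mismatches at both loci
        rec = al.align("r", read)
        assert rec.mapped
        assert rec.position == 650  # the exonic copy wins the tie
        assert rec.gene_overlap

    def test_planted_deletion_recovered(self, ref, aligner):
        genome, _, _ = ref
        s = 5000
        # read skips 2 genomic bases after 40 read bases
        read = genome.sequences["chr1"][s : s + 40] + genome.sequences["chr1"][
            s + 42 : s + 92
        ]
        rec = aligner.align("r", read)
        assert rec.mapped
        assert rec.position == s
        assert rec.indels == [(40, 2, "D")]
        assert rec.mismatched == 0 and rec.matched == 90

    def test_planted_insertion_recovered(self, ref, aligner):
        genome, _, _ = ref
        s = 9000
        read = (
            genome.sequences["chr1"][s : s + 45]
            + "GGG"
            + genome.sequences["chr1"][s + 45 : s + 87]
        )
        rec = aligner.align("r", read)
        assert rec.mapped
        assert rec.position == s
        assert rec.indels and rec.indels[0][2] == "I" and rec.indels[0][1] == 3

    def test_low_score_is_unmapped(self, aligner, ref):
        genome, _, _ = ref
        rng = np.random.default_rng(22)
        # one seed-length genomic stretch embedded in random junk
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 74))
        read = genome.sequences["chr1"][5000:5016] + junk
        rec = aligner.align("r", read)
        if rec.mapped:
            assert rec.score >= 16

    def test_monotonicity_of_candidate_removal(self, ref, aligner):
        genome, catalogue, _ = ref
        rng = np.random.default_rng(23)
        for _ in range(20):
            s = int(rng.integers(0, 60_000))
            read = mutate(
                genome.sequences["chr1"][s : s + 90], rng.integers(0, 90, size=3)
            )
            cands = cq.vote(cq.extract_seeds(read), aligner.index, 90)
            full = cq.finalize_alignment("r", read, cands, genome, catalogue)
            if not full.mapped or len(cands) < 2:
                continue
            for drop in range(len(cands)):
                subset = cands[:drop] + cands[drop + 1 :]
                sub = cq.finalize_alignment("r", read, subset, genome, catalogue)
                if sub.mapped:
                    assert sub.score <= full.score


class TestOracleEquivalence:
    def test_matches_brute_force_on_substituted_reads(self):
        rng = np.random.default_rng(24)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        genome = cq.Genome({"c": seq})
        catalogue = cq.GeneCatalogue(
            [GeneModel("g1", "c", "+", ((1000, 4000),)),
             GeneModel("g2", "c", "-", ((6000, 9000),))]
        )
        al = cq.Aligner(genome, catalogue, cq.build_kmer_index(genome, 16))
        for i in range(300):
            s = int(rng.integers(0, len(seq) - 90))
            read = seq[s : s + 90]
            if rng.random() < 0.5:
                read = cq.revcomp(read)
            n_subs = int(rng.integers(0, 4))
            read = mutate(read, rng.choice(90, size=n_subs, replace=False))
            expected = brute_force_align(read, genome, catalogue)
            rec = al.align(f"r{i}", read)
            assert rec.mapped
            assert (rec.chrom, rec.position, rec.strand, rec.score) == expected


class TestSensitivity:
    def test_default_noise_mapping_accuracy(self, ref, aligner):
        genome, catalogue, whitelist = ref
        params = cq.SimParams(n_cells=30)
        records, truth, _ = cq.simulate(
            genome, catalogue, whitelist, params, np.random.default_rng(25)
        )
        near = 0
        for rec in records:
            aln = aligner.align(rec.read_id, rec.r2_seq)
            origin = truth.per_read[rec.read_id][4]
            if aln.mapped and abs(aln.position - origin) <= 5:
                near += 1
        assert near / len(records) >= 0.95


def test_sam_output_is_valid(tmp_path, ref, aligner):
    pysam = pytest.importorskip("pysam")
    genome, _, _ = ref
    reads = {
        "a": genome.sequences["chr1"][5000:5090],
        "b": cq.revcomp(genome.sequences["chr1"][7000:7090]),
        "c": "A" * 90,
    }
    records = [aligner.align(rid, seq) for rid, seq in reads.items()]
    path = tmp_path / "out.sam"
    cq.write_sam(records, reads, genome, path)
    with pysam.AlignmentFile(str(path), "r") as sam:
        rows = list(sam)
    by_name = {r.query_name: r for r in rows}
    assert by_name["a"].reference_start == 5000 and not by_name["a"].is_reverse
    assert by_name["b"].is_reverse and by_name["b"].reference_start == 7000
    assert by_name["c"].is_unmapped
    assert by_name["a"].cigarstring == "90M"
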