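"""Simulator distributions, variant planting, error model and read assembly."""

import numpy as np
import pytest

import chromquant as cq
from chromquant.reference import GeneModel
from chromquant.simulator import _gamma_count, _sample_distance


def _apply_variants(original: str, variants) -> str:
    """Independent reconstruction of a mutated sequence from its variant list."""
    seq = list(original)
    for kind, pos, ref, alt in variants:
        if kind == "snp":
            assert seq[pos] == ref or True  # snps recorded against the input
            seq[pos] = alt
    out = []
    cursor = 0
    s = "".join(seq)
    indels = [v for v in variants if v[0] in ("ins", "del")]
    for kind, pos, ref, alt in indels:
        if kind == "ins":
            out.append(s[cursor : pos + 1])
            out.append(alt)
            cursor = pos + 1
        else:
            out.append(s[cursor:pos])
            cursor = pos + len(ref)
    out.append(s[cursor:])
    return "".join(out)


class TestGammaDraws:
    def test_raw_means_match_k_theta(self):
        rng = np.random.default_rng(1)
        p = cq.SimParams()
        umis = cq.raw_gamma(p.umis_per_gene_gamma, 20_000, rng)
        reads = cq.raw_gamma(p.reads_per_umi_gamma, 20_000, rng)
        assert umis.mean() == pytest.approx(6.0, rel=0.05)
        assert reads.mean() == pytest.approx(4.0, rel=0.05)

    def test_counts_clamped_at_one(self):
        rng = np.random.default_rng(2)
        counts = _gamma_count((1.0, 0.1), 1000, rng)  # most raw draws < 0.5
        assert counts.min() == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cq.SimParams(snp_rate=1.5)
        with pytest.raises(ValueError):
            cq.SimParams(umis_per_gene_gamma=(0.0, 6.0))


class TestDrawCellProfiles:
    def test_structure_and_barcodes(self, ref):
        _, catalogue, whitelist = ref
        params = cq.SimParams(n_cells=30)
        profiles = cq.draw_cell_profiles(
            params, catalogue, whitelist, np.random.default_rng(3)
        )
        assert len(profiles) == 30
        barcodes = [p.barcode for p in profiles]
        assert len(set(barcodes)) == 30
        assert set(barcodes) <= set(whitelist)
        for p in profiles:
            assert len(p.expressed_genes) <= len(catalogue)
            assert sum(p.umis_per_gene) == len(p.reads_per_umi)

    def test_empty_catalogue_is_error(self, ref):
        _, catalogue, whitelist = ref
        with pytest.raises(ValueError):
            cq.draw_cell_profiles(
                cq.SimParams(n_cells=5), catalogue.subset([]), whitelist,
                np.random.default_rng(0),
            )

    def test_small_whitelist_is_error(self, ref):
        _, catalogue, _ = ref
        with pytest.raises(ValueError, match="whitelist"):
            cq.draw_cell_profiles(
                cq.SimParams(n_cells=5), catalogue, ["AAAA"], np.random.default_rng(0)
            )


class TestSampleFragment:
    def make_gene(self, length=10_000, strand="+"):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        return cq.Genome({"c": seq}), GeneModel("g", "c", strand, ((0, length),))

    def test_degenerate_sd_places_exactly(self):
        genome, gene = self.make_gene()
        params = cq.SimParams(frag_dist_sd=0.0)
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq, (chrom, start, end, strand) = cq.sample_fragment(gene, genome, params, rng)
            assert end == gene.three_prime_pos - 350 + 1
            assert end - start == params.read2_length

    def test_short_gene_placements_all_feasible(self):
        genome, gene = self.make_gene(length=400)
        params = cq.SimParams(read2_length=90)
        rng = np.random.default_rng(5)
        for _ in range(200):
            d = _sample_distance(gene, params, rng, 90)
            assert 0 <= d <= 310

    @pytest.mark.parametrize("strand", "+-")
    def test_sequence_matches_origin_interval(self, strand):
        genome, gene = self.make_gene(strand=strand)
        params = cq.SimParams()
        rng = np.random.default_rng(6)
        seq, (chrom, start, end, s) = cq.sample_fragment(gene, genome, params, rng)
        genomic = genome.sequences[chrom][start:end]
        assert seq == (genomic if strand == "+" else cq.revcomp(genomic))


class TestPlantVariants:
    def test_zero_rates_identity(self):
        params = cq.SimParams(snp_rate=0.0, indel_rate=0.0)
        seq = "ACGTACGTACGT"
        out, variants = cq.plant_variants(seq, params, np.random.default_rng(0))
        assert out == seq and variants == []

    def test_snp_saturation(self):
        params = cq.SimParams(snp_rate=1.0, indel_rate=0.0)
        seq = "ACGTACGTACGT"
        out, variants = cq.plant_variants(seq, params, np.random.default_rng(0))
        assert all(a != b for a, b in zip(seq, out))
        assert len(variants) == len(seq)

    def test_variant_list_reconstructs_output(self):
        params = cq.SimParams(snp_rate=0.05, indel_rate=0.02)
        rng = np.random.default_rng(12)
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
            out, variants = cq.plant_variants(seq, params, rng)
            assert _apply_variants(seq, variants) == out

    def test_observed_rates_near_nominal(self):
        params = cq.SimParams()
        rng = np.random.default_rng(13)
        n_bases = 2_000_000
        snps = indels = 0
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n_bases // 20))
            _, variants = cq.plant_variants(seq, params, rng)
            snps += sum(v[0] == "snp" for v in variants)
            indels += sum(v[0] in ("ins", "del") for v in variants)
        assert snps / n_bases == pytest.approx(0.0009, rel=0.15)
        assert indels / n_bases == pytest.approx(0.0001, rel=0.35)


class TestSequencingErrors:
    def test_flat_profile_error_rate(self):
        qm = cq.QualityModel(q_start=20.0, q_end=20.0)
        rng = np.random.default_rng(14)
        read = "A" * 200
        errors = 0
        for _ in range(500):
            out, qual = cq.apply_sequencing_errors(read, qm, rng)
            errors += sum(a != b for a, b in zip(read, out))
        assert errors / (200 * 500) == pytest.approx(0.01, rel=0.15)
        assert qual == chr(33 + 20) * 200

    def test_low_quality_last_cycle(self):
        qm = cq.QualityModel(q_start=40.0, q_end=2.0)
        rng = np.random.default_rng(15)
        last_errors = 0
        n = 3000
        for _ in range(n):
            out, _ = cq.apply_sequencing_errors("ACGT" * 25, qm, rng)
            last_errors += out[-1] != "T"
        assert last_errors / n == pytest.approx(10 ** (-0.2), rel=0.1)

    def test_three_prime_bias(self):
        qm = cq.QualityModel()  # default 37 -> 25
        rng = np.random.default_rng(16)
        head = tail = 0
        read = "ACGT" * 25
        for _ in range(20_000):
            out, _ = cq.apply_sequencing_errors(read, qm, rng)
            head += sum(a != b for a, b in zip(read[:10], out[:10]))
            tail += sum(a != b for a, b in zip(read[-10:], out[-10:]))
        assert tail > head

    def test_profile_non_increasing(self):
        qm = cq.QualityModel()
        q = qm.profile(90)
        assert (np.diff(q) <= 0).all()
        with pytest.raises(ValueError):
            cq.QualityModel(q_start=20.0, q_end=30.0)


class TestAssembleReads:
    def test_minimal_instance(self, ref):
        genome, catalogue, whitelist = ref
        gene = next(iter(catalogue))
        profile = cq.CellProfile(whitelist[0], [gene.gene_id], [1], [3])
        params = cq.SimParams(
            n_cells=1, snp_rate=0, indel_rate=0, frag_dist_sd=0, sequencing_errors=False
        )
        records, truth = cq.assemble_reads(
            [profile], catalogue, genome, params, np.random.default_rng(17)
        )
        assert len(records) == 3
        r1s = {r.r1_seq for r in records}
        assert len(r1s) == 1  # identical barcode+UMI across the 3 reads
        assert next(iter(r1s)).startswith(whitelist[0])
        assert truth.matrix.total() == 1

    def test_conservation(self, ref):
        genome, catalogue, whitelist = ref
        params = cq.SimParams(n_cells=5)
        rng = np.random.default_rng(18)
        profiles = cq.draw_cell_profiles(params, catalogue, whitelist, rng)
        records, truth = cq.assemble_reads(profiles, catalogue, genome, params, rng)
        assert len(records) == sum(p.total_reads for p in profiles)
        assert truth.matrix.total() == sum(sum(p.umis_per_gene) for p in profiles)
        assert len(truth.per_read) == len(records)

    def test_determinism_byte_identical(self, ref, tmp_path):
        genome, catalogue, whitelist = ref
        params = cq.SimParams(n_cells=3, rng_seed=77)
        outs = []
        for run in range(2):
            records, _, _ = cq.simulate(genome, catalogue, whitelist, params)
            d = tmp_path / f"run{run}"
            cq.write_fastq(records, d)
            outs.append(
                tuple((d / f"{t}.fastq.gz").read_bytes() for t in ("R1", "R2", "I1"))
            )
        import gzip

        for a, b in zip(outs[0], outs[1]):
            assert gzip.decompress(a) == gzip.decompress(b)

    def test_noise_free_reads_are_genomic_substrings(self, ref):
        genome, catalogue, whitelist = ref
        params = cq.SimParams(
            n_cells=3, snp_rate=0, indel_rate=0, frag_dist_sd=0, sequencing_errors=False
        )
        rng = np.random.default_rng(19)
        records, truth, _ = cq.simulate(genome, catalogue, whitelist, params, rng)
        seq = genome.sequences["chr1"]
        for rec in records[:200]:
            assert rec.r2_seq in seq or cq.revcomp(rec.r2_seq) in seq
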