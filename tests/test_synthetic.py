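"""Generator determinism, planted-truth sufficiency and spec validation."""

import numpy as np
import pytest

from genicmarkers.orf import RegionClass, find_longest_orf
from genicmarkers.snp import Zygosity
from genicmarkers.ssr import find_ssrs
from genicmarkers.synthetic import (
    MeltCurveSpec,
    TranscriptSpec,
    generate_transcripts,
    plant_snps,
    plant_ssrs,
    scrub_ssrs,
    simulate_allele_matrix,
    simulate_melt_curve,
)


class TestGenerateTranscripts:
    def test_equal_seeds_identical_output(self, tmp_path):
        from genicmarkers.io import write_fasta

        spec = TranscriptSpec(n_transcripts=10, length_range=(280, 800), seed=2)
        a, _ = generate_transcripts(spec)
        b, _ = generate_transcripts(spec)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(a, pa)
        write_fasta(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_lengths_within_published_contig_range(self):
        spec = TranscriptSpec(n_transcripts=15, length_range=(280, 6445), seed=4)
        records, _ = generate_transcripts(spec)
        assert all(280 <= len(r.sequence) <= 6445 for r in records)

    def test_all_planted_orfs_recovered(self):
        spec = TranscriptSpec(
            n_transcripts=50, length_range=(400, 1200), orf_fraction=1.0, seed=6
        )
        records, truth = generate_transcripts(spec)
        assert sum(1 for v in truth.values() if v is not None) == 50
        for rec in records:
            expected = truth[rec.transcript_id]
            found = find_longest_orf(rec.sequence, 300)
            assert (found.cds_start, found.cds_end) == (
                expected.cds_start,
                expected.cds_end,
            )

    def test_orf_free_transcripts_have_no_orf(self):
        spec = TranscriptSpec(
            n_transcripts=8, length_range=(2000, 4000), orf_fraction=0.0, seed=6
        )
        records, truth = generate_transcripts(spec)
        for rec in records:
            assert truth[rec.transcript_id] is None
            assert find_longest_orf(rec.sequence, 300) is None

    def test_degenerate_length_range_rejected(self):
        with pytest.raises(ValueError):
            TranscriptSpec(length_range=(600, 400))

    def test_too_short_minimum_rejected(self):
        with pytest.raises(ValueError):
            TranscriptSpec(length_range=(100, 400))


class TestPlantSsrs:
    def test_planted_repeats_re_extractable(self, planted_ssr_set):
        records, orfs, truth = planted_ssr_set
        seqs = {r.transcript_id: r.sequence for r in records}
        for t in truth:
            assert seqs[t.transcript_id][t.start : t.end] == t.motif * t.repeat_count

    def test_requested_counts_fulfilled(self, planted_ssr_set):
        _, _, truth = planted_ssr_set
        by_motif = {}
        for t in truth:
            by_motif[t.motif] = by_motif.get(t.motif, 0) + 1
        assert by_motif == {"AAG": 8, "GA": 6, "AGG": 4, "ATCT": 3, "AATGC": 2, "AACGTC": 2}

    def test_planted_maximality(self, planted_ssr_set):
        records, _, truth = planted_ssr_set
        seqs = {r.transcript_id: r.sequence for r in records}
        for t in truth:
            seq = seqs[t.transcript_id]
            k = len(t.motif)
            assert seq[t.start - k : t.start] != t.motif
            assert seq[t.end : t.end + k] != t.motif

    def test_loci_never_overlap_or_abut(self, planted_ssr_set):
        _, _, truth = planted_ssr_set
        by_tid = {}
        for t in truth:
            by_tid.setdefault(t.transcript_id, []).append((t.start, t.end))
        for intervals in by_tid.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 < s2

    def test_region_mix_recovered_exactly(self, small_transcriptome):
        records, orfs = small_transcriptome
        from genicmarkers.orf import classify_region

        modified, truth = plant_ssrs(
            records,
            orfs,
            {"AAG": 12},
            region_mix={RegionClass.CDS: 0.68, RegionClass.FIVE_UTR: 0.16,
                        RegionClass.THREE_UTR: 0.16},
            seed=13,
        )
        for t in truth:
            got = classify_region(orfs[t.transcript_id], (t.start, t.end))
            assert got is t.region

    def test_planted_orf_survives(self, planted_ssr_set):
        records, orfs, _ = planted_ssr_set
        for rec in records:
            expected = orfs[rec.transcript_id]
            if expected is None:
                continue
            found = find_longest_orf(rec.sequence, 300)
            assert (found.cds_start, found.cds_end) == (
                expected.cds_start,
                expected.cds_end,
            )


class TestScrub:
    def test_scrubbed_transcriptome_has_no_ssrs(self, small_transcriptome):
        records, _ = small_transcriptome
        for rec in records:
            assert find_ssrs(rec.sequence) == []


class TestPlantSnps:
    def test_vcf_ref_matches_reference_base(self, planted_snp_set):
        records, _, truth, vcf_table = planted_snp_set
        seqs = {r.transcript_id: r.sequence for r in records}
        for row in vcf_table.itertuples(index=False):
            assert seqs[row.CHROM][row.POS - 1] == row.REF

    def test_het_fraction_zero_all_hom(self, small_transcriptome):
        records, _ = small_transcriptome
        _, truth, _ = plant_snps(records, 60, het_fraction=0.0, seed=1)
        assert all(t.zygosity is Zygosity.HOM for t in truth)

    def test_alt_base_applied_to_alternate_transcripts(self, small_transcriptome):
        records, _ = small_transcriptome
        alts, truth, _ = plant_snps(records, 60, seed=1)
        alt_seqs = {r.transcript_id: r.sequence for r in alts}
        for t in truth:
            assert alt_seqs[t.transcript_id][t.pos] == t.alt_base

    def test_too_many_snps_rejected(self, small_transcriptome):
        records, _ = small_transcriptome
        total = sum(len(r.sequence) for r in records)
        with pytest.raises(ValueError):
            plant_snps(records, total + 1, seed=1)

    def test_determinism(self, small_transcriptome):
        records, _ = small_transcriptome
        a = plant_snps(records, 50, seed=9)
        b = plant_snps(records, 50, seed=9)
        assert a[1] == b[1]
        assert a[2].equals(b[2])


class TestMeltCurveSpec:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MeltCurveSpec((80.0,), (0.9,))

    def test_grid_margin_enforced(self):
        with pytest.raises(ValueError):
            MeltCurveSpec((88.0,), (1.0,), temp_grid=(70.0, 90.0, 0.1))

    def test_two_species_negative_derivative_has_two_maxima(self):
        spec = MeltCurveSpec((79.0, 81.0), (0.5, 0.5))
        curve = simulate_melt_curve(spec)
        deriv = -np.gradient(curve.fluorescence, curve.temperatures)
        is_max = (deriv[1:-1] > deriv[:-2]) & (deriv[1:-1] > deriv[2:])
        prominent = deriv[1:-1] > 0.2 * deriv.max()
        assert int(np.sum(is_max & prominent)) == 2

    def test_determinism_with_noise(self):
        spec = MeltCurveSpec((80.0,), (1.0,), noise_sd=0.01, seed=3)
        a = simulate_melt_curve(spec)
        b = simulate_melt_curve(spec)
        assert np.array_equal(a.fluorescence, b.fluorescence)


class TestAlleleMatrix:
    def test_determinism(self):
        a, _ = simulate_allele_matrix(5, 8, seed=4)
        b, _ = simulate_allele_matrix(5, 8, seed=4)
        assert np.array_equal(a.scores, b.scores)

    def test_zero_genotypes_rejected(self):
        with pytest.raises(ValueError):
            simulate_allele_matrix(3, 0, seed=1)

    def test_out_of_range_allele_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_allele_matrix(3, 5, alleles_per_locus_dist=11, seed=1)

    def test_truth_frequencies_recorded_per_locus(self):
        matrix, truth = simulate_allele_matrix(6, 10, seed=4)
        assert len(truth) == 6
        for t in truth:
            assert sum(t.frequencies) == pytest.approx(1.0)

    def test_null_rate_produces_bandless_genotypes(self):
        matrix, _ = simulate_allele_matrix(4, 200, null_rate=0.3, seed=4)
        per_locus = [
            matrix.scores[:, matrix.locus_columns(l)].sum(axis=1)
            for l in matrix.loci
        ]
        frac_null = np.mean([np.mean(row == 0) for row in per_locus])
        assert frac_null == pytest.approx(0.3, abs=0.08)
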