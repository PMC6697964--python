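"""Shared fixtures: small synthetic transcriptomes with planted truth."""

from __future__ import annotations

import pytest

from genicmarkers.synthetic import (
    TranscriptSpec,
    generate_transcripts,
    plant_snps,
    plant_ssrs,
    scrub_ssrs,
)


@pytest.fixture(scope="session")
def small_transcriptome():
    """40 transcripts (90% with a planted ORF), scrubbed of natural SSRs."""
    spec = TranscriptSpec(
        n_transcripts=40, length_range=(280, 2000), orf_fraction=0.9, seed=11
    )
    records, orfs = generate_transcripts(spec)
    records = scrub_ssrs(records, orfs, seed=11)
    return records, orfs


@pytest.fixture(scope="session")
def planted_ssr_set(small_transcriptome):
    records, orfs = small_transcriptome
    motif_mix = {"AAG": 8, "GA": 6, "AGG": 4, "ATCT": 3, "AATGC": 2, "AACGTC": 2}
    modified, truth = plant_ssrs(records, orfs, motif_mix, seed=7)
    return modified, orfs, truth


@pytest.fixture(scope="session")
def planted_snp_set(planted_ssr_set):
    records, orfs, ssr_truth = planted_ssr_set
    intervals: dict[str, list[tuple[int, int]]] = {}
    for t in ssr_truth:
        intervals.setdefault(t.transcript_id, []).append((t.start, t.end))
    alt_records, truth, vcf_table = plant_snps(
        records, n=250, ts_fraction=0.61, het_fraction=0.05, seed=7, exclude=intervals
    )
    return records, orfs, truth, vcf_table
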