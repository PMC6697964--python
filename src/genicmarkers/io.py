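"""File formats: FASTA, VCF v4.2, and the pipeline's TSV tables.

Internal coordinates are 0-based half-open everywhere; written reports use
1-based inclusive coordinates (and VCF its native 1-based POS).  All
tabular output is plain TSV so every artifact stays text.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orf import OrfAnnotation, Orientation
from .snp import VariantRecord, Zygosity
from .ssr import SSRLocus
from .synthetic import TranscriptRecord


# -- FASTA ------------------------------------------------------------------


def write_fasta(records: list[TranscriptRecord], path: str | os.PathLike) -> None:
    """Write transcripts as 60-column wrapped FASTA."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def read_fasta(path: str | os.PathLike) -> list[TranscriptRecord]:
    return [
        TranscriptRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# -- VCF --------------------------------------------------------------------


def write_vcf(
    table: pd.DataFrame,
    contig_lengths: dict[str, int],
    path: str | os.PathLike,
    sample: str = "SAMPLE",
) -> None:
    """Write an uncompressed VCF v4.2 from a CHROM/POS/REF/ALT/DP/MQ/GT table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for row in table.itertuples(index=False):
            info = f"DP={row.DP};MQ={row.MQ}"
            fh.write(
                f"{row.CHROM}\t{row.POS}\t.\t{row.REF}\t{row.ALT}\t.\t.\t"
                f"{info}\tGT\t{row.GT}\n"
            )


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], dict[str, int]]:
    """Parse biallelic SNVs from a VCF into VariantRecords.

    Multi-allelic lines contribute their first ALT only; indels, MNPs and
    symbolic alleles are skipped.  Returns the records plus a tally of
    skip reasons.  Zygosity comes from the first sample's GT when present
    (any het-looking genotype -> HET), defaulting to HOM.
    """
    records: list[VariantRecord] = []
    skipped: dict[str, int] = {}

    def skip(reason: str) -> None:
        skipped[reason] = skipped.get(reason, 0) + 1

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                skip("no-alt")
                continue
            alt = rec.alts[0]
            if len(rec.alts) > 1:
                skip("extra-alts-dropped")
            if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                skip("not-snv")
                continue
            def info_field(key):
                try:
                    return rec.info.get(key)
                except (KeyError, ValueError):  # undeclared in header
                    return None

            depth = info_field("DP")
            mq = info_field("MQ")
            zyg = Zygosity.HOM
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and len(set(a for a in gt if a is not None)) > 1:
                    zyg = Zygosity.HET
            records.append(
                VariantRecord(
                    transcript_id=rec.chrom,
                    pos=rec.pos,
                    ref_base=rec.ref,
                    alt_base=alt,
                    depth=int(depth) if depth is not None else None,
                    map_quality=float(mq) if mq is not None else None,
                    zygosity=zyg,
                )
            )
    return records, skipped


# -- SSR tables -------------------------------------------------------------


def ssr_table(loci: list[SSRLocus]) -> pd.DataFrame:
    """SSR report table with 1-based inclusive coordinates."""
    return pd.DataFrame(
        {
            "transcript_id": [l.transcript_id for l in loci],
            "start1": [l.start + 1 for l in loci],
            "end1": [l.end for l in loci],
            "motif": [l.motif for l in loci],
            "class": [l.canonical for l in loci],
            "repeat_count": [l.repeat_count for l in loci],
            "region": [l.region.value for l in loci],
        }
    )


def write_primer_input(
    entries: list[tuple[str, str, tuple[int, int]]],
    path: str | os.PathLike,
    product_range: tuple[int, int] = (100, 250),
) -> None:
    """Boulder-IO tag format consumed by primer-design tools.

    ``entries`` are (sequence_id, template_sequence, (target_start0, target_len)).
    """
    with open(path, "w") as fh:
        for seq_id, template, (t_start, t_len) in entries:
            fh.write(f"SEQUENCE_ID={seq_id}\n")
            fh.write(f"SEQUENCE_TEMPLATE={template}\n")
            fh.write(f"SEQUENCE_TARGET={t_start + 1},{t_len}\n")
            fh.write(
                f"PRIMER_PRODUCT_SIZE_RANGE={product_range[0]}-{product_range[1]}\n"
            )
            fh.write("=\n")


# -- ORF tables -------------------------------------------------------------


def orf_table(orfs: dict[str, OrfAnnotation | None]) -> pd.DataFrame:
    rows = []
    for tid in sorted(orfs):
        orf = orfs[tid]
        if orf is None:
            rows.append(
                {"transcript_id": tid, "cds_start1": 0, "cds_end1": 0,
                 "orientation": "NONE", "length_nt": 0}
            )
        else:
            rows.append(
                {
                    "transcript_id": tid,
                    "cds_start1": orf.cds_start + 1,
                    "cds_end1": orf.cds_end,
                    "orientation": orf.orientation.value,
                    "length_nt": orf.length_nt,
                }
            )
    return pd.DataFrame(rows)


def read_orf_table(path: str | os.PathLike) -> dict[str, OrfAnnotation | None]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, OrfAnnotation | None] = {}
    for row in frame.itertuples(index=False):
        if row.orientation == "NONE":
            out[str(row.transcript_id)] = None
        else:
            out[str(row.transcript_id)] = OrfAnnotation(
                str(row.transcript_id),
                int(row.cds_start1) - 1,
                int(row.cds_end1),
                Orientation(row.orientation),
                int(row.length_nt),
            )
    return out


# -- melt curves ------------------------------------------------------------


def write_melt_curves(curves, path: str | os.PathLike, qc_path: str | os.PathLike):
    """Long-format melt TSV (sample, temperature, fluorescence) + QC TSV."""
    rows = []
    qc_rows = []
    for c in curves:
        for t, f in zip(c.temperatures, c.fluorescence):
            rows.append({"sample": c.sample_id, "temperature": t, "fluorescence": f})
        qc_rows.append({"sample": c.sample_id, "ct": c.ct, "efficiency": c.efficiency})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    pd.DataFrame(qc_rows).to_csv(qc_path, sep="\t", index=False)


def read_melt_curves(path: str | os.PathLike, qc_path: str | os.PathLike):
    from .hrm import MeltCurve

    long = pd.read_csv(path, sep="\t")
    qc = pd.read_csv(qc_path, sep="\t").set_index("sample")
    curves = []
    for sample, group in long.groupby("sample", sort=False):
        ct = float(qc.loc[sample, "ct"]) if sample in qc.index else None
        eff = float(qc.loc[sample, "efficiency"]) if sample in qc.index else None
        curves.append(
            MeltCurve(
                str(sample),
                group["temperature"].to_numpy(),
                group["fluorescence"].to_numpy(),
                ct,
                eff,
            )
        )
    return curves


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
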