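"""End-to-end pipeline: simulate -> mine -> annotate -> classify -> summarize.

A run is driven by a plain YAML config (see :data:`DEFAULT_CONFIG`); all
stages execute in dependency order on either simulated or user-supplied
inputs, every per-record table is written as TSV, and a consolidated
human-readable report ties the summaries together.  Identical config and
seed give byte-identical tabular outputs; numbers are rounded only at
write time.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .diversity import AlleleMatrix, DiversitySummary, summarize_diversity
from .expression import DegSummary, classify_degs, records_to_frame
from .hrm import GenotypeCall, call_genotype
from .orf import RegionClass, find_longest_orf
from .snp import FilterThresholds, SubstitutionSpectrum, filter_variants, spectrum
from .ssr import SSRCriteria, SSRSummary, check_flanks, classify_loci, find_ssrs, summarize_ssrs
from .synthetic import (
    TranscriptSpec,
    generate_transcripts,
    genotype_melt_spec,
    plant_snps,
    plant_ssrs,
    scrub_ssrs,
    simulate_allele_matrix,
    simulate_counts,
    simulate_melt_curve,
)

logger = logging.getLogger("genicmarkers")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "genicmarkers-run",
    "simulate": {
        "transcripts": {
            "n_transcripts": 60,
            "length_range": [280, 3000],
            "gc_fraction": 0.42,
            "orf_fraction": 0.9,
        },
        "ssrs": {
            "motif_mix": {"AAG": 12, "GA": 8, "AGG": 5, "ATCT": 3, "AATGC": 2, "AACGTC": 2},
            "region_mix": {"CDS": 0.6, "FIVE_UTR": 0.2, "THREE_UTR": 0.2},
        },
        "snps": {"n": 300, "ts_fraction": 0.61, "het_fraction": 0.01},
        "counts": {
            "n_up": 6,
            "n_down": 6,
            "base_mean": 100.0,
            "dispersion": 0.1,
            "libsize_pair": [1e6, 1e6],
        },
        "alleles": {"n_loci": 12, "n_genotypes": 10, "alleles_per_locus": [2, 3, 4]},
        "melt": {
            "genotypes": [["A", "A"], ["G", "G"], ["A", "G"], ["T", "T"]],
            "noise_sd": 0.003,
        },
    },
    "inputs": {},
    "ssr": {"min_flank": 50, "product_range": [100, 250]},
    "orf": {"min_len_nt": 90},
    "snp": {"min_depth": 20, "max_depth": 200, "min_mapq": 10.0},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def validate_config(user: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown stage keys."""
    unknown = set(user) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


@dataclass
class RunReport:
    """Consolidated summaries of one pipeline run."""

    ssr_summary: SSRSummary | None = None
    snp_spectrum: SubstitutionSpectrum | None = None
    diversity: DiversitySummary | None = None
    deg_summary: DegSummary | None = None
    hrm_calls: list[GenotypeCall] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict) -> RunReport:
    """Execute all stages per the config and write artifact files."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report = RunReport(
        provenance={
            "config_hash": _config_hash(config),
            "seed": seed,
            "version": __version__,
        }
    )
    sim = config.get("simulate") or {}
    inputs = config.get("inputs") or {}

    # -- transcripts and planted features ----------------------------------
    if "fasta" in inputs:
        records = io.read_fasta(inputs["fasta"])
        orfs = {
            r.transcript_id: find_longest_orf(
                r.sequence, config["orf"]["min_len_nt"], r.transcript_id
            )
            for r in records
        }
        logger.info("stage=load fasta=%s n=%d", inputs["fasta"], len(records))
    else:
        tcfg = sim["transcripts"]
        spec = TranscriptSpec(
            n_transcripts=int(tcfg["n_transcripts"]),
            length_range=tuple(tcfg["length_range"]),
            gc_fraction=float(tcfg["gc_fraction"]),
            orf_fraction=float(tcfg["orf_fraction"]),
            seed=seed,
        )
        records, orfs = generate_transcripts(spec)
        records = scrub_ssrs(records, orfs, seed)
        motif_mix = dict(sim["ssrs"]["motif_mix"])
        region_mix = {
            RegionClass[k]: float(v) for k, v in sim["ssrs"]["region_mix"].items()
        }
        records, ssr_truth = plant_ssrs(records, orfs, motif_mix, region_mix, seed)
        ssr_intervals: dict[str, list[tuple[int, int]]] = {}
        for t in ssr_truth:
            ssr_intervals.setdefault(t.transcript_id, []).append((t.start, t.end))
        _, snp_truth, vcf_table = plant_snps(
            records,
            n=int(sim["snps"]["n"]),
            ts_fraction=float(sim["snps"]["ts_fraction"]),
            het_fraction=float(sim["snps"]["het_fraction"]),
            seed=seed,
            exclude=ssr_intervals,
        )
        io.write_fasta(records, outdir / "transcripts.fasta")
        io.write_vcf(
            vcf_table,
            {r.transcript_id: len(r.sequence) for r in records},
            outdir / "variants.vcf",
        )
        io.write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": t.transcript_id,
                        "start1": t.start + 1,
                        "end1": t.end,
                        "motif": t.motif,
                        "repeat_count": t.repeat_count,
                        "region": t.region.value,
                    }
                    for t in ssr_truth
                ]
            ),
            outdir / "truth_ssrs.tsv",
        )
        inputs = dict(inputs)
        inputs["vcf"] = str(outdir / "variants.vcf")
        logger.info(
            "stage=simulate transcripts=%d planted_ssrs=%d planted_snps=%d",
            len(records), len(ssr_truth), len(snp_truth),
        )

    # -- ORF annotation -----------------------------------------------------
    io.write_tsv(io.orf_table(orfs), outdir / "orfs.tsv")
    logger.info(
        "stage=annotate-orf transcripts=%d with_orf=%d",
        len(orfs), sum(1 for v in orfs.values() if v is not None),
    )

    # -- SSR mining ---------------------------------------------------------
    criteria = SSRCriteria()
    loci = []
    for rec in records:
        loci.extend(find_ssrs(rec.sequence, criteria, rec.transcript_id))
    loci = classify_loci(loci, orfs)
    total_bp = sum(len(r.sequence) for r in records)
    report.ssr_summary = summarize_ssrs(loci, total_bp)
    io.write_tsv(io.ssr_table(loci), outdir / "ssr_loci.tsv")
    seq_by_id = {r.transcript_id: r.sequence for r in records}
    flank_cfg = config["ssr"]
    primer_entries = []
    for loc in loci:
        rep = check_flanks(
            seq_by_id[loc.transcript_id],
            loc,
            min_flank=int(flank_cfg["min_flank"]),
            product_range=tuple(flank_cfg["product_range"]),
        )
        if rep.designable:
            template = rep.left_flank + seq_by_id[loc.transcript_id][loc.start : loc.end] + rep.right_flank
            primer_entries.append(
                (
                    f"{loc.transcript_id}_{loc.start + 1}",
                    template,
                    (len(rep.left_flank), loc.length),
                )
            )
    io.write_primer_input(
        primer_entries, outdir / "primer_input.boulder",
        tuple(flank_cfg["product_range"]),
    )
    logger.info("stage=mine-ssr loci=%d designable=%d", len(loci), len(primer_entries))

    # -- SNP characterization ----------------------------------------------
    if "vcf" in inputs:
        variants, skipped = io.read_vcf(inputs["vcf"])
        thresholds = FilterThresholds(
            min_depth=int(config["snp"]["min_depth"]),
            max_depth=int(config["snp"]["max_depth"]),
            min_mapq=float(config["snp"]["min_mapq"]),
        )
        kept, tally = filter_variants(variants, thresholds)
        report.snp_spectrum = spectrum(kept, orfs)
        io.write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": v.transcript_id,
                        "pos": v.pos,
                        "ref": v.ref_base,
                        "alt": v.alt_base,
                        "depth": v.depth,
                        "mapq": v.map_quality,
                        "zygosity": v.zygosity.value,
                    }
                    for v in kept
                ]
            ),
            outdir / "snps_retained.tsv",
        )
        logger.info(
            "stage=classify-snp parsed=%d kept=%d rejected=%s skipped=%s",
            len(variants), len(kept), dict(tally), skipped,
        )

    # -- diversity ----------------------------------------------------------
    if "bands" in inputs:
        matrix = AlleleMatrix.from_frame(
            pd.read_csv(inputs["bands"], sep="\t", index_col=0)
        )
    else:
        acfg = sim["alleles"]
        matrix, _ = simulate_allele_matrix(
            n_loci=int(acfg["n_loci"]),
            n_genotypes=int(acfg["n_genotypes"]),
            alleles_per_locus_dist=acfg.get("alleles_per_locus", (2, 3, 4)),
            seed=seed,
        )
        io.write_tsv(matrix.to_frame().reset_index(names="genotype"), outdir / "bands.tsv")
    div = summarize_diversity(matrix)
    report.diversity = div
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "locus": s.locus,
                    "alleles": s.allele_count,
                    "pic": round(s.pic, 2),
                }
                for s in div.locus_stats
            ]
        ),
        outdir / "locus_stats.tsv",
    )
    pd.DataFrame(
        div.distance_matrix, index=list(div.genotypes), columns=list(div.genotypes)
    ).to_csv(outdir / "distances.tsv", sep="\t")
    (outdir / "dendrogram.nwk").write_text(div.dendrogram.to_newick() + "\n")
    logger.info("stage=diversity loci=%d genotypes=%d", len(div.locus_stats), len(div.genotypes))

    # -- expression ---------------------------------------------------------
    if "counts" in inputs:
        table = pd.read_csv(inputs["counts"], sep="\t")
        libsizes = (
            float(config["snp"].get("libsize_control", table.count_control.sum())),
            float(config["snp"].get("libsize_treated", table.count_treated.sum())),
        )
    else:
        ccfg = sim["counts"]
        table, libsizes, _ = simulate_counts(
            records,
            n_up=int(ccfg["n_up"]),
            n_down=int(ccfg["n_down"]),
            base_mean=float(ccfg["base_mean"]),
            dispersion=float(ccfg["dispersion"]),
            libsize_pair=tuple(float(x) for x in ccfg["libsize_pair"]),
            seed=seed,
        )
        io.write_tsv(table, outdir / "counts.tsv")
    exp_records, deg_summary = classify_degs(table, libsizes[0], libsizes[1])
    report.deg_summary = deg_summary
    io.write_tsv(records_to_frame(exp_records), outdir / "degs.tsv")
    logger.info("stage=express n=%d up=%d down=%d", deg_summary.total, deg_summary.n_up, deg_summary.n_down)

    # -- HRM ----------------------------------------------------------------
    if "melt" in inputs:
        curves = io.read_melt_curves(inputs["melt"], inputs["melt_qc"])
    else:
        mcfg = sim["melt"]
        curves = []
        for gi, genotype in enumerate(mcfg["genotypes"]):
            spec = genotype_melt_spec(
                tuple(genotype), noise_sd=float(mcfg["noise_sd"]), seed=seed + gi
            )
            curves.append(simulate_melt_curve(spec, sample_id=f"{genotype[0]}{genotype[1]}_{gi}"))
        io.write_melt_curves(curves, outdir / "melt.tsv", outdir / "melt_qc.tsv")
    report.hrm_calls = [call_genotype(c) for c in curves]
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "sample": c.sample_id,
                    "domains": c.n_melt_domains,
                    "zygosity": c.zygosity,
                    "tm_values": ",".join(f"{t:.2f}" for t in c.tm_values),
                    "qc_pass": c.qc_pass,
                }
                for c in report.hrm_calls
            ]
        ),
        outdir / "hrm_calls.tsv",
    )
    logger.info("stage=hrm-call curves=%d", len(report.hrm_calls))

    write_report(report, outdir / "report.txt")
    return report


def format_report(report: RunReport) -> str:
    """Human-readable consolidated summary (rounding applied here only)."""
    lines = [f"genicmarkers {report.provenance.get('version', '')} run report"]
    lines.append(f"config hash: {report.provenance.get('config_hash')}")
    lines.append(f"seed: {report.provenance.get('seed')}")
    if report.ssr_summary is not None:
        s = report.ssr_summary
        lines.append("")
        lines.append("[SSR]")
        lines.append(f"total loci: {s.total_loci} in {s.transcripts_with_ssr} transcripts")
        if s.density_kb_per_ssr is None:
            lines.append("density: undefined (no loci)")
        else:
            lines.append(f"density: one SSR per {s.density_kb_per_ssr} kb")
        for unit, count in sorted(s.loci_by_unit_length.items()):
            lines.append(f"unit {unit}: {count} ({s.share_pct('unit_length', unit)}%)")
        for region, count in sorted(s.loci_by_region.items()):
            lines.append(f"region {region}: {count}")
    if report.snp_spectrum is not None:
        p = report.snp_spectrum
        lines.append("")
        lines.append("[SNP]")
        ratio = p.ts_tv_ratio
        lines.append(
            f"total {p.total}: Ts {p.ts_count}, Tv {p.tv_count}, "
            f"Ts/Tv {'undefined' if ratio is None else round(ratio, 2)}"
        )
        lines.append(f"zygosity: {p.hom_count} hom, {p.het_count} het")
        for region, count in sorted(p.region_counts.items()):
            lines.append(f"region {region}: {count}")
    if report.diversity is not None:
        d = report.diversity
        lines.append("")
        lines.append("[diversity]")
        lines.append(
            f"loci {len(d.locus_stats)}, mean alleles/locus "
            f"{round(d.mean_alleles_per_locus, 1)}, PIC "
            f"{round(d.pic_min, 2)}-{round(d.pic_max, 2)} "
            f"(mean {round(d.pic_mean, 2)})"
        )
    if report.deg_summary is not None:
        g = report.deg_summary
        lines.append("")
        lines.append("[expression]")
        lines.append(
            f"transcripts {g.total}: up {g.n_up}, down {g.n_down}, "
            f"unchanged {g.n_unchanged}, undefined {g.n_undefined}"
        )
    if report.hrm_calls:
        lines.append("")
        lines.append("[HRM]")
        for c in report.hrm_calls:
            tms = ",".join(f"{t:.2f}" for t in c.tm_values)
            lines.append(f"{c.sample_id}: {c.zygosity} ({c.n_melt_domains} domains; Tm {tms})")
    return "\n".join(lines) + "\n"


def write_report(report: RunReport, path: str | Path) -> None:
    Path(path).write_text(format_report(report))
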