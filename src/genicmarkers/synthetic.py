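"""Synthetic transcriptome inputs with known planted truth.

Every input the marker pipeline consumes can be generated here with its
ground truth recorded: transcript contigs carrying a single dominant
ATG-initiated ORF plus UTRs, planted perfect SSRs of unit length 2-6,
planted single-nucleotide substitutions with a controllable Ts:Tv
spectrum, two-condition count tables with planted up/down genes,
multi-allele band matrices with known allele frequencies, and sigmoid
melt curves for homozygous and heterozygous templates.

All generators are pure functions of their spec including the seed; a
single global seed fans out to per-generator substreams by stable hashing
of the generator name.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrm import MeltCurve
from .orf import OrfAnnotation, Orientation, RegionClass, find_longest_orf
from .snp import Zygosity
from .ssr import SSRCriteria, find_ssrs

BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Homoduplex Tm offsets (degC) enforcing the A/A < T/T < C/C < G/G
#: nearest-neighbour stability ordering of homozygote melt temperatures.
GENOTYPE_TM_OFFSET = {"A": 0.0, "T": 0.3, "C": 0.6, "G": 0.9}


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from one global seed."""
    digest = hashlib.sha256(f"{name}:{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# transcripts


@dataclass(frozen=True)
class TranscriptSpec:
    """Recipe for a synthetic transcript set."""

    n_transcripts: int = 500
    length_range: tuple[int, int] = (280, 6445)
    gc_fraction: float = 0.42
    orf_fraction: float = 0.964
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError(f"degenerate length_range {self.length_range}")
        if lo < 200:
            raise ValueError("length_range minimum must be >= 200")
        if not (0 <= self.gc_fraction <= 1 and 0 <= self.orf_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")


@dataclass
class TranscriptRecord:
    transcript_id: str
    sequence: str


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons - 2) stop-free random codons + one stop codon."""
    body = []
    while len(body) < n_codons - 2:
        codon = _random_bases(rng, 3, gc)
        if codon not in _STOPS:
            body.append(codon)
    stop = _STOPS[rng.integers(3)]
    return "ATG" + "".join(body) + stop


def _destroy_orfs(seq: str, min_orf_nt: int) -> str:
    """Break every ORF >= min_orf_nt by writing a stop into its middle codon."""
    while True:
        orf = find_longest_orf(seq, min_orf_nt)
        if orf is None:
            return seq
        mid = (orf.length_nt // 3) // 2
        if orf.orientation is Orientation.FORWARD:
            pos = orf.cds_start + 3 * mid
            patch = "TAA"
        else:
            pos = orf.cds_end - 3 * (mid + 1)
            patch = "TTA"  # reverse complement of TAA
        seq = seq[:pos] + patch + seq[pos + 3 :]


def generate_transcripts(
    spec: TranscriptSpec, min_orf_nt: int = 300
) -> tuple[list[TranscriptRecord], dict[str, OrfAnnotation | None]]:
    """Generate transcripts plus their ORF truth table.

    A fraction ``orf_fraction`` of transcripts carries exactly one planted
    forward-strand ATG...stop ORF of at least ``min_orf_nt`` nt that is the
    unique longest ORF over six frames (UTRs are resampled until they host
    no competing ORF); the remainder carry no ORF of that size at all.
    Equal specs produce identical records in a deterministic order.
    """
    rng = substream(spec.seed, "transcripts")
    lo, hi = spec.length_range
    n_orf = int(round(spec.orf_fraction * spec.n_transcripts))
    records: list[TranscriptRecord] = []
    truth: dict[str, OrfAnnotation | None] = {}
    width = len(str(spec.n_transcripts))
    for i in range(spec.n_transcripts):
        tid = f"TCS{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        want_orf = i < n_orf
        for _ in range(1000):
            if want_orf:
                max_codons = (length - 40) // 3  # leave room for UTRs
                min_codons = min_orf_nt // 3
                if max_codons < min_codons:
                    length = max(length, min_orf_nt + 60)
                    max_codons = (length - 40) // 3
                n_codons = int(rng.integers(min_codons, max_codons + 1))
                cds = _random_cds(rng, n_codons, spec.gc_fraction)
                utr_total = length - len(cds)
                utr5 = int(rng.integers(0, utr_total + 1))
                seq = (
                    _random_bases(rng, utr5, spec.gc_fraction)
                    + cds
                    + _random_bases(rng, utr_total - utr5, spec.gc_fraction)
                )
                found = find_longest_orf(seq, min_orf_nt, tid)
                if (
                    found is not None
                    and found.cds_start == utr5
                    and found.cds_end == utr5 + len(cds)
                    and found.orientation is Orientation.FORWARD
                ):
                    records.append(TranscriptRecord(tid, seq))
                    truth[tid] = found
                    break
            else:
                seq = _destroy_orfs(
                    _random_bases(rng, length, spec.gc_fraction), min_orf_nt
                )
                records.append(TranscriptRecord(tid, seq))
                truth[tid] = None
                break
        else:
            raise RuntimeError(f"could not generate transcript {tid}")
    return records, truth


# ---------------------------------------------------------------------------
# planted SSRs


@dataclass(frozen=True)
class PlantedSSRTruth:
    transcript_id: str
    start: int
    end: int
    motif: str
    repeat_count: int
    region: RegionClass


def _region_interval(
    orf: OrfAnnotation | None, length: int, region: RegionClass, margin: int
) -> tuple[int, int] | None:
    """Coordinate window for a region, shrunk by a safety margin."""
    if region is RegionClass.UNCLASSIFIED or orf is None:
        lo, hi = 0, length
    elif region is RegionClass.FIVE_UTR:
        lo, hi = 0, orf.cds_start
    elif region is RegionClass.CDS:
        lo, hi = orf.cds_start + 3, orf.cds_end - 3  # keep start/stop codons
    else:
        lo, hi = orf.cds_end, length
    lo, hi = lo + margin, hi - margin
    return (lo, hi) if hi > lo else None


def _cds_frame_safe(seq_list: list[str], orf: OrfAnnotation, lo: int, hi: int) -> bool:
    """No in-frame stop codon across the replaced window [lo, hi)."""
    first = orf.cds_start + ((lo - orf.cds_start) // 3) * 3
    for c in range(max(first, orf.cds_start), min(hi + 3, orf.cds_end - 3), 3):
        if "".join(seq_list[c : c + 3]) in _STOPS:
            return False
    return True


def scrub_ssrs(
    records: list[TranscriptRecord],
    orfs: dict[str, OrfAnnotation | None],
    seed: int,
    criteria: SSRCriteria | None = None,
) -> list[TranscriptRecord]:
    """Mutate away every natural SSR so only planted loci remain minable.

    Each found repeat gets a center base substituted (re-checked so the ORF
    truth and CDS reading frame survive) until the miner finds nothing.
    """
    rng = substream(seed, "scrub")
    if criteria is None:
        criteria = SSRCriteria()
    out = []
    for rec in records:
        seq_list = list(rec.sequence)
        orf = orfs.get(rec.transcript_id)
        for _ in range(50):
            loci = find_ssrs("".join(seq_list), criteria, rec.transcript_id)
            if not loci:
                break
            for loc in loci:
                mid = (loc.start + loc.end) // 2
                old = seq_list[mid]
                for base in rng.permutation(BASES):
                    if base == old:
                        continue
                    seq_list[mid] = base
                    if orf is not None and orf.cds_start <= mid < orf.cds_end:
                        if not _cds_frame_safe(seq_list, orf, mid, mid + 1):
                            seq_list[mid] = old
                            continue
                    new_orf = find_longest_orf("".join(seq_list), 300)
                    same = (new_orf is None) == (orf is None) and (
                        orf is None
                        or (
                            new_orf.cds_start == orf.cds_start
                            and new_orf.cds_end == orf.cds_end
                        )
                    )
                    if same:
                        break
                    seq_list[mid] = old
        else:
            raise RuntimeError(f"could not scrub SSRs from {rec.transcript_id}")
        out.append(TranscriptRecord(rec.transcript_id, "".join(seq_list)))
    return out


def plant_ssrs(
    records: list[TranscriptRecord],
    orfs: dict[str, OrfAnnotation | None],
    motif_mix: dict[str, int],
    region_mix: dict[RegionClass, float] | None = None,
    seed: int = 0,
    criteria: SSRCriteria | None = None,
    max_extra_units: int = 5,
) -> tuple[list[TranscriptRecord], list[PlantedSSRTruth]]:
    """Plant perfect SSRs of known motif/count/region into clean transcripts.

    ``motif_mix`` maps a concrete motif (e.g. ``"AAG"``) to how many loci to
    plant; ``region_mix`` gives region probabilities (default: uniform over
    5'UTR/CDS/3'UTR).  Each insertion replaces a same-length window, keeps
    the repeat maximal and non-extendable (flanking bases are checked on
    both sides), never abuts another planted locus, and preserves the
    transcript's planted ORF (CDS insertions are screened for in-frame
    stops and the ORF is re-validated).  Run on ``scrub_ssrs`` output if
    downstream precision against the truth list must be exact.
    """
    rng = substream(seed, "plant-ssrs")
    if criteria is None:
        criteria = SSRCriteria()
    if region_mix is None:
        region_mix = {
            RegionClass.FIVE_UTR: 1 / 3,
            RegionClass.CDS: 1 / 3,
            RegionClass.THREE_UTR: 1 / 3,
        }
    regions = list(region_mix)
    region_p = np.array([region_mix[r] for r in regions], dtype=float)
    region_p = region_p / region_p.sum()
    seqs = {r.transcript_id: list(r.sequence) for r in records}
    occupied: dict[str, list[tuple[int, int]]] = {r.transcript_id: [] for r in records}
    orf_ids = [r.transcript_id for r in records if orfs.get(r.transcript_id)]
    if not orf_ids:
        raise ValueError("region planting requires ORF-bearing transcripts")
    truth: list[PlantedSSRTruth] = []
    for motif, n_loci in motif_mix.items():
        k = len(motif)
        min_units = criteria.min_repeats[k]
        for _ in range(n_loci):
            planted = False
            for _ in range(500):
                region = regions[rng.choice(len(regions), p=region_p)]
                tid = orf_ids[rng.integers(len(orf_ids))]
                orf = orfs[tid]
                seq_list = seqs[tid]
                count = int(rng.integers(min_units, min_units + max_extra_units + 1))
                span = k * count
                window = _region_interval(orf, len(seq_list), region, margin=2)
                if window is None or window[1] - window[0] <= span:
                    continue
                start = int(rng.integers(window[0], window[1] - span))
                end = start + span
                # never abut or overlap an existing planted locus
                if any(start <= e and end >= s for s, e in occupied[tid]):
                    continue
                backup = seq_list[start:end]
                seq_list[start:end] = list(motif * count)
                ok = (
                    seq_list[start - 1] != seq_list[start - 1 + k]
                    and seq_list[end] != seq_list[end - k]
                )
                if ok and region is RegionClass.CDS:
                    ok = _cds_frame_safe(seq_list, orf, start, end)
                if ok:
                    new_orf = find_longest_orf("".join(seq_list), 300)
                    ok = (
                        new_orf is not None
                        and new_orf.cds_start == orf.cds_start
                        and new_orf.cds_end == orf.cds_end
                    )
                if not ok:
                    seq_list[start:end] = backup
                    continue
                occupied[tid].append((start, end))
                truth.append(PlantedSSRTruth(tid, start, end, motif, count, region))
                planted = True
                break
            if not planted:
                raise RuntimeError(f"could not place motif {motif} after 500 tries")
    out = [TranscriptRecord(r.transcript_id, "".join(seqs[r.transcript_id])) for r in records]
    truth.sort(key=lambda t: (t.transcript_id, t.start))
    return out, truth


# ---------------------------------------------------------------------------
# planted SNPs


@dataclass(frozen=True)
class PlantedVariantTruth:
    transcript_id: str
    pos: int  # 0-based offset on the transcript
    ref_base: str
    alt_base: str
    zygosity: Zygosity


def plant_snps(
    records: list[TranscriptRecord],
    n: int,
    ts_fraction: float = 0.61,
    het_fraction: float = 17 / 1845,
    seed: int = 0,
    dp_range: tuple[int, int] = (10, 250),
    mq_range: tuple[float, float] = (0.0, 60.0),
    exclude: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[list[TranscriptRecord], list[PlantedVariantTruth], pd.DataFrame]:
    """Plant single-base substitutions and emit truth plus VCF-ready fields.

    Positions are drawn without replacement across all transcripts (skipping
    any ``exclude`` intervals, e.g. planted SSRs).  Each substitution is a
    transition with probability ``ts_fraction`` (A<->G, C<->T), otherwise
    one of the two transversion partners; zygosity is HET with probability
    ``het_fraction``.  DP and MQ are drawn uniformly from ranges wide
    enough that the default variant filters have bite.  Returns alternate
    transcripts (alt base applied), the truth list, and a table of VCF
    fields (CHROM, POS 1-based, REF, ALT, DP, MQ, GT).
    """
    if not (0 <= ts_fraction <= 1 and 0 <= het_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = substream(seed, "plant-snps")
    exclude = exclude or {}
    sites: list[tuple[int, int]] = []  # (record index, offset)
    for ri, rec in enumerate(records):
        blocked = np.zeros(len(rec.sequence), dtype=bool)
        for s, e in exclude.get(rec.transcript_id, []):
            blocked[s:e] = True
        for off in np.nonzero(~blocked)[0]:
            if rec.sequence[off] in "ACGT":
                sites.append((ri, int(off)))
    if n > len(sites):
        raise ValueError(f"requested {n} SNPs but only {len(sites)} positions free")
    chosen = rng.choice(len(sites), size=n, replace=False)
    chosen = sorted(chosen, key=lambda c: sites[c])
    alt_seqs = {r.transcript_id: list(r.sequence) for r in records}
    truth: list[PlantedVariantTruth] = []
    rows = []
    for c in chosen:
        ri, off = sites[c]
        rec = records[ri]
        ref = rec.sequence[off]
        if rng.random() < ts_fraction:
            alt = _TS_PARTNER[ref]
        else:
            choices = [b for b in "ACGT" if b != ref and b != _TS_PARTNER[ref]]
            alt = choices[rng.integers(2)]
        zyg = Zygosity.HET if rng.random() < het_fraction else Zygosity.HOM
        alt_seqs[rec.transcript_id][off] = alt
        truth.append(PlantedVariantTruth(rec.transcript_id, off, ref, alt, zyg))
        rows.append(
            {
                "CHROM": rec.transcript_id,
                "POS": off + 1,
                "REF": ref,
                "ALT": alt,
                "DP": int(rng.integers(dp_range[0], dp_range[1] + 1)),
                "MQ": float(np.round(rng.uniform(*mq_range), 2)),
                "GT": "0/1" if zyg is Zygosity.HET else "1/1",
            }
        )
    alt_records = [
        TranscriptRecord(r.transcript_id, "".join(alt_seqs[r.transcript_id]))
        for r in records
    ]
    return alt_records, truth, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-condition counts


@dataclass(frozen=True)
class DegTruth:
    transcript_id: str
    status: str  # UP / DOWN / UNCHANGED (treated relative to control)


def simulate_counts(
    records: list[TranscriptRecord],
    n_up: int,
    n_down: int,
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    libsize_pair: tuple[float, float] = (1e6, 1e6),
    fold: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[float, float], list[DegTruth]]:
    """Two-condition negative-binomial count table with planted DEGs.

    Counts are gamma-Poisson (negative binomial) with per-gene mean
    ``base_mean`` scaled by each condition's library-size factor; the first
    ``n_up`` genes get their treated mean multiplied by ``fold`` and the
    next ``n_down`` divided by it.  Returns the count table, the library
    sizes (N per condition, at least the summed counts), and truth labels.
    """
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if n_up + n_down > len(records):
        raise ValueError("n_up + n_down exceeds number of transcripts")
    rng = substream(seed, "counts")
    order = rng.permutation(len(records))
    status = ["UNCHANGED"] * len(records)
    for i in order[:n_up]:
        status[i] = "UP"
    for i in order[n_up : n_up + n_down]:
        status[i] = "DOWN"
    scale_c = libsize_pair[0] / 1e6
    scale_t = libsize_pair[1] / 1e6

    def nb(mean: float) -> int:
        r = 1.0 / dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        return int(rng.poisson(lam))

    rows = []
    truth = []
    for rec, st in zip(records, status):
        mean_t = base_mean * {"UP": fold, "DOWN": 1 / fold, "UNCHANGED": 1.0}[st]
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "length": len(rec.sequence),
                "count_control": nb(base_mean * scale_c),
                "count_treated": nb(mean_t * scale_t),
            }
        )
        truth.append(DegTruth(rec.transcript_id, st))
    table = pd.DataFrame(rows)
    n_control = max(libsize_pair[0], float(table.count_control.sum()))
    n_treated = max(libsize_pair[1], float(table.count_treated.sum()))
    return table, (n_control, n_treated), truth


# ---------------------------------------------------------------------------
# melt curves


@dataclass(frozen=True)
class MeltCurveSpec:
    """Mixture-of-duplexes melt-curve recipe.

    Fluorescence follows a two-state melting model: each duplex species k
    (fraction ``weights[k]``) melts along a logistic transition centred on
    ``tm_values[k]`` with width ``transition_width``, between sloped linear
    pre- and post-melt baselines, plus Gaussian noise of ``noise_sd`` times
    the amplitude.
    """

    tm_values: tuple[float, ...]
    weights: tuple[float, ...]
    transition_width: float = 0.3
    noise_sd: float = 0.0
    temp_grid: tuple[float, float, float] = (70.0, 90.0, 0.1)  # start, stop, step
    ct: float = 22.0
    efficiency: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.tm_values):
            raise ValueError("weights and tm_values must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 (tolerance 1e-9)")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        start, stop, _ = self.temp_grid
        if min(self.tm_values) - start < 5 or stop - max(self.tm_values) < 5:
            raise ValueError("temp_grid must span all Tm values with >= 5 degC margin")

    @property
    def temperatures(self) -> np.ndarray:
        start, stop, step = self.temp_grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)


def simulate_melt_curve(
    spec: MeltCurveSpec,
    sample_id: str = "sample",
    upper_slope: float = -0.2,
    lower_slope: float = -0.02,
    amplitude: float = 90.0,
) -> MeltCurve:
    """Render one melt curve from a spec (noiseless when noise_sd = 0)."""
    t = spec.temperatures
    melted = np.zeros_like(t)
    for tm, w in zip(spec.tm_values, spec.weights):
        melted += w / (1.0 + np.exp(-(t - tm) / spec.transition_width))
    upper = 10.0 + amplitude + upper_slope * (t - t[0])
    lower = 10.0 + lower_slope * (t - t[0])
    f = lower + (upper - lower) * (1.0 - melted)
    if spec.noise_sd > 0:
        rng = substream(spec.seed, f"melt:{sample_id}")
        f = f + rng.normal(0.0, spec.noise_sd * amplitude, size=t.shape)
    return MeltCurve(sample_id, t, f, spec.ct, spec.efficiency)


def genotype_melt_spec(
    genotype: tuple[str, str],
    base_tm: float = 80.0,
    heteroduplex_depression: float = 1.5,
    transition_width: float = 0.3,
    noise_sd: float = 0.0,
    temp_grid: tuple[float, float, float] = (70.0, 90.0, 0.1),
    seed: int = 0,
) -> MeltCurveSpec:
    """Auto-build a melt spec from a diploid genotype at one SNP site.

    Homozygotes give a single homoduplex species whose Tm follows the
    A/A < T/T < C/C < G/G stability ordering; heterozygotes give four
    equal-weight species — the two homoduplexes plus two heteroduplexes
    depressed ``heteroduplex_depression`` degC below the lower homoduplex.
    """
    a, b = (x.upper() for x in genotype)
    if a not in GENOTYPE_TM_OFFSET or b not in GENOTYPE_TM_OFFSET:
        raise ValueError(f"invalid genotype {genotype!r}")
    tm_a = base_tm + GENOTYPE_TM_OFFSET[a]
    tm_b = base_tm + GENOTYPE_TM_OFFSET[b]
    if a == b:
        tms, weights = (tm_a,), (1.0,)
    else:
        het = min(tm_a, tm_b) - heteroduplex_depression
        tms = (het, het - 0.3, tm_a, tm_b)
        weights = (0.25, 0.25, 0.25, 0.25)
    return MeltCurveSpec(
        tm_values=tms,
        weights=weights,
        transition_width=transition_width,
        noise_sd=noise_sd,
        temp_grid=temp_grid,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# allele matrices


@dataclass(frozen=True)
class LocusTruth:
    locus: str
    frequencies: tuple[float, ...]


def simulate_allele_matrix(
    n_loci: int,
    n_genotypes: int,
    alleles_per_locus_dist=(2, 3, 4),
    null_rate: float = 0.0,
    equifrequent: bool = False,
    seed: int = 0,
):
    """Binary band-score matrix with known per-locus allele frequencies.

    Each genotype shows exactly one band per locus (homozygous inbred
    lines), drawn from the locus's true frequencies, except that with
    probability ``null_rate`` it shows no band at all (null allele).
    ``alleles_per_locus_dist`` is an int, a sequence sampled uniformly, or
    a {count: probability} map; counts must lie in 1..10.  Returns an
    :class:`~genicmarkers.diversity.AlleleMatrix` plus the truth
    frequencies used for band assignment.
    """
    from .diversity import AlleleMatrix

    if n_genotypes <= 0:
        raise ValueError("n_genotypes must be positive")
    rng = substream(seed, "alleles")
    if isinstance(alleles_per_locus_dist, int):
        counts = [alleles_per_locus_dist] * n_loci
    elif isinstance(alleles_per_locus_dist, dict):
        ks = sorted(alleles_per_locus_dist)
        p = np.array([alleles_per_locus_dist[k] for k in ks], dtype=float)
        counts = [int(ks[i]) for i in rng.choice(len(ks), size=n_loci, p=p / p.sum())]
    else:
        opts = list(alleles_per_locus_dist)
        counts = [int(opts[i]) for i in rng.integers(len(opts), size=n_loci)]
    if any(not 1 <= k <= 10 for k in counts):
        raise ValueError("alleles per locus must lie in 1..10")
    genotypes = tuple(f"G{i + 1:03d}" for i in range(n_genotypes))
    bands: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    truth: list[LocusTruth] = []
    for li, k in enumerate(counts):
        locus = f"L{li + 1:03d}"
        if equifrequent or k == 1:
            freqs = np.full(k, 1.0 / k)
        else:
            freqs = rng.dirichlet(np.full(k, 5.0))
        block = np.zeros((n_genotypes, k), dtype=int)
        for g in range(n_genotypes):
            if null_rate > 0 and rng.random() < null_rate:
                continue
            block[g, rng.choice(k, p=freqs)] = 1
        for a in range(k):
            bands.append((locus, f"A{a + 1}"))
            columns.append(block[:, a])
        truth.append(LocusTruth(locus, tuple(freqs)))
    scores = np.column_stack(columns) if columns else np.zeros((n_genotypes, 0), int)
    return AlleleMatrix(genotypes, tuple(bands), scores), truth
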