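"""Perfect microsatellite (SSR) mining, motif canonicalization and summaries.

Detects maximal perfect tandem repeats of 2–6 bp units under unit-specific
minimum repeat counts (di >= 6, tri >= 5, tetra >= 4, penta >= 4, hexa >= 3
by default; mononucleotide runs are excluded).  Motifs are collapsed into
canonical complement/rotation classes such as ``AAG/CTT`` so that a repeat,
its cyclic rotations and its reverse complement all report the same class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import reverse_complement

from .orf import OrfAnnotation, RegionClass, classify_region

DEFAULT_MIN_REPEATS = {2: 6, 3: 5, 4: 4, 5: 4, 6: 3}

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SSRCriteria:
    """Search criteria: minimum contiguous repeat units per unit length."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    include_mono: bool = False

    def __post_init__(self) -> None:
        expected = {1, 2, 3, 4, 5, 6} if self.include_mono else {2, 3, 4, 5, 6}
        if set(self.min_repeats) != expected:
            raise ValueError(
                f"min_repeats keys must be exactly {sorted(expected)}, "
                f"got {sorted(self.min_repeats)}"
            )


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat on one transcript.

    Coordinates are 0-based half-open; ``sequence[start:end]`` equals
    ``motif * repeat_count`` and the run is not extendable by one unit in
    either direction.
    """

    transcript_id: str
    start: int
    end: int
    motif: str
    canonical: str
    repeat_count: int
    region: RegionClass = RegionClass.UNCLASSIFIED

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_region(self, region: RegionClass) -> "SSRLocus":
        return replace(self, region=region)


def is_irreducible(motif: str) -> bool:
    """True if the motif is not a whole-number power of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Canonical complement/rotation class label, e.g. ``AAG/CTT``.

    The representative M is the lexicographically smallest string among all
    cyclic rotations of the motif and of its reverse complement; the label is
    ``M/revcomp(M)``.  Rotating or reverse-complementing the motif never
    changes the label.
    """
    motif = motif.upper()
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not is_irreducible(motif):
        raise ValueError(f"reducible motif {motif!r}")
    rc = reverse_complement(motif)
    k = len(motif)
    rotations = {motif[i:] + motif[:i] for i in range(k)}
    rotations |= {rc[i:] + rc[:i] for i in range(k)}
    m = min(rotations)
    return f"{m}/{reverse_complement(m)}"


def _maximal_run(seq: str, start: int, k: int) -> int:
    """Number of whole repeat units of ``seq[start:start+k]`` from ``start``."""
    n = len(seq)
    j = start + k
    while j < n and seq[j] == seq[j - k]:
        j += 1
    return (j - start) // k


def _candidate_runs(seq: str, criteria: SSRCriteria):
    """Yield every maximal perfect run meeting its unit-length minimum.

    A candidate is maximal: not preceded nor followed by one further whole
    unit.  Reducible motifs are skipped (the shorter unit's scan reports
    them) and any non-ACGT base terminates a run.
    """
    n = len(seq)
    unit_lengths = sorted(criteria.min_repeats)
    for k in unit_lengths:
        min_units = criteria.min_repeats[k]
        i = 0
        while i + k * min_units <= n:
            motif = seq[i : i + k]
            if set(motif) - set("ACGT") or not is_irreducible(motif):
                i += 1
                continue
            count = _maximal_run(seq, i, k)
            if count >= min_units:
                # left-maximality: a full unit must not precede the run
                if i < k or seq[i - k : i] != motif:
                    yield (i, i + count * k, motif, count)
                    i += (count - 1) * k + 1
                    continue
            i += 1


def find_ssrs(
    sequence: str,
    criteria: SSRCriteria | None = None,
    transcript_id: str = "",
) -> list[SSRLocus]:
    """Mine all perfect SSRs in one sequence (regions left UNCLASSIFIED).

    Overlapping candidate runs of different unit lengths are resolved so
    that a position belongs to at most one locus: the longest run wins,
    ties go to the smaller unit length, then to the leftmost start.
    Returns loci sorted left to right.
    """
    seq = sequence.upper()
    if set(seq) - _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    if criteria is None:
        criteria = SSRCriteria()
    candidates = list(_candidate_runs(seq, criteria))
    # longest run first, then smaller unit, then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    taken: list[tuple[int, int]] = []
    accepted = []
    for start, end, motif, count in candidates:
        if any(start < e and end > s for s, e in taken):
            continue
        taken.append((start, end))
        accepted.append(
            SSRLocus(transcript_id, start, end, motif, canonical_class(motif), count)
        )
    accepted.sort(key=lambda loc: loc.start)
    return accepted


def classify_loci(
    loci: list[SSRLocus], orfs: dict[str, OrfAnnotation | None]
) -> list[SSRLocus]:
    """Assign each locus its ORF-relative region (UNCLASSIFIED if no ORF)."""
    return [
        loc.with_region(
            classify_region(orfs.get(loc.transcript_id), (loc.start, loc.end))
        )
        for loc in loci
    ]


@dataclass(frozen=True)
class SSRSummary:
    """Dataset-level SSR composition and density."""

    total_loci: int
    loci_by_unit_length: dict[int, int]
    loci_by_canonical_class: dict[str, int]
    loci_by_region: dict[str, int]
    transcripts_with_ssr: int
    density_kb_per_ssr: float | None  # kb of sequence per SSR; None if no loci

    def share_pct(self, which: str, key) -> float:
        """Percentage share of ``key`` within one breakdown, 1 decimal."""
        table = getattr(self, f"loci_by_{which}")
        if self.total_loci == 0:
            raise ValueError("no loci: shares undefined")
        return round(100.0 * table.get(key, 0) / self.total_loci, 1)


def summarize_ssrs(loci: list[SSRLocus], total_bp: int) -> SSRSummary:
    """Aggregate mined loci into counts, class shares and kb-per-SSR density."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    by_unit: dict[int, int] = {}
    by_class: dict[str, int] = {}
    by_region: dict[str, int] = {}
    transcripts = set()
    for loc in loci:
        by_unit[loc.unit_length] = by_unit.get(loc.unit_length, 0) + 1
        by_class[loc.canonical] = by_class.get(loc.canonical, 0) + 1
        by_region[loc.region.value] = by_region.get(loc.region.value, 0) + 1
        transcripts.add(loc.transcript_id)
    density = round(total_bp / 1000.0 / len(loci), 1) if loci else None
    return SSRSummary(
        total_loci=len(loci),
        loci_by_unit_length=by_unit,
        loci_by_canonical_class=by_class,
        loci_by_region=by_region,
        transcripts_with_ssr=len(transcripts),
        density_kb_per_ssr=density,
    )


@dataclass(frozen=True)
class FlankReport:
    """Primer-design feasibility of one locus within its transcript."""

    transcript_id: str
    left_flank: str
    right_flank: str
    left_len: int
    right_len: int
    designable: bool


def check_flanks(
    transcript_seq: str,
    locus: SSRLocus,
    min_flank: int = 50,
    product_range: tuple[int, int] = (100, 250),
) -> FlankReport:
    """Report whether primers could bracket a locus.

    Designable iff both flanks are at least ``min_flank`` bp and the locus
    plus available flanks can host an amplicon within ``product_range``.
    """
    n = len(transcript_seq)
    if not (0 <= locus.start <= locus.end <= n):
        raise ValueError("locus outside transcript")
    left_len = locus.start
    right_len = n - locus.end
    lo, hi = product_range
    designable = (
        left_len >= min_flank
        and right_len >= min_flank
        and locus.length + 2 * min_flank <= hi
        and left_len + locus.length + right_len >= lo
    )
    left = transcript_seq[max(0, locus.start - min_flank * 4) : locus.start]
    right = transcript_seq[locus.end : locus.end + min_flank * 4]
    return FlankReport(locus.transcript_id, left, right, left_len, right_len, designable)
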