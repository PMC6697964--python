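"""Longest-ORF annotation and ORF-relative region classification.

A transcript contig is partitioned into 5'UTR / CDS / 3'UTR by its single
accepted open reading frame: the longest ATG-initiated, stop-terminated
frame found over the three forward frames and the three frames of the
reverse complement.  Features (SSR loci, SNP positions) are then classified
relative to that ORF; transcripts without an accepted ORF leave their
features unclassified.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio.Seq import reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class Orientation(enum.Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


class RegionClass(enum.Enum):
    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class OrfAnnotation:
    """An accepted ORF located on the original (given) sequence.

    ``cds_start``/``cds_end`` are 0-based half-open coordinates on the given
    sequence regardless of orientation; the ORF reads ATG...stop in its own
    orientation.  ``length_nt`` includes the stop codon.
    """

    transcript_id: str
    cds_start: int
    cds_end: int
    orientation: Orientation
    length_nt: int

    def __post_init__(self) -> None:
        if self.length_nt != self.cds_end - self.cds_start:
            raise ValueError("length_nt must equal cds_end - cds_start")
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


def _scan_strand(seq: str, min_len_nt: int, require_stop: bool):
    """Yield (start, end, has_stop) candidates on one strand, 0-based half-open."""
    n = len(seq)
    for frame in range(3):
        pos = frame
        pending_starts: list[int] = []
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon == "ATG" and not pending_starts:
                pending_starts.append(pos)
            elif codon in STOP_CODONS and pending_starts:
                start = pending_starts[0]
                end = pos + 3
                if end - start >= min_len_nt:
                    yield (start, end, True)
                pending_starts.clear()
            pos += 3
        if pending_starts and not require_stop:
            start = pending_starts[0]
            end = start + ((n - start) // 3) * 3
            if end - start >= min_len_nt:
                yield (start, end, False)


def find_longest_orf(
    sequence: str,
    min_len_nt: int = 90,
    transcript_id: str = "",
    require_stop: bool = True,
) -> OrfAnnotation | None:
    """Return the longest ATG-initiated ORF over six frames, or None.

    Candidates run ATG through the next in-frame stop (stop included).  Ties
    on length are broken FORWARD first, then by smallest start coordinate on
    the given sequence.  ``require_stop=False`` additionally accepts
    ATG-initiated frames that run off the 3' end without a stop, which suits
    fragmentary assemblies.

    Parameters
    ----------
    sequence : nucleotide string over A/C/G/T/N (case-insensitive).
    min_len_nt : minimum accepted ORF length in nucleotides (default 90,
        i.e. 30 codons) — a small floor against spurious micro-ORFs.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int, Orientation]] = []
    for start, end, _ in _scan_strand(seq, min_len_nt, require_stop):
        candidates.append((end - start, start, end, Orientation.FORWARD))
    rc = reverse_complement(seq)
    for start, end, _ in _scan_strand(rc, min_len_nt, require_stop):
        # map back onto the given sequence
        candidates.append((end - start, n - end, n - start, Orientation.REVERSE))
    if not candidates:
        return None
    # longest first; FORWARD beats REVERSE on ties; then smallest start
    best = min(
        candidates,
        key=lambda c: (-c[0], 0 if c[3] is Orientation.FORWARD else 1, c[1]),
    )
    length, start, end, orientation = best
    return OrfAnnotation(transcript_id, start, end, orientation, length)


def classify_region(
    orf: OrfAnnotation | None, feature_interval: tuple[int, int]
) -> RegionClass:
    """Classify a feature interval (0-based half-open) relative to an ORF.

    Without an ORF every feature is UNCLASSIFIED.  Otherwise the interval is
    oriented by the ORF: entirely on the 5' side of the CDS -> FIVE_UTR,
    entirely on the 3' side -> THREE_UTR, and any overlap with the CDS wins
    (a feature spanning a CDS boundary counts as CDS).
    """
    start, end = feature_interval
    if start > end:
        raise ValueError(f"inverted interval {feature_interval!r}")
    if orf is None:
        return RegionClass.UNCLASSIFIED
    # overlap test on half-open intervals; point features may be zero-width
    fend = max(end, start + 1)
    if start < orf.cds_end and fend > orf.cds_start:
        return RegionClass.CDS
    upstream = fend <= orf.cds_start  # before the CDS in given coordinates
    if orf.orientation is Orientation.FORWARD:
        return RegionClass.FIVE_UTR if upstream else RegionClass.THREE_UTR
    return RegionClass.THREE_UTR if upstream else RegionClass.FIVE_UTR
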