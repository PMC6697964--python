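"""Variant filtering and SNP characterization.

Consumes VCF-style single-nucleotide substitutions (the variant calling
itself is upstream), applies read-depth / mapping-quality filters, and
tallies the substitution spectrum: the 12 directional substitution types,
the transition/transversion (Ts/Tv) split and ratio, zygosity counts,
high-resolution-melting (HRM) SNP classes I-IV, and the ORF-relative
positional distribution (5'UTR / CDS / 3'UTR).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from .orf import OrfAnnotation, RegionClass, classify_region

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


class SubstitutionKind(enum.Enum):
    TRANSITION = "TRANSITION"
    TRANSVERSION = "TRANSVERSION"


class HrmClass(enum.Enum):
    """HRM SNP classes by unordered base pair.

    Class I: C/T and G/A transitions; class II: C/A and G/T transversions;
    class III: C/G; class IV: A/T (the smallest homoduplex Tm shifts).
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class Zygosity(enum.Enum):
    HOM = "HOM"
    HET = "HET"


@dataclass(frozen=True)
class VariantRecord:
    """One single-nucleotide substitution with its filter fields."""

    transcript_id: str
    pos: int  # 1-based, VCF convention
    ref_base: str
    alt_base: str
    depth: int | None = None
    map_quality: float | None = None
    zygosity: Zygosity = Zygosity.HOM

    def __post_init__(self) -> None:
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError(
                f"bases must be in ACGT: {self.ref_base}/{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class FilterThresholds:
    """Retention window: depth in [min_depth, max_depth], MQ >= min_mapq."""

    min_depth: int = 20
    max_depth: int = 200
    min_mapq: float = 10.0

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")


def filter_variants(
    records: list[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[VariantRecord], Counter]:
    """Apply depth and mapping-quality filters; all boundaries inclusive.

    Returns the retained records plus a tally of rejection reasons
    (``low-depth``, ``high-depth``, ``low-mapq``, ``missing-field``).
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    kept: list[VariantRecord] = []
    tally: Counter = Counter()
    for rec in records:
        if rec.depth is None or rec.map_quality is None:
            tally["missing-field"] += 1
        elif rec.depth < thresholds.min_depth:
            tally["low-depth"] += 1
        elif rec.depth > thresholds.max_depth:
            tally["high-depth"] += 1
        elif rec.map_quality < thresholds.min_mapq:
            tally["low-mapq"] += 1
        else:
            kept.append(rec)
    return kept, tally


def substitution_type(ref_base: str, alt_base: str) -> tuple[SubstitutionKind, str]:
    """Classify a substitution as transition or transversion.

    Transitions keep the chemical class (A<->G, C<->T); everything else is
    a transversion.  Returns the kind plus a directional ``ref/alt`` label.
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"invalid bases {ref_base}/{alt_base}")
    if ref == alt:
        raise ValueError("identical bases are not a substitution")
    same_class = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    kind = SubstitutionKind.TRANSITION if same_class else SubstitutionKind.TRANSVERSION
    return kind, f"{ref}/{alt}"


_HRM_CLASSES = {
    frozenset("CT"): HrmClass.I,
    frozenset("AG"): HrmClass.I,
    frozenset("AC"): HrmClass.II,
    frozenset("GT"): HrmClass.II,
    frozenset("CG"): HrmClass.III,
    frozenset("AT"): HrmClass.IV,
}


def hrm_class(ref_base: str, alt_base: str) -> HrmClass:
    """Map a base pair to its HRM SNP class (order-independent)."""
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"invalid bases {ref_base}/{alt_base}")
    if ref == alt:
        raise ValueError("identical bases are not a substitution")
    return _HRM_CLASSES[frozenset((ref, alt))]


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Spectrum of a filtered SNP set."""

    directional_counts: dict[str, int]
    ts_count: int
    tv_count: int
    hom_count: int
    het_count: int
    hrm_class_counts: dict[str, int]
    region_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.ts_count + self.tv_count

    @property
    def ts_tv_ratio(self) -> float | None:
        """Ts/Tv ratio; None when no transversions were observed."""
        if self.tv_count == 0:
            return None
        return self.ts_count / self.tv_count

    def share_pct(self, count: int, decimals: int = 1) -> float:
        if self.total == 0:
            raise ValueError("empty spectrum: shares undefined")
        return round(100.0 * count / self.total, decimals)


def spectrum(
    records: list[VariantRecord],
    orf_annotations: dict[str, OrfAnnotation | None] | None = None,
) -> SubstitutionSpectrum:
    """Tally directional counts, Ts/Tv, zygosity, HRM class and region.

    ``orf_annotations`` maps transcript id to its accepted ORF (or None);
    transcripts absent from the map yield UNCLASSIFIED region counts.
    """
    directional: Counter = Counter()
    hrm: Counter = Counter()
    regions: Counter = Counter()
    ts = tv = hom = het = 0
    for rec in records:
        kind, label = substitution_type(rec.ref_base, rec.alt_base)
        directional[label] += 1
        hrm[hrm_class(rec.ref_base, rec.alt_base).value] += 1
        if kind is SubstitutionKind.TRANSITION:
            ts += 1
        else:
            tv += 1
        if rec.zygosity is Zygosity.HET:
            het += 1
        else:
            hom += 1
        if orf_annotations is not None:
            orf = orf_annotations.get(rec.transcript_id)
            region = classify_region(orf, (rec.pos - 1, rec.pos))
            regions[region.value] += 1
        else:
            regions[RegionClass.UNCLASSIFIED.value] += 1
    return SubstitutionSpectrum(
        directional_counts=dict(directional),
        ts_count=ts,
        tv_count=tv,
        hom_count=hom,
        het_count=het,
        hrm_class_counts=dict(hrm),
        region_counts=dict(regions),
    )
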