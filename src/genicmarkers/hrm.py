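"""High-resolution-melting (HRM) curve genotyping.

A melt curve records fluorescence against temperature as PCR amplicons
denature.  Quality control keeps runs with Ct <= 30 and amplification
efficiency > 1.4; curves are then normalized between linear pre- and
post-melt baselines to a 0-100% scale, and melting domains are read as
peaks of the negative derivative -dF/dT.  One domain means a homozygote,
two or more mean a heterozygote (heteroduplex species melt earlier), and
homozygote pairs are compared by their peak-Tm difference, annotated with
the HRM SNP class (I-IV) of the underlying substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .snp import HrmClass, hrm_class

#: Published homozygote Tm-difference ranges (degC) per HRM SNP class.
CLASS_TM_RANGES: dict[HrmClass, tuple[float, float]] = {
    HrmClass.I: (0.15, 0.51),
    HrmClass.II: (0.03, 0.41),
    HrmClass.III: (0.18, 0.35),
    HrmClass.IV: (0.02, 0.12),
}


@dataclass(frozen=True)
class MeltCurve:
    """Temperature-indexed fluorescence trace with amplification QC fields."""

    sample_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    ct: float | None = None
    efficiency: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperature and fluorescence must be equal-length 1-D")
        if t.size >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-6:
                raise ValueError("temperature grid must be ascending and uniform")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: str | None = None


def qc_filter(curve: MeltCurve, ct_max: float = 30.0, eff_min: float = 1.4) -> QcResult:
    """Amplification QC: pass iff Ct <= ct_max and efficiency > eff_min.

    The Ct bound is inclusive and the efficiency bound strict, matching the
    operators of the instrument protocol the defaults come from.
    """
    if curve.ct is None or curve.efficiency is None:
        return QcResult(False, "missing-field")
    if curve.ct > ct_max:
        return QcResult(False, f"ct {curve.ct} > {ct_max}")
    if curve.efficiency <= eff_min:
        return QcResult(False, f"efficiency {curve.efficiency} <= {eff_min}")
    return QcResult(True)


def normalize_curve(
    curve: MeltCurve,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
) -> MeltCurve:
    """Normalize fluorescence to a 0-100% scale between linear baselines.

    Straight lines are fitted to the pre-melt and post-melt windows
    (defaults: first and last 2 degC of the grid); the output is
    100 * (F - lower) / (upper - lower) clipped to [0, 100], so the
    pre-window sits near 100% and the post-window near 0%.
    """
    t, f = curve.temperatures, curve.fluorescence
    if pre_window is None:
        pre_window = (float(t[0]), float(t[0]) + 2.0)
    if post_window is None:
        post_window = (float(t[-1]) - 2.0, float(t[-1]))
    if pre_window[1] > post_window[0]:
        raise ValueError("pre_window must end before post_window starts")
    pre = (t >= pre_window[0]) & (t <= pre_window[1])
    post = (t >= post_window[0]) & (t <= post_window[1])
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError("baseline windows must each cover >= 2 grid points")
    upper = np.polyval(np.polyfit(t[pre], f[pre], 1), t)
    lower = np.polyval(np.polyfit(t[post], f[post], 1), t)
    span = upper - lower
    if np.any(span <= 0) or np.median(span) < 1e-9 * max(1.0, np.abs(f).max()):
        raise ValueError("degenerate baselines: upper does not exceed lower")
    norm = np.clip(100.0 * (f - lower) / span, 0.0, 100.0)
    return MeltCurve(curve.sample_id, t, norm, curve.ct, curve.efficiency)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge padding (symmetric, phase-free)."""
    if window <= 1:
        return y
    if window % 2 == 0:
        window += 1
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")


@dataclass(frozen=True)
class MeltPeak:
    tm: float  # degC, quadratically interpolated
    height: float  # -dF/dT at the grid maximum


def melt_domains(
    curve: MeltCurve,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.1,
    min_separation: float = 0.5,
) -> list[MeltPeak]:
    """Melting domains as peaks of the smoothed negative derivative.

    Local maxima of -dF/dT count as domains when their prominence exceeds
    ``min_prominence_frac`` of the global maximum and they sit at least
    ``min_separation`` degC apart.  Peak Tm is refined by fitting a
    parabola through the three grid points around each maximum.
    """
    t, f = curve.temperatures, curve.fluorescence
    if t.size < max(smooth_window, 5):
        raise ValueError("curve shorter than smoothing window")
    deriv = -np.gradient(_smooth(f, smooth_window), t)
    top = deriv.max()
    if top <= 0:
        return []
    distance = max(1, int(round(min_separation / curve.step)))
    idx, _ = find_peaks(
        deriv, prominence=min_prominence_frac * top, distance=distance
    )
    peaks = []
    for i in idx:
        tm = float(t[i])
        if 0 < i < t.size - 1:
            y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                tm += 0.5 * curve.step * (y0 - y2) / denom
        peaks.append(MeltPeak(tm=tm, height=float(deriv[i])))
    peaks.sort(key=lambda p: p.tm)
    return peaks


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    n_melt_domains: int
    zygosity: str  # HOMOZYGOUS / HETEROZYGOUS / NO_CALL
    tm_values: tuple[float, ...]
    qc_pass: bool
    qc_reason: str | None = None


def call_genotype(
    curve: MeltCurve,
    ct_max: float = 30.0,
    eff_min: float = 1.4,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.1,
    min_separation: float = 0.5,
) -> GenotypeCall:
    """QC, normalize and domain-count one raw curve into a zygosity call.

    A single melting domain calls HOMOZYGOUS, two or more HETEROZYGOUS;
    QC failure or a domain-free curve yields NO_CALL.
    """
    qc = qc_filter(curve, ct_max, eff_min)
    if not qc.passed:
        return GenotypeCall(curve.sample_id, 0, "NO_CALL", (), False, qc.reason)
    norm = normalize_curve(curve, pre_window, post_window)
    peaks = melt_domains(norm, smooth_window, min_prominence_frac, min_separation)
    tms = tuple(p.tm for p in peaks)
    if len(peaks) == 0:
        zyg = "NO_CALL"
    elif len(peaks) == 1:
        zyg = "HOMOZYGOUS"
    else:
        zyg = "HETEROZYGOUS"
    return GenotypeCall(curve.sample_id, len(peaks), zyg, tms, True)


@dataclass(frozen=True)
class PairComparison:
    sample_a: str
    sample_b: str
    delta_tm: float
    snp_class: HrmClass | None
    class_range_consistent: bool | None = field(default=None)


def compare_pair(
    call_a: GenotypeCall,
    call_b: GenotypeCall,
    snp_bases: tuple[str, str] | None = None,
) -> PairComparison:
    """Tm difference between two homozygous calls, with class annotation.

    ``snp_bases`` (ref, alt) adds the HRM class and whether the measured
    difference falls inside that class's published homozygote range — an
    annotation only, never a filter.
    """
    for call in (call_a, call_b):
        if call.zygosity != "HOMOZYGOUS" or len(call.tm_values) != 1:
            raise ValueError(
                f"{call.sample_id}: pair comparison needs single-Tm homozygotes"
            )
    delta = abs(call_a.tm_values[0] - call_b.tm_values[0])
    cls = consistent = None
    if snp_bases is not None:
        cls = hrm_class(*snp_bases)
        lo, hi = CLASS_TM_RANGES[cls]
        consistent = lo <= delta <= hi
    return PairComparison(call_a.sample_id, call_b.sample_id, delta, cls, consistent)
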