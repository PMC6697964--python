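"""FPKM expression and fold-change classification of two-condition counts.

Expression per transcript is FPKM = 1e9 * C / (N * L) with C the mapped
reads on the transcript, N the condition's total mappable reads and L the
transcript length in bp.  The fold change is FC = log2(treated / control)
on the FPKM values, and genes are classed up-regulated when FC > 0 and
down-regulated when FC < 0 — a pure sign rule, with an optional magnitude
threshold available but defaulting to 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd


class DegStatus(enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"
    UNDEFINED = "UNDEFINED"


def fpkm(C: float, N: float, L: float) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if N <= 0:
        raise ValueError("library size N must be positive")
    if L <= 0:
        raise ValueError("transcript length L must be positive")
    if C < 0:
        raise ValueError("count C must be nonnegative")
    return 1e9 * C / (N * L)


def fold_change(fpkm_treated: float, fpkm_control: float) -> float | None:
    """log2(treated / control); None (undefined) when only control is 0.

    Both zero means no evidence of change and returns 0.0; a positive
    treated value over a zero control has no finite log-ratio and is
    flagged undefined rather than patched with a pseudocount.
    """
    if fpkm_treated < 0 or fpkm_control < 0:
        raise ValueError("FPKM values must be nonnegative")
    if fpkm_control == 0:
        if fpkm_treated == 0:
            return 0.0
        return None
    if fpkm_treated == 0:
        return -math.inf
    return math.log2(fpkm_treated / fpkm_control)


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    fpkm_control: float
    fpkm_treated: float
    fc: float | None  # log2 units; None when undefined
    status: DegStatus


@dataclass(frozen=True)
class DegSummary:
    n_up: int
    n_down: int
    n_unchanged: int
    n_undefined: int

    @property
    def total(self) -> int:
        return self.n_up + self.n_down + self.n_unchanged + self.n_undefined


def classify_degs(
    table: pd.DataFrame,
    libsize_control: float,
    libsize_treated: float,
    min_abs_fc: float = 0.0,
) -> tuple[list[ExpressionRecord], DegSummary]:
    """Per-transcript FPKM, fold change and up/down status.

    ``table`` needs columns ``transcript_id``, ``length``, ``count_control``
    and ``count_treated``.  Records come back in the table's row order.
    ``min_abs_fc`` > 0 additionally requires |FC| to exceed it before a
    gene is called up or down.
    """
    required = {"transcript_id", "length", "count_control", "count_treated"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records: list[ExpressionRecord] = []
    n_up = n_down = n_unchanged = n_undefined = 0
    for row in table.itertuples(index=False):
        f_c = fpkm(row.count_control, libsize_control, row.length)
        f_t = fpkm(row.count_treated, libsize_treated, row.length)
        fc = fold_change(f_t, f_c)
        if fc is None:
            status = DegStatus.UNDEFINED
            n_undefined += 1
        elif fc > min_abs_fc:
            status = DegStatus.UP
            n_up += 1
        elif fc < -min_abs_fc:
            status = DegStatus.DOWN
            n_down += 1
        else:
            status = DegStatus.UNCHANGED
            n_unchanged += 1
        records.append(
            ExpressionRecord(str(row.transcript_id), f_c, f_t, fc, status)
        )
    return records, DegSummary(n_up, n_down, n_unchanged, n_undefined)


def records_to_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "fpkm_control": [r.fpkm_control for r in records],
            "fpkm_treated": [r.fpkm_treated for r in records],
            "log2_fc": [r.fc if r.fc is not None else float("nan") for r in records],
            "status": [r.status.value for r in records],
        }
    )
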