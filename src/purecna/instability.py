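"""Whole Genome Instability Index (WGII).

WGII is the proportion of the genome, by length, carrying a non-neutral
(loss or gain) copy number call. The default resolution is the chromosome
arm: the numerator sums the lengths of aberrant arms and the denominator is
the total length of the autosomal arm frame. A segment-level variant
computes the same ratio over classified segments against the total
segment-covered length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from purecna.adjust import AdjustedSegment, ArmCallSet
from purecna.genome import ArmTable
from purecna.stats import BlandAltmanResult, PearsonResult, bland_altman, pearson_ci

__all__ = ["WgiiResult", "wgii", "wgii_segment_level", "wgii_compare"]


@dataclass(frozen=True)
class WgiiResult:
    sample_id: str
    method: str
    wgii: float
    aberrant_length: int
    total_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.wgii <= 1.0:
            raise ValueError(f"wgii {self.wgii} outside [0, 1]")


def wgii(calls: ArmCallSet, frame: ArmTable) -> WgiiResult:
    """Arm-level WGII: summed length of loss/gain arms over the frame length."""
    if len(frame) == 0 or frame.total_length <= 0:
        raise ValueError("empty arm frame")
    aberrant = sum(
        arm.length for arm in frame if calls.calls.get(arm.name, "neutral") != "neutral"
    )
    total = frame.total_length
    return WgiiResult(
        sample_id=calls.sample_id, method=calls.method,
        wgii=aberrant / total, aberrant_length=aberrant, total_length=total,
    )


def wgii_segment_level(
    sample_id: str, segments: Sequence[AdjustedSegment], method: str = ""
) -> WgiiResult:
    """Segment-level WGII over the segment-covered genome."""
    total = sum(a.segment.length for a in segments)
    if total <= 0:
        raise ValueError("no segment coverage")
    aberrant = sum(a.segment.length for a in segments if a.call != "neutral")
    return WgiiResult(
        sample_id=sample_id, method=method,
        wgii=aberrant / total, aberrant_length=aberrant, total_length=total,
    )


def wgii_compare(
    results_a: Sequence[WgiiResult], results_b: Sequence[WgiiResult]
) -> tuple[PearsonResult, BlandAltmanResult]:
    """Correlation and Bland–Altman agreement of matched WGII vectors (a minus b)."""
    map_a = {r.sample_id: r.wgii for r in results_a}
    map_b = {r.sample_id: r.wgii for r in results_b}
    only_a = sorted(set(map_a) - set(map_b))
    only_b = sorted(set(map_b) - set(map_a))
    if only_a or only_b:
        raise ValueError(f"unmatched sample IDs: only in a={only_a}, only in b={only_b}")
    keys = sorted(map_a)
    if len(keys) < 3:
        raise ValueError("need at least 3 matched samples")
    a = [map_a[k] for k in keys]
    b = [map_b[k] for k in keys]
    ba = bland_altman(a, b)
    import numpy as np

    r = float(np.corrcoef(a, b)[0, 1]) if np.ptp(a) and np.ptp(b) else float("nan")
    if abs(r) == 1.0 or len(keys) == 3:
        pearson = PearsonResult(r=r, ci_low=r, ci_high=r, n=len(keys), p_value=0.0)
    else:
        pearson = pearson_ci(a, b)
    return pearson, ba
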