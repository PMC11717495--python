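"""Purity adjustment of copy number by tumour/normal mixture inversion.

A bulk sample is modelled as a two-component mixture of tumour cells at
purity p and diploid normal cells at 1-p, so the observed absolute copy
number of a segment is

    cn_observed = p * cn_tumour + 2 * (1 - p).

Adjustment inverts this for cn_tumour given a purity estimate. Calls follow
the integer rule: rounded copy number >= 3 is a gain, 2 neutral, <= 1 a loss
(round half away from zero, i.e. cut-points at 1.5 and 2.5 on the real
line). Arm-level calls are the length-weighted plurality of segment calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from purecna.genome import ArmTable, Segment, SegmentProfile, intersect_segments_with_arms

__all__ = [
    "CALLS", "AdjustedSegment", "ArmCallSet",
    "observed_cn_from_log2", "mixture_adjust", "classify_cn",
    "arm_call", "adjust_profile",
    "read_arm_call_matrix", "write_arm_call_matrix", "write_adjusted_segments",
]

#: call labels in genomic order (loss < neutral < gain)
CALLS = ("loss", "neutral", "gain")

#: default floor (fraction) applied to purity before dividing; guards
#: against explosion of the adjusted copy number at near-zero purity
DEFAULT_PURITY_FLOOR = 0.05


def observed_cn_from_log2(log2_ratio: float) -> float:
    """Absolute observed copy number from a log2 ratio relative to diploid."""
    return 2.0 * 2.0**log2_ratio


def mixture_adjust(
    cn_observed: float, purity: float, floor: float = DEFAULT_PURITY_FLOOR
) -> float:
    """Invert the tumour/normal mixture: tumour copy number at given purity.

    Parameters
    ----------
    cn_observed
        Observed absolute copy number (>= 0).
    purity
        Tumour purity as a fraction in (0, 1]. Values below ``floor`` are
        clamped with a warning; non-positive purity is an error.
    floor
        Clamp floor for the purity (default 0.05).

    Returns
    -------
    max(0, (cn_observed - 2*(1 - purity)) / purity); copies cannot be
    negative, so the inversion is clipped at zero.
    """
    if purity <= 0.0:
        raise ValueError(f"purity must be positive, got {purity}")
    if cn_observed < 0.0:
        raise ValueError(f"cn_observed must be >= 0, got {cn_observed}")
    if purity < floor:
        warnings.warn(
            f"purity {purity:.4f} below floor {floor}; clamped", stacklevel=2
        )
        purity = floor
    return max(0.0, (cn_observed - 2.0 * (1.0 - purity)) / purity)


def classify_cn(cn_tumour: float) -> str:
    """Classify a tumour copy number as loss / neutral / gain.

    The copy number is rounded half-away-from-zero to the nearest integer;
    rounded values >= 3 are gains, <= 1 losses, 2 neutral.
    """
    if cn_tumour < 0.0:
        raise ValueError(f"copy number must be >= 0, got {cn_tumour}")
    rounded = math.floor(cn_tumour + 0.5)  # half away from zero for cn >= 0
    if rounded >= 3:
        return "gain"
    if rounded <= 1:
        return "loss"
    return "neutral"


@dataclass(frozen=True)
class AdjustedSegment:
    """A segment after purity adjustment, with its classification."""

    segment: Segment
    purity_used: float
    cn_observed: float
    cn_tumour: float
    call: str


@dataclass(frozen=True)
class ArmCallSet:
    """One {loss, neutral, gain} call per chromosome arm for one sample."""

    sample_id: str
    calls: Mapping[str, str]
    method: str = ""

    def __post_init__(self) -> None:
        bad = {c for c in self.calls.values() if c not in CALLS}
        if bad:
            raise ValueError(f"invalid calls: {sorted(bad)}")

    def as_vector(self, arm_names: Sequence[str]) -> list[str]:
        return [self.calls[name] for name in arm_names]


def arm_call(overlaps: Sequence[tuple[AdjustedSegment, int]]) -> str:
    """Length-weighted plurality call over an arm's overlapping segments.

    An uncovered arm is neutral. Ties are broken toward neutral (conservative:
    without a length majority for an aberration the arm is not called), and
    between loss and gain toward neutral as well.
    """
    if not overlaps:
        return "neutral"
    weight = {c: 0 for c in CALLS}
    for adj, length in overlaps:
        weight[adj.call] += length
    best = max(weight.values())
    winners = [c for c in CALLS if weight[c] == best]
    return winners[0] if len(winners) == 1 else "neutral"


def adjust_profile(
    profile: SegmentProfile,
    purity_percent: float,
    arms: ArmTable,
    floor: float = DEFAULT_PURITY_FLOOR,
    method: str = "",
) -> tuple[list[AdjustedSegment], ArmCallSet]:
    """Adjust every segment of a sample and aggregate to arm-level calls.

    ``purity_percent`` is on the 0–100 scale used for reporting; it is
    converted to a fraction internally. Returns the adjusted segments and an
    :class:`ArmCallSet` with exactly one call per arm of ``arms``.
    """
    if not 0.0 < purity_percent <= 100.0:
        raise ValueError(f"purity_percent must be in (0, 100], got {purity_percent}")
    p = purity_percent / 100.0
    adjusted: dict[Segment, AdjustedSegment] = {}
    for seg in profile.segments:
        cn_obs = observed_cn_from_log2(seg.log2_ratio)
        cn_tum = mixture_adjust(cn_obs, p, floor=floor)
        adjusted[seg] = AdjustedSegment(
            segment=seg, purity_used=max(p, floor), cn_observed=cn_obs,
            cn_tumour=cn_tum, call=classify_cn(cn_tum),
        )
    overlaps = intersect_segments_with_arms(profile, arms)
    calls = {
        arm_name: arm_call([(adjusted[seg], length) for seg, length in segs])
        for arm_name, segs in overlaps.items()
    }
    return list(adjusted.values()), ArmCallSet(sample_id=profile.sample_id, calls=calls, method=method)


# ---------------------------------------------------------------------------
# I/O: arm-call matrix TSV (samples x arms) and adjusted-segment TSV

def write_arm_call_matrix(
    callsets: Iterable[ArmCallSet], arms: ArmTable, path: str | Path
) -> None:
    names = arms.names
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(names) + "\n")
        for cs in callsets:
            fh.write(cs.sample_id + "\t" + "\t".join(cs.as_vector(names)) + "\n")


def read_arm_call_matrix(path: str | Path, method: str = "") -> list[ArmCallSet]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    return [
        ArmCallSet(sample_id=str(idx), calls=row.to_dict(), method=method)
        for idx, row in df.iterrows()
    ]


def write_adjusted_segments(
    per_sample: Mapping[str, Sequence[AdjustedSegment]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tcn_observed\tcn_tumour\tcall\n")
        for sample_id, segs in per_sample.items():
            for a in segs:
                s = a.segment
                fh.write(
                    f"{sample_id}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                    f"{a.cn_observed:.4f}\t{a.cn_tumour:.4f}\t{a.call}\n"
                )
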