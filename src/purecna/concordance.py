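"""Concordance of arm-level CNA calls between two purity-adjustment runs.

Calls from a reference run (rows) and a comparator run (columns) are
cross-tabulated into a 3x3 loss/neutral/gain matrix. Off-diagonal cells are
"different calls"; of those, *undercalling* means the reference detected a
CNA (loss or gain) that the comparator called neutral, and *overcalling*
covers the remaining disagreements — the comparator calls a CNA the
reference did not make, including the rare loss<->gain sign switches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from purecna.adjust import CALLS, ArmCallSet

__all__ = [
    "ConcordanceResult", "cross_tabulate", "concordance_stats",
    "concordance_report", "reported_crosstabs", "round_half_away",
]

_IDX = {c: i for i, c in enumerate(CALLS)}
_NEUTRAL = _IDX["neutral"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (display convention for percentages)."""
    scale = 10.0**ndigits
    return np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale


@dataclass(frozen=True)
class ConcordanceResult:
    """Cross-tabulation plus differing/under/over-calling statistics."""

    matrix: np.ndarray  # 3x3, rows=reference, cols=comparator, loss/neutral/gain
    n_total: int
    n_diff: int
    n_under: int
    n_over: int
    frac_diff: float  # percentages of n_total / n_diff respectively
    frac_under: float
    frac_over: float

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.astype(int).tolist(),
            "labels": list(CALLS),
            "n_total": self.n_total,
            "n_diff": self.n_diff,
            "n_under": self.n_under,
            "n_over": self.n_over,
            "frac_diff": self.frac_diff,
            "frac_under": self.frac_under,
            "frac_over": self.frac_over,
        }


def cross_tabulate(
    reference: Sequence[ArmCallSet], comparator: Sequence[ArmCallSet]
) -> np.ndarray:
    """3x3 call cross-tabulation over matched samples and arms.

    Both sides must cover the same samples and the same arms; the matrix
    sums to n_samples x n_arms.
    """
    ref_by_id = {cs.sample_id: cs for cs in reference}
    cmp_by_id = {cs.sample_id: cs for cs in comparator}
    only_ref = sorted(set(ref_by_id) - set(cmp_by_id))
    only_cmp = sorted(set(cmp_by_id) - set(ref_by_id))
    if only_ref or only_cmp:
        raise ValueError(
            f"sample mismatch: only in reference={only_ref}, only in comparator={only_cmp}"
        )
    matrix = np.zeros((3, 3), dtype=np.int64)
    for sample_id, ref_cs in ref_by_id.items():
        cmp_cs = cmp_by_id[sample_id]
        if set(ref_cs.calls) != set(cmp_cs.calls):
            raise ValueError(f"sample {sample_id}: arm sets differ between runs")
        for arm_name, ref_call in ref_cs.calls.items():
            matrix[_IDX[ref_call], _IDX[cmp_cs.calls[arm_name]]] += 1
    return matrix


def concordance_stats(matrix: np.ndarray | Sequence[Sequence[int]]) -> ConcordanceResult:
    """Differing/undercalling/overcalling statistics of a 3x3 call matrix.

    n_under counts off-diagonal cells in the neutral column (reference CNA
    missed by the comparator); n_over is every other off-diagonal cell.
    Percentages are reported to one decimal, halves away from zero; the
    under/over shares are fractions of the differing calls (0 when there are
    none).
    """
    m = np.asarray(matrix, dtype=np.int64)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("negative counts")
    n_total = int(m.sum())
    off = m.copy()
    np.fill_diagonal(off, 0)
    n_diff = int(off.sum())
    n_under = int(off[:, _NEUTRAL].sum())
    n_over = n_diff - n_under
    return ConcordanceResult(
        matrix=m,
        n_total=n_total,
        n_diff=n_diff,
        n_under=n_under,
        n_over=n_over,
        frac_diff=round_half_away(100.0 * n_diff / n_total, 1) if n_total else 0.0,
        frac_under=round_half_away(100.0 * n_under / n_diff, 1) if n_diff else 0.0,
        frac_over=round_half_away(100.0 * n_over / n_diff, 1) if n_diff else 0.0,
    )


def concordance_report(
    runs: Mapping[str, Sequence[ArmCallSet]], reference_method: str
) -> dict[str, ConcordanceResult]:
    """One ConcordanceResult per comparator method against the reference run."""
    if reference_method not in runs:
        raise ValueError(f"reference method {reference_method!r} not among runs")
    if len(runs) < 2:
        raise ValueError("need at least two methods to compare")
    reference = runs[reference_method]
    return {
        method: concordance_stats(cross_tabulate(reference, callsets))
        for method, callsets in runs.items()
        if method != reference_method
    }


def report_to_json(report: Mapping[str, ConcordanceResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({m: r.to_dict() for m, r in report.items()}, fh, indent=2)


def report_to_tsv(report: Mapping[str, ConcordanceResult], path: str | Path) -> None:
    """Flat TSV mirroring the published layout: matrix cells plus fractions."""
    with open(path, "w") as fh:
        cells = [f"{r}_{c}" for r in CALLS for c in CALLS]
        fh.write("comparator\t" + "\t".join(cells) +
                 "\tn_total\tn_diff\tfrac_diff\tn_under\tfrac_under\tn_over\tfrac_over\n")
        for method, res in report.items():
            flat = "\t".join(str(int(v)) for v in res.matrix.ravel())
            fh.write(
                f"{method}\t{flat}\t{res.n_total}\t{res.n_diff}\t{res.frac_diff}"
                f"\t{res.n_under}\t{res.frac_under}\t{res.n_over}\t{res.frac_over}\n"
            )


def reported_crosstabs() -> dict[str, dict[str, np.ndarray]]:
    """The published FOCUS/GRAMPIAN arm-call cross-tabulations (package data).

    Returns cohort -> comparator method -> 3x3 matrix (rows: reference
    SoftCTM-on-H&E1 call; columns: comparator call; loss/neutral/gain order).
    """
    ref = resources.files("purecna.data").joinpath("reported_arm_crosstabs.json")
    data = json.loads(ref.read_text())
    return {
        cohort: {
            method: np.asarray(mat, dtype=np.int64)
            for method, mat in block.items()
            if method != "n_samples"
        }
        for cohort, block in data.items()
        if not cohort.startswith("_")
    }
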