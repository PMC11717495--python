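"""Method-comparison statistics: Pearson r with Fisher-z CI, paired t-test,
Bland–Altman agreement summary.

The difference convention everywhere is first argument minus second.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PearsonResult", "BlandAltmanResult", "pearson_ci", "paired_ttest", "bland_altman"]


@dataclass(frozen=True)
class PearsonResult:
    """Product-moment correlation with a 95% Fisher-z confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["r_display"] = round(self.r, 3)
        d["ci_display"] = (round(self.ci_low, 3), round(self.ci_high, 3))
        return d


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference (bias) and 95% limits of agreement, a minus b."""

    bias: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_matched(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matched 1-d sequences of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_ci(x, y) -> PearsonResult:
    """Pearson correlation with 95% CI via the Fisher z-transform.

    The CI uses z = atanh(r) with standard error 1/sqrt(n-3) (as implemented
    by scipy's ``pearsonr(...).confidence_interval()``). Degenerate input
    (zero variance on either side) raises rather than returning NaN.
    """
    x, y = _as_matched(x, y, min_n=4)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return PearsonResult(
        r=float(res.statistic), ci_low=float(ci.low), ci_high=float(ci.high),
        n=int(x.size), p_value=float(res.pvalue),
    )


def paired_ttest(x, y) -> tuple[float, float, float]:
    """Two-sided paired-samples t-test; returns (t, p, mean difference x-y)."""
    x, y = _as_matched(x, y, min_n=2)
    d = x - y
    if np.ptp(d) == 0:
        raise ValueError("zero variance of differences: paired t undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), float(d.mean())


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman summary of agreement on paired measurements.

    bias = mean(x - y); limits of agreement bias ± 1.96·SD(x - y), sample SD.
    """
    x, y = _as_matched(x, y, min_n=2)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=int(d.size)
    )
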