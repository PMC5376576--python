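"""Correlation of miRNA / target expression with phytohormone time courses.

Expression of a miRNA (or of its target) measured over both ovary phenotypes
(IFC, incompletely fused carpels; CFC, completely fused carpels) at four
developmental stages gives a paired series of n = 8 observations, which is
correlated with the matching phytohormone series (IAA, ZR+iPA, GA, BR, JA,
ABA).  Pearson correlation, two-tailed, is the default; significance flags
are ``*`` (p < 0.05) and ``**`` (p < 0.01).

miRNA-target pairs fall into two relationship groups with respect to a
hormone: group 1 when both members are significantly correlated with
opposite signs, and group 2 when exactly one member is significantly
correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

HORMONES = ("IAA", "ZR+iPA", "GA", "BR", "JA", "ABA")
PHENOTYPES = ("IFC", "CFC")
STAGES = (0, 1, 2, 3)


class ConstantSeriesError(ValueError):
    """Correlation is undefined for a constant series."""


@dataclass
class CorrelationResult:
    series_id: str
    hormone: str
    r: float
    p: float
    flag: str  # "ns", "*", "**"
    n: int = 8

    @property
    def significant(self) -> bool:
        return self.flag != "ns"


def _flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def correlate(
    x,
    y,
    series_id: str = "",
    hormone: str = "",
    method: str = "pearson",
    tails: str = "two",
) -> CorrelationResult:
    """Correlate an expression series with a hormone series (both length 8:
    IFC stages 0-3 then CFC stages 0-3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != 8 or len(y) != 8:
        raise ValueError("series must have length 8")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("constant series")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method}")
    r = float(res.statistic)
    p = float(res.pvalue)
    if tails == "one":
        p = p / 2.0
    elif tails != "two":
        raise ValueError(f"unknown tails {tails}")
    return CorrelationResult(series_id=series_id, hormone=hormone, r=r, p=p, flag=_flag(p))


def critical_r(n: int = 8, alpha: float = 0.05) -> float:
    """Two-sided critical |r| at sample size n (t-quantile inversion, df = n-2)."""
    df = n - 2
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(np.sqrt(t * t / (t * t + df)))


def group_pairs(
    mirna_corrs: list[CorrelationResult], target_corrs: list[CorrelationResult]
) -> dict[tuple[str, str, str], str]:
    """Classify each (miRNA, target, hormone) triple into relationship groups.

    group1: both significant with opposite signs of r; group2: exactly one
    significant; ungrouped otherwise.  Series are matched by hormone; every
    (miRNA series, target series) combination sharing a hormone is labelled.
    """
    out: dict[tuple[str, str, str], str] = {}
    by_h_t: dict[str, list[CorrelationResult]] = {}
    for tc in target_corrs:
        by_h_t.setdefault(tc.hormone, []).append(tc)
    for mc in mirna_corrs:
        for tc in by_h_t.get(mc.hormone, []):
            key = (mc.series_id, tc.series_id, mc.hormone)
            if mc.significant and tc.significant and np.sign(mc.r) != np.sign(tc.r):
                out[key] = "group1"
            elif mc.significant != tc.significant:
                out[key] = "group2"
            else:
                out[key] = "ungrouped"
    return out
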