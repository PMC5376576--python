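"""Normalized expression, replicate reproducibility and differential calling.

Counts are normalized per library to NE (normalized expression):

    NE = (miRNA read count / total clean reads) * 1,000,000

Differential expression between two conditions (two replicates each) uses a
one-tailed Welch t-test in the direction of the observed mean difference,
with the thresholds fold change > 1.5, p < 0.05, and NE > 5 in at least one
sample.  Fold change is orientation-free (larger mean over smaller mean) with
a small pseudo-count so zero means stay comparable.  A helper implements the
comparative 2^-ddCt method for qPCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class InputError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """NE values (rows = miRNA ids, columns = samples) plus library sizes."""

    ne: pd.DataFrame
    clean_totals: pd.Series
    conditions: dict[str, str]  # sample -> condition label

    @classmethod
    def from_counts(
        cls, counts: pd.DataFrame, clean_totals: pd.Series, conditions: dict[str, str]
    ) -> "ExpressionMatrix":
        if (clean_totals <= 0).any():
            raise InputError("clean totals must be positive")
        ne = counts.div(clean_totals, axis=1) * 1_000_000
        return cls(ne=ne, clean_totals=clean_totals, conditions=conditions)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


@dataclass
class DEResult:
    id: str
    mean_ne: dict[str, float]
    fold_change: float
    direction: str  # up = higher in the first condition
    p: float
    passes: bool


def normalize_ne(count: int, clean_total: int) -> float:
    """NE = count / clean_total * 1e6 (no pseudo-count)."""
    if clean_total <= 0:
        raise InputError("clean_total must be > 0")
    if not 0 <= count <= clean_total:
        raise InputError("count must be in [0, clean_total]")
    return count / clean_total * 1_000_000


def replicate_correlation(
    matrix: ExpressionMatrix,
    condition: str,
    method: str = "spearman",
    expressed_min: float = 1.0,
) -> float:
    """Reproducibility of the two replicates of one condition.

    Correlates log2(NE+1) between the replicate vectors, over rows expressed
    (NE > ``expressed_min``) in at least one replicate.  Returns NaN when the
    correlation is undefined (constant vector).
    """
    samples = matrix.samples_of(condition)
    if len(samples) != 2:
        raise InputError(f"condition {condition} must have exactly 2 replicates")
    sub = matrix.ne[samples]
    sub = sub[(sub > expressed_min).any(axis=1)]
    if len(sub) < 3:
        raise InputError("need at least 3 expressed rows")
    x = np.log2(sub[samples[0]] + 1)
    y = np.log2(sub[samples[1]] + 1)
    if x.nunique() < 2 or y.nunique() < 2:
        return float("nan")
    if method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        raise InputError(f"unknown method {method}")
    return float(r)


def fold_change(ne_a, ne_b, eps: float = 0.01) -> tuple[float, str]:
    """Orientation-free fold change between two NE groups.

    fc = (max(mean_a, mean_b) + eps) / (min(mean_a, mean_b) + eps);
    direction is "up" when the first group's mean is higher.
    """
    if eps < 0:
        raise InputError("eps must be >= 0")
    ma = float(np.mean(ne_a))
    mb = float(np.mean(ne_b))
    hi, lo = max(ma, mb), min(ma, mb)
    fc = (hi + eps) / (lo + eps)
    direction = "up" if ma > mb else "down"
    return fc, direction


def _welch_one_tailed(a: np.ndarray, b: np.ndarray) -> float:
    """One-tailed Welch p in the direction of the observed mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 1.0
        return 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical replicate values trigger a benign precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p_two = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p_two):
        return 1.0
    return float(p_two / 2.0)


def call_de(
    matrix: ExpressionMatrix,
    fc_min: float = 1.5,
    alpha: float = 0.05,
    ne_min: float = 5.0,
    detect_min: float = 1.0,
    eps: float = 0.01,
) -> list[DEResult]:
    """Call differential expression between the two conditions of a matrix.

    Rows with NE > ``detect_min`` in at least one sample are considered.  A
    row passes when fold change > ``fc_min``, one-tailed p < ``alpha`` and
    its larger condition mean NE > ``ne_min``.
    """
    # condition order = first appearance; "up" means higher in the first one
    conds = list(dict.fromkeys(matrix.conditions.values()))
    if len(conds) != 2:
        raise InputError("expected exactly 2 conditions")
    ca, cb = conds
    sa = matrix.samples_of(ca)
    sb = matrix.samples_of(cb)
    if len(sa) < 2 or len(sb) < 2:
        raise InputError("need >= 2 replicates per condition")
    results = []
    for rid, row in matrix.ne.iterrows():
        if not (row > detect_min).any():
            continue
        a = row[sa].to_numpy(dtype=float)
        b = row[sb].to_numpy(dtype=float)
        fc, direction = fold_change(a, b, eps=eps)
        p = _welch_one_tailed(a, b)
        passes = fc > fc_min and p < alpha and max(a.mean(), b.mean()) > ne_min
        results.append(
            DEResult(
                id=str(rid),
                mean_ne={ca: float(a.mean()), cb: float(b.mean())},
                fold_change=fc,
                direction=direction,
                p=p,
                passes=passes,
            )
        )
    return results


def ddct(
    target_ct: dict[str, float],
    reference_ct: dict[str, float],
    calibrator: str,
) -> dict[str, float]:
    """Relative expression by the comparative 2^-ddCt method.

    ddCt(sample) = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator;
    the calibrator's relative expression is 1 by construction.
    """
    if calibrator not in target_ct:
        raise InputError(f"calibrator {calibrator!r} not among samples")
    for d in (target_ct, reference_ct):
        if any(not np.isfinite(v) for v in d.values()):
            raise InputError("non-finite Ct value")
    dct_cal = target_ct[calibrator] - reference_ct[calibrator]
    out = {}
    for sample in target_ct:
        dct = target_ct[sample] - reference_ct[sample]
        out[sample] = float(2.0 ** (-(dct - dct_cal)))
    return out
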