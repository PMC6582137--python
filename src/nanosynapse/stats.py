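"""Group comparison statistics.

The battery used for cluster-area and distance comparisons: two-tailed
unpaired t-test (equal-variance by default, Welch optional), one-way ANOVA
with Tukey's multiple-comparison test, ROUT outlier detection at Q = 0.5%,
and mean +/- SEM summaries. Outliers are flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .errors import InsufficientDataError, InvalidArgumentError


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.values)


def _values(sample) -> np.ndarray:
    return sample.values if isinstance(sample, GroupSample) else np.asarray(sample, dtype=float)


def summarize(sample):
    """(mean, SEM, n) with sample sd (n-1 denominator)."""
    v = _values(sample)
    if len(v) < 2:
        raise InsufficientDataError("need n >= 2")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))), len(v)


def t_test_unpaired(a, b, equal_var: bool = True):
    """Two-tailed unpaired t-test; returns (t, p).

    Equal-variance (pooled, df = n_a + n_b - 2) by default, matching the
    conventional spreadsheet default; ``equal_var=False`` gives Welch.
    Zero pooled variance with equal means returns (0, 1).
    """
    va, vb = _values(a), _values(b)
    if len(va) < 2 or len(vb) < 2:
        raise InsufficientDataError("both groups need n >= 2")
    if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0 and va.mean() == vb.mean():
        return 0.0, 1.0
    t, p = sstats.ttest_ind(va, vb, equal_var=equal_var)
    return float(t), float(p)


def anova_tukey(groups: Sequence):
    """One-way ANOVA plus Tukey HSD on all pairs.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps (i, j) index pairs
    (or labels, for GroupSample inputs) to Tukey-adjusted p values.
    """
    if len(groups) < 3:
        raise InvalidArgumentError("need >= 3 groups (use t_test_unpaired for 2)")
    labels = [
        g.label if isinstance(g, GroupSample) else i for i, g in enumerate(groups)
    ]
    vals = [_values(g) for g in groups]
    for v in vals:
        if len(v) < 2:
            raise InsufficientDataError("every group needs n >= 2")
    if all(v.std(ddof=1) == 0 for v in vals) and len({v.mean() for v in vals}) == 1:
        return 0.0, 1.0, {
            (labels[i], labels[j]): 1.0
            for i in range(len(vals))
            for j in range(i + 1, len(vals))
        }
    F, p = sstats.f_oneway(*vals)
    hsd = sstats.tukey_hsd(*vals)
    pairwise = {
        (labels[i], labels[j]): float(hsd.pvalue[i, j])
        for i in range(len(vals))
        for j in range(i + 1, len(vals))
    }
    return float(F), float(p), pairwise


@dataclass
class OutlierReport:
    """ROUT flags; removal (and re-checking significance) is the caller's duty."""

    q_percent: float
    flags: np.ndarray              # boolean, aligned with the sample
    robust_center: float
    rsdr: float
    p_values: np.ndarray
    note: str = (
        "flagged values are reported, not removed; re-run the downstream test "
        "after removal and confirm the conclusion is unchanged"
    )

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def rout_outliers(sample, q_percent: float = 0.5) -> OutlierReport:
    """ROUT outlier detection for a one-sample scatter, Q in percent.

    The regression model degenerates to a constant: robust center = median,
    robust scale RSDR = 68.27th percentile of |residuals| corrected by
    n/(n-1). Each value's two-tailed t-tail probability of residual/RSDR
    (df = n-1) enters a Benjamini-Hochberg step-up at rate Q; values passing
    are flagged as outliers.
    """
    v = _values(sample)
    n = len(v)
    if n < 10:
        raise InsufficientDataError("ROUT needs n >= 10")
    if not 0 < q_percent < 100:
        raise InvalidArgumentError("Q must be in (0, 100) percent")
    center = float(np.median(v))
    resid = v - center
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * n / (n - 1)
    scale = max(rsdr, 1e-12 * max(1.0, abs(center), float(np.abs(v).max())))
    t = resid / scale
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    alpha = q_percent / 100.0
    order = np.argsort(p)
    ranked = p[order]
    passing = ranked <= alpha * (np.arange(1, n + 1) / n)
    k = int(np.flatnonzero(passing)[-1]) + 1 if passing.any() else 0
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    return OutlierReport(
        q_percent=q_percent, flags=flags, robust_center=center, rsdr=rsdr, p_values=p
    )


def significance_stars(p: float) -> str:
    """Annotation at the conventional levels (alpha = 0.05)."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
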