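"""Robustness and reliability metrics for FC matrices.

Quantifies how much an FC estimate changes between two conditions of
the same scan (e.g. without/with motion, without/with global signal
regression) and how similar a subject's FC pattern is across repeated
scans (test-retest reliability).  The headline robustness summary is
the median absolute percent change across region pairs, using the
reference condition as the baseline; the median is preferred over the
mean because near-zero baseline edges produce a heavy right tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fc_core import FcMatrix

__all__ = [
    "FcComparison",
    "fc_pattern_similarity",
    "abs_percent_change",
    "test_retest",
    "paired_t",
]


@dataclass
class FcComparison:
    """Edgewise comparison of two FC matrices from the same scan pair."""

    pattern_similarity: float
    edge_delta: np.ndarray
    pct_change: np.ndarray  # retained edges only, aligned with retained_mask
    retained_mask: np.ndarray
    median_abs_pct_change: float
    mean_abs_pct_change: float

    @property
    def n_edges_used(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def n_edges_excluded(self) -> int:
        return int((~self.retained_mask).sum())


def _check_pairing(a: FcMatrix, b: FcMatrix) -> None:
    if a.estimator != b.estimator:
        raise ValueError(f"estimator mismatch: {a.estimator} vs {b.estimator}")
    if a.region_labels != b.region_labels:
        raise ValueError("region labels differ between matrices")


def fc_pattern_similarity(a: FcMatrix, b: FcMatrix) -> float:
    """Pearson r between the vectorised upper triangles of two matrices."""
    _check_pairing(a, b)
    ua, ub = a.upper_triangle(), b.upper_triangle()
    ok = np.isfinite(ua) & np.isfinite(ub)
    r = stats.pearsonr(ua[ok], ub[ok]).statistic
    return float(r)


def abs_percent_change(
    baseline: FcMatrix, comparison: FcMatrix, eps: float = 1e-6
) -> FcComparison:
    """Per-edge absolute percent change with the baseline as denominator.

    Edge p maps to ``100 * |(baseline_p - comparison_p) / baseline_p|``;
    edges whose baseline magnitude is below ``eps`` (or not finite) are
    excluded from the summaries and counted.  Raises if every edge is
    excluded.
    """
    _check_pairing(baseline, comparison)
    ub, uc = baseline.upper_triangle(), comparison.upper_triangle()
    delta = ub - uc
    retained = (np.abs(ub) >= eps) & np.isfinite(ub) & np.isfinite(uc)
    if not retained.any():
        raise ValueError("all edges excluded: baseline magnitudes below eps")
    pct = 100.0 * np.abs(delta[retained] / ub[retained])
    return FcComparison(
        pattern_similarity=fc_pattern_similarity(baseline, comparison),
        edge_delta=delta,
        pct_change=pct,
        retained_mask=retained,
        median_abs_pct_change=float(np.median(pct)),
        mean_abs_pct_change=float(np.mean(pct)),
    )


def test_retest(scan1: FcMatrix, scan2: FcMatrix) -> float:
    """Test-retest reliability: FC-pattern similarity of back-to-back scans."""
    return fc_pattern_similarity(scan1, scan2)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Classical paired-samples t-test, two-sided.

    Returns (t, df, p) with df = n - 1.  Zero variance of the paired
    differences with a nonzero mean is degenerate and raises; identical
    samples return (0, df, 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError("paired samples must have equal length")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, n - 1, 1.0
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)
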