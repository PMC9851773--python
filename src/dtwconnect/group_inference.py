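"""Edgewise inference and p-value enrichment.

Mass-univariate tests across all region pairs (two-sample, paired, and
partial-correlation screens), followed by enrichment summaries: the
histogram of edgewise p-values, the Storey fixed-lambda estimate of the
true-null proportion pi0, and the fraction of false nulls 1 - pi0.  No
per-edge multiple-comparison correction is applied anywhere — the
inferential object is the enrichment of small p-values across the
family of edges, not any single edge.  ROI involvement counts (how
often a region participates in a sub-threshold edge, alpha = .05
uncorrected) localise where the family-level signal concentrates.

A 2 (condition) x 3 (region pair) within-subject ANOVA supports the
task-sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .comparison_metrics import paired_t
from .fc_core import FcMatrix

__all__ = [
    "EdgewiseResult",
    "EnrichmentResult",
    "stack_edges",
    "edgewise_two_sample_t",
    "edgewise_paired_t",
    "edgewise_partial_corr",
    "estimate_pi0",
    "roi_involvement_counts",
    "repeated_measures_anova_2x3",
]


@dataclass
class EdgewiseResult:
    """Per-edge statistics over the upper triangle (row-major, i < j)."""

    statistic: np.ndarray
    df: np.ndarray
    pvalues: np.ndarray
    test: str
    estimator: str = ""
    region_labels: list[str] | None = None

    @property
    def n_edges(self) -> int:
        return self.pvalues.shape[0]

    def valid_pvalues(self) -> np.ndarray:
        return self.pvalues[np.isfinite(self.pvalues)]


@dataclass
class EnrichmentResult:
    """Storey fixed-lambda enrichment summary of a p-value family."""

    histogram: np.ndarray
    bin_edges: np.ndarray
    lam: float
    pi0: float
    fraction_false: float
    n_tests: int


def stack_edges(matrices: list[FcMatrix]) -> np.ndarray:
    """Subjects x edges array of upper-triangle values (fixed row-major order)."""
    if not matrices:
        raise ValueError("empty matrix stack")
    labels = matrices[0].region_labels
    est = matrices[0].estimator
    for m in matrices:
        if m.region_labels != labels:
            raise ValueError("region labels differ within the stack")
        if m.estimator != est:
            raise ValueError("estimator differs within the stack")
    return np.vstack([m.upper_triangle() for m in matrices])


def edgewise_two_sample_t(
    group_a: list[FcMatrix], group_b: list[FcMatrix], equal_var: bool = True
) -> EdgewiseResult:
    """Two-sample t-test (pooled variance by default) at every edge."""
    xa, xb = stack_edges(group_a), stack_edges(group_b)
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("edge count mismatch between groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(xa, xb, axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} edge(s) with zero pooled variance; p undefined")
        p[bad] = np.nan
    df = np.full(t.shape, xa.shape[0] + xb.shape[0] - 2, dtype=float)
    return EdgewiseResult(t, df, p, "two_sample_t",
                          group_a[0].estimator, group_a[0].region_labels)


def edgewise_paired_t(cond_a: list[FcMatrix], cond_b: list[FcMatrix]) -> EdgewiseResult:
    """Paired t-test at every edge across matched subjects."""
    xa, xb = stack_edges(cond_a), stack_edges(cond_b)
    if xa.shape != xb.shape:
        raise ValueError("conditions must have the same subjects and edges")
    n, m = xa.shape
    t = np.empty(m)
    p = np.empty(m)
    for e in range(m):
        try:
            t[e], _, p[e] = paired_t(xa[:, e], xb[:, e])
        except ValueError:
            t[e], p[e] = np.nan, np.nan
    df = np.full(m, n - 1, dtype=float)
    return EdgewiseResult(t, df, p, "paired_t",
                          cond_a[0].estimator, cond_a[0].region_labels)


def edgewise_partial_corr(
    fc: list[FcMatrix], behavior: np.ndarray, covariate: np.ndarray
) -> EdgewiseResult:
    """Partial correlation of each edge with a behavioral score, controlling a covariate.

    Edge values and behavior are each residualised on [1, covariate];
    the Pearson correlation of the residuals is tested with the
    t-transform at df = n - 3.
    """
    x = stack_edges(fc)
    y = np.asarray(behavior, dtype=float).ravel()
    c = np.asarray(covariate, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n or c.shape[0] != n:
        raise ValueError("behavior/covariate length must match subject count")
    if n < 4:
        raise ValueError("need at least 4 subjects for df = n - 3 > 0")
    if np.std(y) == 0 or not np.isfinite(y).all():
        raise ValueError("behavior is constant or has missing values")
    design = np.column_stack([np.ones(n), c])
    if np.std(c) == 0:
        design = design[:, :1]  # constant covariate: plain correlation
    proj = design @ np.linalg.pinv(design)
    ry = y - proj @ y
    rx = x - proj @ x
    sy = np.linalg.norm(ry)
    sx = np.linalg.norm(rx, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rx.T @ ry) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 3
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)  # |t| = inf (perfect r) gives p = 0
    p[np.isnan(t)] = np.nan
    return EdgewiseResult(t, np.full(r.shape, df, float), p, "partial_corr",
                          fc[0].estimator, fc[0].region_labels)


def estimate_pi0(pvalues: np.ndarray, lam: float = 0.5, n_bins: int = 20) -> EnrichmentResult:
    """Storey fixed-lambda estimate of the true-null proportion.

    ``pi0 = #{p > lambda} / ((1 - lambda) * m)``, clipped to [0, 1];
    the fraction of false nulls is ``1 - pi0``.  Also returns the
    p-value histogram (``n_bins`` equal bins on [0, 1]).
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float).ravel()
    p = p[np.isfinite(p)]
    m = p.shape[0]
    if m < 20:
        raise ValueError("need at least 20 valid p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    hist, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    pi0 = float(np.clip((p > lam).sum() / ((1.0 - lam) * m), 0.0, 1.0))
    return EnrichmentResult(hist, edges, lam, pi0, 1.0 - pi0, m)


def roi_involvement_counts(result: EdgewiseResult, alpha: float = 0.05) -> np.ndarray:
    """Per-region count of incident edges with p < alpha (uncorrected)."""
    m = result.n_edges
    r = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if r * (r - 1) // 2 != m:
        raise ValueError("edge count is not a triangular number")
    counts = np.zeros(r, dtype=int)
    iu, ju = np.triu_indices(r, k=1)
    hit = result.pvalues < alpha
    np.add.at(counts, iu[hit], 1)
    np.add.at(counts, ju[hit], 1)
    return counts


def repeated_measures_anova_2x3(data: np.ndarray) -> pd.DataFrame:
    """2 x 3 within-subject ANOVA (condition x region pair).

    ``data`` is subjects x 2 x 3 with complete cells.  Returns the
    classical within-subject decomposition (error terms are the
    subject-by-factor interactions; no sphericity correction) as a
    DataFrame indexed by effect with columns F, num_df, den_df, p.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3 or x.shape[1] != 2 or x.shape[2] != 3:
        raise ValueError("data must be subjects x 2 x 3")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("design has missing cells")
    n, a, b = x.shape
    gm = x.mean()
    m_s = x.mean(axis=(1, 2))
    m_a = x.mean(axis=(0, 2))
    m_b = x.mean(axis=(0, 1))
    m_ab = x.mean(axis=0)
    m_sa = x.mean(axis=2)
    m_sb = x.mean(axis=1)

    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (
        x
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - gm
    )
    ss_abs = (resid**2).sum()

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("run", ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        ("pair", ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        ("run:pair", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ss_eff == 0:
            f, p = 0.0, 1.0
        elif ms_err == 0:
            f, p = np.inf, 0.0
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, df_eff, df_err))
        rows.append({"effect": name, "F": f, "num_df": df_eff, "den_df": df_err,
                     "p": p, "ss_effect": ss_eff, "ss_error": ss_err})
    return pd.DataFrame(rows).set_index("effect")
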