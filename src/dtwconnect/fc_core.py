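"""Functional connectivity estimators.

Two estimators of region-pair BOLD similarity are provided:

* Pearson correlation with Fisher z transform (``pearson_fc_matrix``) —
  the field's standard measure, invariant to amplitude and sensitive to
  synchronicity only.
* Window-constrained dynamic time warping (``dtw_similarity_matrix``) —
  an elastic-matching distance between the raw (percent-signal-change,
  *not* z-scored) timecourses, constrained to a Sakoe-Chiba band,
  negated and demeaned across the region pairs of one scan so that 0
  means average similarity, positive values above-average similarity.

The DTW dynamic program uses absolute difference as the local cost and
the symmetric three-way step pattern, matching the classic formulation:

    D(i, j) = |x_i - y_j| + min(D(i-1, j), D(i, j-1), D(i-1, j-1))

restricted to the band ``|i - j| <= w``.  Distances are not normalised
by path length, so cross-scan comparisons require equal-length series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from numba import njit

from .denoise import RoiTimeseries

__all__ = [
    "DtwConfig",
    "FcMatrix",
    "window_samples",
    "dtw_distance",
    "dtw_distance_matrix",
    "dtw_similarity_matrix",
    "pearson_fc_matrix",
    "brute_force_dtw",
]

FISHER_Z_CLIP = 1.0 - 1e-7  # |r| clip before atanh so z stays finite


@dataclass(frozen=True)
class DtwConfig:
    """Parameters of the constrained-DTW estimator.

    ``window_seconds`` is the maximal temporal displacement the warping
    path may introduce; 100 s is the published optimum for BOLD data.
    """

    window_seconds: float = 100.0
    local_cost: str = "absolute"
    step_pattern: str = "symmetric"

    def __post_init__(self):
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.local_cost != "absolute":
            raise ValueError("only the absolute-difference local cost is supported")
        if self.step_pattern != "symmetric":
            raise ValueError("only the symmetric 3-way step pattern is supported")


@dataclass
class FcMatrix:
    """Symmetric R x R edge-value matrix with estimator provenance.

    ``estimator`` is ``pearson_z`` (Fisher-z correlations) or
    ``dtw_similarity`` (negated, demeaned DTW distances).  The diagonal
    is defined as 0 and excluded from all summaries.
    """

    values: np.ndarray
    estimator: str
    region_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    scan_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("FC matrix must be square")
        if not self.region_labels:
            self.region_labels = [f"roi{i:03d}" for i in range(self.values.shape[0])]
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError("label count must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Edge values in fixed row-major (i < j) order, diagonal excluded."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


def window_samples(window_seconds: float, tr_seconds: float) -> int:
    """Convert a warping window from seconds to samples (rounded, min 1)."""
    if window_seconds <= 0 or tr_seconds <= 0:
        raise ValueError("window_seconds and tr_seconds must be positive")
    return max(1, round(window_seconds / tr_seconds))


@njit(cache=True)
def _dtw_band(x, y, w):  # pragma: no cover - exercised via dtw_distance
    n = x.shape[0]
    inf = np.inf
    prev = np.full(n + 1, inf)
    curr = np.full(n + 1, inf)
    for i in range(1, n + 1):
        jlo = max(1, i - w)
        jhi = min(n, i + w)
        curr[:] = inf
        for j in range(jlo, jhi + 1):
            c = abs(x[i - 1] - y[j - 1])
            if i == 1 and j == 1:
                best = 0.0
            else:
                best = prev[j]  # D(i-1, j)
                if curr[j - 1] < best:
                    best = curr[j - 1]  # D(i, j-1)
                if prev[j - 1] < best:
                    best = prev[j - 1]  # D(i-1, j-1)
            curr[j] = c + best
        prev, curr = curr, prev
    return prev[n]


def dtw_distance(x: np.ndarray, y: np.ndarray, w: int) -> float:
    """Banded DTW distance between two equal-length 1-D series.

    Parameters
    ----------
    x, y : arrays of equal length n >= 2
    w : Sakoe-Chiba band half-width in samples (>= 1); cells with
        ``|i - j| > w`` are inadmissible.
    """
    x = np.ascontiguousarray(x, dtype=float).ravel()
    y = np.ascontiguousarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("series must have equal length")
    if x.shape[0] < 2:
        raise ValueError("series must have length >= 2")
    if w < 1:
        raise ValueError("band half-width must be >= 1")
    return float(_dtw_band(x, y, int(w)))


def dtw_distance_matrix(ts: RoiTimeseries, config: DtwConfig = DtwConfig()) -> np.ndarray:
    """Pairwise banded DTW distances between all region timecourses.

    Returns a symmetric R x R distance matrix with zero diagonal.
    """
    data = np.asarray(ts.values, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    w = window_samples(config.window_seconds, ts.tr_seconds)
    r = data.shape[1]
    dist = np.zeros((r, r))
    cols = [np.ascontiguousarray(data[:, i]) for i in range(r)]
    for i, j in combinations(range(r), 2):
        d = _dtw_band(cols[i], cols[j], w)
        dist[i, j] = dist[j, i] = d
    return dist


def dtw_similarity_matrix(
    ts: RoiTimeseries,
    config: DtwConfig = DtwConfig(),
    subject_id: str = "",
    scan_id: str = "",
) -> FcMatrix:
    """DTW similarity FC matrix: distances negated and demeaned per scan.

    Each unordered pair's distance d_p is mapped to the similarity
    ``mean_q(d_q) - d_p`` over the scan's upper-triangle pairs, so
    similarities are centred on 0 within the scan.  Input should be in
    percent signal change, not z-scored: amplitude differences are part
    of what this estimator is sensitive to.
    """
    dist = dtw_distance_matrix(ts, config)
    iu = np.triu_indices(dist.shape[0], k=1)
    sim = np.zeros_like(dist)
    sim[iu] = dist[iu].mean() - dist[iu]
    sim = sim + sim.T
    np.fill_diagonal(sim, 0.0)
    return FcMatrix(sim, "dtw_similarity", list(ts.region_labels), subject_id, scan_id)


def pearson_fc_matrix(
    ts: RoiTimeseries, subject_id: str = "", scan_id: str = ""
) -> FcMatrix:
    """Pearson-correlation FC matrix with Fisher z transform.

    Correlations are clipped to ``|r| <= 1 - 1e-7`` before ``atanh`` so
    degenerate perfect correlations stay finite.  Edges incident to a
    zero-variance region are set to NaN with a warning.
    """
    import warnings

    data = np.asarray(ts.values, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    sd = data.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    z = np.arctanh(np.clip(r, -FISHER_Z_CLIP, FISHER_Z_CLIP))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance region(s); their edges are NaN"
        )
        z[degenerate, :] = np.nan
        z[:, degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetries
    return FcMatrix(z, "pearson_z", list(ts.region_labels), subject_id, scan_id)


def brute_force_dtw(x: np.ndarray, y: np.ndarray, w: int) -> float:
    """Exhaustive-enumeration DTW for tiny inputs (test oracle).

    Enumerates every monotone warping path from (0, 0) to (n-1, n-1)
    inside the band and returns the minimal cumulative cost.  Refuses
    n > 10 (combinatorial).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if n != y.shape[0]:
        raise ValueError("series must have equal length")
    if n > 10:
        raise ValueError("brute-force oracle limited to n <= 10")
    if w < 1:
        raise ValueError("band half-width must be >= 1")

    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(x[i] - y[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == n - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < n and abs(ii - jj) <= w:
                walk(ii, jj, cost)

    walk(0, 0, 0.0)
    return float(best[0])
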