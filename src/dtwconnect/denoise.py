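"""ROI-level BOLD denoising.

Implements the standard resting-state denoising chain at the region
level: percent-signal-change normalisation, motion/intensity outlier
detection, and a single simultaneous nuisance regression whose design
holds the six rigid-body motion parameters and their derivatives,
anatomical-CompCor component timecourses, one spike (scrubbing)
regressor per flagged volume, discrete-cosine columns spanning the
frequencies *outside* the retained band (so the regression removes
out-of-band power), and optionally the global signal.  The residuals of
that regression feed all connectivity estimation.

Volumetric steps (realignment, distortion correction, normalisation)
are out of scope: inputs are region-averaged timecourses plus the
motion-parameter table produced by realignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeseries",
    "DenoiseConfig",
    "NuisanceDesign",
    "MotionTrace",
    "percent_signal_change",
    "framewise_displacement",
    "rmsd_summary",
    "detect_outlier_volumes",
    "compcor_components",
    "build_nuisance_design",
    "regress_nuisance",
    "denoise_timeseries",
]

ROTATION_ARC_MM = 50.0  # rotations (rad) -> mm displacement on a 50 mm sphere


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be T x 6")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class RoiTimeseries:
    """A scan's T x R matrix of region-averaged BOLD values with TR metadata."""

    values: np.ndarray
    tr_seconds: float
    region_labels: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x R matrix")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need T >= 2 and R >= 2")
        if np.isnan(self.values).any():
            raise ValueError("missing values in timeseries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.region_labels:
            self.region_labels = [f"roi{i:03d}" for i in range(self.values.shape[1])]
        if len(self.region_labels) != self.values.shape[1]:
            raise ValueError("label count must match region count")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DenoiseConfig:
    """Denoising parameters.

    band_hz
        Retained frequency band; cosine regressors cover everything
        outside it.  Default 0.008-0.08 Hz, the conventional
        resting-state band.
    fd_threshold_mm
        Framewise-displacement threshold for outlier volumes (0.5 mm,
        the standard threshold for ~2 s TR acquisitions).
    intensity_z_threshold
        Threshold on the z-scored derivative of the global mean
        intensity (3 SD).
    n_compcor
        Number of aCompCor principal-component regressors (5).
    """

    band_hz: tuple[float, float] = (0.008, 0.08)
    fd_threshold_mm: float = 0.5
    intensity_z_threshold: float = 3.0
    n_compcor: int = 5
    use_gsr: bool = False
    motion_derivatives: bool = True

    def validate(self, tr_seconds: float) -> None:
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0 <= low < high < nyquist):
            raise ValueError(f"band {self.band_hz} invalid for Nyquist {nyquist:g} Hz")
        if self.fd_threshold_mm <= 0 or self.intensity_z_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_compcor < 0:
            raise ValueError("n_compcor must be >= 0")


@dataclass
class NuisanceDesign:
    """T x K regressor matrix with per-column roles."""

    matrix: np.ndarray
    roles: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.roles):
            raise ValueError("one role per column required")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def percent_signal_change(ts: RoiTimeseries) -> RoiTimeseries:
    """Normalise each region to percent signal change with zero mean.

    x -> 100 * (x - mean) / mean.  Regions whose mean is numerically
    zero (|mean| < 1e-6 * SD) cannot be expressed as percent change and
    are mean-centred only, with a warning.
    """
    data = np.asarray(ts.values, dtype=float)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    out = np.empty_like(data)
    degenerate = np.abs(mean) < 1e-6 * np.maximum(sd, 1e-300)
    constant_zero = (sd == 0) & (mean == 0)
    degenerate = degenerate | constant_zero
    for r in range(data.shape[1]):
        if degenerate[r]:
            out[:, r] = data[:, r] - mean[r]
        else:
            out[:, r] = 100.0 * (data[:, r] - mean[r]) / mean[r]
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} region(s) with near-zero mean were "
            "mean-centred instead of percent-signal-change scaled"
        )
    return RoiTimeseries(out, ts.tr_seconds, list(ts.region_labels), normalized=True)


def framewise_displacement(trace: MotionTrace) -> np.ndarray:
    """Per-volume framewise displacement in mm.

    Power-style FD: sum of absolute backward differences of the six
    parameters, rotations converted from degrees to arc length on a
    50 mm sphere.  FD at the first volume is 0.
    """
    p = trace.params.copy()
    p[:, 3:] = np.deg2rad(p[:, 3:]) * ROTATION_ARC_MM
    fd = np.zeros(trace.n_volumes)
    if trace.n_volumes > 1:
        fd[1:] = np.abs(np.diff(p, axis=0)).sum(axis=1)
    return fd


def rmsd_summary(trace: MotionTrace) -> float:
    """Root-mean-square of volume-to-volume displacement (mm).

    Uses the same composite displacement (50 mm rotation arc) as
    ``framewise_displacement``; summarises a run's motion as a single
    scalar for group matching and covariate use.
    """
    if trace.n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    fd = framewise_displacement(trace)[1:]
    return float(np.sqrt(np.mean(fd**2)))


def detect_outlier_volumes(
    ts: RoiTimeseries, trace: MotionTrace, config: DenoiseConfig = DenoiseConfig()
) -> set[int]:
    """Volumes flagged for scrubbing (0-based indices).

    A volume is an outlier if FD exceeds ``fd_threshold_mm`` or the
    z-scored change in global mean intensity exceeds
    ``intensity_z_threshold`` in absolute value.
    """
    if trace.n_volumes != ts.n_volumes:
        raise ValueError("trace and timeseries lengths differ")
    config.validate(ts.tr_seconds)
    fd = framewise_displacement(trace)
    flagged = set(np.flatnonzero(fd > config.fd_threshold_mm).tolist())
    g = ts.values.mean(axis=1)
    dg = np.diff(g)
    sd = dg.std()
    # an essentially constant global mean has no intensity outliers
    if sd > 1e-10 * (np.abs(g).mean() + 1.0):
        z = np.zeros_like(g)
        z[1:] = (dg - dg.mean()) / sd
        flagged |= set(np.flatnonzero(np.abs(z) > config.intensity_z_threshold).tolist())
    return flagged


def compcor_components(noise_voxels: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component timecourses of a V x T noise-voxel matrix.

    Each voxel's timecourse is mean-centred; components are the leading
    right singular vectors, returned as a k x T array with unit
    variance, ordered by explained variance.  If k exceeds the matrix
    rank, the available components are returned with a warning.
    """
    if k == 0:
        return np.empty((0, np.asarray(noise_voxels).shape[1]))
    x = np.asarray(noise_voxels, dtype=float)
    if x.ndim != 2:
        raise ValueError("noise voxels must be V x T")
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}")
        k = rank
    comps = vt[:k]
    sd = comps.std(axis=1, keepdims=True)
    return comps / np.where(sd > 0, sd, 1.0)


def _dct_basis(t: int) -> tuple[np.ndarray, np.ndarray]:
    """DCT-II style cosine basis (columns k=1..T-1) and their frequencies (cycles/sample)."""
    n = np.arange(t)[:, None]
    k = np.arange(1, t)[None, :]
    basis = np.cos(np.pi * (n + 0.5) * k / t)
    freq = k.ravel() / (2.0 * t)
    return basis, freq


def build_nuisance_design(
    trace: MotionTrace | None,
    components: np.ndarray | None,
    spikes: set[int] | frozenset[int],
    config: DenoiseConfig,
    n_volumes: int,
    tr_seconds: float,
    global_signal: np.ndarray | None = None,
) -> NuisanceDesign:
    """Assemble the simultaneous nuisance design.

    Columns: intercept; 6 motion parameters (+ backward-difference
    derivatives if configured); CompCor components; one one-hot spike
    column per flagged volume; cosine columns at every frequency outside
    ``band_hz`` (band-pass by regression); and the global signal when
    ``use_gsr`` is set.  Collinear columns are dropped with a warning,
    and if the design would leave fewer than 10 residual degrees of
    freedom the highest-frequency cosine columns are trimmed (warned).
    """
    config.validate(tr_seconds)
    cols: list[np.ndarray] = [np.ones(n_volumes)]
    roles: list[str] = ["intercept"]

    if trace is not None:
        if trace.n_volumes != n_volumes:
            raise ValueError("motion trace length mismatch")
        for i in range(6):
            cols.append(trace.params[:, i])
            roles.append("motion")
        if config.motion_derivatives:
            for i in range(6):
                d = np.zeros(n_volumes)
                d[1:] = np.diff(trace.params[:, i])
                cols.append(d)
                roles.append("derivative")

    if components is not None and len(components):
        comps = np.asarray(components, dtype=float)
        if comps.shape[1] != n_volumes:
            raise ValueError("component length mismatch")
        for c in comps:
            cols.append(c)
            roles.append("compcor")

    for v in sorted(spikes):
        if not 0 <= v < n_volumes:
            raise ValueError(f"spike index {v} out of range")
        onehot = np.zeros(n_volumes)
        onehot[v] = 1.0
        cols.append(onehot)
        roles.append("spike")

    basis, freq_cps = _dct_basis(n_volumes)
    freq_hz = freq_cps / tr_seconds
    low, high = config.band_hz
    outside = (freq_hz < low) | (freq_hz > high)
    for idx in np.flatnonzero(outside):
        cols.append(basis[:, idx])
        roles.append("cosine")

    if config.use_gsr:
        if global_signal is None:
            raise ValueError("use_gsr requires a global signal timecourse")
        gs = np.asarray(global_signal, dtype=float).ravel()
        if gs.shape[0] != n_volumes:
            raise ValueError("global signal length mismatch")
        cols.append(gs)
        roles.append("global")

    matrix = np.column_stack(cols)
    min_dof = 10
    excess = matrix.shape[1] - (n_volumes - min_dof)
    if excess > 0:
        cosine_idx = [j for j, role in enumerate(roles) if role == "cosine"]
        drop = set(cosine_idx[-excess:])  # highest frequencies last
        warnings.warn(
            f"trimmed {len(drop)} high-frequency cosine column(s) to keep "
            f">= {min_dof} residual dof"
        )
        keep = [j for j in range(matrix.shape[1]) if j not in drop]
        matrix = matrix[:, keep]
        roles = [roles[j] for j in keep]
    matrix, roles = _drop_collinear(matrix, roles)
    return NuisanceDesign(matrix, roles)


def _drop_collinear(matrix: np.ndarray, roles: list[str]):
    """Greedy QR-based removal of numerically dependent columns.

    Spike columns take priority: when a spike regressor is collinear
    with other columns (e.g. an isolated motion impulse), the competing
    column is dropped instead, preserving the exact-zero scrubbing
    contract.  Column order in the output is unchanged.
    """
    priority = sorted(range(matrix.shape[1]),
                      key=lambda j: (roles[j] != "spike", j))
    keep: list[int] = []
    q: np.ndarray | None = None
    for j in priority:
        col = matrix[:, j]
        if q is not None:
            resid = col - q @ (q.T @ col)
        else:
            resid = col
        norm = np.linalg.norm(resid)
        if norm > 1e-10 * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            qcol = (resid / norm)[:, None]
            q = qcol if q is None else np.hstack([q, qcol])
    if len(keep) < matrix.shape[1]:
        warnings.warn(f"dropped {matrix.shape[1] - len(keep)} collinear design column(s)")
    keep.sort()
    return matrix[:, keep], [roles[j] for j in keep]


def regress_nuisance(ts: RoiTimeseries, design: NuisanceDesign) -> RoiTimeseries:
    """OLS residuals of every region on the nuisance design.

    Rows carrying a spike (scrubbing) regressor are analytically zero;
    they are set to exactly zero to remove floating-point residue.
    """
    y = ts.values
    x = design.matrix
    if y.shape[0] <= x.shape[1]:
        raise ValueError(
            f"insufficient degrees of freedom: T={y.shape[0]} <= K={x.shape[1]}"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    for j, role in enumerate(design.roles):
        if role == "spike":
            resid[x[:, j] == 1.0] = 0.0
    return RoiTimeseries(resid, ts.tr_seconds, list(ts.region_labels), normalized=True)


def denoise_timeseries(
    ts: RoiTimeseries,
    trace: MotionTrace | None = None,
    noise_voxels: np.ndarray | None = None,
    config: DenoiseConfig = DenoiseConfig(),
) -> tuple[RoiTimeseries, dict]:
    """Full ROI-level denoising chain.

    Percent-signal-change normalisation, outlier detection, design
    assembly and nuisance regression; returns the residual timeseries
    plus a QC dictionary (outlier count, FD statistics, RMSD, design
    width).  The global signal for GSR is the region-mean timecourse of
    the normalised data (a region-level proxy for the whole-brain voxel
    mean).
    """
    config.validate(ts.tr_seconds)
    psc = percent_signal_change(ts) if not ts.normalized else ts
    if trace is not None:
        spikes = detect_outlier_volumes(psc, trace, config)
        fd = framewise_displacement(trace)
        qc_motion = {
            "n_outliers": len(spikes),
            "fd_mean_mm": float(fd.mean()),
            "fd_max_mm": float(fd.max()),
            "rmsd_mm": rmsd_summary(trace) if trace.n_volumes >= 2 else 0.0,
        }
    else:
        spikes = set()
        qc_motion = {"n_outliers": 0, "fd_mean_mm": 0.0, "fd_max_mm": 0.0, "rmsd_mm": 0.0}
    comps = (
        compcor_components(noise_voxels, config.n_compcor)
        if noise_voxels is not None and config.n_compcor > 0
        else None
    )
    gs = psc.values.mean(axis=1) if config.use_gsr else None
    design = build_nuisance_design(
        trace, comps, spikes, config, psc.n_volumes, psc.tr_seconds, gs
    )
    resid = regress_nuisance(psc, design)
    qc = {**qc_motion, "n_design_columns": design.n_columns, "use_gsr": config.use_gsr}
    return resid, qc
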