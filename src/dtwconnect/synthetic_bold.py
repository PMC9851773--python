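"""Synthetic multi-subject BOLD generator with known ground truth.

Emulates a SimTB-style simulation at desk scale: latent Poisson event
trains are mixed through a region-by-source coupling matrix, convolved
with a double-gamma hemodynamic response whose time-to-peak varies per
region, optionally shifted in time per region (BOLD lag), given a
baseline and Rician magnitude noise at a per-subject contrast-to-noise
ratio, and optionally contaminated by a shared respiration-like global
component and by rigid head motion acting on 2-D spatial component
maps.  Two-group cohorts with injected edge differences (coupling, lag
or HRF deltas) provide ground truth for the downstream inference,
reliability and classification analyses.

Defaults follow the published simulation design: 20 subjects, 25
regions, 180 volumes at TR = 2 s, CNR uniform on [0.65, 2], motion
bounded by 0.02 mm translation and 5 degrees rotation, 300 voxels laid
out as a 20 x 15 grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .denoise import MotionTrace, RoiTimeseries, rmsd_summary

__all__ = [
    "SimConfig",
    "SubjectScan",
    "SimulatedCohort",
    "default_coupling",
    "generate_neural_timecourses",
    "hrf_kernel",
    "convolve_hrf",
    "add_rician_noise",
    "generate_motion_trace",
    "make_component_maps",
    "composite_displacement_mm",
    "simulate_motion_corruption",
    "inject_global_signal",
    "generate_subject_fluctuations",
    "generate_subject_timecourses",
    "generate_cohort",
    "generate_group_dataset",
]

BASELINE = 100.0  # signal offset so magnitude (Rician) noise acts on a positive signal
HRF_PEAK_SECONDS = 5.0  # mode of the canonical double-gamma response
HRF_LENGTH_SECONDS = 32.0


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study's simulation conditions."""

    n_subjects: int = 20
    n_regions: int = 25
    n_volumes: int = 180
    tr_seconds: float = 2.0
    cnr_range: tuple[float, float] = (0.65, 2.0)
    max_translation_mm: float = 0.02
    max_rotation_deg: float = 5.0
    global_amplitude: float = 0.0
    lag_range_seconds: tuple[float, float] = (0.0, 0.0)
    hrf_delay_jitter_seconds: float = 0.5
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    spin_history_pct_per_mm: float = 0.5
    event_rate_per_tr: float = 0.25
    unique_event_rate_per_tr: float = 0.05
    coupling: np.ndarray | None = None
    group_effects: tuple[tuple[tuple[int, int], str, float], ...] = ()
    grid_shape: tuple[int, int] = (20, 15)
    mm_per_voxel: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_regions, self.n_volumes) <= 0:
            raise ValueError("dimensions must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        lo, hi = self.cnr_range
        if not (0 < lo <= hi):
            raise ValueError("cnr_range must satisfy 0 < low <= high")
        if self.max_translation_mm < 0 or self.max_rotation_deg < 0:
            raise ValueError("motion bounds must be nonnegative")
        if self.global_amplitude < 0:
            raise ValueError("global_amplitude must be nonnegative")
        if self.coupling is not None:
            c = np.asarray(self.coupling, dtype=float)
            if c.shape != (self.n_regions, self.n_regions):
                raise ValueError("coupling must be n_regions x n_regions")
            object.__setattr__(self, "coupling", c)
        for (i, j), kind, _mag in self.group_effects:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                raise ValueError(f"group-effect edge ({i},{j}) out of range")
            if kind not in ("coupling-delta", "lag-delta", "hrf-delta"):
                raise ValueError(f"unknown group-effect kind {kind!r}")

    def resolved_coupling(self) -> np.ndarray:
        if self.coupling is not None:
            return np.asarray(self.coupling, dtype=float)
        return default_coupling(self.n_regions)


@dataclass
class SubjectScan:
    """One subject-scan with its ground-truth nuisance components."""

    subject_id: str
    group: str
    seed: int
    timeseries: RoiTimeseries
    motion: MotionTrace
    noise_voxels: np.ndarray  # "CSF/WM"-like voxels for CompCor testing
    global_component: np.ndarray
    rmsd: float = 0.0
    cnr: float = 1.0
    fluctuations: np.ndarray | None = None  # clean R x T BOLD fluctuation


@dataclass
class SimulatedCohort:
    """Multi-subject dataset plus the ground truth that generated it."""

    config: SimConfig
    scans: list[SubjectScan]
    coupling: np.ndarray
    region_lags_seconds: np.ndarray
    hrf_delays_seconds: np.ndarray
    region_amplitudes: np.ndarray | None = None
    group_coupling: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return sorted({s.group for s in self.scans})


def default_coupling(n_regions: int, n_modules: int = 5, within: float = 0.45) -> np.ndarray:
    """Modular ground-truth mixing weights.

    Regions are partitioned into ``n_modules`` contiguous communities;
    each region loads 1.0 on its own latent source and ``within`` on the
    sources of its community siblings, giving block-structured true
    connectivity.
    """
    c = np.eye(n_regions)
    labels = np.arange(n_regions) % n_modules
    same = labels[:, None] == labels[None, :]
    c[same & ~np.eye(n_regions, dtype=bool)] = within
    return c


def generate_neural_timecourses(config: SimConfig, subject_seed: int) -> np.ndarray:
    """R x T neural activations from mixed latent Poisson event trains.

    One latent event train per region-source (Bernoulli per TR at
    ``event_rate_per_tr``, amplitudes ~ N(1, 0.3)); region r's
    activation is coupling[r, :] @ trains plus its own unique events at
    ``unique_event_rate_per_tr``.
    """
    rng = np.random.default_rng(subject_seed)
    r, t = config.n_regions, config.n_volumes
    coupling = config.resolved_coupling()
    trains = (rng.random((r, t)) < config.event_rate_per_tr) * rng.normal(
        1.0, 0.3, (r, t)
    )
    neural = coupling @ trains
    if config.unique_event_rate_per_tr > 0:
        unique = (rng.random((r, t)) < config.unique_event_rate_per_tr) * rng.normal(
            1.0, 0.3, (r, t)
        )
        neural = neural + unique
    return neural


def hrf_kernel(tr_seconds: float, delay_shift_seconds: float = 0.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, time-to-peak shifted by
    ``delay_shift`` via an area-conserving time dilation.

    The base response is gamma(shape 6, scale 1) minus
    gamma(shape 16, scale 1)/6, mode at ~5 s, peak scaled to 1.  A
    delayed response is modelled as the dilated kernel
    ``h_d(t) = s * h0(s * t)`` with ``s = 5 / (5 + delay)``: the peak
    moves to ``5 + delay`` s, the response widens proportionally and its
    peak amplitude drops by the same factor (area conserved) —
    hemodynamic responses that peak later are empirically broader and
    shallower, so a delay shift changes the BOLD fluctuation amplitude,
    not just its phase.  A shift that would put the peak at or before
    time zero is rejected.
    """
    from scipy.stats import gamma as gamma_dist

    if HRF_PEAK_SECONDS + delay_shift_seconds <= 0:
        raise ValueError(
            f"delay shift {delay_shift_seconds} s would put the HRF peak at negative time"
        )
    scale = HRF_PEAK_SECONDS / (HRF_PEAK_SECONDS + delay_shift_seconds)
    t = np.arange(0, HRF_LENGTH_SECONDS / scale, tr_seconds)
    ts = t * scale
    h = (gamma_dist.pdf(ts, a=6) - gamma_dist.pdf(ts, a=16) / 6.0) * scale
    peak0 = gamma_dist.pdf(HRF_PEAK_SECONDS, a=6) - gamma_dist.pdf(HRF_PEAK_SECONDS, a=16) / 6.0
    return h / peak0


def convolve_hrf(
    neural: np.ndarray, tr_seconds: float, delay_shift_seconds: float = 0.0
) -> np.ndarray:
    """Convolve a 1-D activation train with the (shifted) canonical HRF.

    Linear convolution truncated to the input length.  Requires the
    series to be at least as long as the kernel.
    """
    x = np.asarray(neural, dtype=float).ravel()
    h = hrf_kernel(tr_seconds, delay_shift_seconds)
    if x.shape[0] < h.shape[0]:
        raise ValueError(
            f"series length {x.shape[0]} shorter than HRF kernel ({h.shape[0]} samples)"
        )
    return np.convolve(x, h)[: x.shape[0]]


def add_rician_noise(
    signal: np.ndarray, cnr: float, seed: int, sigma: float | None = None
) -> np.ndarray:
    """Rician (magnitude-MRI) noise at a given contrast-to-noise ratio.

    The noise-free signal is the in-phase channel:
    ``out = sqrt((s + g1)^2 + g2^2)`` with g1, g2 ~ N(0, sigma).  Unless
    given explicitly, ``sigma = SD(s) / cnr`` so the temporal SD of the
    clean fluctuation over the noise SD equals ``cnr``.  Meaningful for
    signals riding on a positive baseline (the magnitude operation
    rectifies signals near zero).
    """
    if cnr <= 0:
        raise ValueError("cnr must be positive")
    s = np.asarray(signal, dtype=float)
    if sigma is None:
        sigma = float(s.std()) / cnr
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, 1.0, s.shape) * sigma
    g2 = rng.normal(0.0, 1.0, s.shape) * sigma
    return np.sqrt((s + g1) ** 2 + g2**2)


def _reflect(x: np.ndarray, bound: float) -> np.ndarray:
    """Fold an unbounded walk into [-bound, bound] (triangle-wave reflection)."""
    if bound == 0:
        return np.zeros_like(x)
    period = 4.0 * bound
    y = np.mod(x + bound, period)
    return np.abs(y - 2.0 * bound) - bound


def generate_motion_trace(config: SimConfig, seed: int) -> MotionTrace:
    """Smooth bounded 6-parameter head-motion trace.

    Each parameter is a Gaussian random walk, low-pass smoothed, then
    rescaled and reflected so its excursion stays within the configured
    translation/rotation bounds.  The bounds are caps: each subject
    draws a severity factor on [0.3, 1] so that motion varies across
    participants while never exceeding the configured maxima.  Zero
    bounds give an all-zero trace.
    """
    rng = np.random.default_rng(seed)
    t = config.n_volumes
    params = np.zeros((t, 6))
    severity = rng.uniform(0.3, 1.0)
    bounds = [config.max_translation_mm] * 3 + [config.max_rotation_deg] * 3
    k = min(21, t)  # slow drift: framewise steps stay mostly below scrubbing thresholds
    kernel = np.ones(k) / k
    for i, bound in enumerate(bounds):
        if bound == 0:
            continue
        walk = np.cumsum(rng.normal(0.0, 1.0, t))
        walk = np.convolve(walk, kernel, mode="same")
        walk -= walk[0]
        peak = np.abs(walk).max()
        if peak > 0:
            walk *= (1.2 * severity * bound) / peak  # overshoot a little, then reflect
        params[:, i] = _reflect(walk, severity * bound)
    return MotionTrace(params)


def make_component_maps(
    n_regions: int, grid_shape: tuple[int, int], blob_sigma: float = 1.2, seed: int = 0
) -> np.ndarray:
    """Gaussian-blob spatial maps, one per region, on a 2-D voxel grid.

    Blob centres are placed on a jittered regular lattice covering the
    grid; returns an R x V array (V = prod(grid_shape)) with each map
    normalised to peak 1.
    """
    nx, ny = grid_shape
    if nx < 4 or ny < 4:
        raise ValueError("grid too small for component maps")
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n_regions * nx / ny)))
    nrows = int(np.ceil(n_regions / ncols))
    xs = np.linspace(1.5, nx - 2.5, ncols)
    ys = np.linspace(1.5, ny - 2.5, nrows)
    centers = [(x, y) for y in ys for x in xs][:n_regions]
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    maps = np.empty((n_regions, nx * ny))
    for r, (cx, cy) in enumerate(centers):
        cx += rng.uniform(-0.5, 0.5)
        cy += rng.uniform(-0.5, 0.5)
        blob = np.exp(-(((gx - cx) ** 2 + (gy - cy) ** 2) / (2.0 * blob_sigma**2)))
        maps[r] = blob.ravel()
    return maps


def composite_displacement_mm(trace: MotionTrace) -> np.ndarray:
    """Per-volume absolute displacement from the reference position (mm).

    Sum of absolute translations plus rotations converted to arc length
    on a 50 mm sphere — the same convention used for framewise
    displacement, but relative to the reference rather than the
    previous volume.
    """
    return (
        np.abs(trace.translations_mm).sum(axis=1)
        + np.abs(np.deg2rad(trace.rotations_deg)).sum(axis=1) * 50.0
    )


def simulate_motion_corruption(
    component_maps: np.ndarray,
    component_timecourses: np.ndarray,
    trace: MotionTrace,
    grid_shape: tuple[int, int],
    mm_per_voxel: float = 3.0,
    tr_seconds: float = 2.0,
    mask_threshold: float = 0.1,
    baseline: float = 0.0,
    spin_history_pct_per_mm: float = 0.5,
) -> tuple[np.ndarray, RoiTimeseries]:
    """Rigid-motion corruption of spatially mixed component data.

    Two motion effects are modelled.  First, per volume the composite
    fluctuation image (sum over regions of map x timecourse value) is
    rigidly shifted (translations in mm mapped to voxels through
    ``mm_per_voxel``; in-plane rotation taken from the third rotation
    parameter) with linear interpolation and constant zero padding,
    which mixes and modulates regional signals.  Second, a
    spin-history-like whole-volume intensity modulation scales the
    total image (including the spatially uniform tissue ``baseline``)
    by ``1 - spin_history_pct_per_mm/100 x displacement(t)`` — the
    global intensity artifact head motion produces in EPI, and the
    reason motion couples to the global signal.

    ROI timeseries are means over each component's *original* support
    mask (map > mask_threshold x peak), so a zero trace reproduces the
    unmoved data (plus baseline) exactly.

    Returns the V x T corrupted voxel matrix and the corrupted
    RoiTimeseries.
    """
    maps = np.asarray(component_maps, dtype=float)
    tcs = np.asarray(component_timecourses, dtype=float)
    nx, ny = grid_shape
    if maps.shape[1] != nx * ny:
        raise ValueError("map size does not match grid shape")
    if maps.shape[0] != tcs.shape[0]:
        raise ValueError("one timecourse per map required")
    t = tcs.shape[1]
    if trace.n_volumes != t:
        raise ValueError("trace length must equal number of volumes")
    if nx < 4 or ny < 4:
        raise ValueError("grid too small for rotation padding")

    masks = maps > mask_threshold * maps.max(axis=1, keepdims=True)
    mask_sizes = masks.sum(axis=1)
    voxels = np.empty((nx * ny, t))
    center = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])
    shifts_vox = trace.translations_mm[:, :2] / mm_per_voxel
    angles_rad = np.deg2rad(trace.rotations_deg[:, 2])
    intensity = 1.0 - (spin_history_pct_per_mm / 100.0) * composite_displacement_mm(trace)

    for v in range(t):
        image = (maps.T @ tcs[:, v]).reshape(nx, ny)
        theta = angles_rad[v]
        shift = shifts_vox[v]
        if theta == 0.0 and not shift.any():
            moved = image
        else:
            # inverse map: output(x) = input(R^T (x - c - s) + c)
            cos_t, sin_t = np.cos(theta), np.sin(theta)
            rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
            offset = center + shift - rot.T @ center
            moved = ndimage.affine_transform(
                image, rot.T, offset=offset, order=1, mode="constant", cval=0.0
            )
        voxels[:, v] = intensity[v] * (moved.ravel() + baseline)

    roi = (masks @ voxels) / mask_sizes[:, None]
    ts = RoiTimeseries(roi.T, tr_seconds)
    return voxels, ts


def _band_limited_noise(
    t: int, tr_seconds: float, bands_hz: list[tuple[float, float]], rng
) -> np.ndarray:
    """Unit-SD timecourse with power restricted to the given bands."""
    white = rng.normal(0.0, 1.0, t)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = np.zeros_like(freqs, dtype=bool)
    for lo, hi in bands_hz:
        keep |= (freqs >= lo) & (freqs <= hi)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=t)
    sd = out.std()
    return out / sd if sd > 0 else out


def inject_global_signal(
    data: RoiTimeseries,
    amplitude: float,
    seed: int,
    bands_hz: list[tuple[float, float]] | None = None,
    region_lags_seconds: np.ndarray | None = None,
) -> tuple[RoiTimeseries, np.ndarray]:
    """Add a shared band-limited (respiration-like + drift) component.

    One unit-SD timecourse with power in the given bands (default
    aliased-respiration 0.2-0.35 Hz plus 0.01-0.05 Hz drift, truncated
    at Nyquist) is scaled by ``amplitude`` and added to every region,
    optionally delayed per region by ``region_lags_seconds`` (rounded to
    whole samples).  Returns the contaminated timeseries and the global
    timecourse itself.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    t, tr = data.n_volumes, data.tr_seconds
    nyq = 1.0 / (2.0 * tr)
    if bands_hz is None:
        bands_hz = [(0.01, 0.05), (0.2, 0.35)]
    bands_hz = [(lo, min(hi, nyq)) for lo, hi in bands_hz if lo < nyq]
    rng = np.random.default_rng(seed)
    g = _band_limited_noise(t, tr, bands_hz, rng)
    if amplitude == 0:
        return data, np.zeros(t)
    out = data.values.copy()
    for r in range(data.n_regions):
        lag = 0
        if region_lags_seconds is not None:
            lag = int(round(region_lags_seconds[r] / tr))
        out[:, r] = out[:, r] + amplitude * np.roll(g, lag)
    ts = RoiTimeseries(out, tr, list(data.region_labels), data.normalized)
    return ts, amplitude * g


def _draw_region_params(config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort-level per-region BOLD lags, HRF delay shifts and amplitudes."""
    lo, hi = config.lag_range_seconds
    lags = rng.uniform(lo, hi, config.n_regions) if hi > lo else np.zeros(config.n_regions)
    if config.hrf_delay_jitter_seconds > 0:
        delays = rng.uniform(
            -config.hrf_delay_jitter_seconds,
            config.hrf_delay_jitter_seconds,
            config.n_regions,
        )
    else:
        delays = np.zeros(config.n_regions)
    alo, ahi = config.amplitude_range
    amps = rng.uniform(alo, ahi, config.n_regions) if ahi > alo else np.full(
        config.n_regions, alo)
    return lags, delays, amps


def generate_subject_fluctuations(
    config: SimConfig,
    subject_seed: int,
    coupling: np.ndarray,
    region_lags_seconds: np.ndarray,
    hrf_delays_seconds: np.ndarray,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Clean R x T BOLD fluctuations for one subject-scan.

    Pipeline: latent events -> coupling mix -> per-region HRF (shifted
    time-to-peak) -> per-region temporal lag (circular shift in whole
    samples) -> global rescale to unit SD -> per-region amplitude.
    Regional amplitude heterogeneity reflects the documented spatial
    variability of BOLD fluctuation magnitude.
    """
    cfg = replace(config, coupling=coupling)
    neural = generate_neural_timecourses(cfg, subject_seed)
    bold = np.empty_like(neural)
    for r in range(config.n_regions):
        b = convolve_hrf(neural[r], config.tr_seconds, hrf_delays_seconds[r])
        lag = int(round(region_lags_seconds[r] / config.tr_seconds))
        bold[r] = np.roll(b, lag)
    sd = bold.std()
    if sd > 0:
        bold = bold / sd  # common scale so BASELINE/CNR are comparable across draws
    if amplitudes is not None:
        bold = bold * np.asarray(amplitudes, dtype=float)[:, None]
    return bold


def generate_subject_timecourses(
    config: SimConfig,
    subject_seed: int,
    coupling: np.ndarray,
    region_lags_seconds: np.ndarray,
    hrf_delays_seconds: np.ndarray,
    cnr: float,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Noisy R x T BOLD timecourses: fluctuations + baseline + Rician noise.

    The noise SD is calibrated to the pre-amplitude fluctuation scale
    (unit SD) over the requested contrast-to-noise ratio.
    """
    bold = generate_subject_fluctuations(
        config, subject_seed, coupling, region_lags_seconds, hrf_delays_seconds,
        amplitudes,
    )
    noisy = add_rician_noise(
        bold + BASELINE, cnr, seed=subject_seed + 7_654_321, sigma=1.0 / cnr
    )
    return noisy


def _make_noise_voxels(global_component: np.ndarray, rng, n_voxels: int = 40) -> np.ndarray:
    """CSF/WM-like voxel matrix: shared physiological component + drift + noise."""
    t = global_component.shape[0]
    drift = np.linspace(-1.0, 1.0, t)
    weights = rng.uniform(0.5, 1.5, (n_voxels, 1))
    dweights = rng.uniform(-0.5, 0.5, (n_voxels, 1))
    noise = rng.normal(0.0, 0.3, (n_voxels, t))
    return weights * global_component[None, :] + dweights * drift[None, :] + noise


def generate_cohort(
    config: SimConfig,
    group: str = "A",
    seed_offset: int = 0,
    coupling: np.ndarray | None = None,
    region_lags_seconds: np.ndarray | None = None,
    hrf_delays_seconds: np.ndarray | None = None,
    region_amplitudes: np.ndarray | None = None,
) -> SimulatedCohort:
    """Single-group cohort under the configured generative conditions.

    Per subject: CNR drawn uniform from ``cnr_range``, fresh latent
    events and noise, a bounded motion trace, a shared global component
    at ``global_amplitude`` (with per-region lags when configured) and a
    CompCor-testable noise-voxel block.  Regional parameters (coupling,
    BOLD lags, HRF delays) may be supplied explicitly — this is how
    two-group cohorts inject effects — otherwise they are drawn from
    the cohort seed.  Identical config and seed give a bit-identical
    cohort.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    drawn_lags, drawn_delays, drawn_amps = _draw_region_params(config, rng)
    coupling = config.resolved_coupling() if coupling is None else np.asarray(coupling, float)
    lags = drawn_lags if region_lags_seconds is None else np.asarray(region_lags_seconds, float)
    delays = drawn_delays if hrf_delays_seconds is None else np.asarray(hrf_delays_seconds, float)
    amps = drawn_amps if region_amplitudes is None else np.asarray(region_amplitudes, float)
    scans = []
    for s in range(config.n_subjects):
        subject_seed = int(rng.integers(0, 2**31 - 1))
        cnr = float(rng.uniform(*config.cnr_range))
        fluct = generate_subject_fluctuations(config, subject_seed, coupling, lags,
                                              delays, amps)
        bold = add_rician_noise(fluct + BASELINE, cnr,
                                seed=subject_seed + 7_654_321, sigma=1.0 / cnr)
        ts = RoiTimeseries(bold.T, config.tr_seconds)
        gcomp = np.zeros(config.n_volumes)
        if config.global_amplitude > 0:
            ts, gcomp = inject_global_signal(
                ts,
                config.global_amplitude,
                seed=subject_seed + 999_331,
                region_lags_seconds=lags if lags.any() else None,
            )
        trace = generate_motion_trace(config, seed=subject_seed + 555_117)
        sub_rng = np.random.default_rng(subject_seed + 222_003)
        noise_vox = _make_noise_voxels(gcomp if gcomp.any() else
                                       _band_limited_noise(config.n_volumes,
                                                           config.tr_seconds,
                                                           [(0.2, min(0.35, 1/(2*config.tr_seconds)))],
                                                           sub_rng),
                                       sub_rng)
        scans.append(
            SubjectScan(
                subject_id=f"sub-{group}{s:03d}",
                group=group,
                seed=subject_seed,
                timeseries=ts,
                motion=trace,
                noise_voxels=noise_vox,
                global_component=gcomp,
                rmsd=rmsd_summary(trace) if config.n_volumes >= 2 else 0.0,
                cnr=cnr,
                fluctuations=fluct,
            )
        )
    return SimulatedCohort(config, scans, coupling, lags, delays, amps)


def _apply_group_effects(
    config: SimConfig,
    coupling: np.ndarray,
    lags: np.ndarray,
    delays: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Altered generative parameters for the second group."""
    c2, l2, d2 = coupling.copy(), lags.copy(), delays.copy()
    for (i, j), kind, mag in config.group_effects:
        if kind == "coupling-delta":
            c2[i, j] += mag
            c2[j, i] += mag
        elif kind == "lag-delta":
            l2[i] += mag  # the edge's source region is shifted in time
        elif kind == "hrf-delta":
            d2[i] += mag
    return c2, l2, d2


def generate_group_dataset(config: SimConfig) -> SimulatedCohort:
    """Two-group cohort with injected edge differences.

    Groups of ``n_subjects // 2`` share every generative parameter
    except the listed ``group_effects``, applied to group B:
    ``coupling-delta`` changes the mixing weight of an edge,
    ``lag-delta`` shifts the edge's source region's BOLD in time, and
    ``hrf-delta`` changes that region's HRF time-to-peak.  With empty
    ``group_effects`` the cohort is null.
    """
    rng = np.random.default_rng(config.seed)
    coupling = config.resolved_coupling()
    lags, delays, amps = _draw_region_params(config, rng)
    c2, l2, d2 = _apply_group_effects(config, coupling, lags, delays)
    n_half = config.n_subjects // 2
    cohort_a = generate_cohort(
        replace(config, n_subjects=n_half),
        group="A",
        seed_offset=1,
        coupling=coupling,
        region_lags_seconds=lags,
        hrf_delays_seconds=delays,
        region_amplitudes=amps,
    )
    cohort_b = generate_cohort(
        replace(config, n_subjects=config.n_subjects - n_half),
        group="B",
        seed_offset=2,
        coupling=c2,
        region_lags_seconds=l2,
        hrf_delays_seconds=d2,
        region_amplitudes=amps,
    )
    return SimulatedCohort(
        config,
        cohort_a.scans + cohort_b.scans,
        coupling,
        lags,
        delays,
        region_amplitudes=cohort_a.region_amplitudes,
        group_coupling={"A": coupling, "B": c2},
    )
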