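"""End-to-end synthetic analyses and pipeline orchestration.

Chains the generator, denoising, both FC estimators and the downstream
statistics into the five study analyses, each runnable on a synthetic
cohort with known ground truth:

1. motion robustness — FC before/after rigid-motion corruption of the
   spatially mixed data; per-subject median absolute percent change per
   estimator, compared with a paired t-test;
2. GSR robustness — FC from denoising without vs with global signal
   regression on data carrying a shared respiration-like component;
3. test-retest reliability — FC-pattern similarity of two scans per
   subject sharing ground truth but not noise;
4. group differences — edgewise two-sample tests, p-value enrichment
   (1 - pi0), ROI involvement counts, and PCA+SVM classification on a
   two-group cohort with injected edge effects;
5. behavior/confound screens — edgewise partial correlations against a
   subject-level score controlling for head motion (RMSD).

``run_pipeline`` executes the analyses from a YAML-backed
``PipelineConfig`` and writes one JSON report plus provenance sidecars.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as dio
from .classification import (
    ClassificationConfig,
    compare_accuracy_distributions,
    svm_cv_accuracy,
    vectorize_fc,
)
from .comparison_metrics import abs_percent_change, fc_pattern_similarity, paired_t, test_retest
from .denoise import DenoiseConfig, MotionTrace, RoiTimeseries, denoise_timeseries, percent_signal_change
from .fc_core import DtwConfig, FcMatrix, dtw_similarity_matrix, pearson_fc_matrix
from .group_inference import (
    edgewise_partial_corr,
    edgewise_two_sample_t,
    estimate_pi0,
    repeated_measures_anova_2x3,
    roi_involvement_counts,
)
from .synthetic_bold import (
    BASELINE,
    SimConfig,
    SimulatedCohort,
    _draw_region_params,
    add_rician_noise,
    generate_cohort,
    generate_group_dataset,
    generate_subject_fluctuations,
    inject_global_signal,
    make_component_maps,
    simulate_motion_corruption,
)

logger = logging.getLogger("dtwconnect")

__all__ = [
    "PipelineConfig",
    "estimate_both",
    "run_motion_analysis",
    "run_gsr_analysis",
    "run_task_analysis",
    "run_test_retest_analysis",
    "run_group_difference_analysis",
    "run_confound_analysis",
    "run_classification_analysis",
    "run_pipeline",
    "write_cohort",
]

ESTIMATORS = ("pearson", "dtw")


def estimate_both(
    ts: RoiTimeseries, dtw_config: DtwConfig, subject_id: str = "", scan_id: str = ""
) -> dict[str, FcMatrix]:
    """Pearson-z and DTW-similarity FC matrices of one (normalised) scan."""
    if not ts.normalized:
        ts = percent_signal_change(ts)
    return {
        "pearson": pearson_fc_matrix(ts, subject_id, scan_id),
        "dtw": dtw_similarity_matrix(ts, dtw_config, subject_id, scan_id),
    }


# ---------------------------------------------------------------- analysis 1

def run_motion_analysis(config: SimConfig, dtw_config: DtwConfig = DtwConfig()) -> dict:
    """Motion robustness on a simulated cohort.

    For every subject the region timecourses are mixed onto 2-D spatial
    maps and read back through the regions' support masks twice: once
    with a zero motion trace (baseline) and once with the subject's
    bounded motion trace.  Both estimators' FC is compared between the
    runs; the headline statistic is the paired t-test across subjects
    of the per-subject median absolute percent change (Pearson vs DTW).
    """
    cohort = generate_cohort(config)
    maps = make_component_maps(config.n_regions, config.grid_shape, seed=config.seed + 11)
    masks = maps > 0.1 * maps.max(axis=1, keepdims=True)
    mask_sizes = masks.sum(axis=1, keepdims=True)
    zero = MotionTrace(np.zeros((config.n_volumes, 6)))
    med = {e: [] for e in ESTIMATORS}
    sim = {e: [] for e in ESTIMATORS}
    for scan in cohort.scans:
        fluct = scan.fluctuations
        common = dict(
            component_maps=maps,
            component_timecourses=fluct,
            grid_shape=config.grid_shape,
            mm_per_voxel=config.mm_per_voxel,
            tr_seconds=config.tr_seconds,
            baseline=BASELINE,
            spin_history_pct_per_mm=config.spin_history_pct_per_mm,
        )
        runs = {}
        for run_id, trace in (("still", zero), ("motion", scan.motion)):
            voxels, _ = simulate_motion_corruption(trace=trace, **common)
            # thermal (Rician) noise at the voxel level, identical between the
            # runs: scanner noise does not depend on head position
            noisy = add_rician_noise(voxels, scan.cnr, seed=scan.seed + 31_337,
                                     sigma=1.0 / scan.cnr)
            roi = (masks @ noisy) / mask_sizes
            runs[run_id] = RoiTimeseries(roi.T, config.tr_seconds)
        fc_still = estimate_both(runs["still"], dtw_config, scan.subject_id, "still")
        fc_moved = estimate_both(runs["motion"], dtw_config, scan.subject_id, "motion")
        for e in ESTIMATORS:
            cmp = abs_percent_change(fc_still[e], fc_moved[e])
            med[e].append(cmp.median_abs_pct_change)
            sim[e].append(cmp.pattern_similarity)
    t_med, df, p_med = paired_t(med["pearson"], med["dtw"])
    t_sim, _, p_sim = paired_t(sim["pearson"], sim["dtw"])
    return {
        "n_subjects": config.n_subjects,
        "median_abs_pct_change": {e: np.asarray(med[e]) for e in ESTIMATORS},
        "pattern_similarity": {e: np.asarray(sim[e]) for e in ESTIMATORS},
        "paired_t_median_pct_change": {"t": t_med, "df": df, "p": p_med},
        "paired_t_pattern_similarity": {"t": t_sim, "df": df, "p": p_sim},
    }


# ---------------------------------------------------------------- analysis 1 (GSR)

def run_gsr_analysis(
    config: SimConfig,
    dtw_config: DtwConfig = DtwConfig(),
    denoise_config: DenoiseConfig = DenoiseConfig(),
) -> dict:
    """GSR robustness on a cohort carrying a shared global component.

    Each scan is denoised twice — without and with the global-signal
    regressor — and the per-subject median absolute percent change of
    FC (no-GSR as baseline) is compared between estimators.
    """
    if config.global_amplitude <= 0:
        raise ValueError("GSR analysis requires global_amplitude > 0")
    cohort = generate_cohort(config)
    med = {e: [] for e in ESTIMATORS}
    for scan in cohort.scans:
        fc = {}
        for use_gsr in (False, True):
            cfg = replace(denoise_config, use_gsr=use_gsr)
            resid, _ = denoise_timeseries(
                scan.timeseries, scan.motion, scan.noise_voxels, cfg
            )
            fc[use_gsr] = estimate_both(resid, dtw_config, scan.subject_id,
                                        "gsr" if use_gsr else "nogsr")
        for e in ESTIMATORS:
            cmp = abs_percent_change(fc[False][e], fc[True][e])
            med[e].append(cmp.median_abs_pct_change)
    t, df, p = paired_t(med["pearson"], med["dtw"])
    pc, dt = np.asarray(med["pearson"]), np.asarray(med["dtw"])
    return {
        "median_abs_pct_change": {"pearson": pc, "dtw": dt},
        "paired_t": {"t": t, "df": df, "p": p},
        "fraction_subjects_dtw_smaller": float((dt < pc).mean()),
    }


# ---------------------------------------------------------------- analysis 2

def run_test_retest_analysis(config: SimConfig, dtw_config: DtwConfig = DtwConfig()) -> dict:
    """Test-retest reliability from synthetic twin scans.

    Both scans of a subject share the cohort ground truth (coupling,
    regional lags, HRF delays) and the subject's CNR, but use
    independent event trains and noise — emulating back-to-back runs.
    """
    rng = np.random.default_rng(config.seed)
    lags, delays, amps = _draw_region_params(config, rng)
    coupling = config.resolved_coupling()
    rel = {e: [] for e in ESTIMATORS}
    for s in range(config.n_subjects):
        seed1 = int(rng.integers(0, 2**31 - 1))
        seed2 = int(rng.integers(0, 2**31 - 1))
        cnr = float(rng.uniform(*config.cnr_range))
        fc = []
        for scan_id, seed in (("run1", seed1), ("run2", seed2)):
            fluct = generate_subject_fluctuations(config, seed, coupling, lags,
                                                  delays, amps)
            bold = add_rician_noise(fluct + BASELINE, cnr, seed=seed + 7_654_321,
                                    sigma=1.0 / cnr)
            ts = RoiTimeseries(bold.T, config.tr_seconds)
            fc.append(estimate_both(ts, dtw_config, f"sub-{s:03d}", scan_id))
        for e in ESTIMATORS:
            rel[e].append(test_retest(fc[0][e], fc[1][e]))
    t, df, p = paired_t(rel["dtw"], rel["pearson"])
    return {
        "reliability": {e: np.asarray(rel[e]) for e in ESTIMATORS},
        "mean_reliability": {e: float(np.mean(rel[e])) for e in ESTIMATORS},
        "paired_t_dtw_minus_pearson": {"t": t, "df": df, "p": p},
    }


# ---------------------------------------------------------------- analysis 3

def run_task_analysis(
    config: SimConfig,
    dtw_config: DtwConfig = DtwConfig(),
    decoupled_pair: tuple[int, int] = (0, 5),
    control_pairs: tuple[tuple[int, int], ...] = ((1, 6), (2, 7)),
    coupling_drop: float = 0.6,
    amplitude_boost: float = 1.5,
) -> dict:
    """Task sensitivity: rest vs task FC in a 2 x 3 within-subject ANOVA.

    Each subject contributes a rest scan and a task scan generated from
    the same cohort ground truth; in the task scan the coupling of
    ``decoupled_pair`` is reduced by ``coupling_drop`` of its weight
    and the driven (first) region's BOLD amplitude is scaled by
    ``amplitude_boost`` — frequent unilateral responses both decouple a
    homotopic pair and raise the responding region's fluctuation
    amplitude.  The control pairs are untouched.  Both estimators' FC
    at the three pairs enters a 2 (condition) x 3 (pair)
    repeated-measures ANOVA, and the per-subject median absolute
    percent change across the pairs (rest as baseline) is compared
    between estimators.
    """
    rng = np.random.default_rng(config.seed)
    lags, delays, amps = _draw_region_params(config, rng)
    coupling = config.resolved_coupling()
    task_coupling = coupling.copy()
    i, j = decoupled_pair
    task_coupling[i, j] *= 1.0 - coupling_drop
    task_coupling[j, i] *= 1.0 - coupling_drop
    task_amps = amps.copy()
    task_amps[i] *= amplitude_boost
    pairs = (decoupled_pair,) + control_pairs
    cells = {e: np.empty((config.n_subjects, 2, 3)) for e in ESTIMATORS}
    med = {e: [] for e in ESTIMATORS}
    for s in range(config.n_subjects):
        seed_rest = int(rng.integers(0, 2**31 - 1))
        seed_task = int(rng.integers(0, 2**31 - 1))
        cnr = float(rng.uniform(*config.cnr_range))
        fc = {}
        for c, (scan_id, seed, cpl, a) in enumerate(
            (("rest", seed_rest, coupling, amps),
             ("task", seed_task, task_coupling, task_amps))
        ):
            fluct = generate_subject_fluctuations(config, seed, cpl, lags, delays, a)
            bold = add_rician_noise(fluct + BASELINE, cnr, seed=seed + 7_654_321,
                                    sigma=1.0 / cnr)
            ts = RoiTimeseries(bold.T, config.tr_seconds)
            fc[scan_id] = estimate_both(ts, dtw_config, f"sub-{s:03d}", scan_id)
            for e in ESTIMATORS:
                for k, (a, b) in enumerate(pairs):
                    cells[e][s, c, k] = fc[scan_id][e].values[a, b]
        for e in ESTIMATORS:
            cmp = abs_percent_change(fc["rest"][e], fc["task"][e])
            med[e].append(cmp.median_abs_pct_change)
    t, df, p = paired_t(med["dtw"], med["pearson"])
    return {
        "pairs": pairs,
        "anova": {e: repeated_measures_anova_2x3(cells[e]) for e in ESTIMATORS},
        "median_abs_pct_change": {e: np.asarray(med[e]) for e in ESTIMATORS},
        "paired_t_dtw_minus_pearson": {"t": t, "df": df, "p": p},
    }


# ---------------------------------------------------------------- analysis 4

def _cohort_fc(
    cohort: SimulatedCohort, dtw_config: DtwConfig
) -> dict[str, dict[str, list[FcMatrix]]]:
    """Per-group FC stacks for both estimators (percent-signal-change path)."""
    out: dict[str, dict[str, list[FcMatrix]]] = {}
    for scan in cohort.scans:
        fc = estimate_both(scan.timeseries, dtw_config, scan.subject_id, "rest")
        for e in ESTIMATORS:
            out.setdefault(scan.group, {}).setdefault(e, []).append(fc[e])
    return out


def run_group_difference_analysis(
    config: SimConfig, dtw_config: DtwConfig = DtwConfig(), lam: float = 0.5,
    alpha: float = 0.05,
) -> dict:
    """Edgewise two-sample tests and enrichment on a two-group cohort."""
    cohort = generate_group_dataset(config)
    by_group = _cohort_fc(cohort, dtw_config)
    groups = sorted(by_group)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    out: dict = {"groups": groups}
    for e in ESTIMATORS:
        res = edgewise_two_sample_t(by_group[groups[0]][e], by_group[groups[1]][e])
        enr = estimate_pi0(res.valid_pvalues(), lam=lam)
        out[e] = {
            "edgewise": res,
            "enrichment": enr,
            "fraction_false": enr.fraction_false,
            "n_significant": int((res.pvalues < alpha).sum()),
            "roi_counts": roi_involvement_counts(res, alpha=alpha),
        }
    return out


def run_classification_analysis(
    config: SimConfig,
    clf_config: ClassificationConfig = ClassificationConfig(),
    dtw_config: DtwConfig = DtwConfig(),
) -> dict:
    """PCA + linear-SVM classification of group membership per estimator."""
    cohort = generate_group_dataset(config)
    by_group = _cohort_fc(cohort, dtw_config)
    groups = sorted(by_group)
    acc = {}
    for e in ESTIMATORS:
        mats, labels = [], []
        for g in groups:
            mats.extend(by_group[g][e])
            labels.extend([g] * len(by_group[g][e]))
        acc[e] = svm_cv_accuracy(vectorize_fc(mats), np.asarray(labels), clf_config)
    stat, p = compare_accuracy_distributions(acc["dtw"], acc["pearson"])
    return {
        "accuracies": acc,
        "mean_accuracy": {e: float(acc[e].mean()) for e in ESTIMATORS},
        "wilcoxon": {"statistic": stat, "p": p},
    }


# ---------------------------------------------------------------- analysis 5

def run_confound_analysis(
    config: SimConfig,
    amplitude_range: tuple[float, float] = (0.5, 2.0),
    dtw_config: DtwConfig = DtwConfig(),
    denoise_config: DenoiseConfig = DenoiseConfig(),
    lam: float = 0.5,
) -> dict:
    """Sensitivity of edge-behavior screens to a global confound.

    A respiration-like global component with subject-varying amplitude
    is injected; the amplitude plays the role of the physiological
    "behavior".  Edgewise partial correlations (controlling RMSD) are
    screened for enrichment per estimator, from data denoised without
    and with GSR.
    """
    base = replace(config, global_amplitude=0.0)
    cohort = generate_cohort(base)
    rng = np.random.default_rng(config.seed + 77)
    amplitudes = rng.uniform(*amplitude_range, size=config.n_subjects)
    lags = cohort.region_lags_seconds
    fc: dict[tuple[str, bool], list[FcMatrix]] = {}
    rmsd = []
    for scan, amp in zip(cohort.scans, amplitudes):
        ts, _ = inject_global_signal(
            scan.timeseries, float(amp), seed=scan.seed + 999_331,
            region_lags_seconds=lags if lags.any() else None,
        )
        rmsd.append(scan.rmsd)
        for use_gsr in (False, True):
            cfg = replace(denoise_config, use_gsr=use_gsr)
            resid, _ = denoise_timeseries(ts, scan.motion, scan.noise_voxels, cfg)
            est = estimate_both(resid, dtw_config, scan.subject_id)
            for e in ESTIMATORS:
                fc.setdefault((e, use_gsr), []).append(est[e])
    rmsd_arr = np.asarray(rmsd)
    out: dict = {"amplitudes": amplitudes}
    for (e, use_gsr), mats in fc.items():
        res = edgewise_partial_corr(mats, amplitudes, rmsd_arr)
        enr = estimate_pi0(res.valid_pvalues(), lam=lam)
        out[f"{e}_{'gsr' if use_gsr else 'nogsr'}"] = {
            "edgewise": res,
            "fraction_false": enr.fraction_false,
        }
    return out


# ---------------------------------------------------------------- orchestration

@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of the end-to-end synthetic pipeline."""

    simulate: SimConfig = SimConfig()
    dtw: DtwConfig = DtwConfig()
    denoise: DenoiseConfig = DenoiseConfig()
    classify: ClassificationConfig = ClassificationConfig(n_iterations=100)
    analyses: tuple[str, ...] = (
        "motion", "gsr", "test_retest", "task", "group", "classify", "confound"
    )
    gsr_global_amplitude: float = 1.0
    gsr_lag_range_seconds: tuple[float, float] = (-2.0, 2.0)
    retest_lag_range_seconds: tuple[float, float] = (-3.0, 3.0)
    group_effects: tuple[tuple[tuple[int, int], str, float], ...] = (
        ((0, 5), "coupling-delta", 0.6),
        ((1, 6), "hrf-delta", 2.0),
        ((2, 7), "hrf-delta", 2.0),
        ((3, 8), "lag-delta", 4.0),
    )
    confound_amplitude_range: tuple[float, float] = (0.5, 2.0)
    pi0_lambda: float = 0.5
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path, seed: int | None = None) -> "PipelineConfig":
        """Load a nested YAML config; unknown keys are errors."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a mapping")
        sections = {"simulate": SimConfig, "dtw": DtwConfig,
                    "denoise": DenoiseConfig, "classify": ClassificationConfig}
        kwargs: dict = {}
        top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
        for key, value in raw.items():
            if key not in top_fields:
                raise ValueError(f"unknown config key: {key!r}")
            if key in sections:
                cls = sections[key]
                valid = {f.name for f in dataclasses.fields(cls)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(f"unknown {key} config key(s): {sorted(bad)}")
                value = {k: _coerce(v) for k, v in value.items()}
                kwargs[key] = cls(**value)
            else:
                kwargs[key] = _coerce(value)
        cfg = PipelineConfig(**kwargs)
        if seed is not None:
            cfg = replace(cfg, seed=seed,
                          simulate=replace(cfg.simulate, seed=seed))
        return cfg


def _coerce(value):
    """YAML lists become tuples so configs stay hashable/frozen."""
    if isinstance(value, list):
        return tuple(_coerce(v) for v in value)
    return value


def _seeded(config: SimConfig, seed: int, **changes) -> SimConfig:
    return replace(config, seed=seed, **changes)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured analyses in dependency order.

    Every stage derives its own seed from the global seed; the report
    aggregates each analysis's headline numbers.  When ``out_dir`` is
    given, the report, per-analysis tables and a provenance sidecar
    (config hash + seed) are written there.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    sim = config.simulate
    report: dict = {"seed": config.seed}
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        logger.info("running analysis: %s", name)
        try:
            result = fn()
        except Exception as exc:  # stage-tagged failure
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        return result

    if "motion" in config.analyses:
        res = _stage("motion", lambda: run_motion_analysis(
            _seeded(sim, config.seed + 101), config.dtw))
        report["motion"] = {
            "median_abs_pct_change_mean": {
                e: float(res["median_abs_pct_change"][e].mean()) for e in ESTIMATORS},
            "paired_t_median_pct_change": res["paired_t_median_pct_change"],
            "paired_t_pattern_similarity": res["paired_t_pattern_similarity"],
        }
    if "gsr" in config.analyses:
        res = _stage("gsr", lambda: run_gsr_analysis(
            _seeded(sim, config.seed + 202,
                    global_amplitude=config.gsr_global_amplitude,
                    lag_range_seconds=config.gsr_lag_range_seconds),
            config.dtw, config.denoise))
        report["gsr"] = {
            "median_abs_pct_change_mean": {
                e: float(res["median_abs_pct_change"][e].mean()) for e in ESTIMATORS},
            "paired_t": res["paired_t"],
            "fraction_subjects_dtw_smaller": res["fraction_subjects_dtw_smaller"],
        }
    if "test_retest" in config.analyses:
        res = _stage("test_retest", lambda: run_test_retest_analysis(
            _seeded(sim, config.seed + 303,
                    lag_range_seconds=config.retest_lag_range_seconds), config.dtw))
        report["test_retest"] = {
            "mean_reliability": res["mean_reliability"],
            "paired_t_dtw_minus_pearson": res["paired_t_dtw_minus_pearson"],
        }
    if "task" in config.analyses:
        res = _stage("task", lambda: run_task_analysis(
            _seeded(sim, config.seed + 606), config.dtw))
        report["task"] = {
            "anova": {
                e: {eff: {"F": float(res["anova"][e].loc[eff, "F"]),
                          "p": float(res["anova"][e].loc[eff, "p"])}
                    for eff in ("run", "pair", "run:pair")}
                for e in ESTIMATORS
            },
            "median_abs_pct_change_mean": {
                e: float(res["median_abs_pct_change"][e].mean()) for e in ESTIMATORS},
            "paired_t_dtw_minus_pearson": res["paired_t_dtw_minus_pearson"],
        }
    if "group" in config.analyses:
        res = _stage("group", lambda: run_group_difference_analysis(
            _seeded(sim, config.seed + 404, group_effects=config.group_effects),
            config.dtw, lam=config.pi0_lambda, alpha=config.alpha))
        report["group"] = {
            e: {"fraction_false": res[e]["fraction_false"],
                "n_significant": res[e]["n_significant"],
                "roi_counts": res[e]["roi_counts"].tolist()}
            for e in ESTIMATORS
        }
    if "classify" in config.analyses:
        res = _stage("classify", lambda: run_classification_analysis(
            _seeded(sim, config.seed + 404, group_effects=config.group_effects),
            config.classify, config.dtw))
        report["classify"] = {
            "mean_accuracy": res["mean_accuracy"],
            "wilcoxon": res["wilcoxon"],
        }
    if "confound" in config.analyses:
        res = _stage("confound", lambda: run_confound_analysis(
            _seeded(sim, config.seed + 505,
                    lag_range_seconds=config.gsr_lag_range_seconds),
            config.confound_amplitude_range, config.dtw, config.denoise,
            lam=config.pi0_lambda))
        report["confound"] = {
            key: {"fraction_false": val["fraction_false"]}
            for key, val in res.items() if isinstance(val, dict)
        }

    report["timings_seconds"] = {k: round(v, 3) for k, v in timings.items()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg_dict = dataclasses.asdict(replace(config, simulate=sim))
        cfg_dict["simulate"]["coupling"] = (
            None if sim.coupling is None else np.asarray(sim.coupling).tolist())
        dio.write_json({"config": cfg_dict, "config_hash": dio.config_hash(cfg_dict),
                        "seed": config.seed}, out / "provenance.json")
        dio.write_json(report, out / "report.json")
    return report


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Materialise a cohort as TSV/CSV/JSON (timeseries, motion, manifest, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in cohort.scans:
        dio.write_roi_timeseries(scan.timeseries, out / f"{scan.subject_id}_bold.tsv")
        dio.write_motion_trace(scan.motion, out / f"{scan.subject_id}_motion.tsv")
        rows.append({"subject_id": scan.subject_id, "group": scan.group,
                     "seed": scan.seed, "rmsd": scan.rmsd})
    dio.write_manifest(rows, out / "manifest.csv")
    dio.write_json(
        {
            "coupling": cohort.coupling,
            "region_lags_seconds": cohort.region_lags_seconds,
            "hrf_delays_seconds": cohort.hrf_delays_seconds,
            "groups": cohort.groups,
        },
        out / "ground_truth.json",
    )
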