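"""Plain-text I/O: ROI timeseries and motion TSVs, FC matrices with JSON
sidecars, subject manifests, and NIfTI ROI extraction."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .denoise import MotionTrace, RoiTimeseries
from .fc_core import FcMatrix

__all__ = [
    "write_roi_timeseries",
    "read_roi_timeseries",
    "write_motion_trace",
    "read_motion_trace",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_manifest",
    "read_manifest",
    "write_json",
    "config_hash",
    "roi_extract",
]

MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_deg", "rot_y_deg", "rot_z_deg"]


def write_roi_timeseries(ts: RoiTimeseries, path: str | Path) -> None:
    """One row per volume, header row = region labels; TR in a sidecar."""
    path = Path(path)
    pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(path, sep="\t", index=False)
    write_json({"tr_seconds": ts.tr_seconds, "normalized": ts.normalized},
               path.with_suffix(path.suffix + ".json"))


def read_roi_timeseries(path: str | Path, tr_seconds: float | None = None) -> RoiTimeseries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(path.suffix + ".json")
    normalized = False
    if tr_seconds is None or meta_path.exists():
        meta = json.loads(meta_path.read_text())
        tr_seconds = tr_seconds or meta["tr_seconds"]
        normalized = bool(meta.get("normalized", False))
    return RoiTimeseries(df.to_numpy(float), tr_seconds, list(df.columns), normalized)


def write_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    pd.DataFrame(trace.params, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_motion_trace(path: str | Path) -> MotionTrace:
    return MotionTrace(pd.read_csv(path, sep="\t").to_numpy(float))


def write_fc_matrix(fc: FcMatrix, path: str | Path, extra: dict | None = None) -> None:
    """R x R TSV with label header plus a JSON sidecar with provenance."""
    path = Path(path)
    pd.DataFrame(fc.values, index=fc.region_labels, columns=fc.region_labels).to_csv(
        path, sep="\t"
    )
    meta = {"estimator": fc.estimator, "subject_id": fc.subject_id, "scan_id": fc.scan_id}
    if extra:
        meta.update(extra)
    write_json(meta, path.with_suffix(path.suffix + ".json"))


def read_fc_matrix(path: str | Path, atol: float = 1e-8) -> FcMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(float)
    finite = np.isfinite(values)
    sym = finite & finite.T
    if not np.allclose(values[sym], values.T[sym], atol=atol):
        raise ValueError(f"{path}: FC matrix is not symmetric")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FcMatrix(values, meta.get("estimator", "unknown"), list(df.columns),
                    meta.get("subject_id", ""), meta.get("scan_id", ""))


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (provenance sidecars)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def roi_extract(bold_path: str | Path, atlas_path: str | Path,
                tr_seconds: float | None = None) -> RoiTimeseries:
    """Mean timecourse per positive atlas label from a 4-D NIfTI.

    The atlas is a 3-D integer-label image on the same voxel grid;
    labels are returned in ascending order, empty labels dropped with a
    warning.
    """
    import warnings

    import nibabel as nib

    bold = nib.load(str(bold_path))
    atlas = nib.load(str(atlas_path))
    data = np.asanyarray(bold.dataobj, dtype=float)
    labels_img = np.asanyarray(atlas.dataobj)
    if data.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    if labels_img.shape != data.shape[:3]:
        raise ValueError("atlas grid does not match BOLD grid")
    if tr_seconds is None:
        tr_seconds = float(bold.header.get_zooms()[3]) or 1.0
    labels = np.unique(labels_img)
    labels = labels[labels > 0]
    cols, names = [], []
    for lab in labels:
        mask = labels_img == lab
        if not mask.any():
            warnings.warn(f"label {lab} empty; skipped")
            continue
        cols.append(data[mask].mean(axis=0))
        names.append(f"roi{int(lab):03d}")
    return RoiTimeseries(np.column_stack(cols), tr_seconds, names)
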