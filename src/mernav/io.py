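"""Readers and writers: HDF5 recording container, CSV manifests and tables,
JSON result reports (with config hash for provenance), NPZ fallback.

Container layout (one file per cohort)::

    /trajectories/{trajectory_id}/
        attrs: sampling_rate_hz, group, patient_id [, ground-truth fields]
        site_{k:03d}/signal      (n_samples,) float64, microvolts
            attrs: depth_mm, sampling_rate_hz
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .borders import StnAnnotation
from .simulate import GROUPS, TrajectoryRecording

_ANNOT_FIELDS = ("entry_index", "exit_index", "motor_border_index",
                 "entry_depth_mm", "exit_depth_mm", "length_mm")


def write_recording(container_path, recording: TrajectoryRecording,
                    overwrite: bool = False) -> Path:
    """Append one trajectory to the HDF5 container; round-trip safe."""
    path = Path(container_path)
    with h5py.File(path, "a") as fh:
        root = fh.require_group("trajectories")
        tid = recording.trajectory_id
        if tid in root:
            if not overwrite:
                raise ValueError(f"trajectory {tid!r} already in container "
                                 f"(pass overwrite=True to replace)")
            del root[tid]
        grp = root.create_group(tid)
        grp.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
        grp.attrs["group"] = recording.group
        grp.attrs["patient_id"] = recording.patient_id
        if recording.true_rate_hz is not None:
            grp.attrs["true_rate_hz"] = recording.true_rate_hz
        if recording.region_labels:
            grp.attrs["region_labels"] = json.dumps(list(recording.region_labels))
        gt = recording.ground_truth
        if gt is not None:
            for f in _ANNOT_FIELDS:
                grp.attrs[f"gt_{f}"] = getattr(gt, f)
            grp.attrs["gt_method"] = gt.method
        for k, (depth, sig) in enumerate(zip(recording.depths_mm,
                                             recording.signals)):
            site = grp.create_group(f"site_{k:03d}")
            ds = site.create_dataset("signal", data=np.asarray(sig))
            site.attrs["depth_mm"] = float(depth)
            site.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
    return path


def list_trajectories(container_path) -> list[str]:
    with h5py.File(container_path, "r") as fh:
        if "trajectories" not in fh:
            return []
        return sorted(fh["trajectories"].keys())


def read_recording(container_path, trajectory_id: str) -> TrajectoryRecording:
    """Load one trajectory; validates required attributes."""
    with h5py.File(container_path, "r") as fh:
        try:
            grp = fh["trajectories"][trajectory_id]
        except KeyError:
            raise KeyError(f"trajectory {trajectory_id!r} not in container")
        if "sampling_rate_hz" not in grp.attrs:
            raise ValueError(f"trajectory {trajectory_id!r} missing "
                             f"sampling_rate_hz attribute")
        fs = float(grp.attrs["sampling_rate_hz"])
        site_names = sorted(k for k in grp.keys() if k.startswith("site_"))
        depths, signals = [], []
        for name in site_names:
            site = grp[name]
            if "depth_mm" not in site.attrs:
                raise ValueError(f"site {name} of {trajectory_id!r} missing depth_mm")
            if "sampling_rate_hz" not in site.attrs:
                raise ValueError(f"site {name} of {trajectory_id!r} missing "
                                 f"sampling_rate_hz")
            depths.append(float(site.attrs["depth_mm"]))
            signals.append(site["signal"][()])
        gt = None
        if "gt_entry_index" in grp.attrs:
            gt = StnAnnotation(
                entry_index=int(grp.attrs["gt_entry_index"]),
                exit_index=int(grp.attrs["gt_exit_index"]),
                motor_border_index=int(grp.attrs["gt_motor_border_index"]),
                entry_depth_mm=float(grp.attrs["gt_entry_depth_mm"]),
                exit_depth_mm=float(grp.attrs["gt_exit_depth_mm"]),
                length_mm=float(grp.attrs["gt_length_mm"]),
                method=str(grp.attrs.get("gt_method", "ground_truth")))
        labels = ()
        if "region_labels" in grp.attrs:
            labels = tuple(json.loads(grp.attrs["region_labels"]))
        return TrajectoryRecording(
            trajectory_id=trajectory_id,
            patient_id=str(grp.attrs.get("patient_id", "")),
            group=str(grp.attrs.get("group", "")),
            sampling_rate_hz=fs,
            depths_mm=np.asarray(depths),
            signals=np.vstack(signals),
            ground_truth=gt, region_labels=labels)


def write_recording_npz(path, recording: TrajectoryRecording) -> Path:
    """Dependency-light single-trajectory fallback container."""
    path = Path(path)
    meta = {"trajectory_id": recording.trajectory_id,
            "patient_id": recording.patient_id,
            "group": recording.group,
            "sampling_rate_hz": recording.sampling_rate_hz}
    gt = recording.ground_truth
    if gt is not None:
        meta["ground_truth"] = {f: getattr(gt, f) for f in _ANNOT_FIELDS}
        meta["ground_truth"]["method"] = gt.method
    np.savez(path, depths_mm=recording.depths_mm, signals=recording.signals,
             meta=json.dumps(meta))
    return path


def read_recording_npz(path) -> TrajectoryRecording:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        gt = None
        if "ground_truth" in meta:
            gtd = meta["ground_truth"]
            gt = StnAnnotation(**{f: gtd[f] for f in _ANNOT_FIELDS},
                               method=gtd.get("method", "ground_truth"))
        return TrajectoryRecording(
            trajectory_id=meta["trajectory_id"], patient_id=meta["patient_id"],
            group=meta["group"], sampling_rate_hz=meta["sampling_rate_hz"],
            depths_mm=data["depths_mm"], signals=data["signals"],
            ground_truth=gt)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ("trajectory_id", "patient_id", "group")


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    """Typed, validated cohort manifest."""
    try:
        df = pd.read_csv(path, dtype={"trajectory_id": str, "patient_id": str,
                                      "group": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"manifest {path} is empty")
    for col in _MANIFEST_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    if df.empty:
        raise ValueError(f"manifest {path} has no rows")
    dup = df["trajectory_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicated trajectory_id: "
                         f"{df['trajectory_id'][dup].tolist()}")
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return df


def write_annotations(annotations: Mapping[str, Optional[StnAnnotation]],
                      path) -> Path:
    rows = []
    for tid, ann in annotations.items():
        if ann is None:
            rows.append({"trajectory_id": tid, "detected": False})
            continue
        row = {"trajectory_id": tid, "detected": True,
               "method": ann.method, "flags": ";".join(ann.flags)}
        row.update({f: getattr(ann, f) for f in _ANNOT_FIELDS})
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_annotations(path) -> dict[str, Optional[StnAnnotation]]:
    df = pd.read_csv(path, dtype={"trajectory_id": str})
    out: dict[str, Optional[StnAnnotation]] = {}
    for row in df.to_dict("records"):
        tid = row["trajectory_id"]
        if not row.get("detected", True):
            out[tid] = None
            continue
        flags = row.get("flags", "")
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        out[tid] = StnAnnotation(
            entry_index=int(row["entry_index"]),
            exit_index=int(row["exit_index"]),
            motor_border_index=int(row["motor_border_index"]),
            entry_depth_mm=float(row["entry_depth_mm"]),
            exit_depth_mm=float(row["exit_depth_mm"]),
            length_mm=float(row["length_mm"]),
            method=str(row.get("method", "detected")), flags=flags)
    return out


def write_json_report(payload: dict, path, config=None) -> Path:
    """JSON result file stamped with package version and config hash."""
    out = {"mernav_version": __version__}
    if config is not None:
        out["config_hash"] = config.hash()
        out["config"] = config.to_dict()
    out.update(payload)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path = Path(path)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_default)
    return path
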