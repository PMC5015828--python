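"""Serialization of the pipeline's containers.

Trial tables travel as TSV, run series as an HDF5 container (one dataset per
run) with a JSON sidecar holding TR, ROI map and events, decoders as JSON
with sparse index/value weight pairs, induction logs as TSV plus a JSON
summary.  NIfTI export of searchlight maps is available when nibabel is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoder import PreferenceDecoder
from .leakage import SearchlightMap
from .neurofeedback import InductionLog, InductionSchedule
from .preprocess import RunSeries

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_run_series",
    "read_run_series",
    "decoder_to_json",
    "decoder_from_json",
    "write_induction_log",
    "read_induction_log",
    "map_to_nifti",
]

_TRIAL_COLUMNS = ["run", "trial", "face_id", "rating", "period", "onset_s", "duration_s"]


def write_trial_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = set(_TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trial table lacks column(s) {sorted(missing)}")
    table[_TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_series(runs, path_h5, sidecar=None) -> tuple[Path, Path]:
    """One HDF5 dataset per run plus a JSON sidecar (TR, ROI map, events)."""
    path_h5 = Path(path_h5)
    sidecar = Path(sidecar) if sidecar else path_h5.with_suffix(".json")
    meta = {"tr_s": runs[0].tr_s, "roi_map": {}, "runs": []}
    with h5py.File(path_h5, "w") as f:
        for run in runs:
            g = f.create_group(f"run_{run.run_id:03d}")
            g.create_dataset("signal", data=run.signal)
            g.create_dataset("excluded", data=run.excluded)
        meta["roi_map"] = {k: np.asarray(v).tolist() for k, v in runs[0].roi_map.items()}
        meta["runs"] = [
            {
                "run_id": int(run.run_id),
                "stages": list(run.stages),
                "lag_volumes": int(run.lag_volumes),
                "events": run.events.to_dict(orient="records"),
            }
            for run in runs
        ]
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True, default=float))
    return path_h5, sidecar


def read_run_series(path_h5, sidecar=None) -> list[RunSeries]:
    path_h5 = Path(path_h5)
    sidecar = Path(sidecar) if sidecar else path_h5.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    roi_map = {k: np.asarray(v, dtype=int) for k, v in meta["roi_map"].items()}
    runs = []
    with h5py.File(path_h5, "r") as f:
        for spec in meta["runs"]:
            g = f[f"run_{spec['run_id']:03d}"]
            runs.append(
                RunSeries(
                    signal=g["signal"][()],
                    tr_s=float(meta["tr_s"]),
                    run_id=int(spec["run_id"]),
                    events=pd.DataFrame(spec["events"]),
                    roi_map=roi_map,
                    excluded=g["excluded"][()],
                    stages=tuple(spec["stages"]),
                    lag_volumes=int(spec["lag_volumes"]),
                )
            )
    return runs


def decoder_to_json(dec: PreferenceDecoder, path) -> Path:
    path = Path(path)
    sel = dec.selected_voxels
    payload = {
        "weights": {"indices": sel.tolist(), "values": dec.weights[sel].tolist(),
                    "length": int(len(dec.weights))},
        "bias": dec.bias,
        "linearization": {"center": dec.center, "half_range": dec.half_range},
        "roi": dec.roi,
        "voxel_indices": None if dec.voxel_indices is None else np.asarray(dec.voxel_indices).tolist(),
        "norm_mean": None if dec.norm_mean is None else np.asarray(dec.norm_mean).tolist(),
        "norm_sd": None if dec.norm_sd is None else np.asarray(dec.norm_sd).tolist(),
        "training_meta": dec.training_meta,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=float))
    return path


def decoder_from_json(path) -> PreferenceDecoder:
    payload = json.loads(Path(path).read_text())
    w = np.zeros(payload["weights"]["length"])
    w[np.asarray(payload["weights"]["indices"], dtype=int)] = payload["weights"]["values"]

    def arr(key):
        v = payload.get(key)
        return None if v is None else np.asarray(v)

    return PreferenceDecoder(
        weights=w,
        bias=payload["bias"],
        center=payload["linearization"]["center"],
        half_range=payload["linearization"]["half_range"],
        roi=payload["roi"],
        voxel_indices=None if payload["voxel_indices"] is None else np.asarray(payload["voxel_indices"], dtype=int),
        norm_mean=arr("norm_mean"),
        norm_sd=arr("norm_sd"),
        training_meta=payload.get("training_meta", {}),
    )


def write_induction_log(log: InductionLog, path_tsv, path_json=None) -> tuple[Path, Path]:
    path_tsv = Path(path_tsv)
    path_json = Path(path_json) if path_json else path_tsv.with_suffix(".json")
    log.trials.to_csv(path_tsv, sep="\t", index=False)
    summary = {
        "group": log.group,
        "decoder_bias": log.decoder_bias,
        "schedule": {
            "days": log.schedule.days,
            "runs_per_day": log.schedule.runs_per_day,
            "trials_per_run": log.schedule.trials_per_run,
            "tr_s": log.schedule.tr_s,
            "lag_s": log.schedule.lag_s,
        },
        "day_summary": log.day_summary.to_dict(orient="records"),
    }
    path_json.write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
    return path_tsv, path_json


def read_induction_log(path_tsv, path_json=None) -> InductionLog:
    path_tsv = Path(path_tsv)
    path_json = Path(path_json) if path_json else path_tsv.with_suffix(".json")
    trials = pd.read_csv(path_tsv, sep="\t")
    meta = json.loads(path_json.read_text())
    return InductionLog(
        trials=trials,
        group=meta["group"],
        schedule=InductionSchedule(
            days=int(meta["schedule"]["days"]),
            runs_per_day=int(meta["schedule"]["runs_per_day"]),
            trials_per_run=int(meta["schedule"]["trials_per_run"]),
            tr_s=float(meta["schedule"]["tr_s"]),
            lag_s=float(meta["schedule"]["lag_s"]),
        ),
        decoder_bias=meta.get("decoder_bias"),
    )


def map_to_nifti(m: SearchlightMap, path) -> Path:
    """Write a searchlight map as NIfTI (requires nibabel)."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("NIfTI export needs the optional nibabel dependency") from exc
    affine = np.diag([*m.voxel_dims_mm, 1.0])
    img = nib.Nifti1Image(m.volume().astype(np.float32), affine)
    path = Path(path)
    nib.save(img, path)
    return path
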