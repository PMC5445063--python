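"""Readers and writers: TAC tables (CSV), NIfTI volumes, result reports.

TAC tables are comma-separated UTF-8 with a header row:
``frame_start_s,frame_end_s,<region>,...`` — frame times in seconds, one
activity column (kBq/ml) per region.  Times convert to minutes on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    TAC,
    FormatError,
    FrameSchedule,
    RegionMask,
    ValidationError,
    VolumeGrid,
)

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "read_aorta_centres",
    "write_aorta_centres",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_pet4d",
    "write_report",
    "write_input_function",
    "TacTable",
]

_TIME_COLS = ("frame_start_s", "frame_end_s")


@dataclass
class TacTable:
    schedule: FrameSchedule
    tacs: list
    diagnostics: dict


def read_tac_table(path) -> TacTable:
    """Read a TAC CSV into minute-based TACs (one per region column)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse TAC table {path}: {exc}") from exc
    for col in _TIME_COLS:
        if col not in df.columns:
            raise FormatError(f"TAC table {path} is missing column '{col}'")
    regions = [c for c in df.columns if c not in _TIME_COLS]
    if not regions:
        raise FormatError(f"TAC table {path} has no region columns")
    nan_rows = df.index[df.isna().any(axis=1)]
    if len(nan_rows):
        raise ValidationError(f"TAC table {path} has NaN cells in row(s) {list(nan_rows)}")
    try:
        schedule = FrameSchedule.from_seconds(df["frame_start_s"].to_numpy(),
                                              df["frame_end_s"].to_numpy())
    except ValidationError as exc:
        raise ValidationError(f"TAC table {path}: {exc}") from exc
    tacs = [TAC(schedule, df[r].to_numpy(float), r, from_noise=True) for r in regions]
    return TacTable(schedule, tacs,
                    {"n_frames": schedule.n_frames, "regions": regions, "path": str(path)})


def write_tac_table(path, schedule: FrameSchedule, tacs) -> None:
    """Write TACs sharing one schedule to the CSV format read_tac_table reads."""
    data = {"frame_start_s": schedule.start * 60.0, "frame_end_s": schedule.end * 60.0}
    for tac in tacs:
        if tac.schedule.n_frames != schedule.n_frames:
            raise ValidationError("all TACs in one table must share the schedule")
        data[tac.region_label] = tac.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_aorta_centres(path) -> list:
    """Aorta-centre CSV: columns slice_index, x_voxel, y_voxel."""
    df = pd.read_csv(path)
    need = ("slice_index", "x_voxel", "y_voxel")
    for col in need:
        if col not in df.columns:
            raise FormatError(f"aorta centres file {path} is missing column '{col}'")
    return [(int(r.slice_index), int(r.x_voxel), int(r.y_voxel)) for r in df.itertuples()]


def write_aorta_centres(path, centres) -> None:
    pd.DataFrame(centres, columns=["slice_index", "x_voxel", "y_voxel"]).to_csv(path, index=False)


def _nifti_voxel_size(img) -> tuple:
    z = img.header.get_zooms()[:3]
    return tuple(float(v) for v in z)


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), _nifti_voxel_size(img),
                      affine=img.affine)


def save_volume(path, vol: VolumeGrid) -> None:
    affine = vol.affine if vol.affine is not None else np.diag(list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), affine), str(path))


def load_mask(path, label: str = "custom") -> RegionMask:
    img = nib.load(str(path))
    return RegionMask(np.asarray(img.dataobj) > 0.5, _nifti_voxel_size(img), label)


def save_mask(path, mask: RegionMask) -> None:
    affine = np.diag(list(mask.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def load_pet4d(path):
    """Load a 4-D PET NIfTI as ``(array, voxel_size_mm)``."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim != 4:
        raise FormatError(f"{path} is not a 4-D volume")
    return arr, _nifti_voxel_size(img)


def write_input_function(path, fn) -> None:
    pd.DataFrame({"time_min": fn.times, "value_kBq_ml": fn.values,
                  "kind": fn.kind, "delay_s": fn.delay_applied_s}).to_csv(path, index=False)


def write_report(results, out_dir) -> dict:
    """Write per-subject results and group summaries.

    ``results`` is an iterable of flat dicts with at least the keys
    ``subject``, ``group``, ``region`` plus one column per metric.  Writes
    ``results.csv`` (metric x region x subject, long layout) and
    ``summary.json`` with per-group mean/sd/CoV for every numeric metric.
    Returns the summary dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = list(results)
    key_cols = ["subject", "group", "region"]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=key_cols)
    df.to_csv(out_dir / "results.csv", index=False)

    summary: dict = {}
    metrics = [c for c in df.columns if c not in key_cols and pd.api.types.is_numeric_dtype(df[c])]
    for (group, region), sub in df.groupby(["group", "region"]) if rows else []:
        for m in metrics:
            v = sub[m].dropna().to_numpy(float)
            if v.size < 2:
                continue
            mean, sd = float(v.mean()), float(v.std(ddof=1))
            summary.setdefault(m, {}).setdefault(region, {})[group] = {
                "n": int(v.size), "mean": mean, "sd": sd,
                "cov_percent": 100.0 * sd / mean if mean != 0 else None,
            }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
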