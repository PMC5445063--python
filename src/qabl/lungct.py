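"""CT-derived air-fraction estimation and regional extraction.

A lung voxel is a mixture of air (≈ −1024 HU) and soft tissue (≈ 40 HU);
the regional mean Hounsfield value therefore encodes the fractional air
volume

    V_A^CT = 1 − (HU̅_R − HU_air) / (HU_tissue − HU_air)

which the qABL model uses to down-weight the tissue term.  This module also
splits the whole-lung mask into apical/middle/basal thirds along the axial
axis and extracts regional mean TACs from 4-D PET data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    TAC,
    FrameSchedule,
    ParameterError,
    RegionMask,
    ValidationError,
    VolumeGrid,
)

__all__ = [
    "HU_AIR",
    "HU_TISSUE",
    "AirFractionResult",
    "air_fraction_from_hu",
    "regional_mean_hu",
    "air_fraction_of_region",
    "subdivide_lung_axially",
    "extract_tac",
    "downsample_mask",
    "downsample_hu",
]

log = logging.getLogger(__name__)

HU_AIR = -1024.0
HU_TISSUE = 40.0


@dataclass(frozen=True)
class AirFractionResult:
    """Regional fractional air volume with its provenance."""

    va_ct: float
    mean_hu: float
    region_label: str
    region_volume_ml: float


def air_fraction_from_hu(
    mean_hu: float, hu_air: float = HU_AIR, hu_tissue: float = HU_TISSUE
) -> float:
    """Fractional air volume from a regional mean Hounsfield value.

    Values outside [hu_air, hu_tissue] are clipped into [0, 1] with a
    warning (some scanners report HU below −1024).
    """
    if hu_tissue <= hu_air:
        raise ParameterError("hu_tissue must exceed hu_air")
    va = 1.0 - (mean_hu - hu_air) / (hu_tissue - hu_air)
    if va < 0.0 or va > 1.0:
        log.warning("mean HU %.1f outside [%g, %g]; air fraction clipped", mean_hu, hu_air, hu_tissue)
        va = min(max(va, 0.0), 1.0)
    return float(va)


def hu_from_air_fraction(va: float, hu_air: float = HU_AIR, hu_tissue: float = HU_TISSUE) -> float:
    """Inverse of :func:`air_fraction_from_hu` (used by phantom builders)."""
    return hu_tissue - va * (hu_tissue - hu_air)


def regional_mean_hu(ct: VolumeGrid, mask: RegionMask) -> float:
    """Arithmetic mean Hounsfield value over the masked voxels."""
    mask.require_nonempty()
    mask.require_same_grid(ct)
    return float(ct.data[mask.data].mean())


def air_fraction_of_region(ct: VolumeGrid, mask: RegionMask,
                           hu_air: float = HU_AIR, hu_tissue: float = HU_TISSUE) -> AirFractionResult:
    mhu = regional_mean_hu(ct, mask)
    return AirFractionResult(
        va_ct=air_fraction_from_hu(mhu, hu_air, hu_tissue),
        mean_hu=mhu,
        region_label=mask.label,
        region_volume_ml=mask.volume_ml,
    )


def _best_cut(cum: np.ndarray, target: float) -> int:
    """Index i such that slices [0..i] approximate ``target`` voxels.

    Each boundary slice goes wholly to one side, minimising
    |cumulative − target|; ties resolve toward the more apical cut
    (smaller index in apex-first ordering).
    """
    dev = np.abs(cum - target)
    return int(np.argmin(dev))  # argmin takes the first (most apical) tie


def subdivide_lung_axially(wl: RegionMask, axial_axis: int = 2,
                           apex_high_index: bool = True) -> tuple[RegionMask, RegionMask, RegionMask]:
    """Split the whole-lung mask into upper/middle/lower thirds by voxel count.

    Boundaries are whole axial slices; cut points minimise the deviation of
    the cumulative voxel count from N/3 and 2N/3.  Returns (UL, ML, LL)
    with UL the most apical third.
    """
    wl.require_nonempty()
    axes = tuple(a for a in range(3) if a != axial_axis)
    counts = wl.data.sum(axis=axes)
    occupied = np.nonzero(counts)[0]
    if occupied.size < 3:
        raise ValidationError("whole-lung mask spans fewer than 3 non-empty slices")

    order = np.arange(wl.data.shape[axial_axis])
    if apex_high_index:
        order = order[::-1]  # apex-first
    cum = np.cumsum(counts[order])
    n = cum[-1]
    b1 = _best_cut(cum, n / 3.0)
    b2 = _best_cut(cum, 2.0 * n / 3.0)
    b2 = max(b2, b1)  # keep regions ordered even for pathological masks

    region_of_slice = np.empty(order.size, dtype=int)
    region_of_slice[: b1 + 1] = 0
    region_of_slice[b1 + 1 : b2 + 1] = 1
    region_of_slice[b2 + 1 :] = 2

    masks = []
    for r, label in enumerate(("UL", "ML", "LL")):
        sel = np.zeros(order.size, dtype=bool)
        sel[order[region_of_slice == r]] = True
        shape = [1, 1, 1]
        shape[axial_axis] = order.size
        m = wl.data & sel.reshape(shape)
        masks.append(RegionMask(m, wl.voxel_size_mm, label))
    dev = max(abs(m.n_voxels - n / 3.0) for m in masks)
    if dev > n / 6.0:
        log.warning("axial thirds deviate strongly from N/3 (max deviation %d voxels)", int(dev))
    return tuple(masks)


def extract_tac(pet4d, mask: RegionMask, schedule: FrameSchedule,
                region_label: str | None = None, from_noise: bool = True) -> TAC:
    """Mean activity over the masked voxels for each time frame.

    ``pet4d`` is a sequence of :class:`VolumeGrid` frames or a 4-D array
    (x, y, z, frame).  Reconstructed PET voxels can be negative, so the TAC
    is flagged as noise-bearing by default.
    """
    mask.require_nonempty()
    if isinstance(pet4d, np.ndarray):
        if pet4d.ndim != 4:
            raise ValidationError("4-D PET array expected (x, y, z, frame)")
        frames = [pet4d[..., i] for i in range(pet4d.shape[-1])]
    else:
        frames = [f.data if isinstance(f, VolumeGrid) else np.asarray(f) for f in pet4d]
    if len(frames) != schedule.n_frames:
        raise ValidationError(f"{len(frames)} frames != {schedule.n_frames} schedule entries")
    vals = np.empty(len(frames))
    for i, f in enumerate(frames):
        if f.shape != mask.shape:
            raise ValidationError(f"frame {i} shape {f.shape} != mask shape {mask.shape}")
        vals[i] = f[mask.data].mean()
    return TAC(schedule, vals, region_label or mask.label, from_noise=from_noise)


def downsample_mask(mask: RegionMask, factor: int) -> RegionMask:
    """Nearest-neighbour downsampling (preserves binarity)."""
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    d = mask.data[::factor, ::factor, ::factor]
    vs = tuple(v * factor for v in mask.voxel_size_mm)
    return RegionMask(d, vs, mask.label)


def downsample_hu(vol: VolumeGrid, factor: int) -> VolumeGrid:
    """Block-mean downsampling of an HU volume (mean-preserving)."""
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    d = vol.data
    shp = tuple((s // factor) * factor for s in d.shape)
    d = d[: shp[0], : shp[1], : shp[2]]
    d = d.reshape(shp[0] // factor, factor, shp[1] // factor, factor, shp[2] // factor, factor)
    out = d.mean(axis=(1, 3, 5))
    vs = tuple(v * factor for v in vol.voxel_size_mm)
    return VolumeGrid(out, vs)
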