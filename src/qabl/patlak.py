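"""Patlak graphical analysis, the normalised Patlak composite, and SUV.

For an irreversible tracer the transformed measurements

    x_i = ∫0^{t_i} C_p dτ / C_p(t_i),     y_i = C_M(t_i) / C_p(t_i)

become affine for t beyond a linearisation start time t*; the slope is the
apparent uptake rate of the uncorrected ROI and the intercept its apparent
distribution volume.  Earlier lung studies report the ratio
nKi = slope/intercept, which is *not* the tissue metabolic rate: with the
ROI holding air and blood it evaluates to

    nKi = (1 − V_B − V_A) Ki / [ (1 − V_B − V_A) V_ss + V_B ]

so fraction shifts move it even at fixed tissue Ki.  This module provides
the regional and voxelwise Patlak fits, that composite prediction, and the
standardised uptake value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (
    TAC,
    FrameSchedule,
    InputFunction,
    ParameterError,
    SubjectMeta,
    ValidationError,
)

__all__ = [
    "PatlakResult",
    "CompositeParams",
    "patlak_points",
    "patlak_fit",
    "patlak_analysis",
    "nki_composite_prediction",
    "patlak_slope_map",
    "suv",
]

T_STAR_DEFAULT = 10.0  # minutes


@dataclass(frozen=True)
class PatlakResult:
    slope: float              # ml cm^-3 min^-1
    intercept: float          # dimensionless
    nki: float                # slope / intercept
    t_star: float             # minutes
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class CompositeParams:
    """Inputs of the normalised-Patlak composite measure."""

    ki: float
    va: float
    vb: float
    vss: float

    def __post_init__(self):
        if self.vss < 0:
            raise ParameterError("vss must be >= 0")


def patlak_points(tac: TAC, cp: InputFunction):
    """Patlak coordinates at frame midpoints.

    Returns ``(x, y, used)`` where ``used`` flags frames with a positive
    plasma value (points at C_p = 0 are excluded with a warning flag rather
    than poisoning the regression).
    """
    t = tac.schedule.mid
    cp_mid = cp(t)
    cum = cumulative_trapezoid(cp.values, cp.times, initial=0.0)
    cum_mid = np.interp(t, cp.times, cum)
    used = cp_mid > 0
    x = np.full(t.size, np.nan)
    y = np.full(t.size, np.nan)
    x[used] = cum_mid[used] / cp_mid[used]
    y[used] = tac.values[used] / cp_mid[used]
    return x, y, used


def _qualifying(schedule: FrameSchedule, used: np.ndarray, t_star: float) -> np.ndarray:
    # Frames straddling t* are excluded: membership requires the whole
    # frame (hence its start) at or beyond the linearisation time.
    return used & (schedule.start >= t_star - 1e-9)


def patlak_fit(x, y, keep, t_star: float = T_STAR_DEFAULT) -> PatlakResult:
    """Ordinary least-squares line through the qualifying Patlak points."""
    xq, yq = np.asarray(x)[keep], np.asarray(y)[keep]
    if xq.size < 2:
        raise ValidationError("fewer than 2 Patlak points beyond t*")
    slope, intercept = np.polyfit(xq, yq, 1)
    resid = yq - (slope * xq + intercept)
    ss_tot = float(np.sum((yq - yq.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    nki = slope / intercept if intercept != 0.0 else np.nan
    return PatlakResult(float(slope), float(intercept), float(nki), t_star, int(xq.size), r2)


def patlak_analysis(tac: TAC, cp: InputFunction, t_star: float = T_STAR_DEFAULT) -> PatlakResult:
    """Regional Patlak analysis of a measured TAC against the plasma input."""
    x, y, used = patlak_points(tac, cp)
    keep = _qualifying(tac.schedule, used, t_star)
    return patlak_fit(x, y, keep, t_star)


def nki_composite_prediction(p: CompositeParams) -> float:
    """Normalised-Patlak value implied by tissue Ki and the ROI fractions.

    (1 − V_B − V_A)·Ki / [(1 − V_B − V_A)·V_ss + V_B]; raises when the
    denominator (the apparent distribution volume) vanishes.
    """
    tissue = 1.0 - p.vb - p.va
    den = tissue * p.vss + p.vb
    if den <= 0:
        raise ParameterError("composite denominator must be positive")
    return tissue * p.ki / den


def patlak_slope_map(pet4d, cp: InputFunction, schedule: FrameSchedule,
                     t_star: float = T_STAR_DEFAULT, voxel_size_mm=(1.0, 1.0, 1.0)):
    """Voxelwise Patlak slope image.

    The plasma curve (hence x and the qualifying-frame set) is shared by
    all voxels, so the per-voxel OLS slope reduces to one vectorised
    closed-form pass.  Returns a :class:`~qabl.core.VolumeGrid`.
    """
    from .core import VolumeGrid

    if isinstance(pet4d, np.ndarray):
        arr = pet4d
    else:
        arr = np.stack([f.data if isinstance(f, VolumeGrid) else np.asarray(f) for f in pet4d], axis=-1)
    if arr.ndim != 4 or arr.shape[-1] != schedule.n_frames:
        raise ValidationError("4-D PET with one volume per frame expected")

    t = schedule.mid
    cp_mid = cp(t)
    cum = cumulative_trapezoid(cp.values, cp.times, initial=0.0)
    cum_mid = np.interp(t, cp.times, cum)
    used = cp_mid > 0
    keep = _qualifying(schedule, used, t_star)
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 Patlak points beyond t*")
    x = cum_mid[keep] / cp_mid[keep]
    Y = arr[..., keep] / cp_mid[keep]
    xm = x - x.mean()
    slope = (Y * xm).sum(axis=-1) / float((xm**2).sum())
    return VolumeGrid(slope, voxel_size_mm)


def suv(tac: TAC, meta: SubjectMeta, window_min: tuple[float, float] = (30.0, 60.0)) -> float:
    """Standardised uptake value over a late static window.

    Duration-weighted mean of the frames whose midpoints fall in
    ``window_min``, divided by the injected dose per kilogram (kBq/kg).
    """
    lo, hi = window_min
    sel = (tac.schedule.mid >= lo) & (tac.schedule.mid <= hi)
    if not sel.any():
        raise ValidationError("no frames inside the SUV window")
    w = tac.schedule.duration[sel]
    mean_act = float(np.sum(w * tac.values[sel]) / np.sum(w))
    return mean_act / meta.dose_per_kg_kbq
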