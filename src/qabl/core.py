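"""Core domain types and unit conventions.

All public objects carry time in **minutes** (t = 0 at tracer injection) and
radioactivity concentration in **kBq/ml**, decay-corrected to injection time
(the conventional scanner output).  Converters from seconds are provided where
raw tables use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "ParameterError",
    "StateError",
    "FitError",
    "DegenerateDataError",
    "FrameSchedule",
    "TAC",
    "InputFunction",
    "VolumeGrid",
    "RegionMask",
    "SubjectMeta",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (shape, ordering, sign)."""


class FormatError(ValueError):
    """A file does not follow the expected on-disk format."""


class ParameterError(ValueError):
    """A model/algorithm parameter is outside its admissible domain."""


class StateError(RuntimeError):
    """An operation was applied to an object in the wrong state."""


class FitError(RuntimeError):
    """A model fit failed to produce a usable solution."""


class DegenerateDataError(ValueError):
    """Data carry no usable signal for the requested operation."""


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class FrameSchedule:
    """Timing of the dynamic PET frames, in minutes from injection.

    Parameters
    ----------
    start, end : array-like
        Frame start/end times in minutes. Must be equal-length, sorted,
        non-overlapping, with ``end > start`` framewise.
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        s = _as_1d(self.start, "start")
        e = _as_1d(self.end, "end")
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "end", e)
        if s.size != e.size or s.size < 1:
            raise ValidationError("start/end must have equal length >= 1")
        if not (np.isfinite(s).all() and np.isfinite(e).all()):
            raise ValidationError("frame times must be finite")
        if np.any(e <= s):
            raise ValidationError("each frame end must exceed its start")
        if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1] - 1e-12):
            raise ValidationError("frames must be sorted and non-overlapping")

    @classmethod
    def from_seconds(cls, start_s, end_s) -> "FrameSchedule":
        return cls(np.asarray(start_s, float) / 60.0, np.asarray(end_s, float) / 60.0)

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations in minutes."""
        return self.end - self.start

    @property
    def total_minutes(self) -> float:
        return float(self.end[-1])


@dataclass(frozen=True)
class TAC:
    """A regional time-activity curve: mean measured concentration per frame.

    ``values`` is the measured concentration C_M in kBq/ml.  Negative values
    are rejected unless ``from_noise`` is set (simulated noise may dip below
    zero, as real reconstructions can).
    """

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = "custom"
    from_noise: bool = False

    def __post_init__(self):
        v = _as_1d(self.values, "values")
        object.__setattr__(self, "values", v)
        if v.size != self.schedule.n_frames:
            raise ValidationError(
                f"values length {v.size} != frame count {self.schedule.n_frames}"
            )
        if not np.isfinite(v).all():
            raise ValidationError("TAC values must be finite")
        if not self.from_noise and np.any(v < 0):
            raise ValidationError("negative TAC values require from_noise=True")

    def restricted(self, t_max_min: float) -> "TAC":
        """TAC restricted to frames whose midpoint is <= ``t_max_min``."""
        keep = self.schedule.mid <= t_max_min
        if not keep.any():
            raise ValidationError("no frames inside the requested window")
        sched = FrameSchedule(self.schedule.start[keep], self.schedule.end[keep])
        return TAC(sched, self.values[keep], self.region_label, self.from_noise)


InputKind = Literal["whole_blood", "plasma_corrected"]


@dataclass(frozen=True)
class InputFunction:
    """Blood (or plasma-corrected) activity on a dense time grid.

    Houses C_B(t): either the whole-blood image-derived curve or the same
    curve scaled by the plasma-to-whole-blood ratio.  ``delay_applied_s``
    records any time shift already applied (positive = curve delayed).
    """

    times: np.ndarray
    values: np.ndarray
    kind: InputKind = "whole_blood"
    plasma_to_blood_ratio: float = 1.0
    delay_applied_s: float = 0.0

    def __post_init__(self):
        t = _as_1d(self.times, "times")
        v = _as_1d(self.values, "values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size or t.size < 2:
            raise ValidationError("times/values must have equal length >= 2")
        if abs(t[0]) > 1e-12:
            raise ValidationError("input-function grid must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.isfinite(v).all():
            raise ValidationError("input-function values must be finite")
        if self.plasma_to_blood_ratio <= 0:
            raise ValidationError("plasma_to_blood_ratio must be > 0")

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation; zero before t=0, edge-hold after the grid."""
        return np.interp(t, self.times, self.values, left=0.0)

    def shifted(self, delay_s: float) -> "InputFunction":
        """Return the curve delayed by ``delay_s`` seconds (same grid).

        Positive delay moves activity later in time, i.e. the returned curve
        is C(t - delay).
        """
        vals = np.interp(self.times - delay_s / 60.0, self.times, self.values, left=0.0)
        return replace(self, values=vals, delay_applied_s=self.delay_applied_s + delay_s)

    @property
    def dt(self) -> float:
        """Grid spacing in minutes (grids are uniform for model evaluation)."""
        d = np.diff(self.times)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("operation requires a uniform time grid")
        return float(d[0])


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar volume with voxel dimensions in mm.

    Axis order is (x, y, z) with z the axial direction; slice index increases
    toward the lung apex unless an affine says otherwise.
    """

    data: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got shape {d.shape}")
        if not np.isfinite(d).all():
            raise ValidationError("volume values must be finite")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError("voxel dimensions must be three positive numbers")
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0


@dataclass(frozen=True)
class RegionMask:
    """A boolean mask on a :class:`VolumeGrid`'s lattice."""

    data: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    label: str = "custom"

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.dtype != bool:
            if not np.isin(np.unique(d), (0, 1)).all():
                raise ValidationError("mask values must be boolean or 0/1")
            d = d.astype(bool)
        object.__setattr__(self, "data", d)
        if d.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got shape {d.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError("voxel dimensions must be three positive numbers")
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return self.n_voxels * vx * vy * vz / 1000.0

    def require_nonempty(self):
        if self.n_voxels == 0:
            raise ValidationError(f"mask '{self.label}' is empty")

    def require_same_grid(self, vol: "VolumeGrid | RegionMask"):
        if self.shape != vol.shape:
            raise ValidationError(
                f"mask '{self.label}' shape {self.shape} != volume shape {vol.shape}"
            )


@dataclass(frozen=True)
class SubjectMeta:
    """Scalar per-subject metadata used by SUV and reporting."""

    injected_dose_mbq: float
    body_weight_kg: float
    group_label: str = "synthetic"
    subject_id: str = "subject"

    def __post_init__(self):
        if not self.injected_dose_mbq > 0:
            raise ValidationError("injected dose must be > 0")
        if not self.body_weight_kg > 0:
            raise ValidationError("body weight must be > 0")

    @property
    def dose_per_kg_kbq(self) -> float:
        """Injected dose per body weight, kBq/kg."""
        return self.injected_dose_mbq * 1000.0 / self.body_weight_kg
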