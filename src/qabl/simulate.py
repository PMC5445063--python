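"""Synthetic dynamic lung-PET data with known ground truth.

The generator emulates the study conditions of a 60-min dynamic FDG lung
protocol: a bolus-shaped plasma input, regional lung TACs obeying the
air/blood mixture model with irreversible-2TC tissue kinetics, two groups
(healthy-volunteer-like and COPD-like) whose parameter distributions follow
the published group means and dispersions (V_A 0.72 vs 0.79, V_B 0.14 vs
0.11, whole-lung Ki near 6.0e-3 vs 5.7e-3 ml cm^-3 min^-1), and small 4-D
digital phantoms with CT Hounsfield maps consistent with each block's air
fraction.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    TAC,
    FrameSchedule,
    InputFunction,
    ParameterError,
    RegionMask,
    SubjectMeta,
    ValidationError,
    VolumeGrid,
)
from .kinetics import FrameAverager, KineticParams, measured_model
from .lungct import hu_from_air_fraction

__all__ = [
    "default_frame_schedule",
    "dense_time_grid",
    "InputFunctionSpec",
    "synth_input_function",
    "SubjectTruth",
    "synth_regional_tac",
    "GroupSpec",
    "HV_GROUP",
    "COPD_GROUP",
    "SyntheticSubject",
    "Cohort",
    "synth_cohort",
    "dissociation_cohort",
    "PhantomSpec",
    "PhantomData",
    "synth_phantom",
    "DEFAULT_NOISE_SCALE",
]

REGIONS = ("WL", "UL", "ML", "LL")

#: Gaussian TAC-noise scale: sd = scale * sqrt(max(C, eps) / frame_minutes).
#: Whole-lung ROI means average over a multi-litre region, so their noise is
#: small; the default is calibrated so the simulated cohort's whole-lung Ki
#: CoV reproduces the published ~30%, which is dominated by between-subject
#: spread (fitted-Ki replicate noise contributes only a few percent).
DEFAULT_NOISE_SCALE = 0.05

# Deterministic regional modulation of the subject-level truth, shaped after
# the published regional pattern (apical regions: more air, higher Ki).
_REGION_KI_FACTOR = {"WL": 1.0, "UL": 1.2, "ML": 0.98, "LL": 0.9}
_REGION_VA_OFFSET = {"WL": 0.0, "UL": 0.02, "ML": 0.0, "LL": -0.04}
_REGION_VB_OFFSET = {"WL": 0.0, "UL": 0.01, "ML": 0.01, "LL": -0.03}


def default_frame_schedule() -> FrameSchedule:
    """A conventional 60-min dynamic FDG framing: 6x10 s, 4x30 s, 7x60 s, 10x300 s."""
    durations_s = [10] * 6 + [30] * 4 + [60] * 7 + [300] * 10
    ends = np.cumsum(durations_s)
    starts = ends - np.asarray(durations_s)
    return FrameSchedule.from_seconds(starts, ends)


def dense_time_grid(duration_min: float = 60.0, dt_s: float = 1.0) -> np.ndarray:
    """Uniform model-evaluation grid in minutes (1 s spacing by default)."""
    n = int(round(duration_min * 60.0 / dt_s))
    return np.arange(n + 1) * (dt_s / 60.0)


@dataclass(frozen=True)
class InputFunctionSpec:
    """Parametric stand-in for a measured bolus-injection blood curve.

    ``feng_4exp`` is the widely used tri-exponential-with-linear-rise form
    (A1*t − A2 − A3)e^{−l1 t} + A2 e^{−l2 t} + A3 e^{−l3 t}, shifted by the
    bolus arrival time ``t0_min``; ``bolus_biexp`` is a simpler
    rise-times-biexponential; ``tabulated`` passes values through.
    """

    model: str = "feng_4exp"
    t0_min: float = 0.5
    params: dict = field(default_factory=dict)

    _FENG_DEFAULTS = {"A1": 851.1, "A2": 21.9, "A3": 20.8,
                      "l1": 4.134, "l2": 0.0104, "l3": 0.1191}
    _BIEXP_DEFAULTS = {"A1": 40.0, "A2": 15.0, "l1": 0.12, "l2": 0.01, "lr": 6.0}


def synth_input_function(spec: InputFunctionSpec, times: np.ndarray,
                         kind: str = "whole_blood") -> InputFunction:
    """Evaluate an input-function spec on a dense grid.

    The curve is zero before the bolus arrival, peaks early and decays
    monotonically at late times; negative parameterisations are rejected.
    """
    times = np.asarray(times, dtype=float)
    tt = np.maximum(times - spec.t0_min, 0.0)
    if spec.model == "feng_4exp":
        p = {**InputFunctionSpec._FENG_DEFAULTS, **spec.params}
        v = ((p["A1"] * tt - p["A2"] - p["A3"]) * np.exp(-p["l1"] * tt)
             + p["A2"] * np.exp(-p["l2"] * tt) + p["A3"] * np.exp(-p["l3"] * tt))
        v[tt == 0] = 0.0
    elif spec.model == "bolus_biexp":
        p = {**InputFunctionSpec._BIEXP_DEFAULTS, **spec.params}
        v = (p["A1"] * np.exp(-p["l1"] * tt) + p["A2"] * np.exp(-p["l2"] * tt)) \
            * (1.0 - np.exp(-p["lr"] * tt))
    elif spec.model == "tabulated":
        v = np.interp(times, np.asarray(spec.params["times"], float),
                      np.asarray(spec.params["values"], float), left=0.0)
    else:
        raise ParameterError(f"unknown input-function model '{spec.model}'")
    if np.any(v < -1e-9):
        raise ParameterError("input-function spec produces negative values")
    return InputFunction(times, np.maximum(v, 0.0), kind=kind)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one simulated region/subject."""

    params: KineticParams
    delay_s: float = 0.0
    noise_scale: float = DEFAULT_NOISE_SCALE
    group_label: str = "synthetic"

    @property
    def vss(self) -> float:
        """Steady-state distribution volume of non-trapped tracer
        (K1*k2/(k2+k3)^2), recorded for normalised-Patlak composite checks."""
        return self.params.vss_patlak

    def as_dict(self) -> dict:
        p = self.params
        return {
            "K1": p.K1, "k2": p.k2, "k3": p.k3, "vb": p.vb, "va": p.va,
            "ki": p.ki, "vss": self.vss, "delay_s": self.delay_s,
            "noise_scale": self.noise_scale, "group": self.group_label,
        }


def synth_regional_tac(truth: SubjectTruth, cb: InputFunction, schedule: FrameSchedule,
                       rng: np.random.Generator | int | None = None,
                       cp: InputFunction | None = None) -> tuple[TAC, TAC]:
    """Simulate a measured regional TAC; returns ``(noisy, noise_free)``.

    The noise-free curve is the frame-averaged mixture model evaluated with
    the delayed input (positive delay: tissue lags blood).  Noise is
    zero-mean Gaussian with sd = noise_scale*sqrt(max(C, eps)/frame_minutes),
    the standard count-statistics approximation for PET TACs.
    """
    cb_d = cb.shifted(truth.delay_s) if truth.delay_s else cb
    cp_d = (cp.shifted(truth.delay_s) if truth.delay_s else cp) if cp is not None else None
    dense = measured_model(cb_d.times, truth.params, cb_d.values,
                           cp_d.values if cp_d is not None else None)
    clean_vals = FrameAverager(cb_d.times, schedule)(dense)
    clean = TAC(schedule, np.maximum(clean_vals, 0.0), from_noise=False)
    if truth.noise_scale == 0.0:
        return TAC(schedule, clean.values, from_noise=True), clean
    rng = np.random.default_rng(rng)
    sd = truth.noise_scale * np.sqrt(np.maximum(clean.values, 1e-3) / schedule.duration)
    noisy = clean.values + rng.normal(0.0, 1.0, clean.values.size) * sd
    return TAC(schedule, noisy, from_noise=True), clean


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution of a simulated group (truncated normals)."""

    label: str
    ki_mean: float
    ki_sd: float
    va_mean: float
    va_sd: float
    vb_mean: float
    vb_sd: float
    vss_mean: float = 0.5
    vss_sd: float = 0.05
    k2_mean: float = 0.19
    k2_sd: float = 0.03
    noise_scale: float = DEFAULT_NOISE_SCALE
    delay_s: float = 0.0


#: Group defaults follow the published whole-lung means and dispersions.
HV_GROUP = GroupSpec("HV", ki_mean=6.0e-3, ki_sd=1.9e-3,
                     va_mean=0.72, va_sd=0.043, vb_mean=0.14, vb_sd=0.025)
COPD_GROUP = GroupSpec("COPD", ki_mean=5.7e-3, ki_sd=1.7e-3,
                       va_mean=0.79, va_sd=0.041, vb_mean=0.11, vb_sd=0.028)


def micro_from_macro(ki: float, vss: float, k2: float) -> tuple[float, float, float]:
    """Invert (Ki, V_ss, k2) to (K1, k2, k3).

    Uses V_ss = K1*k2/(k2+k3)^2 and Ki = K1*k3/(k2+k3); the positive root of
    the induced quadratic in beta = k2 + k3 always yields k3 > 0 for Ki > 0.
    """
    if min(ki, k2) <= 0 or vss <= 0:
        raise ParameterError("ki, vss and k2 must be positive")
    beta = (vss * k2 + np.sqrt(vss**2 * k2**2 + 4.0 * vss * ki * k2)) / (2.0 * vss)
    k3 = beta - k2
    K1 = vss * beta**2 / k2
    return float(K1), float(k2), float(k3)


def _trunc_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))  # pragma: no cover - pathological spec


def _draw_subject_truth(rng, spec: GroupSpec) -> dict:
    ki = _trunc_normal(rng, spec.ki_mean, spec.ki_sd, 1e-4, 0.05)
    vss = _trunc_normal(rng, spec.vss_mean, spec.vss_sd, 0.1, 2.0)
    k2 = _trunc_normal(rng, spec.k2_mean, spec.k2_sd, 0.02, 2.0)
    va = _trunc_normal(rng, spec.va_mean, spec.va_sd, 0.3, 0.93)
    vb = _trunc_normal(rng, spec.vb_mean, spec.vb_sd, 0.02, min(0.4, 0.97 - va))
    return {"ki": ki, "vss": vss, "k2": k2, "va": va, "vb": vb}


def _regional_truth(base: dict, region: str, spec: GroupSpec) -> SubjectTruth:
    ki = base["ki"] * _REGION_KI_FACTOR[region]
    va = float(np.clip(base["va"] + _REGION_VA_OFFSET[region], 0.05, 0.95))
    vb = float(np.clip(base["vb"] + _REGION_VB_OFFSET[region], 0.01, 0.97 - va))
    K1, k2, k3 = micro_from_macro(ki, base["vss"], base["k2"])
    params = KineticParams(K1=K1, k2=k2, k3=k3, vb=vb, va=va)
    return SubjectTruth(params, delay_s=spec.delay_s, noise_scale=spec.noise_scale,
                        group_label=spec.label)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    meta: SubjectMeta
    truths: dict              # region -> SubjectTruth
    tacs: dict                # region -> noisy TAC
    clean_tacs: dict          # region -> noise-free TAC
    input_plasma: InputFunction


@dataclass
class Cohort:
    subjects: list
    schedule: FrameSchedule
    seed: int

    def truth_rows(self):
        rows = []
        for s in self.subjects:
            for region, truth in s.truths.items():
                rows.append({"subject": s.subject_id, "group": s.group,
                             "region": region, **truth.as_dict()})
        return rows


def _make_inputs(times):
    wb = synth_input_function(InputFunctionSpec(), times, kind="whole_blood")
    from .idif import plasma_correct
    return plasma_correct(wb)


def synth_cohort(n_per_group: int = 10,
                 group_specs: tuple[GroupSpec, ...] = (HV_GROUP, COPD_GROUP),
                 seed: int = 0,
                 schedule: FrameSchedule | None = None,
                 regions: tuple[str, ...] = REGIONS) -> Cohort:
    """Simulate a two-group cohort of regional TACs with truth records.

    One shared plasma-corrected input function drives all subjects; each
    subject draws (Ki, V_ss, k2, V_A, V_B) from its group's truncated
    normals and modulates them per region with fixed offsets.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    schedule = schedule or default_frame_schedule()
    times = dense_time_grid(schedule.total_minutes)
    cp = _make_inputs(times)
    rng = np.random.default_rng(seed)
    subjects = []
    for spec in group_specs:
        for i in range(n_per_group):
            base = _draw_subject_truth(rng, spec)
            truths, tacs, cleans = {}, {}, {}
            for region in regions:
                truth = _regional_truth(base, region, spec)
                noisy, clean = synth_regional_tac(truth, cp, schedule, rng)
                noisy = TAC(schedule, noisy.values, region, from_noise=True)
                clean = TAC(schedule, clean.values, region, from_noise=False)
                truths[region], tacs[region], cleans[region] = truth, noisy, clean
            meta = SubjectMeta(injected_dose_mbq=float(rng.normal(237.3, 10.4)),
                               body_weight_kg=float(np.clip(rng.normal(84.4, 12.0), 45, 130)),
                               group_label=spec.label,
                               subject_id=f"{spec.label}{i + 1:02d}")
            subjects.append(SyntheticSubject(meta.subject_id, spec.label, meta,
                                             truths, tacs, cleans, cp))
    return Cohort(subjects, schedule, seed)


def dissociation_cohort(n_per_group: int = 10, seed: int = 0,
                        noise_scale: float = DEFAULT_NOISE_SCALE,
                        regions: tuple[str, ...] = ("WL",),
                        fraction_dispersion: float = 0.0) -> Cohort:
    """Two groups with IDENTICAL tissue kinetics but shifted ROI fractions.

    Subject i of both groups shares the same (Ki, V_ss, k2) draw (healthy
    distribution); V_A/V_B sit at the published group means shifted HV ->
    COPD, so the only systematic between-group difference is the fraction
    shift.  Any group difference a method reports on these data is
    attributable to the air/blood fractions, not to tissue metabolism —
    the designed dissociation between the corrected fit and the normalised
    Patlak composite.

    ``fraction_dispersion`` scales the within-group fraction variability
    (0 = fractions pinned at the group means, the cleanest isolation of the
    composite bias; 1 = the full published dispersions, under which the
    per-subject composite shift varies strongly and can flip sign).
    Fraction deviates stay paired across groups either way.
    """
    schedule = default_frame_schedule()
    times = dense_time_grid(schedule.total_minutes)
    cp = _make_inputs(times)
    rng = np.random.default_rng(seed)
    kinetic_draws = []
    for _ in range(n_per_group):
        kinetic_draws.append({
            "ki": _trunc_normal(rng, HV_GROUP.ki_mean, HV_GROUP.ki_sd, 1e-4, 0.05),
            "vss": _trunc_normal(rng, HV_GROUP.vss_mean, HV_GROUP.vss_sd, 0.1, 2.0),
            "k2": _trunc_normal(rng, HV_GROUP.k2_mean, HV_GROUP.k2_sd, 0.02, 2.0),
            "z_va": float(np.clip(rng.standard_normal(), -2.5, 2.5)),
            "z_vb": float(np.clip(rng.standard_normal(), -2.5, 2.5)),
        })
    subjects = []
    for spec in (HV_GROUP, COPD_GROUP):
        for i, kin in enumerate(kinetic_draws):
            va = float(np.clip(spec.va_mean + fraction_dispersion * kin["z_va"] * spec.va_sd,
                               0.3, 0.93))
            vb = float(np.clip(spec.vb_mean + fraction_dispersion * kin["z_vb"] * spec.vb_sd,
                               0.02, min(0.4, 0.97 - va)))
            base = {**kin, "va": va, "vb": vb}
            truths, tacs, cleans = {}, {}, {}
            for region in regions:
                truth = _regional_truth(base, region,
                                        GroupSpec(spec.label, kin["ki"], 0, va, 0, vb, 0,
                                                  noise_scale=noise_scale))
                noisy, clean = synth_regional_tac(truth, cp, schedule, rng)
                truths[region] = truth
                tacs[region] = TAC(schedule, noisy.values, region, from_noise=True)
                cleans[region] = TAC(schedule, clean.values, region, from_noise=False)
            meta = SubjectMeta(237.3, 84.4, spec.label, f"{spec.label}{i + 1:02d}")
            subjects.append(SyntheticSubject(meta.subject_id, spec.label, meta,
                                             truths, tacs, cleans, cp))
    return Cohort(subjects, schedule, seed)


@dataclass(frozen=True)
class PhantomSpec:
    """Block layout of a small digital thorax phantom.

    ``lung_blocks`` maps a block label to ``(z_lo, z_hi, SubjectTruth)``
    slabs (z ranges are half-open voxel indices); a 2x2 blood-pool column
    spans all slices at ``blood_xy``; everything else is air.
    """

    shape: tuple = (10, 10, 9)
    lung_blocks: dict = field(default_factory=dict)
    blood_xy: tuple = (0, 0)
    voxel_size_mm: tuple = (8.0, 8.0, 8.0)
    noise_scale: float = 0.0

    def __post_init__(self):
        if any(s > 64 for s in self.shape):
            raise ParameterError("phantom exceeds the 64^3 desk-scale guard")


@dataclass
class PhantomData:
    pet4d: np.ndarray         # (x, y, z, frame), kBq/ml
    ct: VolumeGrid            # HU
    masks: dict               # label -> RegionMask ('WL' + per block)
    aorta_centres: list       # (slice, x, y) per slice
    schedule: FrameSchedule
    truths: dict              # block label -> SubjectTruth
    cb_whole_blood: InputFunction
    cp_plasma: InputFunction


def synth_phantom(spec: PhantomSpec | None = None, seed: int = 0,
                  schedule: FrameSchedule | None = None) -> PhantomData:
    """Build a 4-D PET + CT phantom whose every voxel follows its block truth.

    Block CT values invert the air-fraction relation (HU = 40 − V_A·1064) so
    the CT route recovers each block's V_A exactly; lung-block PET voxels
    carry the frame-averaged mixture model (optionally with voxel noise) and
    the blood column carries the whole-blood curve.
    """
    schedule = schedule or default_frame_schedule()
    if schedule.n_frames > 40:
        raise ParameterError("phantom frame count exceeds the desk-scale guard")
    if spec is None:
        params = KineticParams(K1=0.106, k2=0.188, k3=0.012, vb=0.14, va=0.72)
        truth = SubjectTruth(params, noise_scale=0.0, group_label="HV")
        spec = PhantomSpec(lung_blocks={"lung": (0, 9, truth)})
    times = dense_time_grid(schedule.total_minutes)
    cb = synth_input_function(InputFunctionSpec(), times, kind="whole_blood")
    from .idif import plasma_correct
    cp = plasma_correct(cb)
    avg = FrameAverager(times, schedule)
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(seed)

    ct = np.full(spec.shape, hu_from_air_fraction(1.0))      # air background
    pet = np.zeros((nx, ny, nz, schedule.n_frames))
    masks = {}
    wl = np.zeros(spec.shape, dtype=bool)
    bx, by = spec.blood_xy
    blood = np.zeros(spec.shape, dtype=bool)
    blood[bx : bx + 2, by : by + 2, :] = True
    ct[blood] = hu_from_air_fraction(0.0)
    pet[blood] = avg(cb.values)

    for label, (z0, z1, truth) in spec.lung_blocks.items():
        if not (0 <= z0 < z1 <= nz):
            raise ValidationError(f"block '{label}' z-range outside the grid")
        block = np.zeros(spec.shape, dtype=bool)
        block[:, :, z0:z1] = True
        block &= ~blood
        truth = SubjectTruth(truth.params, truth.delay_s, spec.noise_scale,
                             truth.group_label)
        noisy, clean = synth_regional_tac(truth, cp, schedule, rng)
        ct[block] = hu_from_air_fraction(truth.params.va)
        base = clean.values if spec.noise_scale == 0 else None
        if base is not None:
            pet[block] = base
        else:
            sd = truth.noise_scale * np.sqrt(np.maximum(clean.values, 1e-3) / schedule.duration)
            nvox = int(block.sum())
            pet[block] = clean.values + rng.normal(0, 1, (nvox, schedule.n_frames)) * sd
        masks[label] = RegionMask(block, spec.voxel_size_mm, label)
        wl |= block

    masks["WL"] = RegionMask(wl, spec.voxel_size_mm, "WL")
    masks["DA"] = RegionMask(blood, spec.voxel_size_mm, "DA")
    centres = [(z, bx, by) for z in range(nz)]
    truths = {label: b[2] for label, b in spec.lung_blocks.items()}
    return PhantomData(pet, VolumeGrid(ct, spec.voxel_size_mm), masks, centres,
                       schedule, truths, cb, cp)
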