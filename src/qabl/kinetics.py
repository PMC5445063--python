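"""Compartmental forward models and the qABL fit.

The measured lung signal is modelled as a volume-weighted mixture of blood
and tissue activity (the air term carries no intravenous tracer):

    C_M(t) = V_B * C_B(t) + (1 - V_B - V_A^CT) * C_T(t; K1, k2, k3, C_B)

with the tissue kinetics C_T given by the irreversible two-tissue
compartment (2TC) model standard for FDG.  The fractional air volume
V_A^CT is measured from CT and held fixed; the remaining four parameters
(K1, k2, k3, V_B) are estimated by bounded weighted least squares.  The
outcome of interest is the tissue metabolic rate constant

    Ki = K1 * k3 / (k2 + k3)        [ml cm^-3 min^-1]

Convolutions use the exact solution for a piecewise-linear input sampled on
a uniform dense grid (1 s by default), so the forward model is accurate to
interpolation error only, with no ODE-solver tolerance in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares, minimize_scalar
from scipy.signal import lfilter
from scipy.stats import qmc

from .core import (
    TAC,
    DegenerateDataError,
    FitError,
    FrameSchedule,
    InputFunction,
    ParameterError,
    ValidationError,
)

__all__ = [
    "KineticParams",
    "QABLFit",
    "ki_from_micro",
    "exp_conv",
    "tissue_response_2tc_irrev",
    "measured_model",
    "FrameAverager",
    "frame_average",
    "fit_qabl",
    "fit_1tc",
    "DEFAULT_BOUNDS",
]

#: Fit bounds (min^-1 scale where applicable): K1, k2, k3; V_B bound is
#: [0, 1 - V_A^CT], set per fit.
DEFAULT_BOUNDS = {"K1": (0.0, 2.0), "k2": (0.0, 5.0), "k3": (0.0, 1.0)}

_MULTISTART_SEED = 20170525  # fixed Latin-hypercube seed for reproducible starts


def ki_from_micro(K1: float, k2: float, k3: float) -> float:
    """Net irreversible uptake rate constant Ki = K1*k3/(k2+k3).

    Total on the non-negative orthant: returns 0 when k2 = k3 = 0 (pure
    trapping contributes through K1 directly in that degenerate limit) and
    K1 when k2 = 0, k3 > 0 (all delivered tracer is trapped).
    """
    if min(K1, k2, k3) < 0:
        raise ParameterError("rate constants must be non-negative")
    s = k2 + k3
    if s == 0:
        return 0.0
    return K1 * k3 / s


@dataclass(frozen=True)
class KineticParams:
    """Microparameters and fractional volumes of the measured-signal model.

    Units: K1 and ki in ml cm^-3 min^-1; k2, k3 in min^-1; va, vb are
    dimensionless fractions with va + vb <= 1.
    """

    K1: float
    k2: float
    k3: float
    vb: float = 0.0
    va: float = 0.0

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.vb, self.va) < 0:
            raise ParameterError("kinetic parameters must be non-negative")
        if self.vb + self.va > 1.0 + 1e-12:
            raise ParameterError("vb + va must not exceed 1")

    @property
    def ki(self) -> float:
        return ki_from_micro(self.K1, self.k2, self.k3)

    @property
    def tissue_fraction(self) -> float:
        return 1.0 - self.vb - self.va

    @property
    def vss_patlak(self) -> float:
        """Steady-state distribution volume of non-trapped tracer.

        K1*k2/(k2+k3)^2 — the coefficient the tissue term contributes to the
        late-time Patlak intercept under the irreversible 2TC model.
        """
        s = self.k2 + self.k3
        return self.K1 * self.k2 / s**2 if s > 0 else 0.0


@dataclass(frozen=True)
class QABLFit:
    """Result of a qABL weighted least-squares fit."""

    params: KineticParams
    wrss: float
    n_frames_used: int
    converged: bool
    start_point_index: int
    n_starts_converged: int = 0

    @property
    def ki(self) -> float:
        return self.params.ki


def exp_conv(values: np.ndarray, dt: float, beta: float) -> np.ndarray:
    """Exact convolution of a piecewise-linear signal with exp(-beta*t).

    ``values`` samples the signal on a uniform grid of spacing ``dt``
    (minutes).  For beta = 0 this reduces to the cumulative integral
    (trapezoid, exact for piecewise-linear signals).
    """
    values = np.asarray(values, dtype=float)
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    if beta == 0.0:
        return cumulative_trapezoid(values, dx=dt, initial=0.0)
    E = np.exp(-beta * dt)
    g1 = (1.0 - E) / beta
    g2 = (1.0 - (1.0 + beta * dt) * E) / beta**2
    f_prev = g2 / dt                # weight of c[n]   in y[n+1]
    f_next = g1 - g2 / dt           # weight of c[n+1] in y[n+1]
    y = lfilter([f_next, f_prev], [1.0, -E], values)
    # lfilter seeds y[0] = f_next*c[0]; the true initial value is 0 and the
    # spurious term decays homogeneously, so subtract its propagation.
    if values[0] != 0.0:
        y = y - f_next * values[0] * E ** np.arange(values.size)
    else:
        y[0] = 0.0
    return y


def _uniform_dt(times: np.ndarray) -> float:
    d = np.diff(times)
    if d.size == 0 or not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
        raise ValidationError("model evaluation requires a uniform time grid")
    return float(d[0])


def tissue_response_2tc_irrev(
    times: np.ndarray, K1: float, k2: float, k3: float, cp_values: np.ndarray
) -> np.ndarray:
    """Tissue curve C_T(t) of the irreversible 2TC model driven by ``cp``.

    Impulse response h(t) = K1*[k3/(k2+k3) + k2/(k2+k3)*exp(-(k2+k3) t)]
    (h = K1 for the pure-trapping limit k2 = k3 = 0), convolved exactly with
    the piecewise-linear input.
    """
    if min(K1, k2, k3) < 0:
        raise ParameterError("rate constants must be non-negative")
    times = np.asarray(times, dtype=float)
    cp_values = np.asarray(cp_values, dtype=float)
    dt = _uniform_dt(times)
    beta = k2 + k3
    if beta == 0.0:
        return K1 * cumulative_trapezoid(cp_values, dx=dt, initial=0.0)
    a = k3 / beta
    b = k2 / beta
    out = np.zeros_like(cp_values)
    if a != 0.0:
        out += a * cumulative_trapezoid(cp_values, dx=dt, initial=0.0)
    if b != 0.0:
        out += b * exp_conv(cp_values, dt, beta)
    return K1 * out


def measured_model(
    times: np.ndarray,
    params: KineticParams,
    cb_values: np.ndarray,
    cp_values: np.ndarray | None = None,
) -> np.ndarray:
    """Dense measured-signal curve V_B*C_B + (1 - V_B - V_A^CT)*C_T.

    ``cb_values`` feeds the vascular term; ``cp_values`` (default: same
    curve) drives the tissue compartments.  The air term is omitted:
    intravenously administered tracer contributes no airway activity.
    """
    if params.vb + params.va > 1.0 + 1e-12:
        raise ParameterError("vb + va must not exceed 1")
    cb_values = np.asarray(cb_values, dtype=float)
    if cp_values is None:
        cp_values = cb_values
    ct = tissue_response_2tc_irrev(times, params.K1, params.k2, params.k3, cp_values)
    return params.vb * cb_values + params.tissue_fraction * ct


class FrameAverager:
    """Linear operator averaging a dense curve over each PET frame.

    Precomputes trapezoid quadrature weights mapping dense-grid samples to
    frame means, so repeated model evaluations inside a fit are a single
    matrix-vector product.  ``mode='midpoint'`` samples the curve at frame
    midpoints instead.
    """

    def __init__(self, times: np.ndarray, schedule: FrameSchedule, mode: str = "mean"):
        times = np.asarray(times, dtype=float)
        if schedule.end[-1] > times[-1] + 1e-9:
            raise ValidationError("schedule extends beyond the dense time grid")
        if mode not in ("mean", "midpoint"):
            raise ParameterError(f"unknown frame-averaging mode '{mode}'")
        self.times = times
        self.schedule = schedule
        self.mode = mode
        n, m = schedule.n_frames, times.size
        W = np.zeros((n, m))
        if mode == "midpoint":
            for i, t in enumerate(schedule.mid):
                W[i] = self._interp_row(times, t)
        else:
            for i, (s, e) in enumerate(zip(schedule.start, schedule.end)):
                W[i] = self._mean_row(times, s, e)
        self.W = W

    @staticmethod
    def _interp_row(times, t):
        row = np.zeros(times.size)
        j = np.searchsorted(times, t, side="right") - 1
        j = min(max(j, 0), times.size - 2)
        w = (t - times[j]) / (times[j + 1] - times[j])
        row[j] = 1.0 - w
        row[j + 1] = w
        return row

    @staticmethod
    def _mean_row(times, s, e):
        # Trapezoid integral over [s, e] of the piecewise-linear curve,
        # divided by the frame duration; endpoints land between grid nodes
        # via interpolation weights.
        nodes = list(times[(times > s) & (times < e)])
        pts = np.array([s] + nodes + [e])
        rows = np.stack([FrameAverager._interp_row(times, p) for p in pts])
        seg = np.diff(pts)
        w = np.zeros(times.size)
        for k in range(seg.size):
            w += 0.5 * seg[k] * (rows[k] + rows[k + 1])
        return w / (e - s)

    def __call__(self, dense_values: np.ndarray) -> np.ndarray:
        return self.W @ np.asarray(dense_values, dtype=float)


def frame_average(times, dense_values, schedule: FrameSchedule, mode: str = "mean"):
    """One-shot frame averaging (see :class:`FrameAverager`)."""
    return FrameAverager(times, schedule, mode)(dense_values)


def _frame_weights(schedule: FrameSchedule, values: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        w = np.ones(schedule.n_frames)
    elif scheme == "duration":
        w = schedule.duration.copy()
    elif scheme == "duration_value":
        w = schedule.duration / np.maximum(np.abs(values), 1e-3)
    else:
        raise ParameterError(f"unknown weighting scheme '{scheme}'")
    return w / w.mean()


def _require_aligned(cb: InputFunction, cp: InputFunction | None):
    if cp is None:
        return cb
    if cp.times.size != cb.times.size or not np.allclose(cp.times, cb.times):
        raise ValidationError("blood and plasma curves must share one time grid")
    return cp


def fit_qabl(
    tac: TAC,
    cb: InputFunction,
    cp: InputFunction | None = None,
    va_ct: float = 0.0,
    weights: str = "duration",
    n_starts: int = 10,
    frame_mode: str = "mean",
) -> QABLFit:
    """Fit the air/blood-corrected lung model to a regional TAC.

    Parameters
    ----------
    tac : TAC
        Measured regional curve (delay alignment already applied).
    cb : InputFunction
        Blood curve feeding the vascular term.
    cp : InputFunction, optional
        Curve driving the tissue compartments; defaults to ``cb`` (the
        single corrected blood input function).
    va_ct : float
        CT-derived fractional air volume of the region, in [0, 1).
    weights : {'uniform', 'duration', 'duration_value'}
        Per-frame weights; the default weights residuals by frame duration
        (variance inversely proportional to counting time).
    n_starts : int
        Multi-start count; starts come from a fixed Latin hypercube so the
        fit is deterministic.

    Returns
    -------
    QABLFit
        Best converged start by weighted residual sum of squares, with
        Ki derived from the fitted microparameters.
    """
    if not (0.0 <= va_ct < 1.0):
        raise ParameterError("va_ct must lie in [0, 1)")
    cp = _require_aligned(cb, cp)
    if np.allclose(tac.values, 0.0):
        raise DegenerateDataError("all-zero TAC cannot constrain a fit")

    times = cb.times
    avg = FrameAverager(times, tac.schedule, frame_mode)
    sw = np.sqrt(_frame_weights(tac.schedule, tac.values, weights))
    vb_max = 1.0 - va_ct
    lo = np.array([DEFAULT_BOUNDS["K1"][0], DEFAULT_BOUNDS["k2"][0], DEFAULT_BOUNDS["k3"][0], 0.0])
    hi = np.array([DEFAULT_BOUNDS["K1"][1], DEFAULT_BOUNDS["k2"][1], DEFAULT_BOUNDS["k3"][1], vb_max])

    cbv, cpv = cb.values, cp.values
    cum_cp = cumulative_trapezoid(cpv, dx=cb.dt, initial=0.0)

    def residuals(x):
        K1, k2, k3, vb = x
        beta = k2 + k3
        if beta == 0.0:
            ct = K1 * cum_cp
        else:
            ct = K1 * ((k3 / beta) * cum_cp + (k2 / beta) * exp_conv(cpv, cb.dt, beta))
        model = vb * cbv + (1.0 - vb - va_ct) * ct
        return sw * (avg(model) - tac.values)

    sampler = qmc.LatinHypercube(d=4, seed=_MULTISTART_SEED)
    unit = sampler.random(n=max(n_starts, 1))
    span_lo = np.array([0.005, 0.02, 0.002, 0.0])
    span_hi = np.array([0.5, 1.5, 0.3, 0.8 * vb_max])
    starts = span_lo + unit * (span_hi - span_lo)

    best = None
    best_idx = -1
    n_ok = 0
    diagnostics = []
    for i, x0 in enumerate(starts):
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - optimizer-internal failure
            diagnostics.append((i, f"error: {exc}"))
            continue
        if not (res.success and np.isfinite(res.cost)):
            diagnostics.append((i, f"status {res.status}"))
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best, best_idx = res, i
    if best is None:
        raise FitError(f"no start point converged: {diagnostics}")

    K1, k2, k3, vb = (float(v) for v in best.x)
    params = KineticParams(K1=K1, k2=k2, k3=k3, vb=min(vb, vb_max), va=va_ct)
    return QABLFit(
        params=params,
        wrss=float(2.0 * best.cost),
        n_frames_used=tac.schedule.n_frames,
        converged=True,
        start_point_index=best_idx,
        n_starts_converged=n_ok,
    )


def _profiled_k2_fit(y, w, basis_of_k2):
    """Scan-and-refine over k2 with the linear coefficients profiled out.

    ``basis_of_k2(k2)`` returns a (n_frames, p) design; the non-negative
    linear coefficients are solved per k2 by NNLS, so the outer search is a
    robust 1-D problem.  Returns ``(k2, coefs, wrss)``.
    """
    from scipy.optimize import nnls

    sw = np.sqrt(w)

    def rss_of(k2):
        A = basis_of_k2(k2) * sw[:, None]
        coefs, rnorm = nnls(A, y * sw)
        return rnorm**2, coefs

    k2_grid = np.concatenate(([0.0], np.geomspace(5e-3, 5.0, 48)))
    costs = np.array([rss_of(k)[0] for k in k2_grid])
    j = int(np.argmin(costs))
    lo = k2_grid[max(j - 1, 0)]
    hi = k2_grid[min(j + 1, k2_grid.size - 1)]
    k2 = float(k2_grid[j])
    if hi > lo:
        res = minimize_scalar(lambda k: rss_of(k)[0], bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        if res.fun <= costs[j]:
            k2 = float(res.x)
    wrss, coefs = rss_of(k2)
    if not np.isfinite(wrss):
        raise FitError("one-tissue fit produced non-finite residuals")
    return k2, coefs, float(wrss)


def fit_1tc(
    tac: TAC,
    cp: InputFunction,
    window_min: float | None = None,
    weights: str = "duration",
    blood_fraction: bool = False,
) -> tuple[float, float, float]:
    """Weighted least-squares fit of the one-tissue model K1*exp(-k2 t) (x) Cp.

    K1 enters linearly and is profiled out analytically (constrained to be
    non-negative); k2 is found by a dense scan refined with bounded scalar
    minimisation — robust and fast enough to sit inside the delay grid
    search.  With ``blood_fraction`` an additional vb*Cp vascular term is
    profiled alongside K1, which lets the short model absorb the blood
    spike of an uncorrected lung TAC.  Returns ``(K1, k2, wrss)`` over
    frames with midpoint inside the window (all frames when ``window_min``
    is None).
    """
    work = tac if window_min is None else tac.restricted(window_min)
    times = cp.times
    dt = cp.dt
    avg = FrameAverager(times, work.schedule)
    w = _frame_weights(work.schedule, work.values, weights)
    y = work.values
    cum = cumulative_trapezoid(cp.values, dx=dt, initial=0.0)
    cb_frames = avg(cp.values)

    def basis(k2):
        m = avg(exp_conv(cp.values, dt, k2) if k2 > 0 else cum)
        if blood_fraction:
            return np.column_stack([m, cb_frames])
        return m[:, None]

    k2, coefs, wrss = _profiled_k2_fit(y, w, basis)
    return float(coefs[0]), k2, wrss
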