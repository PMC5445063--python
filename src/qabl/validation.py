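"""Self-validation experiments with independent oracles.

Each function re-derives a known quantity through the full package path and
reports the discrepancy against an independent reference: closed-form
algebra, an ODE integrator, or ground truth carried by the synthetic
generator.  The test suite and the reproduction script both run these.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import KineticParams, tissue_response_2tc_irrev
from .lungct import air_fraction_from_hu, hu_from_air_fraction
from .patlak import CompositeParams, nki_composite_prediction, patlak_analysis
from .simulate import (
    InputFunctionSpec,
    PhantomSpec,
    SubjectTruth,
    default_frame_schedule,
    dense_time_grid,
    micro_from_macro,
    synth_input_function,
    synth_phantom,
    synth_regional_tac,
)
from .workflow import analyze_phantom

__all__ = [
    "CANONICAL_TRUTH",
    "air_fraction_roundtrip_error",
    "convolution_vs_ode_error",
    "phantom_recovery_errors",
    "patlak_asymptote_errors",
    "delay_recovery_errors",
]

#: Reference lung truth for worked examples and asymptote checks: healthy
#: fractions with 2TC rates in the range reported for human lung FDG.
CANONICAL_TRUTH = KineticParams(K1=0.05, k2=0.4, k3=0.06, vb=0.14, va=0.72)


def _plasma(times):
    return synth_input_function(InputFunctionSpec(), times, kind="plasma_corrected")


def air_fraction_roundtrip_error(n: int = 100) -> float:
    """Max |recovered − true| air fraction over an inversion round trip."""
    va = np.linspace(0.0, 1.0, n)
    rec = np.array([air_fraction_from_hu(hu_from_air_fraction(v)) for v in va])
    return float(np.max(np.abs(rec - va)))


def convolution_vs_ode_error(n_sets: int = 20, seed: int = 0) -> float:
    """Max sup-norm relative error of the exact-convolution tissue curve
    against stiff ODE integration of the 2TC system, over random rates."""
    times = dense_time_grid(60.0)
    cp = _plasma(times)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sets):
        K1 = rng.uniform(0.01, 0.5)
        k2 = rng.uniform(0.05, 1.0)
        k3 = rng.uniform(0.005, 0.2)
        ct = tissue_response_2tc_irrev(times, K1, k2, k3, cp.values)

        def rhs(t, y):
            c = np.interp(t, times, cp.values)
            return [K1 * c - (k2 + k3) * y[0], k3 * y[0]]

        sol = solve_ivp(rhs, (0.0, times[-1]), [0.0, 0.0], t_eval=times,
                        rtol=1e-9, atol=1e-12, max_step=1 / 60)
        ref = sol.y.sum(axis=0)
        worst = max(worst, float(np.max(np.abs(ct - ref)) / ref.max()))
    return worst


def _random_truth(rng) -> SubjectTruth:
    ki = rng.uniform(3e-3, 9e-3)
    vss = rng.uniform(0.08, 0.6)
    K1, k2, k3 = micro_from_macro(ki, vss, rng.uniform(0.15, 0.6))
    va = rng.uniform(0.6, 0.85)
    vb = rng.uniform(0.08, min(0.2, 0.95 - va))
    delay = float(rng.integers(-30, 31))
    return SubjectTruth(KineticParams(K1, k2, k3, vb=vb, va=va),
                        delay_s=delay, noise_scale=0.0)


def phantom_recovery_errors(n_truths: int = 20, seed: int = 0) -> dict:
    """Noise-free end-to-end identifiability on single-block phantoms.

    For each random physiologic truth, builds a 4-D phantom, runs the full
    image pipeline (CT air fraction, aorta IDIF, plasma correction, delay
    grid search, corrected fit) and records the worst relative parameter
    errors and delay error.
    """
    rng = np.random.default_rng(seed)
    worst = {k: 0.0 for k in ("K1", "k2", "k3", "vb", "ki")}
    worst_delay = 0.0
    for i in range(n_truths):
        truth = _random_truth(rng)
        ph = synth_phantom(PhantomSpec(lung_blocks={"lung": (0, 9, truth)}),
                           seed=int(rng.integers(0, 2**31 - 1)))
        res = analyze_phantom(ph)
        row = res.rows[0]
        for k in worst:
            ref = getattr(truth.params, k) if k != "ki" else truth.params.ki
            worst[k] = max(worst[k], abs(row[k] - ref) / ref)
        worst_delay = max(worst_delay, abs(res.delay_s - truth.delay_s))
    worst["delay_s"] = worst_delay
    worst["n"] = n_truths
    return worst


def patlak_asymptote_errors(t_star: float = 40.0) -> dict:
    """Late-window Patlak against its algebraic asymptote on the canonical
    truth: slope vs (1−V_A−V_B)·Ki, and nKi vs the composite formula with
    the truth's steady-state distribution volume."""
    schedule = default_frame_schedule()
    times = dense_time_grid(schedule.total_minutes)
    cp = _plasma(times)
    p = CANONICAL_TRUTH
    _, clean = synth_regional_tac(SubjectTruth(p, noise_scale=0.0), cp, schedule)
    res = patlak_analysis(clean, cp, t_star=t_star)
    slope_target = p.tissue_fraction * p.ki
    nki_target = nki_composite_prediction(
        CompositeParams(ki=p.ki, va=p.va, vb=p.vb, vss=p.vss_patlak))
    return {
        "slope_rel_error": abs(res.slope - slope_target) / slope_target,
        "nki_rel_error": abs(res.nki - nki_target) / nki_target,
        "slope": res.slope,
        "nki": res.nki,
        "t_star": t_star,
    }


def delay_recovery_errors(shifts_s=(-37.0, 0.0, 20.0)) -> dict:
    """Grid-search recovery of injected blood-to-tissue shifts (noise-free)."""
    from .idif import estimate_delay

    schedule = default_frame_schedule()
    times = dense_time_grid(schedule.total_minutes)
    cp = _plasma(times)
    errs = {}
    for d in shifts_s:
        truth = SubjectTruth(CANONICAL_TRUTH, delay_s=float(d), noise_scale=0.0)
        _, clean = synth_regional_tac(truth, cp, schedule)
        est = estimate_delay(cp, clean)
        errs[d] = abs(est.delay_s - d)
    return {"max_error_s": max(errs.values()), "per_shift": errs}
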