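import numpy as np
import pytest

from qabl.core import TAC, FrameSchedule, ParameterError, SubjectMeta, ValidationError
from qabl.patlak import (
    CompositeParams,
    nki_composite_prediction,
    patlak_analysis,
    patlak_fit,
    patlak_points,
    patlak_slope_map,
    suv,
)
from qabl.simulate import SubjectTruth, synth_regional_tac


class TestPatlakPoints:
    def test_constant_curves(self, schedule, flat_input):
        tac = TAC(schedule, np.full(schedule.n_frames, 3.0))
        x, y, used = patlak_points(tac, flat_input)
        np.testing.assert_allclose(x[used], schedule.mid[used], rtol=1e-9)
        np.testing.assert_allclose(y[used], 3.0)

    def test_proportional_tac_gives_constant_y(self, schedule, times, cp):
        from qabl.kinetics import FrameAverager
        vals = FrameAverager(times, schedule, mode="midpoint")(0.25 * cp.values)
        tac = TAC(schedule, vals)
        _, y, used = patlak_points(tac, cp)
        np.testing.assert_allclose(y[used], 0.25, rtol=1e-9)


class TestPatlakFit:
    def test_exact_line(self):
        x = np.linspace(11, 60, 8)
        y = 0.5 * x + 0.2
        res = patlak_fit(x, y, np.ones_like(x, bool), t_star=10.0)
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.2)
        assert res.nki == pytest.approx(2.5)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            patlak_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                       np.array([True, False]))

    def test_straddling_frame_excluded(self, cp):
        sched = FrameSchedule([8.0, 9.5, 11.0, 13.0], [9.5, 11.0, 13.0, 15.0])
        tac = TAC(sched, np.ones(4))
        res = patlak_analysis(tac, cp, t_star=10.0)
        assert res.n_points == 2  # frames starting at 11 and 13 only


class TestPatlakOnSyntheticKinetics:
    def test_slope_approaches_tissue_weighted_ki(self, schedule, cp, canonical_params):
        truth = SubjectTruth(canonical_params, noise_scale=0.0)
        _, clean = synth_regional_tac(truth, cp, schedule)
        target = canonical_params.tissue_fraction * canonical_params.ki
        err10 = abs(patlak_analysis(clean, cp, t_star=10).slope - target) / target
        err40 = abs(patlak_analysis(clean, cp, t_star=40).slope - target) / target
        assert err10 < 0.03
        assert err40 < 0.01
        assert err40 < err10  # monotone approach to the asymptote

    def test_nki_matches_composite_prediction(self, schedule, cp, canonical_params):
        truth = SubjectTruth(canonical_params, noise_scale=0.0)
        _, clean = synth_regional_tac(truth, cp, schedule)
        res = patlak_analysis(clean, cp, t_star=40)
        pred = nki_composite_prediction(CompositeParams(
            ki=canonical_params.ki, va=canonical_params.va,
            vb=canonical_params.vb, vss=canonical_params.vss_patlak))
        assert res.nki == pytest.approx(pred, rel=0.05)


class TestCompositePrediction:
    def test_pure_tissue_limit(self):
        p = CompositeParams(ki=6e-3, va=0.0, vb=0.0, vss=0.5)
        assert nki_composite_prediction(p) == pytest.approx(6e-3 / 0.5)

    def test_worked_value_with_published_fractions(self):
        p = CompositeParams(ki=6.0e-3, va=0.72, vb=0.14, vss=0.5)
        assert nki_composite_prediction(p) == pytest.approx(4.0e-3)

    def test_fraction_shift_moves_composite_at_fixed_ki(self):
        hv = nki_composite_prediction(CompositeParams(6e-3, va=0.72, vb=0.14, vss=0.5))
        copd = nki_composite_prediction(CompositeParams(6e-3, va=0.79, vb=0.11, vss=0.5))
        assert hv != pytest.approx(copd, rel=1e-3)

    def test_monotone_in_ki_and_antitone_in_vss(self):
        base = nki_composite_prediction(CompositeParams(6e-3, 0.72, 0.14, 0.5))
        assert nki_composite_prediction(CompositeParams(7e-3, 0.72, 0.14, 0.5)) > base
        assert nki_composite_prediction(CompositeParams(6e-3, 0.72, 0.14, 0.6)) < base

    def test_zero_denominator_rejected(self):
        with pytest.raises(ParameterError):
            nki_composite_prediction(CompositeParams(6e-3, va=1.0, vb=0.0, vss=0.5))


class TestSlopeMap:
    def test_uniform_phantom_matches_regional_value(self, schedule, times, cp, canonical_params):
        truth = SubjectTruth(canonical_params, noise_scale=0.0)
        _, clean = synth_regional_tac(truth, cp, schedule)
        pet = np.broadcast_to(clean.values, (3, 3, 2, schedule.n_frames)).copy()
        vol = patlak_slope_map(pet, cp, schedule)
        regional = patlak_analysis(clean, cp).slope
        np.testing.assert_allclose(vol.data, regional, rtol=1e-9)

    def test_two_blocks_have_distinct_slopes(self, schedule, cp, canonical_params):
        from qabl.kinetics import KineticParams
        p2 = KineticParams(0.1, 0.4, 0.06, vb=0.14, va=0.72)
        _, c1 = synth_regional_tac(SubjectTruth(canonical_params, noise_scale=0.0), cp, schedule)
        _, c2 = synth_regional_tac(SubjectTruth(p2, noise_scale=0.0), cp, schedule)
        pet = np.zeros((2, 1, 1, schedule.n_frames))
        pet[0, 0, 0] = c1.values
        pet[1, 0, 0] = c2.values
        vol = patlak_slope_map(pet, cp, schedule)
        assert vol.data[0, 0, 0] == pytest.approx(patlak_analysis(c1, cp).slope, rel=1e-9)
        assert vol.data[1, 0, 0] == pytest.approx(patlak_analysis(c2, cp).slope, rel=1e-9)

    def test_air_voxels_have_near_zero_slope(self, schedule, cp):
        pet = np.zeros((2, 2, 1, schedule.n_frames))
        vol = patlak_slope_map(pet, cp, schedule)
        np.testing.assert_allclose(vol.data, 0.0, atol=1e-12)


class TestSUV:
    def _meta(self):
        return SubjectMeta(injected_dose_mbq=200.0, body_weight_kg=80.0)

    def test_constant_activity(self, schedule):
        meta = self._meta()
        tac = TAC(schedule, np.full(schedule.n_frames, 5.0))
        assert suv(tac, meta) == pytest.approx(5.0 / meta.dose_per_kg_kbq)

    def test_unit_suv_by_definition(self, schedule):
        meta = self._meta()
        tac = TAC(schedule, np.full(schedule.n_frames, meta.dose_per_kg_kbq))
        assert suv(tac, meta) == pytest.approx(1.0)

    def test_duration_weighted_mean(self, schedule):
        meta = self._meta()
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 5, schedule.n_frames)
        tac = TAC(schedule, vals)
        sel = (schedule.mid >= 30) & (schedule.mid <= 60)
        expected = np.sum(schedule.duration[sel] * vals[sel]) / np.sum(schedule.duration[sel])
        assert suv(tac, meta) == pytest.approx(expected / meta.dose_per_kg_kbq)

    def test_rebinning_invariance_for_constant_tac(self):
        meta = self._meta()
        coarse = FrameSchedule([30.0, 45.0], [45.0, 60.0])
        fine = FrameSchedule(np.arange(30.0, 60.0, 5.0), np.arange(35.0, 65.0, 5.0))
        v = 7.0
        assert suv(TAC(coarse, [v, v]), meta) == pytest.approx(
            suv(TAC(fine, np.full(fine.n_frames, v)), meta))

    def test_window_coverage_required(self):
        sched = FrameSchedule([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            suv(TAC(sched, [1.0, 1.0]), self._meta())
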