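import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qabl.core import FrameSchedule, ParameterError, RegionMask, ValidationError, VolumeGrid
from qabl.lungct import (
    air_fraction_from_hu,
    downsample_hu,
    downsample_mask,
    extract_tac,
    hu_from_air_fraction,
    regional_mean_hu,
    subdivide_lung_axially,
)


class TestAirFraction:
    @pytest.mark.parametrize("hu,expected", [
        (-1024.0, 1.0),          # pure air
        (40.0, 0.0),             # pure tissue
        (-726.08, 0.72),         # healthy-lung scale
        (-492.0, 0.5),           # midpoint of the HU range
    ])
    def test_worked_values(self, hu, expected):
        assert air_fraction_from_hu(hu) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_is_clipped(self):
        assert air_fraction_from_hu(-1100.0) == 1.0
        assert air_fraction_from_hu(100.0) == 0.0

    def test_degenerate_hu_anchors_rejected(self):
        with pytest.raises(ParameterError):
            air_fraction_from_hu(-500.0, hu_air=40.0, hu_tissue=40.0)

    @given(st.floats(min_value=-1023.0, max_value=39.0),
           st.floats(min_value=0.1, max_value=1063.0))
    def test_strictly_decreasing_in_mean_hu(self, hu, delta):
        hu2 = min(hu + delta, 39.9)
        if hu2 > hu:
            assert air_fraction_from_hu(hu2) < air_fraction_from_hu(hu)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_hu_inversion_round_trip(self, va):
        assert air_fraction_from_hu(hu_from_air_fraction(va)) == pytest.approx(va, abs=1e-12)


class TestRegionalMeanHu:
    def test_uniform_volume(self):
        ct = VolumeGrid(np.full((4, 4, 4), -500.0))
        mask = RegionMask(np.ones((4, 4, 4), bool))
        assert regional_mean_hu(ct, mask) == -500.0

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1))
        data[0] = -1000.0
        m = RegionMask(np.ones((2, 1, 1), bool))
        assert regional_mean_hu(VolumeGrid(data), m) == -500.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        ct = VolumeGrid(rng.uniform(-1024, 40, (6, 5, 4)))
        mask = RegionMask(rng.random((6, 5, 4)) > 0.5)
        acc, n = 0.0, 0
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    if mask.data[i, j, k]:
                        acc += ct.data[i, j, k]
                        n += 1
        assert regional_mean_hu(ct, mask) == pytest.approx(acc / n)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            regional_mean_hu(VolumeGrid(np.zeros((2, 2, 2))),
                             RegionMask(np.zeros((2, 2, 2), bool)))


def _brute_force_thirds(counts):
    """Best (b1, b2) slice cuts by independent cumulative targets."""
    cum = np.cumsum(counts)
    n = cum[-1]
    b1 = int(np.argmin(np.abs(cum - n / 3)))
    b2 = int(np.argmin(np.abs(cum - 2 * n / 3)))
    return b1, max(b1, b2)


class TestAxialSubdivision:
    def test_exact_thirds(self):
        wl = RegionMask(np.ones((10, 10, 30), bool), label="WL")
        ul, ml, ll = subdivide_lung_axially(wl)
        assert ul.n_voxels == ml.n_voxels == ll.n_voxels == 1000
        # apex is the high-index end
        assert ul.data[:, :, 29].all() and ll.data[:, :, 0].all()

    def test_partition_invariants(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            data = rng.random((6, 6, 12)) > 0.4
            data[..., rng.integers(0, 12)] = True  # ensure >= 3 non-empty slices
            data[..., 5] = True
            data[..., 9] = True
            wl = RegionMask(data, label="WL")
            ul, ml, ll = subdivide_lung_axially(wl)
            union = ul.data | ml.data | ll.data
            assert (union == wl.data).all()
            assert not (ul.data & ml.data).any()
            assert not (ml.data & ll.data).any()
            assert not (ul.data & ll.data).any()

    def test_matches_brute_force_cuts(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            data = np.zeros((5, 5, 15), bool)
            for z in range(15):
                k = int(rng.integers(0, 26))
                idx = rng.choice(25, size=k, replace=False)
                data[..., z].flat[idx] = True
            if data.sum(axis=(0, 1)).astype(bool).sum() < 3:
                continue
            wl = RegionMask(data, label="WL")
            ul, ml, ll = subdivide_lung_axially(wl)
            counts = data.sum(axis=(0, 1))[::-1]  # apex-first
            b1, b2 = _brute_force_thirds(counts)
            assert ul.n_voxels == counts[: b1 + 1].sum()
            assert ml.n_voxels == counts[b1 + 1 : b2 + 1].sum()

    def test_dominant_slice_stays_whole(self):
        data = np.zeros((10, 10, 5), bool)
        data[..., 2] = True                  # 100 voxels in one slice
        data[0, 0, [0, 1, 3, 4]] = True      # few elsewhere
        ul, ml, ll = subdivide_lung_axially(RegionMask(data, label="WL"))
        homes = [m.data[..., 2].sum() for m in (ul, ml, ll)]
        assert max(homes) == 100  # the dominant slice is not split

    def test_va_volume_additivity(self):
        rng = np.random.default_rng(11)
        ct = VolumeGrid(rng.uniform(-1000, 30, (6, 6, 9)))
        wl = RegionMask(rng.random((6, 6, 9)) > 0.3, label="WL")
        parts = subdivide_lung_axially(wl)
        total = air_fraction_from_hu(regional_mean_hu(ct, wl)) * wl.n_voxels
        split = sum(air_fraction_from_hu(regional_mean_hu(ct, m)) * m.n_voxels
                    for m in parts)
        assert split == pytest.approx(total, rel=1e-12)

    def test_too_few_slices_rejected(self):
        data = np.zeros((4, 4, 5), bool)
        data[..., 1] = True
        data[..., 3] = True
        with pytest.raises(ValidationError):
            subdivide_lung_axially(RegionMask(data, label="WL"))


class TestExtractTac:
    def test_uniform_frames(self):
        sched = FrameSchedule([0, 1, 2], [1, 2, 3])
        frames = np.stack([np.full((3, 3, 3), v) for v in (1.0, 2.0, 3.0)], axis=-1)
        mask = RegionMask(np.ones((3, 3, 3), bool))
        tac = extract_tac(frames, mask, sched)
        assert tac.values.tolist() == [1.0, 2.0, 3.0]

    def test_single_voxel_time_course(self):
        sched = FrameSchedule([0, 1], [1, 2])
        rng = np.random.default_rng(0)
        pet = rng.uniform(0, 10, (3, 3, 3, 2))
        m = np.zeros((3, 3, 3), bool)
        m[1, 2, 0] = True
        tac = extract_tac(pet, RegionMask(m), sched)
        np.testing.assert_allclose(tac.values, pet[1, 2, 0, :])

    def test_matches_brute_force_mean(self):
        sched = FrameSchedule([0, 1], [1, 2])
        rng = np.random.default_rng(5)
        pet = rng.uniform(0, 10, (4, 4, 4, 2))
        mdata = rng.random((4, 4, 4)) > 0.5
        tac = extract_tac(pet, RegionMask(mdata), sched)
        for f in range(2):
            vals = [pet[i, j, k, f] for i in range(4) for j in range(4)
                    for k in range(4) if mdata[i, j, k]]
            assert tac.values[f] == pytest.approx(np.mean(vals))

    def test_grid_mismatch_rejected(self):
        sched = FrameSchedule([0.0], [1.0])
        with pytest.raises(ValidationError):
            extract_tac(np.zeros((3, 3, 3, 1)), RegionMask(np.ones((2, 2, 2), bool)), sched)


class TestDownsampling:
    def test_mask_nearest_neighbour_stays_binary(self):
        m = RegionMask(np.ones((4, 4, 4), bool))
        d = downsample_mask(m, 2)
        assert d.shape == (2, 2, 2) and d.data.dtype == bool

    def test_hu_block_mean_preserves_mean(self):
        rng = np.random.default_rng(2)
        v = VolumeGrid(rng.uniform(-1000, 40, (4, 4, 4)))
        d = downsample_hu(v, 2)
        assert d.data.mean() == pytest.approx(v.data.mean())
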