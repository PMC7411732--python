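"""ROI statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import palsim as ps


@pytest.fixture()
def grid():
    return ps.ImageGrid(nx=41, dx=0.5, ny=61, dy=0.5, standoff=19.5)


@pytest.fixture()
def random_image(grid):
    rng = np.random.default_rng(12)
    return ps.PAImage(rng.normal(size=grid.shape), grid, domain="rf")


ROI_FULLISH = ps.ROI(-8.0, 8.0, 2.0, 25.0, label="test")


def _roi_pixels(img, roi):
    out = []
    for i, y in enumerate(img.grid.depth_mm):
        for j, x in enumerate(img.grid.x_mm):
            if roi.x_min <= x <= roi.x_max and roi.y_min <= y <= roi.y_max:
                out.append((i, j, y))
    return out


class TestArms:
    def test_constant_roi(self, grid):
        img = ps.PAImage(np.full(grid.shape, -3.0), grid, domain="rf")
        assert ps.arms(img, ROI_FULLISH) == pytest.approx(3.0)

    def test_alternating_signs(self, grid):
        vals = np.full(grid.shape, 2.0)
        vals[::2] *= -1
        img = ps.PAImage(vals, grid, domain="rf")
        assert ps.arms(img, ROI_FULLISH) == pytest.approx(2.0)

    def test_random_fixture_vs_double_loop_oracle(self, random_image):
        pix = _roi_pixels(random_image, ROI_FULLISH)
        acc = 0.0
        for i, j, _ in pix:
            acc += random_image.values[i, j] ** 2
        oracle = np.sqrt(acc / len(pix))
        assert ps.arms(random_image, ROI_FULLISH) == pytest.approx(oracle, abs=1e-12)

    def test_sign_flip_invariance_and_linear_scaling(self, random_image):
        a = ps.arms(random_image, ROI_FULLISH)
        flipped = ps.PAImage(-random_image.values, random_image.grid, domain="rf")
        scaled = ps.PAImage(2.5 * random_image.values, random_image.grid, domain="rf")
        assert ps.arms(flipped, ROI_FULLISH) == pytest.approx(a)
        assert ps.arms(scaled, ROI_FULLISH) == pytest.approx(2.5 * a)

    def test_empty_roi_rejected(self, random_image):
        roi = ps.ROI(100.0, 101.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            ps.arms(random_image, roi)


class TestMeanAxialPosition:
    def test_single_pixel(self, grid):
        vals = np.zeros(grid.shape)
        vals[20, 10] = 5.0
        img = ps.PAImage(vals, grid, domain="rf")
        roi = ps.ROI(-10, 10, 0, 30)
        assert ps.mean_axial_position(img, roi) == pytest.approx(grid.depth_mm[20])

    def test_two_equal_pixels_average(self, grid):
        vals = np.zeros(grid.shape)
        vals[10, 5] = 2.0
        vals[40, 5] = -2.0  # magnitude weighting ignores the sign
        img = ps.PAImage(vals, grid, domain="rf")
        roi = ps.ROI(-10, 10, 0, 30)
        expected = (grid.depth_mm[10] + grid.depth_mm[40]) / 2
        assert ps.mean_axial_position(img, roi) == pytest.approx(expected)

    def test_fixture_vs_weighted_mean_oracle(self, random_image):
        pix = _roi_pixels(random_image, ROI_FULLISH)
        num = sum(abs(random_image.values[i, j]) * y for i, j, y in pix)
        den = sum(abs(random_image.values[i, j]) for i, j, _ in pix)
        assert ps.mean_axial_position(random_image, ROI_FULLISH) == pytest.approx(
            num / den, abs=1e-12
        )

    def test_amplitude_scaling_invariance(self, random_image):
        ybar = ps.mean_axial_position(random_image, ROI_FULLISH)
        scaled = ps.PAImage(7.0 * random_image.values, random_image.grid, domain="rf")
        assert ps.mean_axial_position(scaled, ROI_FULLISH) == pytest.approx(ybar)

    def test_all_zero_roi_undefined(self, grid):
        img = ps.PAImage(np.zeros(grid.shape), grid, domain="rf")
        with pytest.raises(ValueError):
            ps.mean_axial_position(img, ROI_FULLISH)


class TestSNR:
    SIGNAL = ps.ROI(-8.0, -1.0, 2.0, 12.0)
    NOISE = ps.ROI(1.0, 8.0, 2.0, 12.0)

    def test_null_case_near_zero_linear(self):
        grid = ps.ImageGrid(nx=201, dx=0.1, ny=201, dy=0.1)
        rng = np.random.default_rng(5)
        env = ps.PAImage(rng.rayleigh(1.0, grid.shape), grid, domain="envelope")
        lin = ps.snr_linear(env, self.SIGNAL, self.NOISE)
        assert abs(lin) < 0.1

    def test_ten_sigma_offset_is_twenty_db(self, grid):
        rng = np.random.default_rng(6)
        vals = rng.random(grid.shape)
        env = ps.PAImage(vals, grid, domain="envelope")
        noise = vals[self.NOISE.mask(env)]
        target = noise.mean() + 10.0 * noise.std()
        vals2 = vals.copy()
        vals2[self.SIGNAL.mask(env)] = target
        env2 = ps.PAImage(vals2, grid, domain="envelope")
        assert ps.snr_db(env2, self.SIGNAL, self.NOISE) == pytest.approx(20.0, abs=1e-12)

    def test_fixture_vs_independent_oracle(self, grid):
        rng = np.random.default_rng(7)
        vals = rng.random(grid.shape) + 0.5
        env = ps.PAImage(vals, grid, domain="envelope")
        noise = []
        signal = []
        for i, y in enumerate(grid.depth_mm):
            for j, x in enumerate(grid.x_mm):
                if self.NOISE.x_min <= x <= self.NOISE.x_max and self.NOISE.y_min <= y <= self.NOISE.y_max:
                    noise.append(vals[i, j])
                if self.SIGNAL.x_min <= x <= self.SIGNAL.x_max and self.SIGNAL.y_min <= y <= self.SIGNAL.y_max:
                    signal.append(vals[i, j])
        noise = np.array(noise)
        oracle_lin = np.mean((np.array(signal) - noise.mean()) / noise.std())
        oracle_db = 20 * np.log10(oracle_lin)
        assert ps.snr_db(env, self.SIGNAL, self.NOISE) == pytest.approx(
            oracle_db, abs=1e-9
        )

    def test_monotone_in_added_signal_offset(self, grid):
        rng = np.random.default_rng(9)
        vals = rng.random(grid.shape) + 1.0
        prev = -np.inf
        for offset in (0.5, 1.0, 2.0, 4.0):
            v = vals.copy()
            env = ps.PAImage(v, grid, domain="envelope")
            v[self.SIGNAL.mask(env)] += offset
            cur = ps.snr_db(ps.PAImage(v, grid, domain="envelope"),
                            self.SIGNAL, self.NOISE)
            assert cur > prev
            prev = cur

    def test_negative_linear_snr_is_minus_inf(self, grid):
        vals = np.ones(grid.shape)
        rng = np.random.default_rng(10)
        env0 = ps.PAImage(vals, grid, domain="envelope")
        vals[self.NOISE.mask(env0)] = rng.random(self.NOISE.mask(env0).sum()) + 5.0
        env = ps.PAImage(vals, grid, domain="envelope")
        assert ps.snr_db(env, self.SIGNAL, self.NOISE) == float("-inf")

    def test_zero_noise_variance_rejected(self, grid):
        env = ps.PAImage(np.ones(grid.shape), grid, domain="envelope")
        with pytest.raises(ValueError):
            ps.snr_db(env, self.SIGNAL, self.NOISE)

    def test_rf_domain_rejected(self, random_image):
        with pytest.raises(ValueError):
            ps.snr_db(random_image, self.SIGNAL, self.NOISE)


class TestProfiles:
    def test_constant_image_constant_profiles(self, grid):
        img = ps.PAImage(np.full(grid.shape, 4.0), grid, domain="rf")
        ax = ps.axial_profile(img, -5, 5)
        lat = ps.lateral_profile(img, 0, 2)
        assert np.allclose(ax["amplitude"], 4.0)
        assert np.allclose(lat["amplitude"], 4.0)

    def test_single_depth_row(self, grid):
        vals = np.zeros(grid.shape)
        vals[30, :] = 1.0
        img = ps.PAImage(vals, grid, domain="rf")
        prof = ps.axial_profile(img, -10, 10)
        nonzero = prof.loc[prof["amplitude"] > 0, "depth_mm"]
        assert list(nonzero) == [grid.depth_mm[30]]

    def test_fixture_vs_loop_oracle(self, random_image):
        grid = random_image.grid
        prof = ps.axial_profile(random_image, -3.0, 3.0)
        cols = [j for j, x in enumerate(grid.x_mm) if -3.0 <= x <= 3.0]
        for i in range(0, grid.ny, 13):
            oracle = np.mean([abs(random_image.values[i, j]) for j in cols])
            assert prof["amplitude"].iloc[i] == pytest.approx(oracle, abs=1e-12)

    def test_empty_ranges_rejected(self, random_image):
        with pytest.raises(ValueError):
            ps.axial_profile(random_image, 100, 101)
        with pytest.raises(ValueError):
            ps.lateral_profile(random_image, 100, 101)


class TestAttenuationFit:
    def test_noiseless_exponential_recovered_exactly(self):
        depth = np.linspace(0, 25, 60)
        prof = pd.DataFrame(
            {"depth_mm": depth, "amplitude": np.exp(-ps.PHANTOM_ATTENUATION * depth)}
        )
        mu, (lo, hi) = ps.fit_attenuation(prof)
        assert mu == pytest.approx(0.133, abs=1e-12)
        # noiseless fit: the interval collapses onto the estimate
        assert hi - lo == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(0.133, abs=1e-12)

    def test_constant_profile_gives_zero(self):
        prof = pd.DataFrame({"depth_mm": np.arange(10.0), "amplitude": np.ones(10)})
        mu, _ = ps.fit_attenuation(prof)
        assert mu == pytest.approx(0.0, abs=1e-14)

    def test_ci_coverage_under_lognormal_noise(self):
        rng = np.random.default_rng(2024)
        depth = np.linspace(0, 25, 30)
        true = 0.133
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            amp = np.exp(-true * depth) * rng.lognormal(0.0, 0.15, size=depth.size)
            _, (lo, hi) = ps.fit_attenuation(
                pd.DataFrame({"depth_mm": depth, "amplitude": amp})
            )
            hits += lo <= true <= hi
        assert hits / n_rep >= 0.90

    def test_nonpositive_amplitudes_rejected_with_advice(self):
        prof = pd.DataFrame({"depth_mm": np.arange(6.0),
                             "amplitude": [1, 1, 0, 1, 1, 1]})
        with pytest.raises(ValueError, match="positive"):
            ps.fit_attenuation(prof)

    def test_too_few_points_rejected(self):
        prof = pd.DataFrame({"depth_mm": [0, 1, 2], "amplitude": [1, 1, 1]})
        with pytest.raises(ValueError):
            ps.fit_attenuation(prof)


class TestRoiMeanFluence:
    @pytest.fixture()
    def fluence(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        vol = ps.VoxelVolume(labels, 0.5,
                             {0: ps.WATER_BACKGROUND}, origin=(-5.0, 0.0, -5.0))
        rng = np.random.default_rng(11)
        return ps.FluenceMap(vol, rng.random(vol.shape), np.zeros(vol.shape),
                             1.0, 1, 0)

    def test_uniform_field(self, fluence):
        fluence.phi[:] = 0.75
        box = ((-3, 3), (2, 8), (-3, 3))
        assert ps.roi_mean_fluence(fluence, box) == 0.75

    def test_single_voxel_box(self, fluence):
        # box tightly around the centre of voxel (4, 6, 8)
        x = fluence.volume.voxel_centers(0)[4]
        y = fluence.volume.voxel_centers(1)[6]
        z = fluence.volume.voxel_centers(2)[8]
        box = ((x - 0.1, x + 0.1), (y - 0.1, y + 0.1), (z - 0.1, z + 0.1))
        assert ps.roi_mean_fluence(fluence, box) == fluence.phi[4, 6, 8]

    def test_fixture_vs_loop_oracle(self, fluence):
        box = ((-2.2, 1.4), (1.1, 4.9), (-0.6, 3.8))
        vals = []
        vol = fluence.volume
        for i, x in enumerate(vol.voxel_centers(0)):
            for j, y in enumerate(vol.voxel_centers(1)):
                for k, z in enumerate(vol.voxel_centers(2)):
                    if (box[0][0] <= x <= box[0][1] and box[1][0] <= y <= box[1][1]
                            and box[2][0] <= z <= box[2][1]):
                        vals.append(fluence.phi[i, j, k])
        assert ps.roi_mean_fluence(fluence, box) == pytest.approx(
            np.mean(vals), abs=1e-12
        )

    def test_empty_box_rejected(self, fluence):
        with pytest.raises(ValueError):
            ps.roi_mean_fluence(fluence, ((50, 51), (0, 1), (0, 1)))


class TestRoiPresets:
    def test_central_roi_matches_five_elements(self, array):
        roi = ps.central_roi(array)
        assert roi.x_max - roi.x_min == pytest.approx(5 * array.pitch)
        assert roi.y_max == 25.5
        # elements 62-66 straddle the array centre slightly left of zero
        assert roi.x_min < 0 < roi.x_max

    def test_peripheral_rois_on_opposite_sides(self, array):
        roi2, roi3 = ps.peripheral_rois(array)
        assert roi2.x_max < 0 < roi3.x_min
        assert roi2.x_max - roi2.x_min == pytest.approx(5 * array.pitch)
        assert roi3.x_max - roi3.x_min == pytest.approx(5 * array.pitch)
        # element ranges 5-9 and 119-123 (1-based) as published
        assert roi2.x_min == pytest.approx(array.element_lateral_mm(5)
                                           - array.pitch / 2)
        assert roi3.x_max == pytest.approx(array.element_lateral_mm(123)
                                           + array.pitch / 2)
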