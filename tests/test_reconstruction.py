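"""Delay-and-sum, coherent summation, and envelope detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import palsim as ps


def _point_rf(volume, array, ix, iy, iz, duration):
    p0 = np.zeros(volume.shape)
    p0[ix, iy, iz] = 1.0
    return ps.simulate_rf(p0, volume, array, duration)


class TestTimeOfFlight:
    def test_on_axis(self):
        assert ps.time_of_flight(3.0, 3.0, 7.7, 1540.0) == pytest.approx(
            7.7e-3 / 1540.0
        )

    def test_three_four_five_triangle(self):
        assert ps.time_of_flight(4.0, 1.0, 4.0, 1540.0) == pytest.approx(
            5e-3 / 1540.0
        )

    @given(
        x=st.floats(-19, 19), xi=st.floats(-19, 19), y=st.floats(0, 50)
    )
    def test_matches_high_precision_oracle(self, x, xi, y):
        expected = float(np.sqrt(np.float64(y) ** 2 + (np.float64(x) - xi) ** 2))
        assert ps.time_of_flight(x, xi, y, 1540.0) == pytest.approx(
            expected * 1e-3 / 1540.0, rel=1e-12
        )

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            ps.time_of_flight(0, 0, -1.0, 1540.0)


class TestDelayAndSum:
    def test_zero_rf_zero_image(self, array, point_image_setup):
        grid, _ = point_image_setup
        rf = ps.RFFrame(np.zeros((128, 800)), array.sampling_rate)
        img = ps.das_reconstruct(rf, grid, array)
        assert not np.any(img.values)

    def test_linearity_in_rf(self, array, water_volume, point_image_setup):
        grid, duration = point_image_setup
        rf1 = _point_rf(water_volume, array, 60, 110, 20, duration)
        rf2 = _point_rf(water_volume, array, 100, 140, 20, duration)
        a = ps.das_reconstruct(rf1, grid, array)
        b = ps.das_reconstruct(rf2, grid, array)
        ab = ps.das_reconstruct(rf1 + rf2, grid, array)
        ref = np.abs(ab.values).max()
        assert np.allclose(a.values + b.values, ab.values, atol=1e-9 * ref)

    def test_point_absorber_peak_localized(self, array, water_volume, point_image_setup):
        grid, duration = point_image_setup
        ix, iy, iz = 70, 130, 20
        xt = water_volume.voxel_centers(0)[ix]
        yt = water_volume.voxel_centers(1)[iy] - grid.standoff
        rf = _point_rf(water_volume, array, ix, iy, iz, duration)
        env = ps.envelope_image(ps.das_reconstruct(rf, grid, array))
        k = np.unravel_index(np.argmax(env.values), env.values.shape)
        assert abs(grid.x_mm[k[1]] - xt) <= grid.dx
        assert abs(grid.depth_mm[k[0]] - yt) <= grid.dy

    def test_aperture_growth_never_reduces_peak(self, array, water_volume, point_image_setup):
        grid, duration = point_image_setup
        rf = _point_rf(water_volume, array, 80, 130, 20, duration)  # on-axis point
        peaks = []
        for alpha in (4, 8, 16, 32, 64):
            env = ps.envelope_image(ps.das_reconstruct(rf, grid, array, alpha))
            peaks.append(env.values.max())
        assert np.all(np.diff(peaks) >= -1e-12)

    def test_nearest_neighbour_mode_close_to_linear(self, array, water_volume, point_image_setup):
        grid, duration = point_image_setup
        rf = _point_rf(water_volume, array, 80, 130, 20, duration)
        lin = ps.das_reconstruct(rf, grid, array, interpolation="linear")
        near = ps.das_reconstruct(rf, grid, array, interpolation="nearest")
        # the two delay lookups agree on where the target is
        kl = np.unravel_index(np.argmax(np.abs(lin.values)), lin.values.shape)
        kn = np.unravel_index(np.argmax(np.abs(near.values)), near.values.shape)
        assert abs(kl[0] - kn[0]) <= 1 and abs(kl[1] - kn[1]) <= 1


class TestCoherentSum:
    def test_singleton_identity(self, array, water_volume, point_image_setup):
        grid, duration = point_image_setup
        rf = _point_rf(water_volume, array, 80, 120, 20, duration)
        img = ps.das_reconstruct(rf, grid, array)
        out = ps.coherent_sum([img])
        assert np.array_equal(out.values, img.values)
        assert out.angle == "combined"

    def test_cancellation(self, array, point_image_setup):
        grid, _ = point_image_setup
        rng = np.random.default_rng(3)
        vals = rng.normal(size=grid.shape)
        img = ps.PAImage(vals, grid, domain="rf")
        neg = ps.PAImage(-vals, grid, domain="rf")
        assert not np.any(ps.coherent_sum([img, neg]).values)

    def test_equivalent_to_wide_illumination(self, array, water_volume, point_image_setup):
        """Summing per-angle partial-illumination subframes equals one
        reconstruction of the fully illuminated scene (noise-free)."""
        grid, duration = point_image_setup
        rng = np.random.default_rng(4)
        p0_full = np.zeros(water_volume.shape)
        parts = []
        for _ in range(3):  # three partial illuminations
            part = np.zeros(water_volume.shape)
            idx = (rng.integers(10, 150, 4), rng.integers(90, 190, 4),
                   rng.integers(5, 35, 4))
            part[idx] = rng.random(4)
            p0_full += part
            parts.append(part)
        subframes = [
            ps.das_reconstruct(
                ps.simulate_rf(p, water_volume, array, duration), grid, array
            )
            for p in parts
        ]
        combined = ps.coherent_sum(subframes)
        wide = ps.das_reconstruct(
            ps.simulate_rf(p0_full, water_volume, array, duration), grid, array
        )
        ref = np.abs(wide.values).max()
        assert np.allclose(combined.values, wide.values, atol=1e-9 * ref)

    def test_envelope_domain_inputs_rejected(self, point_image_setup):
        grid, _ = point_image_setup
        env = ps.PAImage(np.ones(grid.shape), grid, domain="envelope")
        with pytest.raises(ValueError):
            ps.coherent_sum([env])

    def test_grid_mismatch_rejected(self, array, point_image_setup):
        grid, _ = point_image_setup
        other = ps.ImageGrid(nx=10, dx=0.1, ny=10, dy=0.1)
        a = ps.PAImage(np.zeros(grid.shape), grid, domain="rf")
        b = ps.PAImage(np.zeros(other.shape), other, domain="rf")
        with pytest.raises(ValueError):
            ps.coherent_sum([a, b])


def _dft_analytic_magnitude(col):
    """Brute-force DFT analytic signal: zero negative frequencies, double
    positive ones, inverse-transform, take magnitude."""
    n = len(col)
    spec = np.array(
        [sum(col[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n))
         for k in range(n)]
    )
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    analytic = np.array(
        [sum(spec[k] * h[k] * np.exp(2j * np.pi * k * t / n) for k in range(n)) / n
         for t in range(n)]
    )
    return np.abs(analytic)


class TestEnvelope:
    def test_pure_tone_column_nearly_constant(self, point_image_setup):
        grid, _ = point_image_setup
        ny = grid.ny
        col = np.cos(2 * np.pi * 12 * np.arange(ny) / ny)
        vals = np.tile(col[:, None], (1, grid.nx))
        env = ps.envelope_image(ps.PAImage(vals, grid, domain="rf"))
        core = env.values[ny // 4 : -ny // 4, 0]
        assert np.all(np.abs(core - 1.0) < 0.05)

    def test_zero_image(self, point_image_setup):
        grid, _ = point_image_setup
        env = ps.envelope_image(ps.PAImage(np.zeros(grid.shape), grid, domain="rf"))
        assert not np.any(env.values)

    def test_matches_quadrature_dft_oracle(self):
        rng = np.random.default_rng(8)
        n = 64
        col = rng.normal(size=n)
        grid = ps.ImageGrid(nx=1, dx=0.1, ny=n, dy=0.1)
        env = ps.envelope_image(ps.PAImage(col[:, None], grid, domain="rf"))
        oracle = _dft_analytic_magnitude(col)
        assert np.allclose(env.values[:, 0], oracle, rtol=0.01, atol=1e-9)

    def test_envelope_of_envelope_rejected(self, point_image_setup):
        grid, _ = point_image_setup
        env = ps.PAImage(np.ones(grid.shape), grid, domain="envelope")
        with pytest.raises(ValueError):
            ps.envelope_image(env)
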