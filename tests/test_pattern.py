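import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpsquant import (PatternParams, TabulatedPattern, evaluate_profile,
                      phase_distance, render_pattern)


class TestProfile:
    @pytest.mark.parametrize(
        "params, x, expected",
        [
            (dict(A=0, B=1, P=6, T=190, phi=0), 95.0, 1.0),        # sin(pi/2)^6
            (dict(A=0, B=1, P=6, T=190, phi=0), 0.0, 0.0),
            (dict(A=3.5, B=0, P=2, T=100, phi=1.2), 17.0, 3.5),    # amplitude-free limit
            (dict(A=3.5, B=0, P=2, T=100, phi=1.2), -260.0, 3.5),
        ],
    )
    def test_pointwise_values(self, params, x, expected):
        assert evaluate_profile(x, PatternParams(**params)) == pytest.approx(expected, abs=1e-12)

    def test_maxima_spacing_equals_period(self):
        """Even sine powers halve the natural 2T period: maxima sit T apart."""
        p = PatternParams(A=0, B=1, P=6, T=190.0, phi=0.0)
        x = np.arange(0.0, 2000.0, 0.01)
        y = evaluate_profile(x, p)
        local_max = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        peaks = x[1:-1][local_max]
        spacing = np.diff(peaks)
        assert np.allclose(spacing, 190.0, atol=0.05)

    @given(st.floats(-5e3, 5e3), st.integers(1, 4),
           st.floats(0, 2 * np.pi), st.floats(50.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_periodicity_and_bounds(self, x, half_p, phi, T):
        p = PatternParams(A=0.3, B=2.0, P=2 * half_p, T=T, phi=phi)
        y0 = evaluate_profile(x, p)
        assert evaluate_profile(x + T, p) == pytest.approx(y0, abs=1e-9)
        assert p.A - 1e-12 <= y0 <= p.A + p.B + 1e-12

    def test_phase_shift_equals_translation(self):
        """f(x; phi) = f(x + T*phi/pi; 0) on a grid."""
        T, phi = 190.0, 0.83
        x = np.linspace(0, 1000, 257)
        shifted = evaluate_profile(x, PatternParams(T=T, phi=phi))
        translated = evaluate_profile(x + T * phi / np.pi, PatternParams(T=T, phi=0.0))
        np.testing.assert_allclose(shifted, translated, atol=1e-12)

    @pytest.mark.parametrize("bad", [dict(T=-1), dict(T=0), dict(B=-0.5),
                                     dict(P=5), dict(P=0), dict(P=-2)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PatternParams(**bad)


class TestRender:
    def test_theta_zero_columns_constant(self):
        img = render_pattern((40, 60), 20.0, PatternParams(theta=0.0))
        assert np.ptp(img, axis=0).max() == 0.0   # constant along each column
        assert np.ptp(img, axis=1).max() > 0.0    # varies along rows

    def test_theta_180_equals_theta_0_at_zero_phase(self):
        a = render_pattern((32, 32), 20.0, PatternParams(theta=0.0, phi=0.0))
        b = render_pattern((32, 32), 20.0, PatternParams(theta=180.0, phi=0.0))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_matches_1d_oracle_along_variation_axis(self):
        """2D render at theta=0 equals the 1D profile at pixel centers."""
        p = PatternParams(T=190.0, phi=0.0, theta=0.0)
        img = render_pattern((50, 50), 20.0, p)
        x = (np.arange(50) + 0.5) * 20.0
        oracle = evaluate_profile(x, p)
        np.testing.assert_allclose(img[0], oracle, atol=1e-12)
        assert np.argmax(img[0]) == np.argmax(oracle)

    def test_rotation_equivariance(self):
        """render(theta) equals render(0) rotated by theta at matching centers."""
        from scipy.ndimage import map_coordinates

        theta = 25.0
        px = 20.0
        n = 51
        rotated = render_pattern((n, n), px, PatternParams(theta=theta))
        base_big = render_pattern((3 * n, 3 * n), px, PatternParams(theta=0.0),
                                  origin=(-n, -n))
        # sampling render(0) at coordinates rotated by -theta about the
        # coordinate origin must reproduce render(theta)
        t = np.deg2rad(theta)
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        x, y = (cc + 0.5) * px, (rr + 0.5) * px
        xp = x * np.cos(t) + y * np.sin(t)
        yp = -x * np.sin(t) + y * np.cos(t)
        expected = map_coordinates(base_big, [yp / px - 0.5 + n, xp / px - 0.5 + n], order=3)
        np.testing.assert_allclose(rotated, expected, atol=5e-3)

    def test_mean_over_integer_periods_is_phase_free(self):
        """<f> over whole periods approaches A + B*<sin^P>, independent of phi."""
        means = []
        for phi in (0.0, 0.9, 2.4):
            p = PatternParams(A=0.5, B=2.0, P=6, T=190.0, phi=phi, theta=0.0)
            img = render_pattern((4, 1900), 1.0, p)   # 10 periods along rows
            means.append(img.mean())
        expected = 0.5 + 2.0 * 5.0 / 16.0             # <sin^6> = 5/16
        np.testing.assert_allclose(means, expected, atol=2e-3)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            render_pattern((0, 10), 20.0, PatternParams())
        with pytest.raises(ValueError):
            render_pattern((10, 10), 0.0, PatternParams())


class TestWrapping:
    def test_angle_and_phase_wrapping(self):
        p = PatternParams(theta=190.0, phi=7.0)
        assert p.theta == pytest.approx(10.0)
        assert 0.0 <= p.phi < 2 * np.pi

    def test_phase_distance_period_pi(self):
        """sin^P is blind to phase shifts of pi, so distances wrap at pi."""
        assert phase_distance(0.1, 0.1 + np.pi) == pytest.approx(0.0, abs=1e-12)
        assert phase_distance(0.0, 1.5) == pytest.approx(1.5)
        assert phase_distance(0.0, 2.0) == pytest.approx(np.pi - 2.0)


class TestTabulated:
    def test_tabulated_reproduces_analytic_profile(self):
        p = PatternParams(T=190.0, phi=0.0)
        xs = np.linspace(0, 190.0, 400, endpoint=False)
        tab = TabulatedPattern(xs, evaluate_profile(xs, p), period=190.0)
        x = np.linspace(0, 600, 113)
        np.testing.assert_allclose(tab.profile(x), evaluate_profile(x, p), atol=1e-4)

    def test_tabulated_render_matches_analytic_render(self):
        p = PatternParams(T=190.0, phi=0.0, theta=35.0)
        xs = np.linspace(0, 190.0, 800, endpoint=False)
        tab = TabulatedPattern(xs, evaluate_profile(xs, p.with_angles(theta=0.0)), period=190.0)
        a = render_pattern((30, 30), 20.0, p)
        b = tab.render((30, 30), 20.0, theta_deg=35.0)
        np.testing.assert_allclose(a, b, atol=1e-4)
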