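"""Coupled-wave layer solver vs Fresnel/thin-film closed forms."""

import numpy as np
import pytest

from chemholo import (LayerStack, PlaneWave, SingularStackError, field_at,
                      reflectance_transmittance, solve_layered)


def fresnel_rt(n1, n2, theta1=0.0, pol="s"):
    c1 = np.cos(theta1)
    s2 = n1 * np.sin(theta1) / n2
    c2 = np.sqrt(1 - s2**2 + 0j)
    if pol == "s":
        r = (n1 * c1 - n2 * c2) / (n1 * c1 + n2 * c2)
        t = 2 * n1 * c1 / (n1 * c1 + n2 * c2)
    else:
        r = (n2 * c1 - n1 * c2) / (n2 * c1 + n1 * c2)
        t = 2 * n1 * c1 / (n2 * c1 + n1 * c2)
    return r, t


def two_layer_stack(n1, n2):
    # input anchored at the interface so amplitude ratios are the Fresnel
    # coefficients directly
    return LayerStack(n_layers=[n1, n2], boundaries=[0.0], z0=0.0)


class TestFresnel:
    def test_normal_incidence_amplitudes(self):
        sol = solve_layered(two_layer_stack(1.0, 1.5), PlaneWave(wavelength=1.0),
                            polarization="s")
        r, t = fresnel_rt(1.0, 1.5)
        assert sol.amp_down[0] == pytest.approx(r, abs=1e-10)
        assert sol.amp_up[1] == pytest.approx(t, abs=1e-10)

    @pytest.mark.parametrize("pol", ["s", "p"])
    @pytest.mark.parametrize("theta_deg", [0.0, 20.0, 55.0])
    def test_oblique_reflectance(self, pol, theta_deg):
        th = np.deg2rad(theta_deg)
        d = np.array([np.sin(th), 0.0, np.cos(th)])
        sol = solve_layered(two_layer_stack(1.0, 1.7),
                            PlaneWave(direction=d, wavelength=1.3),
                            polarization=pol)
        r, _ = fresnel_rt(1.0, 1.7, th, pol)
        assert abs(sol.amp_down[0]) == pytest.approx(abs(r), abs=1e-10)
        R, T = reflectance_transmittance(sol)
        assert R == pytest.approx(abs(r) ** 2, abs=1e-10)
        assert R + T == pytest.approx(1.0, abs=1e-10)

    def test_brewster_angle_p(self):
        n1, n2 = 1.0, 1.5
        th = np.arctan(n2 / n1)
        d = np.array([np.sin(th), 0.0, np.cos(th)])
        sol = solve_layered(two_layer_stack(n1, n2),
                            PlaneWave(direction=d, wavelength=1.0),
                            polarization="p")
        assert abs(sol.amp_down[0]) < 1e-10


class TestThinFilm:
    def test_quarter_wave_film(self):
        lam, nf, ns = 1.0, 1.38, 1.5
        df = lam / (4 * nf)
        stack = LayerStack(n_layers=[1.0, nf, ns], boundaries=[0.0, df],
                           z0=0.0)
        sol = solve_layered(stack, PlaneWave(wavelength=lam))
        R, T = reflectance_transmittance(sol)
        r1 = (1 - nf) / (1 + nf)
        r2 = (nf - ns) / (nf + ns)
        r_exact = (r1 + r2 * np.exp(1j * np.pi)) / (1 + r1 * r2 * np.exp(1j * np.pi))
        assert R == pytest.approx(abs(r_exact) ** 2, abs=1e-10)
        assert R + T == pytest.approx(1.0, abs=1e-10)

    def test_absorbing_layer_attenuation(self):
        # index-matched bounds: only the Beer-Lambert attenuation remains
        n = 1.5 + 0.05j
        d = 2.0
        stack = LayerStack(n_layers=[n, n, n], boundaries=[0.0, d], z0=-1.0)
        sol = solve_layered(stack, PlaneWave(wavelength=1.0))
        e_in = field_at(sol, 0.0, 0.0, 0.0)
        e_out = field_at(sol, 0.0, 0.0, d)
        k = 2 * np.pi / 1.0
        assert abs(e_out[0] / e_in[0]) == pytest.approx(np.exp(-k * 0.05 * d),
                                                        rel=1e-10)


class TestHomogeneousAndContinuity:
    def test_homogeneous_stack_no_reflection(self):
        stack = LayerStack(n_layers=[1.3, 1.3, 1.3, 1.3],
                           boundaries=[0.5, 1.5, 2.5], z0=0.0)
        sol = solve_layered(stack, PlaneWave(wavelength=0.8))
        assert np.max(np.abs(sol.amp_down[:-1])) < 1e-10
        # transmitted equals incident with accumulated phase
        z = 5.0
        e = field_at(sol, 0.0, 0.0, z)
        expected = np.exp(1j * (2 * np.pi / 0.8) * 1.3 * z)
        assert e[0] == pytest.approx(expected, abs=1e-10)

    def test_periodicity_in_homogeneous_medium(self):
        stack = LayerStack(n_layers=[1.2, 1.2], boundaries=[1.0], z0=0.0)
        sol = solve_layered(stack, PlaneWave(wavelength=1.0))
        z0 = 0.3
        e1 = field_at(sol, 0.0, 0.0, z0)
        e2 = field_at(sol, 0.0, 0.0, z0 + 1.0 / 1.2)
        np.testing.assert_allclose(e1, e2, atol=1e-10)

    def test_tangential_continuity_at_boundaries(self, rng):
        for _ in range(5):
            L = rng.integers(3, 6)
            n_layers = 1.0 + rng.uniform(0, 1.2, L) + 1j * rng.uniform(0, 0.1, L)
            n_layers[0] = n_layers[0].real
            bounds = np.cumsum(rng.uniform(0.3, 2.0, L - 1))
            stack = LayerStack(n_layers=n_layers, boundaries=bounds,
                               z0=bounds[0] - 1.0)
            th = rng.uniform(0, 0.9)
            d = np.array([np.sin(th), 0.0, np.cos(th)])
            pol = ["s", "p"][rng.integers(2)]
            sol = solve_layered(stack, PlaneWave(direction=d, wavelength=1.0),
                                polarization=pol)
            for b, zb in enumerate(bounds):
                lo = field_at(sol, 0.1, -0.2, zb, layer=b)
                hi = field_at(sol, 0.1, -0.2, zb, layer=b + 1)
                np.testing.assert_allclose(lo[:2], hi[:2], atol=1e-10)

    def test_gauss_residuals_random_stacks(self, rng):
        for _ in range(5):
            L = rng.integers(2, 7)
            n_layers = 1.0 + rng.uniform(0, 1.5, L) + 1j * rng.uniform(0, 0.2, L)
            n_layers[0] = n_layers[0].real
            bounds = np.cumsum(rng.uniform(0.2, 1.5, L - 1))
            stack = LayerStack(n_layers=n_layers, boundaries=bounds,
                               z0=bounds[0] - 0.5 if L > 1 else 0.0)
            th = rng.uniform(0, 1.0)
            d = np.array([np.sin(th), 0.0, np.cos(th)])
            sol = solve_layered(stack, PlaneWave(direction=d, wavelength=1.0),
                                polarization="p")
            assert sol.gauss_residuals().max() < 1e-10

    def test_energy_conservation_random_lossless(self, rng):
        for _ in range(8):
            L = int(rng.integers(2, 7))
            n_layers = 1.0 + rng.uniform(0, 1.5, L)
            bounds = np.cumsum(rng.uniform(0.2, 1.5, max(L - 1, 1)))[: L - 1]
            stack = LayerStack(n_layers=n_layers, boundaries=bounds,
                               z0=bounds[0] - 0.5)
            pol = ["s", "p"][int(rng.integers(2))]
            th = rng.uniform(0, 0.8)
            d = np.array([np.sin(th), 0.0, np.cos(th)])
            sol = solve_layered(stack, PlaneWave(direction=d, wavelength=0.9),
                                polarization=pol)
            R, T = reflectance_transmittance(sol)
            assert R + T == pytest.approx(1.0, abs=1e-10)


class TestEqualOplPair:
    def test_same_phase_at_exit_different_at_detector(self):
        """Two layers with equal OPL agree at the sample exit boundary but
        differ at a detector beyond it (the thickness difference shows up in
        the remaining air path)."""
        lam = 1.5
        na, da = 3.0 + 0.05j, 2.0
        nb, db = 1.0 + 0.05j, 6.0
        # OPL pairs from the reference configuration differ in geometric
        # thickness only; compare exit-relative and detector-plane phases
        pw = PlaneWave(wavelength=lam)
        sols = {}
        for tag, (n, d) in {"a": (na, da), "b": (nb, db)}.items():
            stack = LayerStack(n_layers=[1.0, n, 1.0], boundaries=[0.0, d],
                               z0=0.0)
            sols[tag] = (solve_layered(stack, pw), d)
        # transmitted phase accumulated across the layer (anchored at exit)
        phases_exit = {}
        phases_det = {}
        z_det = 8.0
        for tag, (sol, d) in sols.items():
            e_exit = field_at(sol, 0.0, 0.0, d)[0]
            phases_exit[tag] = np.angle(e_exit)
            phases_det[tag] = np.angle(field_at(sol, 0.0, 0.0, z_det)[0])
        # na*da = nb*db = 6 (real part): equal OPL -> equal exit phase
        # (interface reflections differ, allow a small tolerance)
        d_exit = np.angle(np.exp(1j * (phases_exit["a"] - phases_exit["b"])))
        d_det = np.angle(np.exp(1j * (phases_det["a"] - phases_det["b"])))
        assert abs(d_det) > 10 * abs(d_exit) or abs(d_exit) < 0.05 < abs(d_det)


class TestErrors:
    def test_grazing_incidence_rejected(self):
        d = np.array([1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="polarization|direction|grazing"):
            solve_layered(two_layer_stack(1.0, 1.5),
                          PlaneWave(direction=d, wavelength=1.0))

    def test_absorbing_outer_layers_reject_rt(self):
        stack = LayerStack(n_layers=[1.0, 1.5, 1.2 + 0.1j], boundaries=[0.0, 1.0],
                           z0=0.0)
        sol = solve_layered(stack, PlaneWave(wavelength=1.0))
        with pytest.raises(ValueError, match="lossless"):
            reflectance_transmittance(sol)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            LayerStack(n_layers=[1.0, 1.5, 1.0], boundaries=[1.0, 0.5], z0=0.0)
        with pytest.raises(ValueError):
            LayerStack(n_layers=[1.0], boundaries=[], z0=0.0)
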