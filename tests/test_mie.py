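"""Scalar Mie model: coefficients vs an independent boundary-matching oracle,
field symmetries, aperture band-limiting, and the two-sphere superposition."""

import numpy as np
import pytest
from scipy.special import spherical_jn, spherical_yn

from chemholo import (ApertureFilter, Sphere, apply_bandpass_1d,
                      apply_bandpass_2d, far_field_radial, mie_coefficients,
                      near_field_2d, scattered_field_2d, two_sphere_field)


def oracle_coefficient(t, a, n, wavelength):
    """Independent per-order 2x2 continuity solve for (A_t, B_t).

    Matches the interior field A_t j_t(k n r) to the exterior
    (2t+1) i^t j_t(k r) + B_t h_t(k r) in value and radial derivative at
    r = a, solved numerically rather than via the closed form.
    """
    k = 2 * np.pi / wavelength
    ka, kna = k * a, k * n * a
    h = spherical_jn(t, ka) + 1j * spherical_yn(t, ka)
    hp = (spherical_jn(t, ka, derivative=True)
          + 1j * spherical_yn(t, ka, derivative=True))
    c = (2 * t + 1) * 1j**t
    mat = np.array([[spherical_jn(t, kna), -h],
                    [n * spherical_jn(t, kna, derivative=True), -hp]])
    rhs = np.array([c * spherical_jn(t, ka),
                    c * spherical_jn(t, ka, derivative=True)])
    _, b = np.linalg.solve(mat, rhs)
    return b


class TestCoefficients:
    @pytest.mark.parametrize("a", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n", [1.2 + 0.0j, 1.5 + 0.03j, 2.0 + 0.05j])
    def test_boundary_matching_oracle(self, a, n):
        series = mie_coefficients(Sphere(a, n), 1.0)
        scale = np.abs(series.coefficients).max()
        for t, bt in enumerate(series.coefficients):
            oracle = oracle_coefficient(t, a, n, 1.0)
            assert abs(bt - oracle) < 1e-10 * scale

    def test_index_matched_sphere_silent(self):
        series = mie_coefficients(Sphere(1.0, 1.0 + 0.0j), 1.0)
        assert np.abs(series.coefficients).max() < 1e-12

    def test_truncation_shrinks_with_wavelength(self):
        s = Sphere(1.0, 1.5 + 0.03j)
        n1 = mie_coefficients(s, 1.0).truncation_order
        n2 = mie_coefficients(s, 2.0).truncation_order
        assert mie_coefficients(s, 1.0).size_parameter == pytest.approx(2 * np.pi)
        assert n2 < n1

    def test_invalid_sphere(self):
        with pytest.raises(ValueError):
            Sphere(-1.0, 1.5)
        with pytest.raises(ValueError):
            mie_coefficients(Sphere(1.0, 1.5), -1.0)


class TestFields2D:
    def test_zero_contrast_total_is_incident(self):
        f = scattered_field_2d(Sphere(1.0, 1.0 + 0.0j), 8.0, 64, 1.0,
                               plane="vertical", total=True)
        k = 2 * np.pi
        ax = f.axes()[0]
        zz = ax[:, None] * np.ones(64)[None, :]
        ok = ~np.isnan(f.samples)
        np.testing.assert_allclose(f.samples[ok], np.exp(1j * k * zz.T).T[ok],
                                   atol=1e-12)

    def test_horizontal_plane_radial_symmetry(self):
        f = scattered_field_2d(Sphere(1.0, 1.5 + 0.03j), 16.0, 64, 1.0,
                               plane="horizontal", z_plane=3.0)
        x, _ = f.axes()
        xi, yi = np.meshgrid(x, x)
        r = np.hypot(xi, yi)
        # pick pairs of pixels at (x,y) and (y,x): same radius
        np.testing.assert_allclose(f.samples, f.samples.T, atol=1e-8)

    def test_interior_masked(self):
        f = scattered_field_2d(Sphere(2.0, 1.4 + 0.02j), 8.0, 64, 1.0,
                               plane="vertical")
        x, _ = f.axes()
        xi, zi = np.meshgrid(x, x)
        inside = np.hypot(xi, zi) < 2.0
        assert np.all(np.isnan(f.samples[inside]))

    def test_far_scattered_decays_as_inverse_kr(self):
        series_sphere = Sphere(0.5, 1.5 + 0.0j)
        lam = 1.0
        from chemholo.mie import _series_eval, mie_coefficients as mc

        series = mc(series_sphere, lam)
        k = 2 * np.pi / lam
        r1, r2 = 200.0, 400.0
        e1 = _series_eval(series, np.array([k * r1]), np.array([1.0]))[0]
        e2 = _series_eval(series, np.array([k * r2]), np.array([1.0]))[0]
        assert abs(e1) / abs(e2) == pytest.approx(2.0, rel=0.02)


class TestFarFieldRadial:
    def test_zero_contrast(self):
        far = far_field_radial(Sphere(1.0, 1.0 + 0.0j), 1.0, 128, 8.0)
        assert np.abs(far.samples).max() < 1e-12

    def test_linear_in_coefficients(self):
        from chemholo import far_field_amplitude, mie_coefficients
        from chemholo.mie import MieSeries

        series = mie_coefficients(Sphere(1.0, 1.5 + 0.03j), 1.0)
        ct = np.linspace(0, 1, 50)
        s1 = far_field_amplitude(series, ct)
        scaled = MieSeries(series.coefficients * 2.5, series.size_parameter,
                           series.truncation_order)
        np.testing.assert_allclose(far_field_amplitude(scaled, ct), 2.5 * s1,
                                   rtol=1e-12)

    def test_matches_2d_extraction(self):
        """The 1-D reciprocal profile equals the radial cut of the 2-D far
        field (both sample the same angular amplitude)."""
        from scipy.interpolate import CubicSpline

        from chemholo import far_field_2d

        sphere = Sphere(2.0, 1.4 + 0.02j)
        F2, freq = far_field_2d(sphere, 1.0, 32.0, 256)
        row = F2[128, 128:]
        # interpolate only over the smooth propagating band (the spectrum has
        # a physical kink at the light-cone edge that would pollute a spline)
        knots = freq[128:][freq[128:] <= 0.97]
        vals = row[: len(knots)]
        cs_r = CubicSpline(knots, vals.real)
        cs_i = CubicSpline(knots, vals.imag)
        far1 = far_field_radial(sphere, 1.0, 128, 16.0)
        sel = far1.radii <= 0.85
        ref = cs_r(far1.radii[sel]) + 1j * cs_i(far1.radii[sel])
        err = np.max(np.abs(far1.samples[sel] - ref))
        assert err < 1e-4 * np.abs(far1.samples).max()

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            far_field_radial(Sphere(1.0, 1.5), 1.0, 32, 8.0)


class TestBandpass:
    def test_all_pass_identity_2d(self):
        field = near_field_2d(Sphere(1.0, 1.5 + 0.03j), 1.0, 16.0, 64,
                              total=True)
        filt = ApertureFilter(0.0, 20.0, 1.0)   # passes the whole grid band
        out = apply_bandpass_2d(field, filt)
        np.testing.assert_allclose(out.samples, field.samples, atol=1e-10)

    def test_empty_passband_rejected(self):
        # an annulus squeezed between two occupied grid radii retains nothing
        field = near_field_2d(Sphere(1.0, 1.5 + 0.03j), 1.0, 16.0, 64)
        freq = np.fft.fftfreq(64, d=16.0 / 64)
        u, v = np.meshgrid(freq, freq)
        radii = np.unique(np.round(np.hypot(u, v), 12))
        gaps = np.diff(radii)
        i = int(np.argmax(gaps))     # widest gap between occupied radii
        lo = radii[i] + 0.2 * gaps[i]
        hi = radii[i] + 0.8 * gaps[i]
        with pytest.raises(ValueError, match="empty passband"):
            apply_bandpass_2d(field, ApertureFilter(lo, hi, 1.0))

    def test_passband_pixel_count_brute_force(self):
        """Annulus mask pixel count equals brute-force enumeration of grid
        frequencies (reference aperture NA_out = 0.7 on the 128-pixel,
        16-um grid)."""
        fov, R, lam = 16.0, 128, 1.0
        filt = ApertureFilter(0.0, 0.7, lam)
        freq = np.fft.fftfreq(R, d=fov / R)
        u, v = np.meshgrid(freq, freq)
        q = np.hypot(u, v)
        mask = (q >= filt.fl) & (q <= filt.fu)
        brute = sum(1 for uu in freq for vv in freq
                    if filt.fl <= np.hypot(uu, vv) <= filt.fu)
        assert mask.sum() == brute

    def test_1d_allpass_and_monotone(self):
        far = far_field_radial(Sphere(1.0, 1.5 + 0.03j), 1.0, 128, 8.0)
        allp = apply_bandpass_1d(far, ApertureFilter(0.0, 50.0, 1.0))
        np.testing.assert_allclose(allp.samples, far.samples, atol=0)
        counts = []
        for na in [0.1, 0.3, 0.5, 0.7, 0.9]:
            out = apply_bandpass_1d(far, ApertureFilter(0.0, na, 1.0),
                                    clamp=True)
            counts.append(int(np.count_nonzero(out.samples)))
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_1d_agrees_with_2d_radial_cut(self):
        """Band-passed 1-D near field tracks the radial cut of the band-passed
        2-D near field for the radially symmetric single sphere."""
        from scipy.interpolate import CubicSpline

        from chemholo import spatial_profile

        sphere = Sphere(1.0, 1.5 + 0.03j)
        filt = ApertureFilter(0.0, 0.7, 1.0)
        f2 = near_field_2d(sphere, 1.0, 32.0, 256, aperture=filt)
        row = f2.samples[128, 128:]
        x = np.arange(128) * (32.0 / 256)
        cs_r = CubicSpline(x, row.real)
        cs_i = CubicSpline(x, row.imag)
        prof = spatial_profile(sphere, 1.0, 256, 16.0, aperture=filt,
                               total=False)
        sel = prof.radii < 12.0
        ref = cs_r(prof.radii[sel]) + 1j * cs_i(prof.radii[sel])
        err = np.max(np.abs(prof.samples[sel] - ref))
        assert err < 0.05 * np.abs(prof.samples).max()

    def test_wrong_domain_rejected(self):
        from chemholo import RadialField1D

        spat = RadialField1D(np.ones(8, complex), np.arange(1.0, 9.0),
                             "spatial", 1.0)
        with pytest.raises(ValueError, match="reciprocal"):
            apply_bandpass_1d(spat, ApertureFilter(0.0, 0.5, 1.0))


class TestTwoSpheres:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            two_sphere_field(Sphere(1.0, 1.5 + 0.01j), 1.5, 1.0, 16.0, 64)

    def test_mirror_symmetry_of_identical_pair(self):
        f2, _ = two_sphere_field(Sphere(1.0, 1.5 + 0.01j), 4.0, 1.0, 16.0, 128)
        # mirror about the plane bisecting the two centres (x -> -4 - x);
        # with the perturber at -4 and grid centred at 0, reflecting columns
        # about x = -2 maps the field onto itself where both sides exist
        x, _ = f2.axes()
        xi, yi = np.meshgrid(x, x)
        mirrored_x = -4.0 - xi
        inside = np.abs(mirrored_x) <= x.max() - 0.1
        from scipy.interpolate import RegularGridInterpolator

        interp_r = RegularGridInterpolator((x, x), f2.samples.real)
        interp_i = RegularGridInterpolator((x, x), f2.samples.imag)
        pts = np.column_stack([yi[inside], mirrored_x[inside]])
        mirrored = interp_r(pts) + 1j * interp_i(pts)
        np.testing.assert_allclose(mirrored, f2.samples[inside], atol=1e-3)

    def test_far_perturber_vanishes_and_ordering(self):
        from chemholo import spatial_profile

        sphere = Sphere(1.0, 1.5 + 0.01j)
        # converged single-sphere reference on a dense wide grid
        dense = spatial_profile(sphere, 1.0, 4096, 160.0, total=False)
        diffs = {}
        for sep in (4.0, 8.0, 128.0):
            _, half = two_sphere_field(sphere, sep, 1.0, 16.0, 64,
                                       n_radial=320)
            ref = 1.0 \
                + np.interp(half.radii, dense.radii, dense.samples.real) \
                + 1j * np.interp(half.radii, dense.radii, dense.samples.imag)
            diffs[sep] = np.max(np.abs(half.samples - ref))
        # the scattered field decays only algebraically, so the perturbation
        # at 8x the FOV is small but not negligible
        assert diffs[128.0] < 0.05
        assert diffs[4.0] > diffs[8.0] > diffs[128.0]
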