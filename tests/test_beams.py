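"""Laguerre-Gaussian mode evaluation, launch directions and source sampling."""

import math

import numpy as np
import pytest
from scipy.special import eval_genlaguerre

from vortexmc import (
    BeamSpec,
    CylindricalPoint,
    PixelGrid,
    fork_hologram,
    launch_direction,
    lg_field,
    lg_phase,
    sample_source,
    wrap_phase,
)
from vortexmc.beams import mode_power

HENE = 633e-6


class TestLgField:
    def test_vortex_null_on_axis(self, lg5):
        for z in (0.0, 10.0, 500.0):
            assert lg_field(lg5, CylindricalPoint(0.0, 0.3, z)) == 0

    def test_gaussian_origin_value(self, gauss):
        val = lg_field(gauss, CylindricalPoint(0.0, 0.0, 0.0))
        assert val.imag == pytest.approx(0.0, abs=1e-15)
        assert val.real == pytest.approx(math.sqrt(2 / math.pi) / 0.8, rel=1e-12)

    def test_ring_radius_of_lg3(self, lg3):
        # |rho^3 exp(-rho^2/w^2)| peaks at rho = w sqrt(3/2)
        rho = np.linspace(0.2, 2.0, 4001)
        amp = np.abs(lg_field(lg3, (rho, np.zeros_like(rho), np.zeros_like(rho))))
        assert rho[np.argmax(amp)] == pytest.approx(0.8 * math.sqrt(1.5), abs=1e-3)

    @pytest.mark.parametrize("ell", range(6))
    @pytest.mark.parametrize("p", range(3))
    def test_mode_normalization(self, ell, p):
        beam = BeamSpec(ell, p, 0.8, HENE)
        for z in (0.0, beam.rayleigh_range, 3 * beam.rayleigh_range):
            assert mode_power(beam, z) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("pair", [((0, 0), (0, 1)), ((3, 0), (3, 2)), ((1, 0), (2, 0)), ((5, 0), (5, 1))])
    def test_mode_orthogonality(self, pair):
        (l1, p1), (l2, p2) = pair
        b1 = BeamSpec(l1, p1, 0.8, HENE)
        b2 = BeamSpec(l2, p2, 0.8, HENE)
        rho = np.linspace(1e-6, 6.0, 6000)
        phi = np.linspace(-np.pi, np.pi, 181)
        R, PHI = np.meshgrid(rho, phi)
        Z = np.zeros_like(R)
        a1 = lg_field(b1, (R, PHI, Z))
        a2 = lg_field(b2, (R, PHI, Z))
        inner = np.trapezoid(np.trapezoid(a1 * np.conj(a2) * R, rho, axis=1), phi)
        assert abs(inner) < 1e-6

    def test_rejects_nonfinite(self, lg3):
        with pytest.raises(ValueError):
            lg_field(lg3, (np.array([np.nan]), np.zeros(1), np.zeros(1)))


class TestLgPhase:
    def test_initial_sector_worked_example(self, lg3):
        # at z=0 the phase is -3*phi: phi = -pi/10 gives +3*pi/10
        assert lg_phase(lg3, CylindricalPoint(1.0, -np.pi / 10, 0.0)) == pytest.approx(
            3 * np.pi / 10, rel=1e-12)
        assert lg_phase(lg3, CylindricalPoint(1.0, -np.pi / 10, 0.0)) == pytest.approx(0.9425, abs=1e-4)

    def test_all_terms_vanish_at_origin_plane(self, lg5):
        assert lg_phase(lg5, CylindricalPoint(1.3, 0.0, 0.0)) == 0.0

    def test_gouy_at_rayleigh_range(self):
        beam = BeamSpec(1, 0, 0.8, HENE)
        assert beam.gouy(beam.rayleigh_range) == pytest.approx(np.pi / 2, rel=1e-12)

    def test_gouy_limit_far_field(self):
        beam = BeamSpec(2, 1, 0.8, HENE)
        order = 2 * 1 + 2 + 1
        assert beam.gouy(1e12) == pytest.approx(order * np.pi / 2, rel=1e-8)

    @pytest.mark.parametrize("ell,p", [(0, 0), (3, 0), (5, 0), (2, 0)])
    def test_phase_equals_field_argument(self, ell, p):
        beam = BeamSpec(ell, p, 0.8, HENE)
        rng = np.random.default_rng(7)
        rho = rng.uniform(0.05, 2.5, 200)
        phi = rng.uniform(-np.pi, np.pi, 200)
        z = rng.uniform(0, 2 * beam.rayleigh_range, 200)
        f = lg_field(beam, (rho, phi, z))
        psi = lg_phase(beam, (rho, phi, z))
        assert np.max(np.abs(wrap_phase(np.angle(f) - psi))) < 1e-9

    def test_phase_equals_argument_where_envelope_positive(self):
        # for p > 0 the Laguerre polynomial changes sign; the closed-form
        # phase tracks arg(field) wherever the radial envelope is positive
        beam = BeamSpec(2, 1, 0.8, HENE)
        rho = np.linspace(0.05, 2.5, 500)
        lag = eval_genlaguerre(1, 2, 2 * rho**2 / 0.8**2)
        rho = rho[lag > 1e-3]
        phi = np.full_like(rho, 0.4)
        z = np.full_like(rho, 5.0)
        f = lg_field(beam, (rho, phi, z))
        psi = lg_phase(beam, (rho, phi, z))
        assert np.max(np.abs(wrap_phase(np.angle(f) - psi))) < 1e-9


class TestLaunchDirection:
    def test_axial_for_gaussian(self, gauss):
        s = launch_direction(gauss, 0.7, -0.3, 0.0)
        assert np.allclose(s, [0, 0, 1], atol=1e-15)

    def test_skew_angle_single_charge(self):
        beam = BeamSpec(1, 0, 0.8, HENE)
        r = 0.9
        s = launch_direction(beam, r, 0.0, 0.0)
        # unnormalized (0, 1/r, k): skew angle arctan(1/(k r))
        expected = np.array([0.0, 1.0 / r, beam.k])
        expected /= np.linalg.norm(expected)
        assert np.allclose(s, expected, atol=1e-12)
        skew = math.acos(np.clip(s[2], -1, 1))
        assert skew == pytest.approx(math.atan(1.0 / (beam.k * r)), rel=1e-9)

    def test_mirror_symmetry_in_charge(self):
        bp = BeamSpec(4, 0, 0.8, HENE)
        bm = BeamSpec(-4, 0, 0.8, HENE)
        sp = launch_direction(bp, 1.1, 0.0, 0.0)
        sm = launch_direction(bm, 1.1, 0.0, 0.0)
        assert sp[1] == pytest.approx(-sm[1], rel=1e-12)
        assert sp[0] == pytest.approx(sm[0], abs=1e-15)

    def test_on_axis_is_singular(self, lg3):
        with pytest.raises(ValueError):
            launch_direction(lg3, 0.0, 0.0, 0.0)

    def test_angular_frequency_never_matters(self):
        a = BeamSpec(3, 0, 0.8, HENE, angular_frequency=1.0)
        b = BeamSpec(3, 0, 0.8, HENE, angular_frequency=2.97e15)
        assert np.allclose(launch_direction(a, 0.5, 0.4, 2.0),
                           launch_direction(b, 0.5, 0.4, 2.0), atol=0)


class TestSampleSource:
    def test_radial_histogram_matches_mode(self, lg5):
        from scipy.stats import chisquare

        n = 100_000
        src = sample_source(lg5, n, seed=3)
        rho = np.hypot(src.x, src.y)
        edges = np.linspace(0.0, 3.0, 31)
        counts, _ = np.histogram(rho, edges)
        centers = 0.5 * (edges[1:] + edges[:-1])
        dens = np.abs(lg_field(lg5, (centers, np.zeros_like(centers), np.zeros_like(centers)))) ** 2 * centers
        probs = dens / dens.sum()
        # fold the far tail into the last bin so expectations stay > 5
        keep = probs * n > 5
        stat, p = chisquare(counts[keep], n * probs[keep] * counts[keep].sum() / (n * probs[keep].sum()))
        assert p > 0.01

    def test_azimuth_uniform_for_gaussian(self, gauss):
        n = 50_000
        src = sample_source(gauss, n, seed=4)
        phi = np.arctan2(src.y, src.x)
        # Rayleigh test: n R^2 ~ chi^2(2)/2 under uniformity
        z = n * np.abs(np.mean(np.exp(1j * phi))) ** 2
        assert z < 4.6  # p > 0.01

    def test_initial_phase_is_mode_phase(self, lg3):
        src = sample_source(lg3, 500, seed=5, z_launch=2.0)
        rho = np.hypot(src.x, src.y)
        phi = np.arctan2(src.y, src.x)
        expected = lg_phase(lg3, (rho, phi, np.full_like(rho, 2.0)))
        assert np.allclose(src.psi0, expected, atol=0)

    def test_directions_and_polarization_are_consistent(self, lg3):
        src = sample_source(lg3, 2000, seed=6)
        assert np.allclose(np.linalg.norm(src.directions, axis=1), 1.0, atol=1e-12)
        assert np.max(np.abs(np.sum(src.pol_x * src.directions, axis=1))) < 1e-9
        assert np.max(np.abs(np.sum(src.pol_y * src.directions, axis=1))) < 1e-9
        # default x-polarized: the second Jones amplitude is zero
        assert np.allclose(src.pol_y, 0.0)
        assert np.allclose(np.linalg.norm(src.pol_x, axis=1), 1.0, atol=1e-12)

    def test_stratified_sampling_matches_mode_closely(self, lg5):
        src = sample_source(lg5, 2**16, seed=8, method="stratified")
        rho = np.hypot(src.x, src.y)
        edges = np.linspace(0.3, 2.2, 20)
        counts, _ = np.histogram(rho, edges)
        centers = 0.5 * (edges[1:] + edges[:-1])
        dens = np.abs(lg_field(lg5, (centers, np.zeros_like(centers), np.zeros_like(centers)))) ** 2 * centers
        expect = dens / dens.sum() * counts.sum()
        sel = expect > 500  # populated bins; edge bins are shot-noise limited
        assert np.max(np.abs(counts[sel] - expect[sel]) / expect[sel]) < 0.05

    def test_guard_band_and_validation(self, lg3):
        src = sample_source(lg3, 10_000, seed=9)
        assert np.hypot(src.x, src.y).min() > 1e-12 * 0.8
        with pytest.raises(ValueError):
            sample_source(lg3, 0, seed=1)


class TestForkHologram:
    def test_pure_grating_for_zero_charge(self):
        grid = PixelGrid.centered(64, 0.01)
        phase = fork_hologram(0, 0.08, grid)
        x = grid.x_centers
        expected = wrap_phase(2 * np.pi * x / 0.08)
        assert np.allclose(phase[0], expected, atol=1e-12)

    def test_dislocation_winding_equals_charge(self):
        grid = PixelGrid.centered(256, 0.01)
        for ell in (1, 5, -3):
            phase = fork_hologram(ell, 0.08, grid)
            theta = np.linspace(-np.pi, np.pi, 720, endpoint=False)
            r = 0.3
            x, y = r * np.cos(theta), r * np.sin(theta)
            iy, ix = grid.index_of(x, y)
            vals = phase[iy, ix] - 2 * np.pi * grid.x_centers[ix] / 0.08
            winding = np.sum(wrap_phase(np.diff(np.append(vals, vals[0]))))
            assert round(winding / (2 * np.pi)) == ell

    def test_conjugate_symmetry(self):
        grid = PixelGrid.centered(64, 0.01)
        f_plus = fork_hologram(3, 0.08, grid)
        f_minus = fork_hologram(-3, 0.08, grid)
        linear = 2 * np.pi * grid.meshgrid()[0] / 0.08
        resid = wrap_phase((f_plus - linear) + (f_minus - linear))
        assert np.max(np.abs(resid)) < 1e-9

    def test_period_must_be_positive(self):
        with pytest.raises(ValueError):
            fork_hologram(1, 0.0, PixelGrid.centered(8, 0.01))
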