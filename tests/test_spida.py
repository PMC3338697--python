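import numpy as np
import pytest

from oligofluct import (
    DetectorModel,
    HistogramModel,
    IntensityHistogram,
    RoiSpec,
    SpidaFitOptions,
    broaden_histogram,
    compound_histogram,
    convolve_histograms,
    fit_histogram,
    image_to_histogram,
    model_histogram,
    simulate_image,
    single_particle_distribution,
)
from oligofluct.errors import InvalidDataError

from conftest import monomer_spec


def tv_distance(p, q):
    L = max(len(p), len(q))
    a, b = np.zeros(L), np.zeros(L)
    a[: len(p)] = p
    b[: len(q)] = q
    return 0.5 * np.abs(a - b).sum()


class TestSingleParticleDistribution:
    def test_support_and_profile_value(self, psf):
        # a particle at r = w0 contributes round(eps * e^-2) = 14 for eps=100
        rho = single_particle_distribution(psf, 100.0)
        assert len(rho) == 101
        assert rho[100] > 0  # particle at the pixel center
        assert round(100.0 * np.exp(-2.0)) == 14
        assert rho[14] > 0

    def test_mean_times_disc_over_beam_area_is_eps(self, psf):
        """E[rho] * (disc area / BA) = eps: the disc-uniform position average
        of the profile integrates back to one quantal brightness."""
        eps = 80.0
        R = 3.0 * psf.e2_radius
        rho = single_particle_distribution(psf, eps, R, bin_width=0.25)
        mean = np.sum(np.arange(len(rho)) * 0.25 * rho)
        assert mean * (np.pi * R**2) / psf.beam_area == pytest.approx(eps, rel=2e-3)

    def test_matches_grid_subsample_oracle(self, psf):
        rho_exact = single_particle_distribution(psf, 50.0)
        rho_grid = single_particle_distribution(psf, 50.0, subsample=40)
        assert tv_distance(rho_exact, rho_grid) < 5e-3

    def test_cutoff_validation(self, psf):
        with pytest.raises(ValueError):
            single_particle_distribution(psf, 50.0, cutoff_radius=2.0 * psf.e2_radius)


class TestCompoundHistogram:
    def test_empty_field_point_mass(self, psf):
        h = compound_histogram(0.0, 50.0, psf)
        assert h.pmf == pytest.approx([1.0])

    @pytest.mark.parametrize("N,eps", [(0.1, 10.0), (1.0, 50.0), (5.0, 200.0)])
    def test_normalization_and_mean(self, psf, N, eps):
        h = compound_histogram(N, eps, psf, bin_width=0.25)
        assert abs(h.pmf.sum() - 1.0) <= 1e-9
        assert h.mean() == pytest.approx(N * eps, rel=0.02, abs=0.3)

    @pytest.mark.parametrize("N,eps", [(1.0, 50.0), (1.5, 20.0)])
    def test_direct_and_cf_routes_agree(self, psf, N, eps):
        hd = compound_histogram(N, eps, psf, method="direct")
        hc = compound_histogram(N, eps, psf, method="cf")
        assert tv_distance(hd.pmf, hc.pmf) < 1e-8

    def test_poisson_superposition_additivity(self, psf):
        """compound(N1+N2) = compound(N1) * compound(N2) for one species
        (evaluated on a common intensity grid)."""
        h_sum = compound_histogram(3.0, 40.0, psf, bin_width=1.0)
        h_conv = convolve_histograms(
            compound_histogram(1.0, 40.0, psf, bin_width=1.0),
            compound_histogram(2.0, 40.0, psf, bin_width=1.0),
        )
        assert tv_distance(h_sum.pmf, h_conv.pmf) < 1e-8

    def test_monte_carlo_oracle_agreement(self, psf):
        """Model histogram vs the empirical pixel histogram of a noiseless
        simulated image (same forward physics, independent code path)."""
        spec = monomer_spec(psf, 1.0, 50.0, shape=(1024, 1024), seed=3)
        img = simulate_image(spec)
        emp = np.bincount(img.ravel().astype(np.int64)).astype(float)
        emp /= emp.sum()
        h = compound_histogram(1.0, 50.0, psf)
        assert tv_distance(h.pmf, emp) < 0.015


class TestConvolveAndBroaden:
    def test_point_mass_is_identity_element(self, psf):
        h = compound_histogram(1.0, 30.0, psf)
        delta = HistogramModel(np.array([1.0]))
        assert tv_distance(convolve_histograms(h, delta).pmf, h.pmf) < 1e-12

    def test_point_masses_add_positions(self):
        a = HistogramModel(np.eye(1, 6, 5).ravel())  # delta at 5
        b = HistogramModel(np.eye(1, 4, 3).ravel())  # delta at 3
        out = convolve_histograms(a, b)
        assert out.pmf[8] == pytest.approx(1.0)

    def test_zero_noise_broadening_is_identity(self, psf):
        h = compound_histogram(1.0, 30.0, psf)
        out = broaden_histogram(h, DetectorModel(slope=0.0, intercept=0.0))
        np.testing.assert_allclose(out.pmf, h.pmf)

    def test_point_mass_broadens_to_discrete_gaussian(self):
        h = HistogramModel(np.eye(1, 101, 100).ravel())  # delta at 100
        out = broaden_histogram(h, DetectorModel(slope=0.5, intercept=0.0))
        assert abs(out.pmf.sum() - 1.0) <= 1e-9
        assert out.mean() == pytest.approx(100.0, abs=0.01)
        assert out.variance() == pytest.approx(50.0 + 1 / 12, rel=0.01)

    def test_law_of_total_variance(self, psf):
        """Broadening adds exactly intercept + slope*mean for interior pmfs."""
        det = DetectorModel(slope=0.4, intercept=3.0)
        h = compound_histogram(2.0, 40.0, psf)
        out = broaden_histogram(h, det)
        assert out.mean() == pytest.approx(h.mean(), abs=0.05)
        added = det.intercept + det.slope * h.mean()
        assert out.variance() - h.variance() == pytest.approx(added, rel=0.02)

    def test_standalone_vs_joint_cf_broadening(self, psf, detector):
        """Two independent broadening implementations must agree closely."""
        joint = model_histogram([(1.0, 50.0)], psf, detector=detector)
        seq = broaden_histogram(compound_histogram(1.0, 50.0, psf), detector)
        assert tv_distance(joint.pmf, seq.pmf) < 2e-3


class TestImageToHistogram:
    def test_constant_image_all_mass_at_zero(self):
        h = image_to_histogram(np.full((64, 64), 10.0), background=10.0)
        assert h.counts[0] == 64 * 64

    def test_two_value_image(self):
        img = np.tile([5.0, 15.0], (64, 32))
        h = image_to_histogram(img, background=5.0)
        assert h.counts[0] == h.counts[10] == 64 * 32

    def test_pixel_count_conserved_with_rois(self):
        img = np.arange(64 * 64, dtype=float).reshape(64, 64)
        h = image_to_histogram(img, rois=[RoiSpec(0, 0, 32, 64)])
        assert h.total_pixels == 32 * 64

    def test_saturated_pixels_flagged(self):
        img = np.full((64, 64), 4095.0)
        h = image_to_histogram(img, saturation=4095.0)
        assert h.n_saturated == 64 * 64


class TestFitHistogram:
    def test_self_consistency_fixed_point(self, psf):
        """Fitting an exactly model-generated histogram recovers the
        generating parameters to high precision."""
        h = model_histogram([(2.0, 30.0)], psf)
        observed = IntensityHistogram(h.pmf * 1e6)
        fit = fit_histogram(observed, SpidaFitOptions(model="one_pop"), psf,
                            init={"N1": 1.0, "eps1": 20.0})
        assert fit.params["N1"] == pytest.approx(2.0, rel=1e-4)
        assert fit.params["eps1"] == pytest.approx(30.0, rel=1e-4)

    def test_monomer_recovery_from_simulated_image(self, psf, detector):
        spec = monomer_spec(psf, 2.0, 44.0, shape=(256, 256), detector=detector, seed=13)
        img = simulate_image(spec)
        fit = fit_histogram(image_to_histogram(img), SpidaFitOptions(model="one_pop"),
                            psf, detector=detector)
        assert fit.success
        assert fit.params["eps1"] == pytest.approx(44.0, rel=0.10)
        assert fit.params["N1"] == pytest.approx(2.0, rel=0.15)

    def test_monomer_dimer_mode_ties_brightness(self, psf, detector):
        h = model_histogram([(1.5, 25.0), (0.8, 50.0)], psf, detector=detector)
        observed = IntensityHistogram(h.pmf * 1e6)
        opts = SpidaFitOptions(model="monomer_dimer", fixed_monomer_eps=25.0)
        fit = fit_histogram(observed, opts, psf, detector=detector)
        assert fit.params["eps2"] == 2 * fit.params["eps1"]
        assert fit.params["N1"] == pytest.approx(1.5, rel=0.02)
        assert fit.params["N2"] == pytest.approx(0.8, rel=0.02)

    def test_requires_enough_pixels(self, psf):
        h = IntensityHistogram(np.array([50.0, 50.0]))
        with pytest.raises(InvalidDataError):
            fit_histogram(h, SpidaFitOptions(), psf)
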