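import numpy as np
import pytest

from oligofluct import (
    DetectorModel,
    RoiSpec,
    compute_raw_moments,
    correct_moments,
    estimate_background,
    forward_cumulants,
    moments_from_image,
    simulate_image,
    solve_one_population,
    solve_two_populations,
)
from oligofluct.errors import InvalidDataError, NoSignalError
from oligofluct.moments import MomentSet

from conftest import monomer_spec


def moment_set(k1, k2, k3, k4, n=10**6):
    return MomentSet(mean=k1, kappa2=k2, kappa3=k3, kappa4=k4, n_pixels=n,
                     raw_mu2=0.0, raw_mu3=0.0, raw_mu4=0.0)


class TestBackground:
    def test_flat_image(self):
        img = np.full((64, 64), 7.0)
        assert estimate_background(img, [RoiSpec(0, 0, 16, 16, "background")]) == 7.0

    def test_auto_mode_on_half_dark_image(self):
        img = np.zeros((64, 64))
        img[:32] = 12.0
        img[32:] = 500.0
        assert estimate_background(img) == pytest.approx(12.0)

    def test_manual_empty_list_rejected(self):
        with pytest.raises(InvalidDataError):
            estimate_background(np.zeros((64, 64)), [])


class TestRawMoments:
    def test_constant_pixels(self):
        m, mu2, mu3, mu4 = compute_raw_moments(np.full(128, 5.0))
        assert (m, mu2, mu3, mu4) == (5.0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "values,expected",
        [
            (np.tile([0.0, 2.0], 64), (1.0, 1.0, 0.0, 1.0)),
            (np.tile([0.0, 0.0, 3.0], 64), (1.0, 2.0, 2.0, 6.0)),
        ],
    )
    def test_closed_form_two_and_three_point(self, values, expected):
        assert compute_raw_moments(values) == pytest.approx(expected)

    def test_rejects_tiny_samples(self):
        with pytest.raises(InvalidDataError):
            compute_raw_moments(np.zeros(32))


class TestCorrectMoments:
    def test_identity_when_noiseless(self):
        ms = correct_moments(10.0, 4.0, 1.5, 50.0, 1000, detector=None)
        assert ms.kappa2 == 4.0
        assert ms.kappa3 == 1.5
        assert ms.kappa4 == 50.0 - 3 * 16.0  # mu4 - 3 mu2^2

    def test_algebraic_inverse_of_noise_forward_model(self):
        """Forward-contaminate known cumulants with the conditional-Gaussian
        law, then verify the correction chain recovers them exactly."""
        k1, k2, k3, k4 = 70.0, 450.0, 4333.0, 52500.0
        c, s = 3.0, 0.6
        m2 = k2 + c + s * k1
        m3 = k3 + 3 * s * k2
        m4c = k4 + 6 * s * k3 + 3 * s**2 * k2
        mu4 = m4c + 3 * m2**2
        det = DetectorModel(slope=s, intercept=c)
        ms = correct_moments(k1, m2, m3, mu4, 10**6, detector=det)
        assert ms.kappa2 == pytest.approx(k2)
        assert ms.kappa3 == pytest.approx(k3)
        assert ms.kappa4 == pytest.approx(k4)
        assert not ms.over_corrected

    def test_background_enters_noise_level(self):
        det = DetectorModel(slope=1.0, intercept=0.0)
        ms = correct_moments(10.0, 25.0, 0.0, 3 * 25.0**2, 1000, detector=det, background=5.0)
        assert ms.kappa2 == pytest.approx(25.0 - 15.0)

    def test_over_correction_flagged(self):
        det = DetectorModel(slope=1.0, intercept=0.0)
        ms = correct_moments(100.0, 50.0, 0.0, 3 * 50.0**2, 1000, detector=det)
        assert ms.over_corrected

    def test_flat_noise_only_field_corrects_to_zero(self, psf, detector):
        """Pure background + detector noise: corrected cumulants ~ 0."""
        spec = monomer_spec(psf, 0.0, 1.0, shape=(256, 256), detector=detector,
                            background=50.0, seed=31)
        img = simulate_image(spec).astype(float)
        m, mu2, mu3, mu4 = compute_raw_moments(img)
        ms = correct_moments(m - 50.0, mu2, mu3, mu4, img.size,
                             detector=detector, background=50.0)
        noise_var = detector.variance(50.0)
        assert abs(ms.kappa2) < 0.05 * noise_var + 1 / 6  # rounding adds ~1/12
        assert abs(ms.kappa3) < 0.05 * noise_var**1.5
        assert abs(ms.kappa4) < 0.2 * noise_var**2


class TestOnePopulation:
    def test_spec_point(self, psf):
        N, eps = solve_one_population(moment_set(70.0, 175.0, 0, 0), psf)
        assert eps == pytest.approx(5.0)
        assert N == pytest.approx(14.0)

    def test_single_particle_fixed_point(self, psf):
        m = 33.0
        N, eps = solve_one_population(moment_set(m, 0.5 * m**2, 0, 0), psf)
        assert N == pytest.approx(1.0)
        assert eps == pytest.approx(m)

    def test_no_signal_raises(self, psf):
        with pytest.raises(NoSignalError):
            solve_one_population(moment_set(10.0, -1.0, 0, 0), psf)

    def test_recovery_from_simulated_monomers(self, psf, detector):
        spec = monomer_spec(psf, 2.0, 30.0, shape=(512, 512), detector=detector,
                            background=5.0, seed=41)
        img = simulate_image(spec).astype(float)
        ms = moments_from_image(img, detector=detector, background=5.0)
        N, eps = solve_one_population(ms, psf)
        assert eps == pytest.approx(30.0, rel=0.05)
        assert N == pytest.approx(2.0, rel=0.10)


class TestTwoPopulations:
    def test_forward_cumulants_reference_point(self):
        assert forward_cumulants([5, 1], [10, 20]) == pytest.approx(
            (70.0, 450.0, 13000.0 / 3.0, 52500.0)
        )

    def test_exact_inversion_of_reference_point(self, psf):
        ms = moment_set(*forward_cumulants([5, 1], [10, 20]))
        res = solve_two_populations(ms, psf)
        assert res.model == "two"
        assert (res.N1, res.eps1, res.N2, res.eps2) == pytest.approx(
            (5.0, 10.0, 1.0, 20.0), rel=1e-6
        )

    @pytest.mark.parametrize(
        "params",
        [
            (2.0, 15.0, 2.0, 30.0),
            (10.0, 8.0, 0.5, 64.0),
            (1.0, 40.0, 4.0, 60.0),
            (0.5, 12.0, 3.0, 24.0),
        ],
    )
    def test_round_trip_grid(self, psf, params):
        """Noise-free forward cumulants invert back to 1e-6 relative."""
        n1, e1, n2, e2 = params
        ms = moment_set(*forward_cumulants([n1, n2], [e1, e2]))
        res = solve_two_populations(ms, psf)
        assert res.model == "two"
        assert (res.N1, res.eps1, res.N2, res.eps2) == pytest.approx(params, rel=1e-6)

    def test_fixed_alpha_inversion(self, psf):
        ms = moment_set(*forward_cumulants([5, 1], [10, 20]))
        res = solve_two_populations(ms, psf, fix_alpha=2.0)
        assert (res.N1, res.eps1, res.N2, res.eps2) == pytest.approx(
            (5.0, 10.0, 1.0, 20.0), rel=1e-6
        )

    def test_pure_one_population_falls_back(self, psf):
        ms = moment_set(*forward_cumulants([14], [5]))
        res = solve_two_populations(ms, psf)
        assert res.model == "one"
        assert res.N2 == 0.0
        assert (res.N1, res.eps1) == pytest.approx((14.0, 5.0))

    def test_calibrated_pipeline_is_linear_solve(self, psf):
        ms = moment_set(*forward_cumulants([5, 5], [30, 60]))
        res = solve_two_populations(ms, psf, fix_alpha=2.0, fix_eps1=30.0)
        assert (res.N1, res.N2) == pytest.approx((5.0, 5.0), rel=1e-9)

    def test_fix_eps1_requires_alpha(self, psf):
        ms = moment_set(*forward_cumulants([5, 5], [30, 60]))
        with pytest.raises(ValueError):
            solve_two_populations(ms, psf, fix_eps1=30.0)


class TestImagePipeline:
    def test_tile_filter_discards_heterogeneous_tiles(self, psf):
        """A bright corner patch should be rejected, not averaged in."""
        rng = np.random.default_rng(51)
        img = rng.normal(100.0, 5.0, size=(512, 512))
        img[:128, :128] = 5000.0
        ms = moments_from_image(img)
        assert ms.mean == pytest.approx(100.0, rel=0.02)

    def test_small_roi_single_tile(self, psf):
        img = np.tile([0.0, 2.0], (64, 32))
        ms = moments_from_image(img, signal_rois=[RoiSpec(0, 0, 64, 64)])
        assert ms.mean == pytest.approx(1.0)
        assert ms.kappa2 == pytest.approx(1.0)
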