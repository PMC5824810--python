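import numpy as np
import pytest

from memscaffold.fcs import (
    AutocorrelationCurve,
    DensityEstimate,
    DetectionVolume,
    build_intensity_calibration,
    density_from_intensity,
    diffusion_time,
    fcs_model_2d,
    fit_fcs,
    load_fcs_curves,
    surface_density,
    temperature_correct_d,
    waist_from_reference,
    water_viscosity_mpa_s,
)
from memscaffold.simulate import FCSSimConfig, gen_fcs_curve


class TestModel2D:
    def test_amplitude_is_inverse_particle_number(self):
        assert fcs_model_2d(0.0, n_particles=10.0, tau_d_s=1e-3) == pytest.approx(0.1)

    def test_half_decay_at_tau_d(self):
        assert fcs_model_2d(1e-3, n_particles=10.0, tau_d_s=1e-3) == pytest.approx(
            0.05
        )

    def test_direct_value(self):
        # tau = 3 tau_D -> G = (1/10) / 4 = 0.025
        assert fcs_model_2d(3e-3, n_particles=10.0, tau_d_s=1e-3) == pytest.approx(
            0.025
        )

    def test_strictly_decreasing_in_lag_and_n(self):
        lags = np.logspace(-5, 0, 60)
        g = fcs_model_2d(lags, 10.0, 1e-3)
        assert (np.diff(g) < 0).all()
        assert (fcs_model_2d(lags, 20.0, 1e-3) < g).all()


class TestFitFCS:
    def test_noise_free_round_trip(self):
        curve = gen_fcs_curve(FCSSimConfig(true_n=12.0, true_tau_d_s=0.020,
                                           noise_sd=0.0))
        fit = fit_fcs(curve)
        assert fit.n_particles == pytest.approx(12.0, rel=1e-6)
        assert fit.tau_d_s == pytest.approx(0.020, rel=1e-6)

    def test_noisy_recovery_single_seed(self):
        curve = gen_fcs_curve(FCSSimConfig(), seed=7)
        fit = fit_fcs(curve)
        assert fit.n_particles == pytest.approx(12.0, rel=0.10)
        assert fit.n_sd > 0

    def test_constant_curve_rejected(self):
        lags = np.logspace(-4, 0, 40)
        with pytest.raises(ValueError, match="decay"):
            fit_fcs(AutocorrelationCurve(lags_s=lags, g=np.full(40, 0.1)))

    def test_negative_amplitude_rejected(self):
        lags = np.logspace(-4, 0, 40)
        g = -fcs_model_2d(lags, 10.0, 1e-2)
        with pytest.raises(ValueError):
            fit_fcs(AutocorrelationCurve(lags_s=lags, g=g))

    def test_curve_invariants(self):
        with pytest.raises(ValueError, match="10 lag points"):
            AutocorrelationCurve(lags_s=np.array([1e-4, 1e-3]),
                                 g=np.array([0.1, 0.05]))
        with pytest.warns(UserWarning, match="decades"):
            AutocorrelationCurve(
                lags_s=np.linspace(1e-3, 2e-3, 12),
                g=np.linspace(0.1, 0.09, 12),
            )


class TestWaistCalibration:
    def test_round_trip_on_calibration_dye(self):
        # Reference dye with D = 414 um^2/s through a 207 nm waist.
        tau_d = diffusion_time(207.0, 414.0)
        assert tau_d == pytest.approx(25.9e-6, rel=1e-2)
        assert waist_from_reference(tau_d, 414.0) == pytest.approx(207.0, rel=1e-12)

    def test_closed_form(self):
        assert waist_from_reference(1.0, 1.0) == pytest.approx(2000.0)  # 2 um

    def test_sqrt_scaling_in_d(self):
        r1 = waist_from_reference(1e-5, 400.0)
        r2 = waist_from_reference(1e-5, 800.0)
        assert r2 / r1 == pytest.approx(np.sqrt(2.0))


class TestTemperatureCorrection:
    def test_identity_at_same_temperature(self):
        assert temperature_correct_d(414.0, 298.15, 298.15) == pytest.approx(414.0)

    def test_dye_corrected_to_objective_temperature(self):
        # 25 C -> 27.5 C raises D by ~6.5% (Stokes-Einstein with water viscosity).
        d = temperature_correct_d(414.0, 298.15, 300.65)
        assert d == pytest.approx(441.0, rel=0.01)

    def test_monotone_in_working_temperature(self):
        temps = np.arange(293.15, 308.15, 1.0)
        ds = [temperature_correct_d(414.0, 298.15, t) for t in temps]
        assert all(a < b for a, b in zip(ds, ds[1:]))

    def test_viscosity_reference_point_and_range(self):
        assert water_viscosity_mpa_s(298.15) == pytest.approx(0.890, rel=0.005)
        with pytest.raises(ValueError, match="range"):
            water_viscosity_mpa_s(350.0)


class TestSurfaceDensity:
    def test_absolute_density_from_particle_number(self):
        dens = surface_density(12.12, DetectionVolume(r0_nm=207.0))
        assert dens.sigma_per_um2 == pytest.approx(90.0, rel=1e-2)

    def test_crowding_flag(self):
        dens = surface_density(12.12, DetectionVolume(r0_nm=207.0),
                               scaffold_length_nm=110.0)
        assert dens.rho == pytest.approx(90.0 * 0.11**2, rel=1e-2)  # ~1.09
        assert not dens.valid

    def test_zero_particles(self):
        dens = surface_density(0.0, DetectionVolume(r0_nm=207.0))
        assert dens.sigma_per_um2 == 0.0 and dens.rho == 0.0 and dens.valid

    def test_boundary_rho_is_valid(self):
        # rho exactly 0.2 is still the valid regime (invalid only above).
        vol = DetectionVolume(r0_nm=207.0)
        n = 0.2 / 0.11**2 * vol.area_um2
        assert surface_density(n, vol).valid

    def test_linear_in_n(self):
        vol = DetectionVolume(r0_nm=207.0)
        d1 = surface_density(5.0, vol)
        d2 = surface_density(10.0, vol)
        assert d2.sigma_per_um2 == pytest.approx(2 * d1.sigma_per_um2)
        assert d2.rho == pytest.approx(2 * d1.rho)


def make_pair(intensity, sigma, length_nm=110.0):
    rho = sigma * (length_nm / 1000.0) ** 2
    return intensity, DensityEstimate(sigma_per_um2=sigma, rho=rho,
                                      valid=rho <= 0.2)


class TestIntensityCalibration:
    def test_exact_line_recovered(self):
        pairs = [make_pair(i, 2.0 * i) for i in range(1, 9)]
        cal = build_intensity_calibration(pairs)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_crowded_pairs_excluded(self):
        good = [make_pair(i, 2.0 * i) for i in range(1, 6)]
        crowded = [make_pair(100.0, 200.0)]  # rho >> 0.2
        cal = build_intensity_calibration(good + crowded)
        assert cal.n_guvs == 5
        assert cal.n_excluded == 1
        assert cal.slope == pytest.approx(2.0)

    def test_too_few_valid_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_intensity_calibration([make_pair(1.0, 2.0), make_pair(2.0, 4.0)])

    def test_noisy_slope_recovery(self, rng):
        intensity = np.linspace(1, 10, 12)
        sigma = 1.5 * intensity * rng.lognormal(0, 0.1, 12)
        cal = build_intensity_calibration(
            [make_pair(i, s) for i, s in zip(intensity, sigma)]
        )
        assert cal.slope == pytest.approx(1.5, rel=0.15)

    def test_density_from_intensity_inverts_line(self):
        cal = build_intensity_calibration([make_pair(i, 2.0 * i) for i in range(1, 9)])
        dens = density_from_intensity(45.0, cal)
        assert dens.sigma_per_um2 == pytest.approx(90.0, rel=1e-9)
        assert dens.source == "intensity_calibration"
        assert not dens.valid  # 90/um^2 is deep in the crowded regime

    def test_negative_prediction_clipped(self):
        cal = build_intensity_calibration([make_pair(i, 2.0 * i) for i in range(1, 9)])
        shifted = type(cal)(slope=cal.slope, intercept=-10.0, n_guvs=cal.n_guvs,
                            r_squared=cal.r_squared)
        with pytest.warns(UserWarning, match="negative"):
            dens = density_from_intensity(0.0, shifted)
        assert dens.sigma_per_um2 == 0.0


class TestIO:
    def test_load_curves_csv(self, tmp_path):
        curve = gen_fcs_curve(FCSSimConfig(noise_sd=0.0), curve_id="c1")
        lines = ["curve_id,lag_s,g"] + [
            f"c1,{t},{g}" for t, g in zip(curve.lags_s, curve.g)
        ]
        path = tmp_path / "fcs.csv"
        path.write_text("\n".join(lines))
        loaded = load_fcs_curves(path)
        assert len(loaded) == 1
        fit = fit_fcs(loaded[0])
        assert fit.n_particles == pytest.approx(12.0, rel=1e-6)
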