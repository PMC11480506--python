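"""FRAP processing/fitting, Soumpasis diffusion, mass and binding fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drcluster.experiments import synth_binding, synth_frap, synth_masses
from drcluster.fits import (
    BSA_LADDER_KDA,
    ProcessingError,
    calibrate_masses,
    diffusion_coefficient,
    fit_binding,
    fit_frap,
    fit_mass_distribution,
    fit_one_phase,
    process_frap,
)


class TestProcessFrap:
    def test_noiseless_round_trip_recovers_underlying_recovery(self):
        tr = synth_frap(0.7, 50.0, frame_interval_s=2.0, n_frames=100, seed=0)
        t, y = process_frap(tr)
        k = np.log(2) / 50.0
        expected = 0.7 * (1 - np.exp(-k * t))
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_acquisition_bleaching_is_corrected_away(self):
        clean = synth_frap(0.6, 40.0, n_frames=80, seed=0)
        bleached = synth_frap(
            0.6, 40.0, n_frames=80, bleach_decay_per_frame=0.10, seed=0
        )
        _, y0 = process_frap(clean)
        _, y1 = process_frap(bleached)
        np.testing.assert_allclose(y1, y0, atol=1e-10)

    def test_reference_crossing_zero_raises(self):
        tr = synth_frap(0.5, 30.0, n_frames=50, seed=0)
        tr.reference[10] = tr.background[10] - 5.0
        with pytest.raises(ProcessingError):
            process_frap(tr)

    def test_immobile_sample_stays_at_zero(self):
        tr = synth_frap(0.0, 30.0, n_frames=60, seed=0)
        _, y = process_frap(tr)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)


class TestOnePhaseFit:
    @pytest.mark.parametrize(
        "mobile,t_half",
        [
            (0.82, 169.0),     # LD condensates
            (0.276, 281.5),    # cLD condensates
        ],
    )
    def test_noiseless_recovery_of_reported_condensate_parameters(self, mobile, t_half):
        tr = synth_frap(mobile, t_half, frame_interval_s=5.0, n_frames=122, seed=0)
        fit = fit_frap(tr)
        assert fit.mobile_fraction == pytest.approx(mobile, rel=1e-6)
        assert fit.t_half_s == pytest.approx(t_half, rel=1e-6)

    def test_t_half_times_k_is_ln2(self):
        tr = synth_frap(0.5, 77.0, n_frames=100, seed=0)
        fit = fit_frap(tr)
        assert fit.t_half_s * fit.k == pytest.approx(np.log(2), rel=1e-12)

    def test_flat_curve_flagged(self):
        t = np.arange(20.0)
        fit = fit_one_phase(t, np.zeros(20))
        assert not fit.converged
        assert fit.mobile_fraction == 0.0

    def test_offset_variant_fits_shifted_curve(self):
        t = np.linspace(0, 300, 100)
        y = 0.2 + (0.8 - 0.2) * (1 - np.exp(-0.02 * t))
        fit = fit_one_phase(t, y, no_offset=False)
        assert fit.y0 == pytest.approx(0.2, abs=1e-6)
        assert fit.plateau == pytest.approx(0.8, abs=1e-6)

    def test_noise_robustness_bias(self):
        # 100 replicates at 2% noise: plateau bias < 0.01, t-half bias < 2%
        plateaus, halves = [], []
        for seed in range(100):
            tr = synth_frap(
                0.82, 169.0, frame_interval_s=5.0, n_frames=122,
                noise_sd=0.02, seed=seed,
            )
            fit = fit_frap(tr)
            plateaus.append(fit.mobile_fraction)
            halves.append(fit.t_half_s)
        assert abs(np.mean(plateaus) - 0.82) < 0.01
        assert abs(np.mean(halves) - 169.0) / 169.0 < 0.02


class TestDiffusionCoefficient:
    def test_soumpasis_value_for_2um_spot(self):
        # t_half chosen so D = 0.224 w^2 / t_half = 0.18 um^2/s
        t_half = 0.224 * 4 / 0.18
        assert diffusion_coefficient(t_half, 2.0) == pytest.approx(0.18, rel=1e-12)

    def test_long_half_time_limit(self):
        assert diffusion_coefficient(1e9, 2.0) < 1e-8

    def test_doubling_radius_quadruples_d(self):
        assert diffusion_coefficient(10.0, 4.0) == pytest.approx(
            4 * diffusion_coefficient(10.0, 2.0)
        )

    @given(
        c=st.floats(0.1, 10.0),
        t=st.floats(1.0, 1e4),
        w=st.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, c, t, w):
        d1 = diffusion_coefficient(t, w)
        d2 = diffusion_coefficient(c * t, np.sqrt(c) * w)
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            diffusion_coefficient(0.0, 2.0)
        with pytest.raises(ValueError):
            diffusion_coefficient(10.0, -1.0)


class TestCalibration:
    def test_exact_linear_standards(self):
        contrasts = np.array([1.0, 2.0, 3.0])
        cal = calibrate_masses(contrasts, np.asarray(BSA_LADDER_KDA))
        assert cal.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(cal.apply(contrasts), BSA_LADDER_KDA)

    def test_default_ladder_is_bsa_multiples(self):
        assert BSA_LADDER_KDA == (66.4, 132.8, 199.2)
        assert BSA_LADDER_KDA[1] == pytest.approx(2 * BSA_LADDER_KDA[0])

    def test_swapped_arguments_warn_via_monotonicity(self):
        # masses decreasing with contrast is fishy and flagged
        cal = calibrate_masses(np.array([1.0, 2.0, 3.0]), np.array([199.2, 132.8, 66.4]))
        assert cal.monotonic_warning

    def test_too_few_distinct_standards(self):
        with pytest.raises(ValueError):
            calibrate_masses(np.array([1.0, 1.0]), np.array([66.4, 132.8]))


class TestMassDistribution:
    def test_single_component_recovery_wild_type_dimer(self):
        sample = synth_masses([(135.0, 67.0, 1.0)], n_events=5000, seed=42)
        fit = fit_mass_distribution(sample, n_components=1)
        assert abs(fit.components[0].mean_kda - 135.0) < 3.0
        assert abs(fit.components[0].sd_kda - 67.0) < 5.0

    def test_sample_mean_within_three_se(self):
        sample = synth_masses([(135.0, 67.0, 1.0)], n_events=5000, seed=1)
        se = 67.0 / np.sqrt(5000)
        assert abs(sample.masses.mean() - 135.0) < 3 * se

    def test_two_component_recovery(self):
        sample = synth_masses(
            [(95.0, 15.0, 0.5), (190.0, 20.0, 0.5)], n_events=6000, seed=3
        )
        fit = fit_mass_distribution(sample, n_components=2, monomer_kda=95.0)
        means = fit.means()
        assert abs(means[0] - 95.0) < 3.0
        assert abs(means[1] - 190.0) < 4.0
        for comp in fit.components:
            assert abs(comp.weight - 0.5) < 0.05
        assert [c.oligomer for c in fit.components] == [1, 2]

    def test_point_mass_triggers_degeneracy_handling(self):
        sample = synth_masses([(100.0, 0.001, 1.0)], n_events=200, seed=0)
        fit = fit_mass_distribution(sample, n_components=2)
        assert fit.degenerate
        assert fit.n_components == 1

    def test_deterministic_given_seed(self):
        sample = synth_masses([(135.0, 67.0, 1.0)], n_events=2000, seed=5)
        f1 = fit_mass_distribution(sample, n_components=1)
        f2 = fit_mass_distribution(sample, n_components=1)
        assert f1.components[0].mean_kda == f2.components[0].mean_kda

    def test_too_few_events_rejected(self):
        sample = synth_masses([(100.0, 10.0, 1.0)], n_events=20, seed=0)
        with pytest.raises(ValueError):
            fit_mass_distribution(sample, n_components=1)


class TestBinding:
    @pytest.mark.parametrize(
        "kd,grid",
        [
            (2.0, np.geomspace(0.05, 100, 12)),   # tandem two-site peptide
            (20.0, np.geomspace(0.5, 500, 12)),   # single-site peptide
        ],
    )
    def test_noiseless_kd_recovery(self, kd, grid):
        curve = synth_binding(kd, conc_grid_um=grid, seed=0)
        fit = fit_binding(curve)
        assert fit.kd_um == pytest.approx(kd, rel=1e-6)
        assert not fit.flagged

    def test_half_saturation_at_kd(self):
        curve = synth_binding(5.0, r0=0.1, r_max=0.3,
                              conc_grid_um=np.array([0.5, 1, 5, 25, 100]), seed=0)
        at_kd = curve.anisotropy[2]
        assert at_kd == pytest.approx((0.1 + 0.3) / 2)

    def test_flat_curve_flagged(self):
        curve = synth_binding(1.0, r0=0.2, r_max=0.2,
                              conc_grid_um=np.geomspace(0.01, 100, 8), seed=0)
        fit = fit_binding(curve)
        assert fit.flagged
        assert not fit.converged

    def test_grid_not_bracketing_kd_warned_at_generation(self):
        curve = synth_binding(500.0, conc_grid_um=np.geomspace(0.01, 1.0, 6), seed=0)
        assert curve.ill_conditioned

    def test_round_trip_with_offset_parameters(self):
        curve = synth_binding(7.5, r0=0.12, r_max=0.31,
                              conc_grid_um=np.geomspace(0.1, 300, 14), seed=0)
        fit = fit_binding(curve)
        assert fit.r0 == pytest.approx(0.12, abs=1e-8)
        assert fit.r_max == pytest.approx(0.31, abs=1e-8)
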