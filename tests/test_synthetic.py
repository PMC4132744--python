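"""Synthetic force-curve and thermal-trace generator."""

import numpy as np
import pytest

from capsidmech import (
    CantileverModel,
    EnsembleSpec,
    IndentationProtocol,
    ParticleModel,
    series_stiffness,
    simulate_ensemble,
    simulate_glass_curve,
    simulate_particle_curve,
    simulate_thermal_trace,
)
from capsidmech.constants import BOLTZMANN_NN_NM_PER_K
from capsidmech.errors import ProtocolError


def post_contact_slope(curve, z0):
    mask = curve.z > z0 + 1.0
    return np.polyfit(curve.z[mask], curve.force[mask], 1)[0]


class TestGlassCurve:
    def test_noise_free_slope_equals_cantilever_stiffness(self, protocol):
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        curve = simulate_glass_curve(cant, protocol)
        assert post_contact_slope(curve, 30.0) == pytest.approx(0.06, rel=1e-12)

    @pytest.mark.parametrize("kc", [0.03, 0.06])
    def test_measured_cantilever_stiffnesses(self, kc, protocol):
        """The two instruments of the study: 0.03 N/m (phage lambda) and
        0.06 N/m (HSV-1); noise-free glass slope reproduces each."""
        cant = CantileverModel(stiffness_kc=kc, force_noise_sd=0.0)
        curve = simulate_glass_curve(cant, protocol)
        assert post_contact_slope(curve, 30.0) == pytest.approx(kc, rel=1e-12)

    def test_noisy_slope_within_2pct_by_least_squares(self):
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.05)
        curve = simulate_glass_curve(cant, IndentationProtocol(seed=42))
        n_contact = int(np.sum(curve.z > 30.0))
        assert n_contact >= 200
        slope = post_contact_slope(curve, 30.0)
        assert slope == pytest.approx(0.06, rel=0.02)

    def test_pre_contact_baseline_flat(self, protocol):
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        curve = simulate_glass_curve(cant, protocol)
        assert np.allclose(curve.force[curve.z <= 30.0], 0.0)

    def test_empty_contact_region_is_error(self, protocol):
        cant = CantileverModel(stiffness_kc=0.06)
        with pytest.raises(ProtocolError):
            simulate_glass_curve(cant, protocol, contact_offset_z=250.0)


class TestParticleCurve:
    def test_series_spring_slopes(self, protocol):
        """k_c = k_s = 0.06: force-vs-z slope is 0.03 (series springs) and
        force vs indentation recovers 0.06."""
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        particle = ParticleModel(spring_constant_ks=0.06, breaking_force=50.0)
        curve = simulate_particle_curve(cant, particle, protocol)
        slope = post_contact_slope(curve, 30.0)
        assert slope == pytest.approx(0.03, rel=1e-9)
        # force vs indentation: delta = (z - z0) - F/kc
        mask = curve.z > 31.0
        delta = (curve.z[mask] - 30.0) - curve.force[mask] / 0.06
        k = np.polyfit(delta, curve.force[mask], 1)[0]
        assert k == pytest.approx(0.06, rel=1e-9)

    def test_series_spring_identity_noise_free(self, protocol):
        """Measured force-vs-z slope equals kc*ks/(kc+ks) to 1e-6."""
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        for ks in (0.05, 0.11, 0.35, 2.0):
            particle = ParticleModel(spring_constant_ks=ks, breaking_force=1e6)
            curve = simulate_particle_curve(cant, particle, protocol)
            expected = series_stiffness(0.06, ks)
            assert post_contact_slope(curve, 30.0) == pytest.approx(
                expected, rel=1e-6
            )

    def test_very_stiff_particle_indistinguishable_from_glass(self, protocol):
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        glass = simulate_glass_curve(cant, protocol)
        particle = ParticleModel(spring_constant_ks=0.06e6, breaking_force=1e9)
        curve = simulate_particle_curve(cant, particle, protocol)
        assert np.max(np.abs(curve.force - glass.force)) < 1e-4

    def test_breaking_force_and_indentation(self, protocol):
        """Programmed F_break = 5.7 nN at k_s = 0.35 N/m: peak pre-drop
        force is exactly the breaking force and the tip-sample indentation
        there is F/k = 16.3 nm (the wild-type C-capsid magnitudes)."""
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        particle = ParticleModel(spring_constant_ks=0.35, breaking_force=5.7)
        curve = simulate_particle_curve(cant, particle, protocol)
        i_peak = int(np.argmax(curve.force))
        assert curve.force[i_peak] == pytest.approx(5.7, abs=1e-12)
        delta_at_peak = 5.7 / 0.35
        assert delta_at_peak == pytest.approx(16.3, abs=0.05)
        # abrupt drop follows the peak
        assert curve.force[i_peak + 1] < 0.5 * 5.7

    def test_unreachable_break_flagged(self, protocol):
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        particle = ParticleModel(spring_constant_ks=0.35, breaking_force=100.0)
        curve = simulate_particle_curve(cant, particle, protocol)
        assert curve.metadata["no_break_simulated"] is True
        assert np.all(np.diff(curve.force) >= -1e-12)

    def test_break_consistency_with_noise(self):
        """Peak force before the drop equals the programmed breaking force
        within one force-noise sd."""
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.05)
        particle = ParticleModel(spring_constant_ks=0.35, breaking_force=5.7)
        for seed in range(5):
            curve = simulate_particle_curve(
                cant, particle, IndentationProtocol(seed=seed)
            )
            zb = curve.metadata["true_z_break"]
            peak = np.max(curve.force[curve.z <= zb])
            assert peak == pytest.approx(5.7, abs=3 * 0.05)


class TestEnsemble:
    def test_zero_sd_all_curves_share_slope(self, protocol):
        cant = CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)
        spec = EnsembleSpec(
            n_particles=20, ks_mean=0.35, ks_sd=0.0,
            fbreak_mean=5.7, fbreak_sd=0.0, seed=0,
        )
        curves = simulate_ensemble(cant, spec, protocol)
        assert len(curves) == 20
        slopes = {round(post_contact_slope(c, 30.0), 9) for c in curves}
        assert len(slopes) == 1

    def test_large_sample_mean_matches_spec(self, protocol):
        spec = EnsembleSpec(
            n_particles=1000, ks_mean=0.35, ks_sd=0.045,
            fbreak_mean=5.7, fbreak_sd=0.9, seed=123,
        )
        cant = CantileverModel(stiffness_kc=0.06)
        curves = simulate_ensemble(cant, spec, protocol)
        ks = np.array([c.metadata["true_ks"] for c in curves])
        assert ks.mean() == pytest.approx(0.35, abs=0.005)

    def test_truncation_rejects_non_positive_draws(self, protocol):
        spec = EnsembleSpec(
            n_particles=200, ks_mean=0.05, ks_sd=0.1,
            fbreak_mean=0.3, fbreak_sd=0.5, seed=7,
        )
        cant = CantileverModel(stiffness_kc=0.03)
        curves = simulate_ensemble(cant, spec, protocol)
        assert all(c.metadata["true_ks"] > 0 for c in curves)
        assert all(c.metadata["true_fbreak"] > 0 for c in curves)

    def test_seed_determinism_bit_identical(self, protocol):
        cant = CantileverModel(stiffness_kc=0.06)
        spec = EnsembleSpec(
            n_particles=5, ks_mean=0.35, ks_sd=0.045,
            fbreak_mean=5.7, fbreak_sd=0.9, seed=99,
        )
        a = simulate_ensemble(cant, spec, protocol)
        b = simulate_ensemble(cant, spec, protocol)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.force, cb.force)
            np.testing.assert_array_equal(ca.z, cb.z)


class TestThermalTrace:
    def test_equipartition_variance(self):
        """Variance approaches k_B*T/k_c: 4.11e-3 nN*nm / 0.06 N/m
        ~ 0.0685 nm^2 (rms ~ 0.26 nm)."""
        cant = CantileverModel(stiffness_kc=0.06, temperature=298.0)
        target = BOLTZMANN_NN_NM_PER_K * 298.0 / 0.06
        assert target == pytest.approx(0.0685, abs=0.001)
        trace = simulate_thermal_trace(cant, n_samples=100_000, seed=2)
        assert np.var(trace.deflection) == pytest.approx(target, rel=0.05)
        assert np.std(trace.deflection) == pytest.approx(0.26, abs=0.02)

    def test_cold_limit_vanishing_variance(self):
        cant = CantileverModel(stiffness_kc=0.06, temperature=1e-9)
        trace = simulate_thermal_trace(cant, n_samples=2000, seed=0)
        assert np.var(trace.deflection) < 1e-12

    def test_softer_lever_doubles_variance(self):
        soft = simulate_thermal_trace(
            CantileverModel(stiffness_kc=0.03), n_samples=200_000, seed=3
        )
        stiff = simulate_thermal_trace(
            CantileverModel(stiffness_kc=0.06), n_samples=200_000, seed=3
        )
        ratio = np.var(soft.deflection) / np.var(stiff.deflection)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_input_validation(self):
        cant = CantileverModel(stiffness_kc=0.06)
        with pytest.raises(ValueError):
            simulate_thermal_trace(cant, n_samples=10)
        with pytest.raises(ValueError):
            CantileverModel(stiffness_kc=-0.06)
        with pytest.raises(ValueError):
            CantileverModel(stiffness_kc=0.06, temperature=0.0)


class TestModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spring_constant_ks": 0.0, "breaking_force": 1.0},
            {"spring_constant_ks": 0.3, "breaking_force": -1.0},
            {"spring_constant_ks": 0.3, "breaking_force": 1.0,
             "post_break_residual_stiffness_fraction": 1.0},
        ],
    )
    def test_particle_model_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ParticleModel(**kwargs)

    def test_protocol_rejects_degenerate_ramp(self):
        with pytest.raises(ValueError):
            IndentationProtocol(z_start=10.0, z_end=5.0)
        with pytest.raises(ValueError):
            IndentationProtocol(n_samples=10)
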