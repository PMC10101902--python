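"""Synthetic voltammogram generator: physics, determinism, reproducibility."""

import numpy as np
import pytest

from itieskit import (
    IonPartitionModel,
    SimConfig,
    TransferSpecies,
    boundary_potential,
    fit_partition_model,
    nitrazepam,
    randles_sevcik_peak_current,
    simulate_calibration_table,
    simulate_macro_itv,
    simulate_micro_itv,
    simulate_ph_series,
)
from itieskit.errors import ConfigError, InvalidInputError
from itieskit.voltsim import macro_mass_balance


class TestMacroSimulator:
    def test_peak_current_matches_randles_sevcik(
        self, clean_macro_itv, clean_macro_cfg, conditions
    ):
        fwd = np.arange(len(clean_macro_itv)) <= np.argmax(clean_macro_itv.potential)
        peak = clean_macro_itv.current[fwd].max()
        expected = randles_sevcik_peak_current(
            1, clean_macro_cfg.geometry.area, 20e-9, 14.1e-6, 0.02, conditions
        )
        assert peak == pytest.approx(expected, rel=0.02)

    def test_mass_conserved_over_full_cycle(self, nit_species, conditions):
        cfg = SimConfig(
            potential_start=-0.1, potential_vertex=0.5, n_space=300,
            noise_sd=0.0, wall_amplitude=0.0, double_layer_capacitance=0.0,
        )
        mass = macro_mass_balance(nit_species, cfg, conditions)
        assert (mass.max() - mass.min()) / mass[0] < 1e-3

    def test_grid_independence_of_peak_current(self, nit_species, conditions):
        peaks = []
        for n in (300, 600):
            cfg = SimConfig(
                potential_start=-0.1, potential_vertex=0.5, n_space=n,
                noise_sd=0.0, wall_amplitude=0.0, double_layer_capacitance=0.0,
            )
            v = simulate_macro_itv([nit_species], cfg, conditions)
            peaks.append(v.current.max())
        assert abs(peaks[1] / peaks[0] - 1.0) < 0.005

    def test_same_seed_reproduces_bitwise(self, nit_species, conditions):
        cfg = SimConfig(n_space=100, seed=11)
        a = simulate_macro_itv([nit_species], cfg, conditions)
        b = simulate_macro_itv([nit_species], cfg, conditions)
        np.testing.assert_array_equal(a.current, b.current)
        np.testing.assert_array_equal(a.potential, b.potential)

    def test_different_seed_changes_noise(self, nit_species, conditions):
        a = simulate_macro_itv([nit_species], SimConfig(n_space=100, seed=1), conditions)
        b = simulate_macro_itv([nit_species], SimConfig(n_space=100, seed=2), conditions)
        assert not np.array_equal(a.current, b.current)

    def test_zero_concentration_gives_pure_background(self, conditions):
        cfg = SimConfig(n_space=100, noise_sd=0.0, seed=0)
        ghost = TransferSpecies("ghost", 1, 0.25, 1e-5, 1e-5, 0.0)
        with_species = simulate_macro_itv([ghost], cfg, conditions)
        cfg_direction = np.sign(np.gradient(with_species.potential))
        from itieskit.voltsim import _background_current

        background = _background_current(
            with_species.potential, np.where(cfg_direction == 0, 1, cfg_direction), cfg
        )
        np.testing.assert_allclose(with_species.current, background, atol=1e-18)

    def test_unstable_grid_rejected_before_compute(self):
        with pytest.raises(ConfigError):
            SimConfig(stability_factor=0.7)

    def test_degenerate_scan_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(potential_start=0.2, potential_vertex=0.2)

    def test_internal_reference_ion_appears_as_second_peak(self, conditions):
        ref = TransferSpecies("TPrA+", 1, -0.160, 1e-5, 1e-5, 30e-6)
        drug = TransferSpecies("NIT+", 1, 0.242, 1.4e-5, 1.4e-5, 20e-6)
        cfg = SimConfig(
            potential_start=-0.30, potential_vertex=0.5, n_space=300,
            noise_sd=0.0, wall_amplitude=0.0, double_layer_capacitance=0.0,
        )
        v = simulate_macro_itv([ref, drug], cfg, conditions)
        fwd = np.arange(len(v)) <= np.argmax(v.potential)
        near_ref = fwd & (np.abs(v.potential + 0.160) < 0.05)
        near_drug = fwd & (np.abs(v.potential - 0.242) < 0.05)
        assert v.current[near_ref].max() > 1e-6
        assert v.current[near_drug].max() > 1e-6


class TestMicroSimulator:
    def test_forward_plateau_matches_saito(self, clean_micro_itv, conditions):
        from itieskit import saito_current

        fwd = np.arange(len(clean_micro_itv)) <= np.argmax(clean_micro_itv.potential)
        mask = fwd & (clean_micro_itv.potential >= 0.44) & (
            clean_micro_itv.potential <= 0.49
        )
        plateau = clean_micro_itv.current[mask].mean()
        expected = saito_current(12e-4, 1, 13.8e-6, 50e-9, conditions)
        assert plateau == pytest.approx(expected, rel=0.02)

    def test_backward_branch_forms_negative_peak(self, clean_micro_itv):
        fwd_mask = np.arange(len(clean_micro_itv)) <= np.argmax(
            clean_micro_itv.potential
        )
        bwd = clean_micro_itv.current[~fwd_mask]
        # clear negative peak: minimum well below both endpoints
        assert bwd.min() < -0.2e-9
        assert bwd.min() < bwd[0] - 1e-10 and bwd.min() < bwd[-1] - 1e-10

    def test_macro_geometry_rejected(self, tma_species, conditions):
        with pytest.raises(ConfigError):
            simulate_micro_itv([tma_species], SimConfig(), conditions)

    def test_zero_concentration_background_only(self, conditions):
        cfg = SimConfig.micro_defaults(noise_sd=0.0, wall_amplitude=0.0,
                                       double_layer_capacitance=0.0)
        ghost = TransferSpecies("ghost", 1, 0.25, 1e-5, 1e-5, 0.0)
        v = simulate_micro_itv([ghost], cfg, conditions)
        np.testing.assert_allclose(v.current, 0.0, atol=1e-18)


class TestPhSeries:
    def test_kd_recovery_from_generated_series(self, conditions):
        truth = IonPartitionModel(formal_potential=0.242, pka=3.2, kd=10.0,
                                  conditions=conditions)
        series = simulate_ph_series(
            nitrazepam(), truth, np.linspace(2.0, 5.0, 8),
            potential_noise_sd=0.002, seed=21,
        )
        pts = [(p.ph, p.observed_potential) for p in series]
        fit = fit_partition_model(pts, pka=3.2, conditions=conditions)
        assert fit.kd == pytest.approx(10.0, rel=0.5)  # single noisy series

    def test_zero_kd_low_ph_is_flat_at_formal_potential(self, conditions):
        truth = IonPartitionModel(formal_potential=0.242, pka=3.2, kd=0.0,
                                  conditions=conditions)
        series = simulate_ph_series(nitrazepam(), truth, [1.0, 1.2, 1.5],
                                    potential_noise_sd=0.0)
        for point in series:
            assert point.observed_potential == pytest.approx(0.242, abs=1e-3)

    def test_signal_lost_when_boundary_hits_window_wall(self, conditions):
        """The facilitated branch runs into the positive wall at high pH."""
        truth = IonPartitionModel(formal_potential=0.242, pka=3.2, kd=10.0,
                                  conditions=conditions)
        series = simulate_ph_series(
            nitrazepam(), truth, [2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
            potential_noise_sd=0.0,
        )
        detect = {p.ph: p.detectable for p in series}
        assert detect[2.0] and detect[5.0]
        assert not detect[6.0] and not detect[7.0]

    def test_voltammograms_only_on_request(self, conditions):
        truth = IonPartitionModel(formal_potential=0.242, pka=3.2, kd=10.0,
                                  conditions=conditions)
        series = simulate_ph_series(nitrazepam(), truth, [2.0, 3.0])
        assert all(p.voltammogram is None for p in series)

    def test_out_of_range_ph_rejected(self, conditions):
        truth = IonPartitionModel(formal_potential=0.242, pka=3.2, kd=10.0)
        with pytest.raises(InvalidInputError):
            simulate_ph_series(nitrazepam(), truth, [0.5, 2.0])


class TestCalibrationTable:
    def test_zero_noise_is_exact_line(self):
        table = simulate_calibration_table(0.375, [10, 15, 20, 25], noise_sd=0.0)
        np.testing.assert_allclose(table[:, 1], 0.375 * table[:, 0], rtol=1e-15)

    def test_reproducible_by_seed(self):
        a = simulate_calibration_table(0.375, [10, 15, 20], noise_sd=0.1, seed=5)
        b = simulate_calibration_table(0.375, [10, 15, 20], noise_sd=0.1, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_calibration_table(0.375, [10, 10, 20])

    def test_single_concentration_fails_downstream_fit(self):
        from itieskit import fit_calibration
        from itieskit.errors import SingularDesignError

        table = simulate_calibration_table(0.375, [10.0], noise_sd=0.0)
        tripled = np.vstack([table, table, table])
        with pytest.raises(SingularDesignError):
            fit_calibration(tripled)
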