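"""Sweep segmentation, baselines, peak/wave extraction and presence calls."""

import numpy as np
import pytest

from itieskit import (
    SimConfig,
    TransferSpecies,
    Voltammogram,
    detect_analyte,
    extract_peaks,
    extract_wave,
    potential_window_width,
    randles_sevcik_peak_current,
    reference_correct,
    saito_current,
    segment_sweeps,
    simulate_macro_itv,
)
from itieskit.errors import (
    InvalidInputError,
    NoPeakError,
    NotAPlateauError,
    SegmentationError,
)
from itieskit.voltprocess import smooth_current


def triangle(n=200, start=0.0, vertex=0.5):
    up = np.linspace(start, vertex, n // 2 + 1)
    down = np.linspace(vertex, start, n // 2 + 1)
    return np.concatenate([up, down[1:]])


class TestSegmentSweeps:
    def test_triangle_splits_at_vertex(self):
        pot = triangle(200)
        v = Voltammogram(pot, np.zeros_like(pot), 0.02)
        fwd, bwd = segment_sweeps(v)
        assert fwd.potential[-1] == pytest.approx(0.5)
        assert fwd.direction == 1 and bwd.direction == -1
        assert len(fwd.potential) + len(bwd.potential) == len(pot)

    def test_multi_cycle_uses_first_and_warns(self):
        one = triangle(100)
        pot = np.concatenate([one, one[1:]])
        v = Voltammogram(pot, np.zeros_like(pot), 0.02)
        with pytest.warns(UserWarning, match="first cycle"):
            fwd, bwd = segment_sweeps(v)
        assert len(fwd.potential) + len(bwd.potential) == len(one)

    def test_constant_potential_rejected(self):
        pot = np.full(32, 0.1)
        with pytest.raises(SegmentationError):
            segment_sweeps(Voltammogram(pot, np.zeros_like(pot), 0.02))

    def test_monotone_potential_rejected(self):
        pot = np.linspace(0, 0.5, 64)
        with pytest.raises(SegmentationError):
            segment_sweeps(Voltammogram(pot, np.zeros_like(pot), 0.02))


class TestExtractPeaks:
    def test_midpoint_matches_formal_potential(self, background_macro_itv):
        peaks = extract_peaks(background_macro_itv, (0.12, 0.37))
        assert peaks.midpoint_potential == pytest.approx(0.242, abs=2e-3)

    def test_peak_separation_near_reversible_value(self, clean_macro_itv, conditions):
        peaks = extract_peaks(clean_macro_itv, (0.12, 0.37), baseline="none")
        assert peaks.peak_separation == pytest.approx(
            2.218 * conditions.thermal_voltage, abs=2e-3
        )

    def test_forward_peak_current_close_to_randles_sevcik(
        self, background_macro_itv, nit_species, conditions
    ):
        peaks = extract_peaks(background_macro_itv, (0.12, 0.37))
        expected = randles_sevcik_peak_current(
            1, np.pi * 0.65 ** 2, 20e-9, 14.1e-6, 0.02, conditions
        )
        assert peaks.forward_peak_current == pytest.approx(expected, rel=0.03)

    def test_blank_raises_no_peak(self, conditions):
        cfg = SimConfig(
            potential_start=-0.1, potential_vertex=0.5, n_space=200,
            noise_sd=0.02e-6, seed=9,
        )
        blank = simulate_macro_itv(
            [TransferSpecies("bg", 1, 0.0, 1e-5, 1e-5, 0.0)], cfg, conditions
        )
        with pytest.raises(NoPeakError):
            extract_peaks(blank, (0.12, 0.37))

    def test_window_outside_scan_rejected(self, clean_macro_itv):
        with pytest.raises(InvalidInputError):
            extract_peaks(clean_macro_itv, (0.8, 0.9))

    def test_baseline_method_recorded(self, background_macro_itv):
        peaks = extract_peaks(background_macro_itv, (0.12, 0.37))
        assert peaks.baseline_method == "linear_pre_peak"


class TestExtractWave:
    def test_steady_state_current_matches_saito(self, clean_micro_itv, conditions):
        wave = extract_wave(clean_micro_itv, (0.42, 0.50))
        expected = saito_current(12e-4, 1, 13.8e-6, 50e-9, conditions)
        assert wave.steady_state_current == pytest.approx(expected, rel=0.02)

    def test_half_wave_potential_in_rising_region(self, clean_micro_itv):
        wave = extract_wave(clean_micro_itv, (0.42, 0.50))
        assert 0.2 < wave.half_wave_potential < 0.35

    def test_zero_current_rejected(self):
        pot = triangle(200)
        v = Voltammogram(pot, np.zeros_like(pot), 0.02)
        with pytest.raises(NotAPlateauError):
            extract_wave(v, (0.4, 0.48))

    def test_narrow_window_rejected(self, clean_micro_itv):
        with pytest.raises(InvalidInputError):
            extract_wave(clean_micro_itv, (0.449999, 0.45))

    def test_steep_window_rejected(self):
        pot = triangle(400, 0.0, 0.5)
        cur = np.maximum(pot, 0.0) * 1e-6  # steadily rising ramp, no plateau
        v = Voltammogram(pot, cur, 0.02)
        with pytest.raises(NotAPlateauError):
            extract_wave(v, (0.3, 0.45))


class TestReferenceCorrect:
    def test_shift_arithmetic(self, triangle_voltammogram):
        v = triangle_voltammogram()
        out = reference_correct(v, -0.120, -0.160)
        np.testing.assert_allclose(out.potential, v.potential - 0.040)
        np.testing.assert_array_equal(out.current, v.current)

    def test_zero_shift_is_identity(self, triangle_voltammogram):
        v = triangle_voltammogram()
        out = reference_correct(v, -0.160, -0.160)
        np.testing.assert_array_equal(out.potential, v.potential)

    def test_opposite_shifts_cancel(self, triangle_voltammogram):
        v = triangle_voltammogram()
        out = reference_correct(reference_correct(v, 0.0, 0.04), 0.0, -0.04)
        np.testing.assert_allclose(out.potential, v.potential, atol=1e-15)

    def test_peak_measurements_shift_exactly(self, triangle_voltammogram):
        v = triangle_voltammogram(peak_amplitude=1e-6)
        before = extract_peaks(v, (0.1, 0.4), baseline="none")
        after = extract_peaks(
            reference_correct(v, -0.120, -0.160), (0.06, 0.36), baseline="none"
        )
        assert after.midpoint_potential == pytest.approx(
            before.midpoint_potential - 0.040, abs=1e-12
        )
        assert after.forward_peak_current == pytest.approx(
            before.forward_peak_current, rel=1e-12
        )


@pytest.fixture(scope="module")
def model_blank(conditions):
    cfg = SimConfig(
        potential_start=-0.35, potential_vertex=0.65, n_space=200,
        noise_sd=0.01e-6, seed=3,
    )
    return simulate_macro_itv(
        [TransferSpecies("bg", 1, 0.0, 1e-5, 1e-5, 0.0)], cfg, conditions
    ), cfg


class TestPotentialWindow:

    def test_model_system_window_near_800_mV(self, model_blank):
        blank, cfg = model_blank
        thr = cfg.resolved_wall_amplitude() + 1e-7
        assert potential_window_width(blank, thr) == pytest.approx(0.80, abs=0.05)

    def test_biofluid_like_window_near_600_mV(self, conditions):
        cfg = SimConfig(
            potential_start=-0.35, potential_vertex=0.65, n_space=200,
            wall_onset_negative=-0.20, wall_onset_positive=0.40,
            noise_sd=0.01e-6, seed=3,
        )
        blank = simulate_macro_itv(
            [TransferSpecies("bg", 1, 0.0, 1e-5, 1e-5, 0.0)], cfg, conditions
        )
        thr = cfg.resolved_wall_amplitude() + 1e-7
        assert potential_window_width(blank, thr) == pytest.approx(0.60, abs=0.05)

    def test_huge_threshold_returns_full_scan_range(self, model_blank):
        blank, _ = model_blank
        width = potential_window_width(blank, 1.0)
        assert width == pytest.approx(1.0, abs=0.02)  # -0.35 .. 0.65 V

    def test_threshold_below_noise_rejected(self, model_blank):
        blank, _ = model_blank
        with pytest.raises(InvalidInputError):
            potential_window_width(blank, 1e-12)


class TestDetectAnalyte:
    def test_blank_against_itself_is_negative(self, triangle_voltammogram):
        blank = triangle_voltammogram(peak_amplitude=0.0, noise_sd=1e-8, seed=1)
        assert detect_analyte(blank, blank, 0.25, 0.05) == 0

    def test_strong_spike_at_expected_potential_is_positive(self, triangle_voltammogram):
        blank = triangle_voltammogram(peak_amplitude=0.0, noise_sd=1e-8, seed=1)
        sample = triangle_voltammogram(peak_amplitude=1e-7, noise_sd=1e-8, seed=2)
        assert detect_analyte(sample, blank, 0.25, 0.05) == 1

    def test_displaced_spike_is_negative(self, triangle_voltammogram):
        blank = triangle_voltammogram(peak_amplitude=0.0, noise_sd=1e-8, seed=1)
        # same noise realization as the blank: isolates the displacement effect
        sample = triangle_voltammogram(
            peak_amplitude=1e-7, peak_potential=0.45, noise_sd=1e-8, seed=1
        )
        assert detect_analyte(sample, blank, 0.05, 0.04) == 0

    def test_monotone_in_spike_amplitude(self, triangle_voltammogram):
        blank = triangle_voltammogram(peak_amplitude=0.0, noise_sd=1e-8, seed=1)
        calls = [
            detect_analyte(
                triangle_voltammogram(peak_amplitude=a, noise_sd=1e-8, seed=2),
                blank,
                0.25,
                0.05,
            )
            for a in np.logspace(-9, -6, 12)
        ]
        assert calls == sorted(calls)  # never flips 1 -> 0 as amplitude grows

    def test_disjoint_potential_ranges_rejected(self, triangle_voltammogram):
        from itieskit.errors import AlignmentError

        blank = triangle_voltammogram(start=-0.2, vertex=0.6)
        sample = triangle_voltammogram(start=1.0, vertex=1.8)
        with pytest.raises(AlignmentError):
            detect_analyte(sample, blank, 1.2, 0.05)


class TestSmoothing:
    def test_five_point_smoothing_reduces_noise(self):
        rng = np.random.default_rng(0)
        noisy = rng.normal(0, 1.0, 500)
        assert smooth_current(noisy, 5).std() < 0.6 * noisy.std()

    def test_preserves_length_and_constant_signal(self):
        const = np.full(64, 2.5)
        out = smooth_current(const, 5)
        assert out.shape == const.shape
        np.testing.assert_allclose(out, const)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidInputError):
            smooth_current(np.zeros(32), 4)


class TestVoltammogramValidation:
    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            Voltammogram(np.linspace(0, 1, 20), np.zeros(19), 0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            Voltammogram(np.linspace(0, 1, 8), np.zeros(8), 0.02)

    def test_non_finite_rejected(self):
        cur = np.zeros(20)
        cur[3] = np.nan
        with pytest.raises(InvalidInputError):
            Voltammogram(np.linspace(0, 1, 20), cur, 0.02)
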