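"""Spectral estimation, peak detection, phase difference, classification."""

import numpy as np
import pytest

from tremoremg import (
    AnalysisConfig,
    ContractError,
    InsufficientDataError,
    NoTremorDetectedError,
    PatternLabel,
    Recording,
    SynthParams,
    UndefinedPhaseError,
    analyze,
    bandpass,
    circular_summary,
    classify_pattern,
    detect_tremor_frequency,
    estimate_spectrum,
    generate_burst_envelope,
    generate_raw_emg,
    phase_difference,
)
from conftest import sine_recording


def _spectra(env_rec, min_res=0.05):
    return estimate_spectrum(bandpass(env_rec), env_rec, min_res)


class TestEstimateSpectrum:
    def test_requested_resolution_achieved(self):
        rec = sine_recording([(4.0, 0.0), (4.0, 0.0)])
        spec = _spectra(rec, 0.05)
        assert spec.resolution_hz <= 0.05
        assert np.allclose(np.diff(spec.freqs), spec.resolution_hz)

    def test_grid_covers_dc_to_twenty_hz(self):
        spec = _spectra(sine_recording([(4.0, 0.0), (4.0, 0.0)]))
        assert spec.freqs[0] == 0.0
        assert spec.freqs[-1] >= 20.0

    def test_pure_tone_peaks_at_its_frequency(self):
        spec = _spectra(sine_recording([(4.0, 0.0), (4.0, 0.0)]))
        i = np.argmax(spec.power[0])
        assert spec.freqs[i] == pytest.approx(4.0, abs=spec.resolution_hz)

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(8)
        x = np.abs(rng.normal(0, 1, (2, 4000)))
        env = Recording(x, 200.0, stage="envelope")
        filt = bandpass(env)
        spec = estimate_spectrum(filt, env, 0.05)
        # reconstruct the windowed, trimmed, mean-removed filtered signal
        k = int(200.0 * 1.0)
        seg = filt.in_role_order()[:, k:-k]
        seg = seg - seg.mean(axis=1, keepdims=True)
        win = np.hanning(seg.shape[1])
        energy = np.sum((seg * win) ** 2, axis=1)
        np.testing.assert_allclose(spec.power.sum(axis=1), energy, rtol=1e-6)

    def test_power_matches_magnitude_of_own_complex_spectrum(self):
        # power and complex spectrum of the same segment agree up to the
        # fixed one-sided Parseval normalization
        rec = sine_recording([(4.0, 0.0), (4.0, 0.0)])
        spec = estimate_spectrum(rec.replace(stage="filtered"), rec, 0.05)
        w = np.full(len(spec.freqs), 2.0)
        w[0] = 1.0
        if spec.meta["nfft"] % 2 == 0:
            w[-1] = 1.0
        np.testing.assert_allclose(
            spec.power,
            np.abs(spec.complex_spectrum) ** 2 * w / spec.meta["nfft"],
            rtol=1e-10, atol=1e-12,
        )

    def test_short_recording_rejected(self):
        rec = sine_recording([(4.0, 0.0), (4.0, 0.0)], duration=3.0)
        with pytest.raises(InsufficientDataError):
            _spectra(rec)

    def test_mismatched_inputs_rejected(self):
        a = sine_recording([(4.0, 0.0), (4.0, 0.0)])
        b = sine_recording([(4.0, 0.0), (4.0, 0.0)], fs=100.0)
        with pytest.raises(ContractError):
            estimate_spectrum(a.replace(stage="filtered"), b, 0.05)


class TestDetectTremorFrequency:
    def test_synthetic_five_hz_peak(self):
        rec = generate_burst_envelope(SynthParams(f_tremor=5.0, seed=17))
        spec = _spectra(rec)
        f, q = detect_tremor_frequency(spec)
        assert abs(f - 5.0) <= spec.resolution_hz + 1e-9
        assert q > 3

    def test_matches_brute_force_dft_scan(self):
        """Grid argmax equals an independent single-frequency DFT magnitude
        scan at 0.01 Hz steps, within one grid step."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            f_true = rng.uniform(3.0, 7.0)
            rec = generate_burst_envelope(
                SynthParams(f_tremor=f_true, seed=int(rng.integers(1e6)))
            )
            spec = _spectra(rec)
            f_est, _ = detect_tremor_frequency(spec)
            # oracle: same trimmed/windowed filtered segment, explicit DFT
            filt = bandpass(rec)
            k = int(200.0 * 1.0)
            seg = filt.in_role_order()[:, k:-k]
            seg = seg - seg.mean(axis=1, keepdims=True)
            win = np.hanning(seg.shape[1])
            t = np.arange(seg.shape[1]) / 200.0
            fgrid = np.arange(1.0, 10.0, 0.01)
            mags = np.zeros((2, len(fgrid)))
            for i, f in enumerate(fgrid):
                e = np.exp(-2j * np.pi * f * t)
                mags[:, i] = np.abs((seg * win) @ e)
            total = (mags**2).sum(axis=1, keepdims=True)
            f_oracle = fgrid[np.argmax((mags**2 / total).sum(axis=0))]
            assert abs(f_est - f_oracle) <= spec.resolution_hz + 0.01

    def test_one_tremor_channel_dominates_flat_channel(self):
        rng = np.random.default_rng(3)
        t = np.arange(6000) / 200.0
        a = 1.0 + 0.5 * np.cos(2 * np.pi * 4 * t)
        b = np.abs(rng.normal(1.0, 0.1, 6000))
        env = Recording(np.stack([a, b]), 200.0, stage="envelope")
        spec = _spectra(env)
        f, _ = detect_tremor_frequency(spec)
        assert f == pytest.approx(4.0, abs=spec.resolution_hz)

    def test_noise_quality_far_below_tremor_quality(self, noise_recording):
        """White noise is not flagged 'no tremor' at the default floor, but
        its peak quality sits orders of magnitude below a real tremor's."""
        spec_noise = _spectra(noise_recording)
        _, q_noise = detect_tremor_frequency(spec_noise, quality_floor=0.0)
        rec = generate_burst_envelope(SynthParams(seed=1))
        _, q_tremor = detect_tremor_frequency(_spectra(rec))
        assert q_noise < 20 < 100 < q_tremor

    def test_no_tremor_error_when_quality_below_floor(self, noise_recording):
        spec = _spectra(noise_recording)
        _, q = detect_tremor_frequency(spec, quality_floor=0.0)
        with pytest.raises(NoTremorDetectedError):
            detect_tremor_frequency(spec, quality_floor=q + 1.0)


class TestPhaseDifference:
    def test_identical_channels_zero_phase(self):
        rec = sine_recording([(5.0, 0.0), (5.0, 0.0)])
        assert phase_difference(_spectra(rec), 5.0) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("phi", [30.0, 60.0, 90.0, 120.0, 150.0])
    def test_closed_form_cosine_pairs(self, phi):
        rec = sine_recording([(5.0, 0.0), (5.0, phi)])
        assert phase_difference(_spectra(rec), 5.0) == pytest.approx(phi, abs=0.5)

    def test_antiphase_wrap_boundary(self):
        rec = sine_recording([(5.0, 0.0), (5.0, 180.0)])
        assert phase_difference(_spectra(rec), 5.0) == pytest.approx(180.0, abs=0.5)

    def test_result_always_in_0_180(self):
        # flexor *leading* by 120° must fold to 120°, not -120° or 240°
        rec = sine_recording([(5.0, 240.0), (5.0, 0.0)])
        d = phase_difference(_spectra(rec), 5.0)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(120.0, abs=0.5)

    def test_zero_magnitude_channel_is_undefined(self):
        t = np.arange(6000) / 200.0
        a = np.cos(2 * np.pi * 5 * t)
        b = np.zeros_like(a)
        rec = Recording(np.stack([a, b]), 200.0, stage="envelope")
        spec = estimate_spectrum(rec.replace(stage="filtered"), rec, 0.05)
        with pytest.raises(UndefinedPhaseError):
            phase_difference(spec, 5.0)


class TestClassifyPattern:
    def test_table_like_group_means(self):
        # group-mean phases of alternating (parkinsonian) and synchronous
        # (essential-tremor) cohorts fall on the expected sides of 90°
        assert classify_pattern(154.4) is PatternLabel.ALTERNATING
        assert classify_pattern(38.4) is PatternLabel.SYNCHRONOUS

    def test_boundary_split_is_half_open(self):
        assert classify_pattern(0.0) is PatternLabel.SYNCHRONOUS
        assert classify_pattern(89.999) is PatternLabel.SYNCHRONOUS
        assert classify_pattern(90.0) is PatternLabel.ALTERNATING
        assert classify_pattern(180.0) is PatternLabel.ALTERNATING

    def test_custom_boundary(self):
        assert classify_pattern(80.0, boundary_deg=75.0) is PatternLabel.ALTERNATING

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            classify_pattern(-1.0)
        with pytest.raises(ContractError):
            classify_pattern(181.0)


class TestAnalyze:
    def test_alternating_regime_measurement(self, pd_params):
        m = analyze(generate_burst_envelope(pd_params))
        assert m.f_tremor == pytest.approx(4.63, abs=0.1)
        assert m.phase_diff_deg == pytest.approx(154.4, abs=5.0)
        assert m.pattern is PatternLabel.ALTERNATING
        assert m.resolution_hz <= 0.05
        assert all(a > 0 for a in m.amplitude)

    def test_zero_shift_raw_emg_is_synchronous(self):
        p = SynthParams(f_tremor=5.0, delta_phi_deg=0.0, seed=2)
        m = analyze(generate_raw_emg(p))
        assert m.f_tremor == pytest.approx(5.0, abs=0.1)
        assert m.phase_diff_deg < 5.0
        assert m.pattern is PatternLabel.SYNCHRONOUS

    def test_rejects_filtered_input(self):
        rec = sine_recording([(5.0, 0.0), (5.0, 0.0)], stage="envelope")
        with pytest.raises(ContractError):
            analyze(bandpass(rec))

    def test_amplitude_scale_invariance(self, et_params):
        rec = generate_burst_envelope(et_params)
        m1 = analyze(rec)
        m2 = analyze(rec.replace(samples=rec.samples * np.array([[3.0], [1.0]])))
        assert m2.f_tremor == m1.f_tremor
        assert m2.phase_diff_deg == pytest.approx(m1.phase_diff_deg, abs=1e-6)
        assert m2.amplitude[0] == pytest.approx(3 * m1.amplitude[0], rel=1e-9)

    def test_channel_swap_symmetry(self, pd_params):
        rec = generate_burst_envelope(pd_params)
        # same physical channels stored in the opposite row order: the
        # analysis must be invariant because it resolves channels by role
        reordered = rec.replace(
            samples=rec.samples[::-1].copy(),
            channel_roles=(rec.channel_roles[1], rec.channel_roles[0]),
        )
        # role labels exchanged (extensor electrode on the flexor muscle):
        # the unsigned phase difference must not change, the sign must flip
        relabeled = rec.replace(
            channel_roles=(rec.channel_roles[1], rec.channel_roles[0])
        )
        m1 = analyze(rec)
        m2 = analyze(reordered)
        m3 = analyze(relabeled)
        assert m2.phase_diff_deg == pytest.approx(m1.phase_diff_deg, abs=1e-9)
        assert m3.phase_diff_deg == pytest.approx(m1.phase_diff_deg, abs=1e-9)
        assert m3.meta["signed_phase_deg"] == pytest.approx(
            -m1.meta["signed_phase_deg"], abs=1e-9
        )

    def test_config_boundary_propagates(self):
        p = SynthParams(f_tremor=5.0, delta_phi_deg=60.0, seed=4)
        m = analyze(generate_burst_envelope(p), AnalysisConfig(boundary_deg=45.0))
        assert m.pattern is PatternLabel.ALTERNATING


class TestCircularSummary:
    def test_degenerate_all_equal(self):
        s = circular_summary([45.0] * 7)
        assert s.mean_deg == pytest.approx(45.0)
        assert s.R == pytest.approx(1.0)
        assert s.n == 7

    def test_orthogonal_axial_pair_has_zero_resultant(self):
        # doubled angles 0° and 180° cancel exactly
        s = circular_summary([0.0, 90.0])
        assert s.R == pytest.approx(0.0, abs=1e-12)

    def test_bin_counts(self):
        rng = np.random.default_rng(9)
        phases = rng.uniform(0, 180, 21)
        s = circular_summary(phases, bin_width_deg=20.0)
        assert len(s.bins) == 9
        assert s.bins.sum() == 21

    def test_boundary_value_180_counted(self):
        s = circular_summary([180.0, 0.0, 90.0])
        assert s.bins.sum() == 3

    def test_contracts(self):
        with pytest.raises(ContractError):
            circular_summary([])
        with pytest.raises(ContractError):
            circular_summary([200.0])
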