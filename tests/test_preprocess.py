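"""FA and lock-in demodulation contracts, plus their composition."""

import numpy as np
import pytest

from mdfa.phantom_sim import (
    CameraSpec,
    FrameSequence,
    ModulationSpec,
    simulate_sequence,
)
from mdfa.preprocess import (
    NoCarrierError,
    demodulate,
    frame_accumulate,
    locate_carrier,
    md_fa,
)
from mdfa.phantom_sim import default_phantom, render_transmittance

from conftest import make_sinusoid_sequence


def _const_seq(values, shape=(3, 3), fs=42.0, condition="raw"):
    frames = np.asarray(values, dtype=float)[:, None, None] * np.ones((1, *shape))
    return FrameSequence(frames, fs, "B435", condition)


class TestFrameAccumulate:
    def test_mean_of_identical_frames(self):
        out = frame_accumulate(_const_seq([7.0] * 12), 12)
        assert out.n_frames == 1
        np.testing.assert_array_equal(out.frames, 7.0)
        assert out.condition == "accumulated"

    def test_mean_of_ramp(self):
        out = frame_accumulate(_const_seq(np.arange(1, 13)), 12)
        np.testing.assert_allclose(out.frames, 6.5)

    def test_campaign_scale_frame_count(self):
        seq = _const_seq(np.zeros(1200) + 5.0)
        assert frame_accumulate(seq, 12).n_frames == 100

    def test_remainder_dropped_and_logged(self):
        out = frame_accumulate(_const_seq(np.arange(27.0)), 12)
        assert out.n_frames == 2
        assert out.meta["fa_dropped_frames"] == 3

    @pytest.mark.parametrize("window", [0, -1, 30])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            frame_accumulate(_const_seq(np.arange(24.0)), window)

    def test_global_mean_preserved(self):
        rng = np.random.default_rng(5)
        frames = rng.uniform(0, 50, size=(48, 6, 6))
        seq = FrameSequence(frames, 42.0, "B435", "raw")
        out = frame_accumulate(seq, 12)
        assert abs(out.frames.mean() - frames.mean()) < 1e-9 * frames.mean()

    def test_noise_variance_reduced_by_window(self):
        """iid noise on a constant: residual variance ~ sigma^2/N (3 SE)."""
        rng = np.random.default_rng(42)
        sigma = 5.0
        frames = 100.0 + rng.normal(0, sigma, size=(2400, 8, 8))
        seq = FrameSequence(frames, 42.0, "B435", "raw")
        out = frame_accumulate(seq, 12)
        resid = out.frames - 100.0
        n = resid.size  # 200 windows x 64 px
        var = resid.var()
        expected = sigma ** 2 / 12
        se = expected * np.sqrt(2.0 / n)
        assert abs(var - expected) < 3 * se

    def test_demodulated_condition_advances(self):
        seq = _const_seq(np.ones(24), condition="demodulated")
        assert frame_accumulate(seq, 12).condition == "demod_accumulated"


class TestLocateCarrier:
    @pytest.mark.parametrize(
        "f, expected_bin", [(3.5, 93), (4.0, 107)]
    )
    def test_peak_bin_at_45fps(self, f, expected_bin):
        # nearest bin to f*T/fs (93.33 / 106.67): leakage argmax oracle
        seq = make_sinusoid_sequence(
            n_frames=1200, sampling_hz=45.0, carrier_hz=f, amplitude=1.0, offset=10.0
        )
        est = locate_carrier(seq, expected_hz=f)
        assert est.bin_index == expected_bin
        assert est.estimated_hz == pytest.approx(expected_bin * 45.0 / 1200)

    def test_constant_stack_has_no_carrier(self):
        seq = _const_seq(np.full(64, 9.0), condition="modulated")
        with pytest.raises(NoCarrierError):
            locate_carrier(seq)

    def test_search_band_restriction(self):
        # two tones; restricting the band must pick the in-band one
        t = np.arange(480.0)
        series = 10 + np.sin(2 * np.pi * 3.5 * t / 42.0) + 2 * np.sin(
            2 * np.pi * 10.5 * t / 42.0
        )
        seq = FrameSequence(
            series[:, None, None] * np.ones((1, 2, 2)), 42.0, "B435", "modulated"
        )
        est_free = locate_carrier(seq)
        est_band = locate_carrier(seq, expected_hz=3.5, search_halfwidth_hz=0.5)
        assert est_free.estimated_hz == pytest.approx(10.5)
        assert est_band.estimated_hz == pytest.approx(3.5)


class TestDemodulate:
    def test_recovers_amplitude_exactly_on_integer_cycles(self):
        seq = make_sinusoid_sequence(amplitude=7.0, offset=100.0)
        est = locate_carrier(seq, expected_hz=3.5)
        out = demodulate(seq, est, lowpass_cycles=1)
        assert out.n_frames == seq.n_frames
        assert out.condition == "demodulated"
        interior = out.frames[out.meta["boundary_frames"] : -out.meta["boundary_frames"]]
        np.testing.assert_allclose(interior, 7.0, rtol=1e-6)

    def test_pure_dc_demodulates_to_zero(self):
        seq = make_sinusoid_sequence(amplitude=0.0, offset=50.0)
        est_seq = make_sinusoid_sequence(amplitude=1.0)
        est = locate_carrier(est_seq, expected_hz=3.5)
        out = demodulate(seq, est, lowpass_cycles=1)
        np.testing.assert_allclose(out.frames, 0.0, atol=1e-9)

    def test_output_count_preserved(self):
        seq = make_sinusoid_sequence(n_frames=1200, sampling_hz=45.0)
        est = locate_carrier(seq, expected_hz=3.5)
        assert demodulate(seq, est).n_frames == 1200

    def test_linear_in_modulation_amplitude(self):
        est = locate_carrier(make_sinusoid_sequence(amplitude=1.0), expected_hz=3.5)
        a1 = demodulate(make_sinusoid_sequence(amplitude=3.0), est, 1)
        a2 = demodulate(make_sinusoid_sequence(amplitude=6.0), est, 1)
        b = a1.meta["boundary_frames"]
        np.testing.assert_allclose(
            a2.frames[b:-b], 2.0 * a1.frames[b:-b], rtol=1e-6
        )

    def test_requires_modulated_condition(self):
        seq = make_sinusoid_sequence(condition="raw")
        est = locate_carrier(make_sinusoid_sequence(), expected_hz=3.5)
        with pytest.raises(ValueError, match="modulated"):
            demodulate(seq, est)

    def test_rejects_carrier_at_nyquist(self):
        from mdfa.preprocess import CarrierEstimate

        seq = make_sinusoid_sequence()
        bad = CarrierEstimate(bin_index=120, estimated_hz=21.0,
                              peak_magnitude=1.0, snr_of_peak=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            demodulate(seq, bad)


class TestMdFa:
    def test_output_length_is_cycles(self):
        mod = ModulationSpec(3.5, 0.6, 12)
        seq = make_sinusoid_sequence(n_frames=1200, sampling_hz=42.0)
        assert md_fa(seq, mod).n_frames == 100

    def test_noiseless_recovery_of_depth_scaled_transmittance(self, noiseless_camera, carrier_3p5):
        phantom = default_phantom()
        seq = simulate_sequence(phantom, 0, carrier_3p5, noiseless_camera, 480)
        out = md_fa(seq, carrier_3p5)
        assert out.condition == "demod_accumulated"
        expected = (
            noiseless_camera.base_intensity
            * noiseless_camera.gain
            * carrier_3p5.depth
            * render_transmittance(phantom, 0)
        )
        boundary_out = -(-out.meta["boundary_frames"] // 12)  # FA frames touched
        interior = out.frames[boundary_out:-boundary_out]
        err = np.abs(interior - expected[None]) / expected.min()
        assert err.max() < 1e-4
        corr = np.corrcoef(
            interior.mean(axis=0).ravel(),
            render_transmittance(phantom, 0).ravel(),
        )[0, 1]
        assert corr > 0.99

    def test_unmodulated_stack_raises_no_carrier(self):
        mod = ModulationSpec(3.5, 0.6, 12)
        cam = CameraSpec(base_intensity=100.0, shot_noise=False, read_noise_sd=0.0, seed=0)
        seq = simulate_sequence(
            default_phantom(), 0, ModulationSpec(3.5, 0.0, 12), cam, 120
        )
        seq = seq.replace(condition="modulated")  # depth-0 stack offered as modulated
        with pytest.raises(NoCarrierError):
            md_fa(seq, mod)
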