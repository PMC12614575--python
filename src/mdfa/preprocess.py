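"""Frame accumulation (FA), lock-in demodulation (M_D) and their composition.

Three transforms on :class:`~mdfa.phantom_sim.FrameSequence` stacks:

* ``frame_accumulate`` — cycle-synchronous averaging: each block of ``window``
  consecutive frames is replaced by its mean, suppressing uncorrelated noise
  by the window length.
* ``locate_carrier`` + ``demodulate`` — locate the illumination carrier in
  the DFT of the spatial-mean time series, then recover the per-pixel
  modulation amplitude with a coherent lock-in: mix with in-phase and
  quadrature references at the carrier, low-pass both products with a
  moving average, and return ``2 * sqrt(I^2 + Q^2)`` per frame.  Amplitude
  (not phase) is returned since the downstream use is intensity imaging,
  and the quadrature sum makes the result insensitive to the unknown
  carrier phase and to small frequency offsets of the estimated bin.
* ``md_fa`` — demodulation followed by accumulation over one carrier cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .phantom_sim import FrameSequence, ModulationSpec

__all__ = [
    "CarrierEstimate",
    "NoCarrierError",
    "frame_accumulate",
    "locate_carrier",
    "demodulate",
    "md_fa",
]

logger = logging.getLogger(__name__)

#: Minimum peak-to-floor ratio for a carrier detection to be accepted.
DEFAULT_CARRIER_SNR_THRESHOLD = 3.0

#: Default lock-in integration time in carrier cycles.  A moving average
#: spanning a single cycle has an equivalent noise bandwidth equal to the
#: carrier frequency itself and rejects almost nothing; standard lock-in
#: practice sets the time constant well above the carrier period.  Ten
#: cycles narrows the band to a tenth of the carrier while staying short
#: against the record lengths used here.
DEFAULT_LOWPASS_CYCLES = 10

# condition transitions applied by frame_accumulate
_ACCUMULATE_TRANSITIONS = {
    "raw": "accumulated",
    "modulated": "accumulated",
    "demodulated": "demod_accumulated",
    "accumulated": "accumulated",
    "demod_accumulated": "demod_accumulated",
}


class NoCarrierError(RuntimeError):
    """No spectral peak rose sufficiently above the noise floor."""


@dataclass(frozen=True)
class CarrierEstimate:
    """DFT peak describing the located illumination carrier.

    ``estimated_hz = bin_index * sampling_hz / T`` and ``snr_of_peak`` is the
    peak magnitude over the median off-peak (non-DC) magnitude.
    """

    bin_index: int
    estimated_hz: float
    peak_magnitude: float
    snr_of_peak: float


def frame_accumulate(seq: FrameSequence, window: int) -> FrameSequence:
    """Average non-overlapping blocks of ``window`` consecutive frames.

    Output frame ``j`` is the arithmetic mean of input frames
    ``[j*window, (j+1)*window)``; trailing remainder frames are dropped (and
    the drop count logged) so every output averages exactly ``window``
    frames.  The output stays in floating representation — no requantization.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    T = seq.n_frames
    if window > T:
        raise ValueError(f"window {window} exceeds sequence length {T}")
    n_out = T // window
    dropped = T - n_out * window
    if dropped:
        logger.info("frame_accumulate: dropping %d trailing frames", dropped)
    frames = seq.frames[: n_out * window].astype(np.float64)
    out = frames.reshape(n_out, window, *seq.frames.shape[1:]).mean(axis=1)
    result = seq.replace(
        frames=out,
        sampling_hz=seq.sampling_hz / window,
        condition=_ACCUMULATE_TRANSITIONS[seq.condition],
    )
    result.meta["fa_window"] = window
    result.meta["fa_dropped_frames"] = dropped
    return result


def locate_carrier(
    seq: FrameSequence,
    expected_hz: Optional[float] = None,
    search_halfwidth_hz: float = 0.5,
    snr_threshold: float = DEFAULT_CARRIER_SNR_THRESHOLD,
) -> CarrierEstimate:
    """Find the carrier bin in the DFT of the spatial-mean time series.

    The spatial mean (rather than per-pixel spectra) is used for robustness
    at low light; per-pixel demodulation then shares the global estimate.
    The DC bin is always excluded; when ``expected_hz`` is given the search
    is restricted to ``expected_hz +/- search_halfwidth_hz``.  Equal
    magnitudes are broken toward the lowest bin index.

    Raises :class:`NoCarrierError` when the best peak is below
    ``snr_threshold`` times the median off-peak magnitude.
    """
    series = seq.frames.astype(np.float64).mean(axis=(1, 2))
    T = series.size
    if T < 2:
        raise ValueError("need at least 2 frames to locate a carrier")
    mag = np.abs(np.fft.rfft(series - series.mean()))
    freqs = np.fft.rfftfreq(T, d=1.0 / seq.sampling_hz)

    candidates = np.arange(1, mag.size)  # DC excluded always
    if expected_hz is not None:
        lo, hi = expected_hz - search_halfwidth_hz, expected_hz + search_halfwidth_hz
        in_band = candidates[(freqs[candidates] >= lo) & (freqs[candidates] <= hi)]
        if in_band.size == 0:
            raise NoCarrierError(
                f"no DFT bin within {expected_hz} +/- {search_halfwidth_hz} Hz"
            )
        candidates = in_band

    peak_pos = int(candidates[np.argmax(mag[candidates])])  # argmax: first/lowest wins
    peak_magnitude = float(mag[peak_pos])

    off_peak = np.delete(np.arange(1, mag.size), peak_pos - 1)
    floor = float(np.median(mag[off_peak])) if off_peak.size else 0.0
    snr_of_peak = peak_magnitude / floor if floor > 0 else (
        np.inf if peak_magnitude > 0 else 0.0
    )
    if snr_of_peak < snr_threshold:
        raise NoCarrierError(
            f"spectral peak SNR {snr_of_peak:.2f} below threshold {snr_threshold}"
        )
    return CarrierEstimate(
        bin_index=peak_pos,
        estimated_hz=float(peak_pos * seq.sampling_hz / T),
        peak_magnitude=peak_magnitude,
        snr_of_peak=float(snr_of_peak),
    )


def demodulate(
    seq: FrameSequence,
    carrier: CarrierEstimate,
    lowpass_cycles: int = DEFAULT_LOWPASS_CYCLES,
) -> FrameSequence:
    """Per-pixel coherent lock-in demodulation at the located carrier.

    Each pixel's DC-removed time series is multiplied by in-phase and
    quadrature references at ``carrier.estimated_hz``; both products are
    low-passed with a moving average spanning ``lowpass_cycles`` carrier
    cycles (reflected boundaries) and combined into the amplitude
    ``2 * sqrt(I^2 + Q^2)`` per frame.  The output frame count equals the
    input frame count.  Frames within half a filter window of either end
    are boundary-affected; their count is flagged in the metadata.
    """
    if seq.condition != "modulated":
        raise ValueError(
            f"demodulate requires a modulated sequence, got {seq.condition!r}"
        )
    if lowpass_cycles <= 0:
        raise ValueError("lowpass_cycles must be positive")
    if carrier.estimated_hz >= seq.sampling_hz / 2:
        raise ValueError("carrier at or above Nyquist frequency")

    frames = seq.frames.astype(np.float64)
    x = frames - frames.mean(axis=0, keepdims=True)  # carrier rides on large DC
    t = np.arange(seq.n_frames, dtype=np.float64)
    phase = 2.0 * np.pi * carrier.estimated_hz * t / seq.sampling_hz
    ref_i = np.sin(phase)[:, None, None]
    ref_q = np.cos(phase)[:, None, None]

    window = max(2, int(round(lowpass_cycles * seq.sampling_hz / carrier.estimated_hz)))
    window = min(window, seq.n_frames)
    i_comp = uniform_filter1d(x * ref_i, size=window, axis=0, mode="reflect")
    q_comp = uniform_filter1d(x * ref_q, size=window, axis=0, mode="reflect")
    amp = 2.0 * np.sqrt(i_comp ** 2 + q_comp ** 2)

    result = seq.replace(frames=amp, condition="demodulated")
    result.meta["carrier"] = carrier
    result.meta["lowpass_window_frames"] = window
    result.meta["boundary_frames"] = window // 2
    return result


def md_fa(
    seq: FrameSequence,
    mod: ModulationSpec,
    lowpass_cycles: int = DEFAULT_LOWPASS_CYCLES,
    search_halfwidth_hz: float = 0.5,
) -> FrameSequence:
    """Demodulate at the located carrier, then accumulate over one cycle.

    Composition ``locate_carrier -> demodulate -> frame_accumulate`` with the
    accumulation window equal to ``mod.frames_per_cycle``; the output length
    is ``floor(T / frames_per_cycle)`` and the condition advances to
    ``demod_accumulated``.
    """
    carrier = locate_carrier(
        seq, expected_hz=mod.carrier_hz, search_halfwidth_hz=search_halfwidth_hz
    )
    demod = demodulate(seq, carrier, lowpass_cycles=lowpass_cycles)
    return frame_accumulate(demod, mod.frames_per_cycle)
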