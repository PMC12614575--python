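import numpy as np
import pytest

from mdfa.phantom_sim import (
    CameraSpec,
    FrameSequence,
    InclusionSpec,
    ModulationSpec,
    PhantomSpec,
    default_phantom,
)


@pytest.fixture
def phantom() -> PhantomSpec:
    return default_phantom()


@pytest.fixture
def small_phantom() -> PhantomSpec:
    """A 32x32 single-wavelength phantom with one centred inclusion."""
    return PhantomSpec(
        height_px=32,
        width_px=32,
        medium_attenuation=(0.1,),
        inclusions=(
            InclusionSpec("potato", (16, 16), (6, 6), (np.log(2.0),)),
        ),
        wavelengths=("B435",),
    )


def make_sinusoid_sequence(
    *,
    n_frames: int = 240,
    sampling_hz: float = 42.0,
    carrier_hz: float = 3.5,
    amplitude: float = 7.0,
    offset: float = 100.0,
    shape=(4, 4),
    condition: str = "modulated",
) -> FrameSequence:
    """Analytic noiseless stack: every pixel is offset + A*sin(2*pi*f*t/fs)."""
    t = np.arange(n_frames, dtype=float)
    series = offset + amplitude * np.sin(2 * np.pi * carrier_hz * t / sampling_hz)
    frames = series[:, None, None] * np.ones((1, *shape))
    return FrameSequence(frames, sampling_hz, "B435", condition)


@pytest.fixture
def noiseless_camera() -> CameraSpec:
    return CameraSpec(
        base_intensity=50000.0, bit_depth=16, shot_noise=False,
        read_noise_sd=0.0, seed=7,
    )


@pytest.fixture
def carrier_3p5() -> ModulationSpec:
    return ModulationSpec(carrier_hz=3.5, depth=0.6, frames_per_cycle=12)
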