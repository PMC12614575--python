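"""Synthetic multispectral transmission stacks of a turbid slab phantom.

Emulates a transmission-imaging rig: a semi-translucent slab (fat-emulsion
stand-in) containing six absorbing/scattering vegetable blocks, illuminated
by sinusoidally modulated LED light at four wavelengths and digitized by a
low-light camera with shot and read noise.

The optical model is a Beer-Lambert stand-in: each pixel's transmittance is
``exp(-OD)`` where the optical density OD is the background medium's
per-wavelength OD plus the extra OD of every inclusion whose footprint
covers the pixel (overlaps sum).  This gives full control over ground truth
while reproducing the qualitative material contrasts of real phantoms:
potato most translucent at every wavelength, carrot strongly absorbing in
the red band, pumpkin most translucent in the near infrared.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "MATERIAL_CLASSES",
    "InclusionSpec",
    "PhantomSpec",
    "ModulationSpec",
    "CameraSpec",
    "FrameSequence",
    "render_transmittance",
    "simulate_sequence",
    "ground_truth_masks",
    "default_phantom",
]

DEFAULT_WAVELENGTHS: Tuple[str, ...] = ("B435", "G546", "R700", "NIR860")

MATERIAL_CLASSES: Tuple[str, ...] = ("potato", "carrot", "pumpkin")

#: Default extra optical densities per material over (B435, G546, R700, NIR860).
#: Potato is the most translucent at all wavelengths; carrot absorbs most
#: strongly in the red band; pumpkin is most translucent in the near infrared.
DEFAULT_MATERIAL_OD = {
    "potato": (0.15, 0.12, 0.10, 0.08),
    "carrot": (0.45, 0.55, 0.90, 0.40),
    "pumpkin": (0.50, 0.45, 0.40, 0.12),
}

# Condition state machine for FrameSequence.condition.
CONDITIONS = ("raw", "modulated", "demodulated", "accumulated", "demod_accumulated")


@dataclass(frozen=True)
class InclusionSpec:
    """A rectangular absorbing block embedded in the slab.

    The footprint covers rows ``[center-half_extent, center+half_extent)``
    and analogously for columns, so a half extent of ``h`` spans ``2h``
    pixels.  ``extra_attenuation`` is the optical density added to the
    background inside the footprint, one value per wavelength.
    """

    material_class: str
    center_rc: Tuple[int, int]
    half_extent_rc: Tuple[int, int]
    extra_attenuation: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.material_class not in MATERIAL_CLASSES:
            raise ValueError(
                f"material_class must be one of {MATERIAL_CLASSES}, "
                f"got {self.material_class!r}"
            )
        if min(self.half_extent_rc) < 1:
            raise ValueError("half extents must be >= 1 px")
        if any(not np.isfinite(a) or a < 0 for a in self.extra_attenuation):
            raise ValueError("extra_attenuation must be finite and >= 0")

    def footprint(self) -> Tuple[slice, slice]:
        (cr, cc), (hr, hc) = self.center_rc, self.half_extent_rc
        return slice(cr - hr, cr + hr), slice(cc - hc, cc + hc)


@dataclass(frozen=True)
class PhantomSpec:
    """Slab geometry, background turbidity and embedded inclusions."""

    height_px: int
    width_px: int
    medium_attenuation: Tuple[float, ...]
    inclusions: Tuple[InclusionSpec, ...] = ()
    wavelengths: Tuple[str, ...] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("image dimensions must be positive")
        if len(self.wavelengths) < 1:
            raise ValueError("at least one wavelength required")
        if len(self.medium_attenuation) != len(self.wavelengths):
            raise ValueError("medium_attenuation length must match wavelengths")
        if any(not np.isfinite(a) or a < 0 for a in self.medium_attenuation):
            raise ValueError("medium_attenuation must be finite and >= 0")
        for k, inc in enumerate(self.inclusions):
            if len(inc.extra_attenuation) != len(self.wavelengths):
                raise ValueError(
                    f"inclusion {k}: extra_attenuation length must match wavelengths"
                )
            rs, cs = inc.footprint()
            if rs.start < 0 or cs.start < 0 or rs.stop > self.height_px or cs.stop > self.width_px:
                raise ValueError(f"inclusion {k}: footprint exceeds image bounds")

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class ModulationSpec:
    """Sinusoidal illumination carrier.

    ``sampling_hz`` defaults to ``carrier_hz * frames_per_cycle`` so that one
    carrier cycle spans exactly ``frames_per_cycle`` frames; when both are
    supplied, ``frames_per_cycle`` governs cycle bookkeeping (accumulation
    windows) regardless of the nominal rate ratio.
    """

    carrier_hz: float = 3.5
    depth: float = 0.6
    frames_per_cycle: int = 12
    sampling_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise ValueError("carrier_hz must be positive")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")
        if self.frames_per_cycle < 2:
            raise ValueError("frames_per_cycle must be >= 2")
        if self.sampling_hz is None:
            object.__setattr__(
                self, "sampling_hz", self.carrier_hz * self.frames_per_cycle
            )
        elif self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")


@dataclass(frozen=True)
class CameraSpec:
    """Digitization model: gain, base level, shot/read noise, bit depth.

    ``base_intensity`` is the mean digital level of unattenuated illumination
    before gain; the expected digital value is ``base_intensity * gain *
    transmittance``.  Shot noise is Poisson on the photon-equivalent count
    (expected level / gain), so its digital-level variance equals
    ``gain * expected level``; read noise is additive Gaussian in digital
    levels.  ``seed`` fully determines the noise stream.
    """

    base_intensity: float = 30.0
    gain: float = 1.0
    bit_depth: int = 8
    read_noise_sd: float = 0.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.base_intensity <= 0 or self.gain <= 0:
            raise ValueError("base_intensity and gain must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.base_intensity * self.gain > self.max_value:
            raise ValueError("base_intensity * gain exceeds bit-depth range")

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class FrameSequence:
    """A time-ordered single-wavelength image stack plus acquisition metadata.

    ``condition`` tracks processing state along the allowed transitions
    raw -> accumulated and modulated -> demodulated -> demod_accumulated.
    """

    frames: np.ndarray  # (T, H, W)
    sampling_hz: float
    wavelength: str
    condition: str = "raw"
    modulation: Optional[ModulationSpec] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape

    def replace(self, **kwargs) -> "FrameSequence":
        """Shallow-copy the sequence with some fields replaced."""
        out = dataclasses.replace(self, **kwargs)
        if "meta" not in kwargs:
            out.meta = dict(self.meta)
        return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_transmittance(phantom: PhantomSpec, wavelength_index: int) -> np.ndarray:
    """Per-pixel transmittance map in (0, 1] at one wavelength.

    Optical densities are additive: overlapping inclusions sum their extra
    attenuation on the overlap (never an error), on top of the background
    medium OD.  All background pixels share a single value.
    """
    if not 0 <= wavelength_index < phantom.n_wavelengths:
        raise IndexError(
            f"wavelength_index {wavelength_index} out of range "
            f"[0, {phantom.n_wavelengths})"
        )
    od = np.full(
        (phantom.height_px, phantom.width_px),
        float(phantom.medium_attenuation[wavelength_index]),
    )
    for inc in phantom.inclusions:
        rs, cs = inc.footprint()
        od[rs, cs] += inc.extra_attenuation[wavelength_index]
    return np.exp(-od)


def ground_truth_masks(phantom: PhantomSpec) -> np.ndarray:
    """Labeled (H, W) integer mask: 0 background, k = k-th inclusion.

    Labels follow the inclusion list order; where footprints overlap the
    later inclusion's label wins (it is painted last).
    """
    if not phantom.inclusions:
        raise ValueError("phantom has no inclusions; mask would be empty")
    mask = np.zeros((phantom.height_px, phantom.width_px), dtype=np.int32)
    for k, inc in enumerate(phantom.inclusions, start=1):
        rs, cs = inc.footprint()
        mask[rs, cs] = k
    return mask


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

def simulate_sequence(
    phantom: PhantomSpec,
    wavelength_index: int,
    mod: ModulationSpec,
    cam: CameraSpec,
    n_frames: int,
) -> FrameSequence:
    """Simulate a digitized stack of ``n_frames`` modulated transmission frames.

    The expected intensity at frame ``t`` is
    ``base_intensity * gain * transmittance * (1 + depth * sin(2*pi*f*t/fs))``.
    Poisson shot noise and Gaussian read noise are applied when enabled, then
    the stack is clipped and quantized to the camera bit depth.  A fixed
    camera seed yields a bit-identical stack on rerun.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    trans = render_transmittance(phantom, wavelength_index)
    t = np.arange(n_frames, dtype=float)
    carrier = 1.0 + mod.depth * np.sin(2.0 * np.pi * mod.carrier_hz * t / mod.sampling_hz)
    expected = (
        cam.base_intensity * cam.gain * trans[None, :, :] * carrier[:, None, None]
    )

    meta = {"seed": cam.seed, "saturation_warning": False}
    if expected.max() > cam.max_value:
        meta["saturation_warning"] = True

    rng = np.random.default_rng(cam.seed)
    frames = expected
    if cam.shot_noise:
        frames = cam.gain * rng.poisson(expected / cam.gain).astype(float)
    if cam.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, cam.read_noise_sd, size=frames.shape)

    frames = np.clip(np.rint(frames), 0, cam.max_value)
    dtype = np.uint8 if cam.bit_depth == 8 else np.uint16
    frames = frames.astype(dtype)

    return FrameSequence(
        frames=frames,
        sampling_hz=float(mod.sampling_hz),
        wavelength=phantom.wavelengths[wavelength_index],
        condition="modulated" if mod.depth > 0 else "raw",
        modulation=mod,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Default phantom
# ---------------------------------------------------------------------------

def default_phantom(
    height_px: int = 96,
    width_px: int = 96,
    medium_attenuation: Sequence[float] = (0.35, 0.30, 0.25, 0.20),
    wavelengths: Sequence[str] = DEFAULT_WAVELENGTHS,
) -> PhantomSpec:
    """The standard six-inclusion test phantom.

    Two blocks each of potato, carrot and pumpkin arranged in a 3 x 2 grid
    centred around two-thirds of the slab width (where lesions typically sit
    in transmission phantoms).  The second block of each material is slightly
    larger and slightly denser (+0.06 OD at every wavelength), so the six
    blocks form six distinguishable classes.
    """
    if len(medium_attenuation) != len(wavelengths):
        raise ValueError("medium_attenuation length must match wavelengths")
    n_wl = len(wavelengths)
    # Column anchors straddle 2/3 of the width; rows split the height in three.
    col_anchor = int(round(width_px * 2 / 3))
    cols = (col_anchor - width_px // 8, col_anchor + width_px // 8)
    rows = (height_px // 5, height_px // 2, height_px - height_px // 5)
    half1 = max(3, height_px // 14)
    half2 = max(4, height_px // 11)

    inclusions = []
    for i, material in enumerate(MATERIAL_CLASSES):
        base_od = DEFAULT_MATERIAL_OD[material][:n_wl]
        for j in range(2):
            extra = tuple(od + 0.06 * j for od in base_od)
            half = (half1, half1) if j == 0 else (half2, half2)
            inclusions.append(
                InclusionSpec(
                    material_class=material,
                    center_rc=(rows[i], cols[j]),
                    half_extent_rc=half,
                    extra_attenuation=extra,
                )
            )
    return PhantomSpec(
        height_px=height_px,
        width_px=width_px,
        medium_attenuation=tuple(float(a) for a in medium_attenuation),
        inclusions=tuple(inclusions),
        wavelengths=tuple(wavelengths),
    )
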