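"""VGG16 classifier variants with batch norm, SE attention and a GAP head.

Four architectures over the same 13-convolution, 5-stage backbone
(widths 64, 128, 256, 512, 512; 3x3 kernels, stride 1, padding 1; 2x2/2
max pooling after each stage):

* ``base``        — the plain backbone plus three fully connected layers
                    (4096, 4096, n_classes) with dropout 0.5 on the two
                    hidden layers.
* ``bn``          — batch normalization after every convolution.
* ``bn_se``       — additionally a squeeze-and-excitation block with
                    bottleneck ratio r (default 16) after each convolution
                    (``per_conv``) or after each stage (``per_stage``).
* ``bn_se_gap``   — the fully connected stack replaced by global average
                    pooling followed by a single linear map to n_classes.
                    (A head with zero parameters would leave channel count
                    != class count unresolved, so one linear layer remains.)

``count_parameters`` gives closed-form per-layer counts (conv:
``Cin*Cout*9 + Cout``; dense: ``in*out + out``; batch norm: ``2*C``;
SE: ``2*C^2/r``, bias-free; pooling: 0) that must agree with a brute-force
traversal of a built network's parameter tensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from . import nn

__all__ = [
    "VARIANTS",
    "ModelSpec",
    "SEWeights",
    "ParameterReport",
    "se_squeeze",
    "se_excite",
    "se_scale",
    "build_model",
    "count_parameters",
    "brute_force_parameter_count",
    "scaled_spec",
]

VARIANTS = ("base", "bn", "bn_se", "bn_se_gap")

#: The 13-conv / 5-stage plan: (channel width, convolutions per stage).
DEFAULT_CONV_PLAN: Tuple[Tuple[int, int], ...] = (
    (64, 2), (128, 2), (256, 3), (512, 3), (512, 3),
)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture configuration for one classifier variant."""

    variant: str = "base"
    conv_plan: Tuple[Tuple[int, int], ...] = DEFAULT_CONV_PLAN
    se_ratio: int = 16
    se_placement: str = "per_conv"
    n_classes: int = 6
    input_size: int = 224
    fc_widths: Tuple[int, int] = (4096, 4096)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.se_placement not in ("per_conv", "per_stage"):
            raise ValueError("se_placement must be 'per_conv' or 'per_stage'")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_size < 32 or self.input_size % 32:
            raise ValueError(
                "input_size must be a multiple of 32 (five 2x2 poolings)"
            )
        if self.se_ratio < 1:
            raise ValueError("se_ratio must be a positive integer")
        if self.has_se:
            for width, _ in self.conv_plan:
                if width % self.se_ratio:
                    raise ValueError(
                        f"se_ratio {self.se_ratio} must divide stage width {width}"
                    )

    @property
    def has_bn(self) -> bool:
        return self.variant in ("bn", "bn_se", "bn_se_gap")

    @property
    def has_se(self) -> bool:
        return self.variant in ("bn_se", "bn_se_gap")

    @property
    def has_gap(self) -> bool:
        return self.variant == "bn_se_gap"

    @property
    def feature_size(self) -> int:
        """Spatial side length of the feature map after the five poolings."""
        return self.input_size // 32


def scaled_spec(variant: str, *, input_size: int = 32, width_divisor: int = 4,
                se_ratio: int = 16, n_classes: int = 6,
                se_placement: str = "per_conv") -> ModelSpec:
    """A desk-scale spec: same 13-conv topology at reduced width and input."""
    plan = tuple((max(se_ratio, w // width_divisor), n) for w, n in DEFAULT_CONV_PLAN)
    fc = tuple(max(64, w // width_divisor) for w in (4096, 4096))
    return ModelSpec(
        variant=variant, conv_plan=plan, se_ratio=se_ratio,
        se_placement=se_placement, n_classes=n_classes,
        input_size=input_size, fc_widths=fc,
    )


# ---------------------------------------------------------------------------
# SE primitives on single feature maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SEWeights:
    """Bias-free excitation projections: W1 is (C/r, C), W2 is (C, C/r)."""

    w1: np.ndarray
    w2: np.ndarray

    def __post_init__(self) -> None:
        w1 = np.asarray(self.w1)
        w2 = np.asarray(self.w2)
        if w1.ndim != 2 or w2.ndim != 2 or w1.shape != w2.shape[::-1]:
            raise ValueError("W1 must be (C/r, C) and W2 its transpose shape")
        if not (np.isfinite(w1).all() and np.isfinite(w2).all()):
            raise ValueError("SE weights must be finite")


def se_squeeze(featuremap: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of a (C, H, W) feature map -> length-C vector."""
    fm = np.asarray(featuremap, dtype=np.float64)
    if fm.ndim != 3 or fm.shape[1] < 1 or fm.shape[2] < 1:
        raise ValueError("featuremap must be (C, H, W) with H, W >= 1")
    return fm.mean(axis=(1, 2))


def se_excite(z: np.ndarray, w: SEWeights) -> np.ndarray:
    """Channel weights ``sigmoid(W2 relu(W1 z))``, all strictly in (0, 1)."""
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 1 or z.shape[0] != w.w1.shape[1]:
        raise ValueError(
            f"z length {z.shape} does not match W1 shape {np.shape(w.w1)}"
        )
    hidden = np.maximum(np.asarray(w.w1, dtype=np.float64) @ z, 0.0)
    return 1.0 / (1.0 + np.exp(-(np.asarray(w.w2, dtype=np.float64) @ hidden)))


def se_scale(featuremap: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Multiply channel c of a (C, H, W) map by s_c."""
    fm = np.asarray(featuremap, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if fm.ndim != 3 or s.ndim != 1 or s.shape[0] != fm.shape[0]:
        raise ValueError("s length must equal the channel count")
    return fm * s[:, None, None]


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> nn.Sequential:
    """Instantiate a variant as an ``nn.Sequential`` ready for training.

    Weight initialization (He normal) is fully determined by ``seed``.  The
    forward pass on an (N, 3, input_size, input_size) batch returns
    ``n_classes`` scores per item.
    """
    rng = np.random.default_rng(seed)
    layers: List[nn.Layer] = []
    in_ch = 3
    for stage, (width, n_convs) in enumerate(spec.conv_plan, start=1):
        for conv in range(1, n_convs + 1):
            name = f"conv{stage}_{conv}"
            layers.append(nn.Conv2d(in_ch, width, rng, name=name, dtype=dtype))
            if spec.has_bn:
                layers.append(nn.BatchNorm2d(width, name=f"bn{stage}_{conv}", dtype=dtype))
            layers.append(nn.ReLU())
            if spec.has_se and spec.se_placement == "per_conv":
                layers.append(nn.SEBlock(width, spec.se_ratio, rng,
                                         name=f"se{stage}_{conv}", dtype=dtype))
            in_ch = width
        if spec.has_se and spec.se_placement == "per_stage":
            layers.append(nn.SEBlock(width, spec.se_ratio, rng,
                                     name=f"se{stage}", dtype=dtype))
        layers.append(nn.MaxPool2d())

    last_width = spec.conv_plan[-1][0]
    if spec.has_gap:
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Linear(last_width, spec.n_classes, rng, name="head", dtype=dtype))
    else:
        flat = last_width * spec.feature_size ** 2
        fc1, fc2 = spec.fc_widths
        layers.append(nn.Flatten())
        layers.append(nn.Linear(flat, fc1, rng, name="fc1", dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout))
        layers.append(nn.Linear(fc1, fc2, rng, name="fc2", dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout))
        layers.append(nn.Linear(fc2, spec.n_classes, rng, name="fc3", dtype=dtype))
    return nn.Sequential(layers)


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterReport:
    """Closed-form per-layer parameter counts with FC/SE share percentages."""

    layers: Tuple[Tuple[str, int], ...]
    total: int
    fc_total: int
    se_total: int
    fc_share_percent: float
    se_share_percent: float

    def as_dict(self) -> Dict[str, object]:
        return {
            "layers": dict(self.layers),
            "total": self.total,
            "fc_total": self.fc_total,
            "se_total": self.se_total,
            "fc_share_percent": self.fc_share_percent,
            "se_share_percent": self.se_share_percent,
        }


def count_parameters(spec: ModelSpec) -> ParameterReport:
    """Closed-form parameter table for a variant (no network instantiated).

    conv: ``Cin*Cout*9 + Cout``; batch norm: ``2*C``; SE: ``2*C**2/r``
    (bias-free); dense: ``in*out + out``; pooling layers: 0.
    """
    rows: List[Tuple[str, int]] = []
    fc_total = 0
    se_total = 0
    in_ch = 3
    for stage, (width, n_convs) in enumerate(spec.conv_plan, start=1):
        for conv in range(1, n_convs + 1):
            rows.append((f"conv{stage}_{conv}", in_ch * width * 9 + width))
            if spec.has_bn:
                rows.append((f"bn{stage}_{conv}", 2 * width))
            if spec.has_se and spec.se_placement == "per_conv":
                n_se = 2 * width * width // spec.se_ratio
                rows.append((f"se{stage}_{conv}", n_se))
                se_total += n_se
            in_ch = width
        if spec.has_se and spec.se_placement == "per_stage":
            n_se = 2 * width * width // spec.se_ratio
            rows.append((f"se{stage}", n_se))
            se_total += n_se

    last_width = spec.conv_plan[-1][0]
    if spec.has_gap:
        rows.append(("gap", 0))
        n_head = last_width * spec.n_classes + spec.n_classes
        rows.append(("head", n_head))
        fc_total += n_head
    else:
        flat = last_width * spec.feature_size ** 2
        fc1, fc2 = spec.fc_widths
        for name, n_in, n_out in (
            ("fc1", flat, fc1), ("fc2", fc1, fc2), ("fc3", fc2, spec.n_classes)
        ):
            n_fc = n_in * n_out + n_out
            rows.append((name, n_fc))
            fc_total += n_fc

    total = sum(count for _, count in rows)
    return ParameterReport(
        layers=tuple(rows),
        total=total,
        fc_total=fc_total,
        se_total=se_total,
        fc_share_percent=100.0 * fc_total / total,
        se_share_percent=100.0 * se_total / total,
    )


def brute_force_parameter_count(model: nn.Sequential) -> int:
    """Independent traversal: sum of all trainable tensor sizes."""
    return int(sum(p.data.size for p in model.params()))
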