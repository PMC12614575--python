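"""Pseudo-color wavelength fusion, mask cropping and dataset bookkeeping.

Three of the four wavelength images are assigned to the R, G and B channels
of a pseudo-color image; with order significant this gives A(4,3) = 24
assignments per time point.  Ground-truth (or user-supplied) labeled masks
then cut one patch per heterogeneity out of each fused frame, and the
bookkeeping helpers compute how many frames each preprocessing branch
contributes to the four pseudo-color datasets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "ChannelAssignment",
    "AcquisitionPlan",
    "DatasetCounts",
    "channel_assignments",
    "fuse_pseudocolor",
    "crop_by_mask",
    "dataset_counts",
    "split_dataset",
]


@dataclass(frozen=True)
class ChannelAssignment:
    """Which wavelength fills each RGB channel of a pseudo-color image."""

    red: str
    green: str
    blue: str

    def __post_init__(self) -> None:
        if len({self.red, self.green, self.blue}) != 3:
            raise ValueError("channel assignment labels must be pairwise distinct")

    @property
    def labels(self) -> Tuple[str, str, str]:
        return (self.red, self.green, self.blue)


def channel_assignments(wavelengths: Sequence[str]) -> List[ChannelAssignment]:
    """All ordered selections of 3 wavelengths from ``n``: n*(n-1)*(n-2) of them.

    Deterministic lexicographic order over the input ordering, so repeated
    calls (and repeated runs) enumerate identically.
    """
    labels = list(wavelengths)
    if len(labels) != len(set(labels)):
        raise ValueError("wavelength labels must be distinct")
    if len(labels) < 3:
        raise ValueError("need at least 3 wavelengths for RGB fusion")
    return [
        ChannelAssignment(red=r, green=g, blue=b)
        for r, g, b in itertools.permutations(labels, 3)
    ]


def fuse_pseudocolor(
    frames_by_wavelength: Mapping[str, np.ndarray],
    assignment: ChannelAssignment,
    normalize: str = "bitdepth",
    max_val: float = 255.0,
) -> np.ndarray:
    """Fuse three wavelength images into an (H, W, 3) float image in [0, 1].

    ``normalize='bitdepth'`` divides by ``max_val`` (radiometry stays
    comparable across combinations); ``'per_channel_minmax'`` stretches each
    channel to span [0, 1] exactly (display parity; a constant channel maps
    to zeros).
    """
    if normalize not in ("bitdepth", "per_channel_minmax"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    channels = []
    shape = None
    for label in assignment.labels:
        if label not in frames_by_wavelength:
            raise ValueError(f"missing wavelength {label!r} in input")
        img = np.asarray(frames_by_wavelength[label], dtype=np.float64)
        if img.ndim != 2:
            raise ValueError(f"wavelength {label!r}: expected a 2-D image")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"shape mismatch: {label!r} is {img.shape}, expected {shape}"
            )
        channels.append(img)

    out = np.empty((*shape, 3), dtype=np.float64)
    for c, img in enumerate(channels):
        if normalize == "bitdepth":
            out[..., c] = np.clip(img / max_val, 0.0, 1.0)
        else:
            lo, hi = float(img.min()), float(img.max())
            out[..., c] = (img - lo) / (hi - lo) if hi > lo else 0.0
    return out


def crop_by_mask(
    image: np.ndarray,
    labeled_mask: np.ndarray,
    pad_px: int = 0,
) -> List[Tuple[int, np.ndarray]]:
    """Cut one patch per nonzero mask label from ``image``.

    Each patch is the label's tight bounding box expanded by ``pad_px`` and
    clipped to the image bounds; pixels inside the patch that belong to
    another label (or the background) are zeroed.  Returns ``(label, patch)``
    pairs in ascending label order; an empty mask yields an empty list with
    a warning.
    """
    image = np.asarray(image)
    labeled_mask = np.asarray(labeled_mask)
    if labeled_mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {labeled_mask.shape} does not match image {image.shape[:2]}"
        )
    if pad_px < 0:
        raise ValueError("pad_px must be >= 0")
    labels = np.unique(labeled_mask)
    labels = labels[labels != 0]
    if labels.size == 0:
        warnings.warn("empty mask: no patches produced", stacklevel=2)
        return []
    H, W = labeled_mask.shape
    patches = []
    for label in labels:
        rows, cols = np.nonzero(labeled_mask == label)
        r0 = max(int(rows.min()) - pad_px, 0)
        r1 = min(int(rows.max()) + 1 + pad_px, H)
        c0 = max(int(cols.min()) - pad_px, 0)
        c1 = min(int(cols.max()) + 1 + pad_px, W)
        patch = image[r0:r1, c0:c1].astype(np.float64, copy=True)
        keep = labeled_mask[r0:r1, c0:c1] == label
        patch[~keep] = 0
        patches.append((int(label), patch))
    return patches


# ---------------------------------------------------------------------------
# Acquisition bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionPlan:
    """The acquisition campaign layout: wavelengths x phantom configs x conditions.

    One "set" is a stack of ``frames_per_set`` frames for one wavelength,
    one phantom configuration and one illumination condition; the default
    plan (4 wavelengths, 5 configurations, unmodulated + two carriers,
    1,200 frames, 12-frame accumulation window) is the full campaign.
    """

    n_wavelengths: int = 4
    n_configs: int = 5
    conditions: Tuple[str, ...] = ("unmodulated", "mod_3p5", "mod_4")
    frames_per_set: int = 1200
    fa_window: int = 12

    def __post_init__(self) -> None:
        if self.n_wavelengths < 1 or self.n_configs < 1 or self.frames_per_set < 1:
            raise ValueError("plan dimensions must be positive")
        if self.fa_window < 1:
            raise ValueError("fa_window must be positive")
        if len(self.conditions) != len(set(self.conditions)):
            raise ValueError("conditions must be distinct")

    @property
    def total_sets(self) -> int:
        return self.n_wavelengths * self.n_configs * len(self.conditions)


@dataclass(frozen=True)
class DatasetCounts:
    """Frame totals per preprocessing branch and per pseudo-color dataset."""

    total_raw_frames: int
    fa_frames: int
    md_frames: int
    mdfa_frames: int
    pseudo_original: int
    pseudo_fa: int
    pseudo_md: int
    pseudo_mdfa: int

    def as_dict(self) -> Dict[str, int]:
        return {
            "total_raw_frames": self.total_raw_frames,
            "fa_frames": self.fa_frames,
            "md_frames": self.md_frames,
            "mdfa_frames": self.mdfa_frames,
            "pseudo_original": self.pseudo_original,
            "pseudo_fa": self.pseudo_fa,
            "pseudo_md": self.pseudo_md,
            "pseudo_mdfa": self.pseudo_mdfa,
        }


def dataset_counts(plan: AcquisitionPlan) -> DatasetCounts:
    """Frame bookkeeping for an acquisition plan (pure arithmetic).

    The FA branch runs on the unmodulated sets; demodulation runs on the
    modulated sets and preserves frame count; the combined branch then
    accumulates the demodulated frames over ``fa_window``.  Each pseudo-color
    dataset holds (branch frames / n_wavelengths) per-time-point slots times
    the number of ordered 3-channel assignments; the original pseudo-color
    dataset is built from the unmodulated branch.
    """
    n_wl = plan.n_wavelengths
    unmod_sets = n_wl * plan.n_configs if "unmodulated" in plan.conditions else 0
    n_mod_conditions = sum(1 for c in plan.conditions if c != "unmodulated")
    mod_sets = n_wl * plan.n_configs * n_mod_conditions

    total_raw = plan.total_sets * plan.frames_per_set
    fa = unmod_sets * (plan.frames_per_set // plan.fa_window)
    md = mod_sets * plan.frames_per_set
    mdfa = mod_sets * (plan.frames_per_set // plan.fa_window)

    n_assign = n_wl * (n_wl - 1) * (n_wl - 2) if n_wl >= 3 else 0

    def pseudo(branch_frames: int) -> int:
        return (branch_frames // n_wl) * n_assign

    return DatasetCounts(
        total_raw_frames=total_raw,
        fa_frames=fa,
        md_frames=md,
        mdfa_frames=mdfa,
        pseudo_original=pseudo(unmod_sets * plan.frames_per_set),
        pseudo_fa=pseudo(fa),
        pseudo_md=pseudo(md),
        pseudo_mdfa=pseudo(mdfa),
    )


# ---------------------------------------------------------------------------
# Train / validation / test split
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, ratios: Sequence[float]) -> List[int]:
    """Apportion ``n`` items to ratio buckets exactly (largest remainder)."""
    quotas = [n * r for r in ratios]
    counts = [int(q) for q in quotas]
    leftover = n - sum(counts)
    remainders = sorted(
        range(len(ratios)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:leftover]:
        counts[i] += 1
    return counts


def split_dataset(
    labels: Sequence[int],
    seed: int,
    ratios: Tuple[float, float, float] = (0.6, 0.1, 0.3),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified 6:1:3 train/validation/test split, seed-deterministic.

    Returns three disjoint, exhaustive index arrays into ``labels``.  Within
    each class the per-split sizes are the largest-remainder apportionment
    of the ratios (exact and deterministic, so 100 one-class items split
    60/10/30).  A class with fewer than 3 members cannot be stratified; it
    is kept whole in the training split with a warning.
    """
    labels = np.asarray(labels)
    if labels.size < 10:
        raise ValueError("need at least 10 items to split 6:1:3")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        if idx.size < 3:
            warnings.warn(
                f"class {cls!r} has {idx.size} member(s); kept whole in train",
                stacklevel=2,
            )
            train.extend(idx.tolist())
            continue
        n_train, n_val, n_test = _largest_remainder(idx.size, ratios)
        train.extend(idx[:n_train].tolist())
        val.extend(idx[n_train : n_train + n_val].tolist())
        test.extend(idx[n_train + n_val :].tolist())
    return (
        np.array(sorted(train), dtype=np.int64),
        np.array(sorted(val), dtype=np.int64),
        np.array(sorted(test), dtype=np.int64),
    )
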