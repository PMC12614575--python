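"""Image-quality metrics used to quantify preprocessing gains.

The SNR here is a single-image statistic in decibels,

    SNR = 10 * log10( sum f(i,j)^2 / sum (f(i,j) - mean(f))^2 ),

i.e. total signal power over deviation-from-mean power: it rewards noise
suppression relative to the retained signal level, independent of any
reference image.  MSE and PSNR are the usual reference-based measures;
PSNR's peak value defaults to ``2**bit_depth - 1`` of the reference stack
since a peak is otherwise undefined for float images.

A constant image has zero deviation power, so its SNR is reported as an
infinite flagged value rather than raising — batch sweeps over many
wavelength/condition cells must not abort on one degenerate cell.  The same
convention applies to the PSNR of an identical pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QualityReport",
    "snr_db",
    "mse",
    "psnr_db",
    "percent_snr_increase",
    "write_report_csv",
    "read_report_csv",
]

REPORT_COLUMNS = ("image_id", "reference_id", "snr_db", "mse", "psnr_db")


@dataclass(frozen=True)
class QualityReport:
    """One row of a Table-1-style quality sweep.

    ``image_id``/``reference_id`` label the processed image and its
    reference (e.g. condition and wavelength); before/after columns are two
    rows sharing a reference, not separate formulas.  ``psnr_db`` and
    ``snr_db`` may be ``inf`` (flagged degenerate cases).
    """

    image_id: str
    reference_id: str
    snr_db: float
    mse: float
    psnr_db: float


def snr_db(img: np.ndarray) -> float:
    """Single-image SNR in dB: signal power over deviation-from-mean power.

    Scale-invariant (``snr_db(c*f) == snr_db(f)`` for c > 0).  A constant
    nonzero image returns ``inf`` (flagged, not an exception); an all-zero
    image has no defined signal and raises ``ValueError``.
    """
    f = np.asarray(img, dtype=np.float64)
    if f.size < 2:
        raise ValueError("image must have at least 2 pixels")
    signal_power = float(np.sum(f * f))
    if signal_power == 0.0:
        raise ValueError("all-zero image: SNR undefined")
    noise_power = float(np.sum((f - f.mean()) ** 2))
    if noise_power == 0.0:
        return math.inf
    return 10.0 * math.log10(signal_power / noise_power)


def mse(processed: np.ndarray, reference: np.ndarray) -> float:
    """Mean squared pixel difference between two equal-shape images."""
    a = np.asarray(processed, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr_db(processed: np.ndarray, reference: np.ndarray, max_val: float = 255.0) -> float:
    """Peak SNR in dB: ``10*log10(max_val**2 / MSE)``, ``inf`` when MSE is 0.

    ``max_val`` should be ``2**bit_depth - 1`` of the reference stack
    (255 for 8-bit); override it for float imagery with a known peak.
    """
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    err = mse(processed, reference)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val * max_val / err)


def percent_snr_increase(snr_before: float, snr_after: float) -> float:
    """Relative SNR change in percent: ``100*(after - before)/before``."""
    if snr_before == 0:
        raise ValueError("zero baseline SNR: percent increase undefined")
    return 100.0 * (snr_after - snr_before) / snr_before


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def write_report_csv(reports: Sequence[QualityReport], path) -> None:
    """Write quality rows as CSV; infinities serialize as 'inf'."""
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "reference_id": r.reference_id,
                "snr_db": r.snr_db,
                "mse": r.mse,
                "psnr_db": r.psnr_db,
            }
            for r in reports
        ],
        columns=list(REPORT_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_report_csv(path) -> List[QualityReport]:
    df = pd.read_csv(path)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report CSV missing columns: {sorted(missing)}")
    return [
        QualityReport(
            image_id=str(row.image_id),
            reference_id=str(row.reference_id),
            snr_db=float(row.snr_db),
            mse=float(row.mse),
            psnr_db=float(row.psnr_db),
        )
        for row in df.itertuples(index=False)
    ]
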