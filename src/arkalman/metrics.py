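"""Denoising quality measures over (clean, estimate) signal pairs.

All metrics take the known clean signal and a denoised estimate of equal
length:

* ``rmse``   — root mean square error, in signal units.
* ``snr_db`` — 10 log10 of clean-signal energy over error energy, in dB.
* ``mape``   — mean absolute percentage error over samples whose clean
  amplitude is above a small relative floor (EMG crosses zero constantly,
  so an unfloored MAPE diverges).
* ``local_similarity_mean`` — mean over sliding windows of the Pearson
  correlation between the two signals; sensitive to coherent signal
  energy lost to the removed-noise estimate.  This is a windowed-
  correlation summary, not the shaping-regularisation similarity map
  some denoising work uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal import Signal

logger = logging.getLogger(__name__)

#: samples with |clean| below this fraction of max|clean| are excluded
#: from the MAPE average
MAPE_REL_FLOOR = 1e-3

DEFAULT_WINDOW = 64
DEFAULT_HOP = 32


class MetricError(ValueError):
    """Metric undefined for these inputs."""


def _pair(clean: Signal | np.ndarray,
          estimate: Signal | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = clean.samples if isinstance(clean, Signal) else np.asarray(clean, float)
    b = (estimate.samples if isinstance(estimate, Signal)
         else np.asarray(estimate, float))
    if a.shape != b.shape:
        raise MetricError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(clean: Signal | np.ndarray, estimate: Signal | np.ndarray) -> float:
    """Root mean square error; symmetric in its arguments."""
    a, b = _pair(clean, estimate)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def snr_db(clean: Signal | np.ndarray, estimate: Signal | np.ndarray) -> float:
    """Output signal-to-noise ratio 10 log10(sum clean^2 / sum err^2), dB.

    Identical inputs have zero error energy and return ``inf``.
    """
    a, b = _pair(clean, estimate)
    sig = float(a @ a)
    if sig == 0.0:
        raise MetricError("clean signal has zero energy; SNR undefined")
    err = float((a - b) @ (a - b))
    if err == 0.0:
        return float("inf")
    return 10.0 * np.log10(sig / err)


def mape(clean: Signal | np.ndarray, estimate: Signal | np.ndarray,
         rel_floor: float = MAPE_REL_FLOOR) -> float:
    """Mean absolute percentage error, in percent.

    Samples with |clean| below ``rel_floor * max|clean|`` are excluded
    from the average.
    """
    a, b = _pair(clean, estimate)
    floor = rel_floor * float(np.max(np.abs(a)))
    mask = np.abs(a) >= floor
    if floor == 0.0 or not mask.any():
        raise MetricError("all clean samples below the amplitude floor; "
                          "MAPE undefined")
    return float(100.0 * np.mean(np.abs(a[mask] - b[mask]) / np.abs(a[mask])))


def local_similarity_mean(clean: Signal | np.ndarray,
                          estimate: Signal | np.ndarray,
                          window: int = DEFAULT_WINDOW,
                          hop: int = DEFAULT_HOP) -> float:
    """Mean windowed Pearson correlation between two signals.

    Windows of ``window`` samples are taken every ``hop`` samples;
    windows where either signal is constant (zero variance) are skipped
    with a logged count.  The result lies in [-1, 1].
    """
    a, b = _pair(clean, estimate)
    if window > a.size:
        raise MetricError(f"window {window} exceeds signal length {a.size}")
    if hop < 1:
        raise MetricError(f"hop must be >= 1, got {hop}")
    corrs = []
    skipped = 0
    for start in range(0, a.size - window + 1, hop):
        wa = a[start:start + window]
        wb = b[start:start + window]
        sa, sb = wa.std(), wb.std()
        if sa == 0.0 or sb == 0.0:
            skipped += 1
            continue
        corrs.append(float(np.mean((wa - wa.mean()) * (wb - wb.mean()))
                           / (sa * sb)))
    if skipped:
        logger.info("local similarity: skipped %d constant windows", skipped)
    if not corrs:
        raise MetricError("no window had nonzero variance in both signals")
    return float(np.clip(np.mean(corrs), -1.0, 1.0))


@dataclass(frozen=True)
class EvaluationReport:
    """All four quality measures for one (clean, estimate) pair."""

    rmse: float
    snr_db: float
    mape: float
    local_similarity_mean: float

    HEADER = "rmse\tsnr_db\tmape\tlocal_similarity_mean"

    def to_row(self) -> str:
        """One tab-delimited row matching :attr:`HEADER`."""
        return (f"{self.rmse:.6g}\t{self.snr_db:.6g}\t{self.mape:.6g}"
                f"\t{self.local_similarity_mean:.6g}")


def evaluate(clean: Signal | np.ndarray, estimate: Signal | np.ndarray,
             window: int = DEFAULT_WINDOW,
             hop: int = DEFAULT_HOP) -> EvaluationReport:
    """Compute all four metrics for a (clean, estimate) pair."""
    return EvaluationReport(
        rmse=rmse(clean, estimate),
        snr_db=snr_db(clean, estimate),
        mape=mape(clean, estimate),
        local_similarity_mean=local_similarity_mean(clean, estimate,
                                                    window=window, hop=hop),
    )
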