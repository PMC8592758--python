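"""Uniformly sampled single-channel biosignals.

The package works on plain real-valued time series with sampling-rate
metadata.  Surface EMG is the motivating signal (microvolt amplitudes,
useful energy roughly 10-500 Hz, typically sampled at 1000 Hz), but
nothing here is EMG-specific.

On disk a signal is delimited text: one sample per line, with an optional
``# fs=<Hz>`` comment header.  A file without the header is read at the
default 1000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_FS = 1000.0


class SignalError(ValueError):
    """Invalid signal content (too short, non-finite, bad sampling rate)."""


@dataclass(frozen=True)
class Signal:
    """A finite, uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        Sample values in signal units (e.g. microvolts).  Must contain at
        least two finite values.
    fs
        Sampling rate in Hz, strictly positive.  Defaults to 1000 Hz.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", samples)
        if samples.size < 2:
            raise SignalError(f"signal needs >= 2 samples, got {samples.size}")
        if not np.all(np.isfinite(samples)):
            raise SignalError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise SignalError(f"sampling rate must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Signal":
        """Return a new signal with the same metadata and new samples."""
        return Signal(samples=np.asarray(samples, dtype=float), fs=self.fs,
                      meta=dict(self.meta))


def read_signal(path: str | Path, fs: float | None = None) -> Signal:
    """Read a signal from delimited text (one sample per line).

    Lines starting with ``#`` are comments; a ``# fs=<Hz>`` comment sets
    the sampling rate.  An explicit ``fs`` argument overrides the header;
    with neither, the default 1000 Hz applies.
    """
    path = Path(path)
    header_fs = None
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("fs"):
                    try:
                        header_fs = float(body.split("=", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise SignalError(
                            f"{path}:{lineno}: malformed fs header {line!r}"
                        ) from exc
                continue
            try:
                values.append(float(line.split()[0]))
            except ValueError as exc:
                raise SignalError(
                    f"{path}:{lineno}: not a number: {line!r}") from exc
    if fs is None:
        fs = header_fs if header_fs is not None else DEFAULT_FS
    return Signal(samples=np.array(values), fs=fs)


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write a signal as delimited text with a ``# fs=`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={signal.fs:g}\n")
        for v in signal.samples:
            fh.write(f"{v:.10g}\n")
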