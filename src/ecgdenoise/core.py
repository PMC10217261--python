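"""Core containers shared across the pipeline.

A :class:`Signal` is the universal currency of the package: a uniformly
sampled, finite, real-valued series (amplitudes in mV) together with its
sampling rate in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Signal"]


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled single-channel time series.

    Parameters
    ----------
    samples:
        Real amplitudes in millivolts. Must contain at least two finite
        values.
    fs:
        Sampling rate in Hz, strictly positive.
    label:
        Free-text identifier carried through the pipeline (e.g. the source
        record name).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"samples must be one-dimensional, got shape {arr.shape}")
        if arr.size < 2:
            raise ValueError(f"a signal needs at least 2 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values (NaN or inf)")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be a positive finite number, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds; sample i occurs at t = i / fs."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "Signal":
        """Return a copy with replaced samples (fs preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       label=self.label if label is None else label)

    def power(self) -> float:
        """Mean squared amplitude (mV^2)."""
        return float(np.mean(self.samples ** 2))
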