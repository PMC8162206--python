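"""Core domain types and exceptions shared across the package.

The cosine convention used everywhere is ``x[n] = A * cos(2*pi*f*n/fs + phi)``:
a sinusoid is the triple (frequency in Hz, amplitude in signal units, initial
phase in radians), and sample ``n`` corresponds to time ``n / fs`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArspecError",
    "NyquistError",
    "RankDeficientError",
    "ConvergenceError",
    "SignalFormatError",
    "DivergenceWarning",
    "SinusoidComponent",
    "SignalRecord",
]


class ArspecError(ValueError):
    """Base class for all rejected preconditions in this package."""


class NyquistError(ArspecError):
    """A component frequency is at or above half the sampling rate."""


class RankDeficientError(ArspecError):
    """The lagged design matrix does not have full column rank."""


class ConvergenceError(ArspecError):
    """Iterative training diverged (loss exceeded the divergence guard)."""


class SignalFormatError(ArspecError):
    """A signal file could not be parsed or failed validation."""


class DivergenceWarning(UserWarning):
    """An AR model has a characteristic root outside the unit circle."""


@dataclass(frozen=True)
class SinusoidComponent:
    """One harmonic term: ``amplitude * cos(2*pi*frequency*t + phase)``.

    The Nyquist check (frequency < fs/2) is deferred to generation time,
    because a component carries no sampling rate of its own.
    """

    frequency: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.frequency) or self.frequency < 0:
            raise ArspecError(f"frequency must be finite and >= 0, got {self.frequency}")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ArspecError(f"amplitude must be finite and >= 0, got {self.amplitude}")
        if not np.isfinite(self.phase):
            raise ArspecError("phase must be finite")

    def check_nyquist(self, fs: float) -> None:
        if self.frequency >= fs / 2:
            raise NyquistError(
                f"component frequency {self.frequency} Hz is at or above "
                f"Nyquist ({fs / 2} Hz for fs={fs} Hz)"
            )


@dataclass
class SignalRecord:
    """A uniformly sampled real-valued series with its sampling rate.

    ``samples[n]`` is the value at time ``n / fs``; the record length ``L``
    is ``len(samples)``.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ArspecError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ArspecError("samples must all be finite")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ArspecError(f"sampling rate must be positive, got {self.fs}")
        self.samples = arr

    def __len__(self) -> int:
        return self.samples.size

    @property
    def L(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total sampling interval T = L / fs in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs
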