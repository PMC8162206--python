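"""Synthetic multi-sinusoid, power-line and biosignal-template generators.

Every downstream stage (AR fitting, spectrum correction, interference
removal) is exercised on signals from this module, so all generation is
deterministic given its arguments: noise flows through a mandatory seed and
the noiseless part is an exact analytic evaluation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .types import ArspecError, SignalRecord, SinusoidComponent

__all__ = [
    "generate_msw",
    "generate_powerline",
    "generate_biosignal_template",
]


def generate_msw(
    components: Iterable[SinusoidComponent],
    fs: float,
    n_samples: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SignalRecord:
    """Sum of cosines ``A*cos(2*pi*f*n/fs + phi)`` plus optional white noise.

    Parameters
    ----------
    components
        Harmonic terms; each frequency must be strictly below ``fs / 2``.
    fs
        Sampling rate in Hz.
    n_samples
        Number of samples to generate (>= 1).
    noise_sigma
        Standard deviation of additive i.i.d. Gaussian noise; 0 gives the
        exact analytic sum.
    seed
        Seed for the noise generator; two calls with identical arguments are
        bit-identical.
    """
    if n_samples < 1:
        raise ArspecError("n_samples must be >= 1")
    if noise_sigma < 0:
        raise ArspecError("noise_sigma must be >= 0")
    components = list(components)
    for c in components:
        c.check_nyquist(fs)
    n = np.arange(int(n_samples))
    x = np.zeros(int(n_samples))
    for c in components:
        x += c.amplitude * np.cos(2.0 * np.pi * c.frequency * n / fs + c.phase)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sigma, size=int(n_samples))
    return SignalRecord(x, fs)


def generate_powerline(
    line_freq: float,
    amplitude: float,
    phase: float,
    fs: float,
    n_samples: int,
) -> SignalRecord:
    """A single noiseless interference tone (e.g. 50/60 Hz mains pickup)."""
    comp = SinusoidComponent(line_freq, amplitude, phase)
    return generate_msw([comp], fs, n_samples, noise_sigma=0.0)


def generate_biosignal_template(
    heart_rate_bpm: float,
    bump_params: Sequence[tuple[float, float, float]],
    fs: float,
    n_samples: int,
) -> SignalRecord:
    """Periodic ECG-like host signal built from Gaussian bumps.

    Each beat of period ``60 / heart_rate_bpm`` seconds carries one Gaussian
    bump per ``(center_fraction, width_s, height)`` triple: the bump peaks at
    ``center_fraction`` of the way through the beat, with standard deviation
    ``width_s`` seconds and peak value ``height``. Distances are measured
    circularly within the beat, so the result is exactly periodic with the
    beat period. This is a morphological stand-in for demos and tests, not a
    physiological ECG model.
    """
    if heart_rate_bpm <= 0:
        raise ArspecError("heart_rate_bpm must be positive")
    if n_samples < 1:
        raise ArspecError("n_samples must be >= 1")
    for center, width, _height in bump_params:
        if not 0 <= center < 1:
            raise ArspecError(f"center_fraction must be in [0, 1), got {center}")
        if width <= 0:
            raise ArspecError(f"bump width must be positive, got {width}")
    period_samples = 60.0 * fs / heart_rate_bpm
    n = np.arange(int(n_samples))
    pos = np.mod(n, period_samples)  # position within the beat, in samples
    x = np.zeros(int(n_samples))
    for center, width, height in bump_params:
        center_samp = center * period_samples
        d = np.abs(pos - center_samp)
        d = np.minimum(d, period_samples - d)  # circular distance
        x += height * np.exp(-0.5 * (d / (width * fs)) ** 2)
    return SignalRecord(x, fs)
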