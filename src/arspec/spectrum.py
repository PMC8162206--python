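"""FFT spectra with explicit resolution semantics, peak detection and
picket-fence (leakage) correction.

The discrete spectrum of an N-sample record has lines spaced at the
resolution ``df = fs / N`` — the reciprocal of the total sampling interval.
A tone whose frequency is not an integer multiple of ``df`` (non-full-period
sampling) leaks energy across neighbouring bins: the picket fence effect.
:func:`correct_peak` recovers the tone's true frequency, amplitude and phase
from between the bins, using the adjacent-bin ratio of the rectangular
window's Dirichlet-kernel leakage to locate the tone and a least-squares
cosine fit to read off amplitude and phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import windows as _windows

from .types import ArspecError, SignalRecord

__all__ = [
    "Spectrum",
    "PeakEstimate",
    "compute_spectrum",
    "spectral_resolution",
    "detect_peaks",
    "correct_peak",
]

#: Window identifier -> callable returning N window samples (peak value 1).
WINDOWS = {
    "rectangular": lambda n: np.ones(n),
    "hann": lambda n: _windows.hann(n, sym=False),
    "hamming": lambda n: _windows.hamming(n, sym=False),
}


@dataclass
class Spectrum:
    """Unnormalised DFT coefficients of a (windowed) real record.

    Bin ``k`` maps to frequency ``k * fs / N``; the resolution is
    ``fs / N``. The pre-window source samples are retained so that peak
    correction can re-estimate amplitude and phase from the data itself.
    """

    coefficients: np.ndarray
    fs: float
    window: str = "rectangular"
    samples: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.coefficients.size

    @property
    def resolution(self) -> float:
        """Bin spacing ``fs / N`` in Hz."""
        return self.fs / self.N

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.N) * self.fs / self.N

    def one_sided_amplitude(self) -> np.ndarray:
        """Amplitude reading ``2|X_k|/N`` for ``0 < k < N/2``, ``|X_0|/N`` at DC.

        Returns bins ``0 .. floor(N/2)`` (the Nyquist bin, when present, is
        also scaled by ``1/N``).
        """
        half = self.N // 2
        mag = np.abs(self.coefficients[: half + 1]) * (2.0 / self.N)
        mag[0] /= 2.0
        if self.N % 2 == 0:
            mag[half] /= 2.0
        return mag


@dataclass
class PeakEstimate:
    """A spectral peak with fractional-bin offset and corrected parameters.

    ``frequency = (bin_index + fractional_offset) * fs / N``; the phase
    follows the package's cosine convention and lies in ``(-pi, pi]``.
    """

    bin_index: int
    fractional_offset: float
    frequency: float
    amplitude: float
    phase: float


def compute_spectrum(signal: SignalRecord, window: str = "rectangular") -> Spectrum:
    """Unnormalised DFT of the windowed record (``X_0 = N`` for all-ones input)."""
    if signal.L < 2:
        raise ArspecError("need at least 2 samples for a spectrum")
    try:
        win = WINDOWS[window](signal.L)
    except KeyError:
        raise ArspecError(
            f"unknown window {window!r}: expected one of {sorted(WINDOWS)}"
        ) from None
    coeffs = np.fft.fft(signal.samples * win)
    return Spectrum(coeffs, signal.fs, window=window, samples=signal.samples)


def spectral_resolution(n: int, fs: float) -> float:
    """Bin spacing of an n-sample spectrum: the reciprocal of the total
    sampling interval, ``fs / n`` Hz."""
    if n < 1:
        raise ArspecError("n must be >= 1")
    if fs <= 0:
        raise ArspecError("fs must be positive")
    return fs / n


def detect_peaks(
    spectrum: Spectrum,
    rel_threshold: float = 0.05,
    min_separation_bins: int = 1,
) -> list[int]:
    """Strict local maxima of the one-sided magnitude above a relative floor.

    Considers bins ``1 .. floor(N/2) - 1`` (DC and Nyquist excluded).
    Candidates must be strict local maxima, exceed ``rel_threshold`` times
    the global maximum over that range, and be kept greedily by descending
    magnitude subject to pairwise separation of at least
    ``min_separation_bins``. Returned sorted ascending by bin.
    """
    if not 0 < rel_threshold < 1:
        raise ArspecError("rel_threshold must be in (0, 1)")
    if min_separation_bins < 1:
        raise ArspecError("min_separation_bins must be >= 1")
    half = spectrum.N // 2
    if half < 2:
        return []
    mag = np.abs(spectrum.coefficients[: half + 1])
    band = mag[1:half]
    peak_floor = rel_threshold * band.max() if band.size else 0.0
    if peak_floor == 0.0 and band.size and band.max() == 0.0:
        return []
    candidates = [
        k
        for k in range(1, half)
        if mag[k] > mag[k - 1] and mag[k] > mag[k + 1] and mag[k] > peak_floor
    ]
    candidates.sort(key=lambda k: mag[k], reverse=True)
    kept: list[int] = []
    for k in candidates:
        if all(abs(k - j) >= min_separation_bins for j in kept):
            kept.append(k)
    return sorted(kept)


def _sinusoid_ls(x: np.ndarray, fs: float, freq: float) -> tuple[float, float, float]:
    """Least-squares fit of ``a cos(w n) + b sin(w n)``; returns (A, phi, rss)."""
    n = np.arange(x.size)
    w = 2.0 * np.pi * freq / fs
    basis = np.column_stack([np.cos(w * n), np.sin(w * n)])
    coef, _res, _rank, _sv = np.linalg.lstsq(basis, x, rcond=None)
    a, b = coef
    rss = float(np.sum((basis @ coef - x) ** 2))
    amplitude = float(np.hypot(a, b))
    phase = float(np.arctan2(-b, a))
    if phase <= -np.pi:
        phase += 2.0 * np.pi
    return amplitude, phase, rss


def correct_peak(spectrum: Spectrum, k: int) -> PeakEstimate:
    """Estimate the true tone behind peak bin ``k`` of a rectangular spectrum.

    The adjacent-bin ratio of the Dirichlet leakage kernel gives the initial
    fractional offset: with ``beta = |X_{k+1}| / |X_k|`` when the right
    neighbour dominates (ties resolve toward the higher bin), the tone sits
    at ``delta = beta / (1 + beta)`` bins above ``k``, and symmetrically to
    the left. The offset is then polished by minimising, over one bin width,
    the residual of a two-parameter cosine/sine least-squares fit to the
    source samples; the same fit at the final frequency supplies amplitude
    and phase. For a noiseless single tone this is exact to solver
    tolerance.
    """
    if spectrum.window != "rectangular":
        raise ArspecError("peak correction is defined for the rectangular window only")
    if spectrum.samples is None:
        raise ArspecError("spectrum does not carry its source samples")
    half = spectrum.N // 2
    if not 1 <= k <= half - 1:
        raise ArspecError(f"bin {k} outside correctable range 1..{half - 1}")
    mag = np.abs(spectrum.coefficients)
    if mag[k] == 0:
        raise ArspecError(f"bin {k} has zero magnitude: not a peak")
    df = spectrum.resolution
    # ratio estimate; tie between neighbours resolves toward the higher bin
    if mag[k + 1] >= mag[k - 1]:
        beta = mag[k + 1] / mag[k]
        delta0 = beta / (1.0 + beta)
    else:
        beta = mag[k - 1] / mag[k]
        delta0 = -beta / (1.0 + beta)

    x = spectrum.samples
    fs = spectrum.fs
    res = minimize_scalar(
        lambda f: _sinusoid_ls(x, fs, f)[2],
        bounds=((k - 0.5) * df, (k + 0.5) * df),
        method="bounded",
        options={"xatol": 1e-11 * df},
    )
    freq = float(res.x)
    if not np.isfinite(freq):  # optimiser failure: keep the ratio estimate
        freq = (k + delta0) * df
    # a full-period tone sits exactly on the bin centre; prefer it whenever
    # it explains the data at least as well as the polished offset
    if _sinusoid_ls(x, fs, k * df)[2] <= _sinusoid_ls(x, fs, freq)[2]:
        freq = k * df
    delta = float(np.clip(freq / df - k, -0.5, 0.5))
    freq = (k + delta) * df
    amplitude, phase, _rss = _sinusoid_ls(x, fs, freq)
    return PeakEstimate(
        bin_index=k,
        fractional_offset=delta,
        frequency=freq,
        amplitude=amplitude,
        phase=phase,
    )
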