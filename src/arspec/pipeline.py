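"""End-to-end super-resolution and interference-removal procedures.

The core procedure: fit an AR model to the recorded series by least squares,
extrapolate additional samples so the effective sampling interval — and
hence the FFT resolution — grows by the extension factor, recompute the
spectrum of the lengthened series, and correct each detected peak for
between-bin leakage. Tones whose spacing is below the raw resolution merge
into one raw-spectrum peak but separate in the extended spectrum.

Interference removal applies the same machinery to identify the harmonic
parameters of in-band components (typically 50/60 Hz power-line pickup),
synthesises a compensation signal from the estimates, and subtracts it from
the original measurement.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ar_engine import ARModel, characteristic_roots, extrapolate, fit_ar_bp, fit_ar_lms
from .spectrum import PeakEstimate, Spectrum, compute_spectrum, correct_peak, detect_peaks
from .types import ArspecError, DivergenceWarning, NyquistError, SignalRecord

__all__ = [
    "PeakOptions",
    "ResolutionReport",
    "resolve_msw",
    "build_compensation",
    "remove_interference",
]

logger = logging.getLogger("arspec")


@dataclass(frozen=True)
class PeakOptions:
    """Detection thresholds shared by the raw and extended passes."""

    rel_threshold: float = 0.05
    min_separation_bins: int = 1


@dataclass
class ResolutionReport:
    """Peak lists and resolutions before and after AR extension."""

    raw_peaks: list[PeakEstimate]
    extended_peaks: list[PeakEstimate]
    raw_resolution: float
    extended_resolution: float
    extension_factor: float
    model: ARModel
    warnings: list[str] = field(default_factory=list)


def resolve_msw(
    signal: SignalRecord,
    p: int,
    extension_factor: float = 10.0,
    peak_options: PeakOptions | None = None,
    include_intercept: bool = False,
    trainer: str = "lms",
    **trainer_kwargs,
) -> ResolutionReport:
    """Fit, extrapolate, and re-analyse a record at higher resolution.

    The extended series has ``ceil(extension_factor * L)`` samples in total;
    the reported ``extension_factor`` is the realised ratio, so
    ``extended_resolution == raw_resolution / extension_factor`` holds
    exactly. Peak detection and leakage correction run on both the raw and
    the extended spectrum with the same options.
    """
    if extension_factor < 1:
        raise ArspecError("extension_factor must be >= 1")
    opts = peak_options or PeakOptions()
    if trainer == "lms":
        model = fit_ar_lms(signal, p, include_intercept)
    elif trainer == "bp":
        model = fit_ar_bp(signal, p, include_intercept=include_intercept, **trainer_kwargs)
    else:
        raise ArspecError(f"unknown trainer {trainer!r}: expected 'lms' or 'bp'")
    total = math.ceil(extension_factor * signal.L)
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DivergenceWarning)
        extended = extrapolate(model, signal, total - signal.L)
    notes.extend(str(w.message) for w in caught if issubclass(w.category, DivergenceWarning))

    raw_spec = compute_spectrum(signal)
    ext_spec = compute_spectrum(extended)
    raw_peaks = [
        correct_peak(raw_spec, k)
        for k in detect_peaks(raw_spec, opts.rel_threshold, opts.min_separation_bins)
    ]
    ext_peaks = [
        correct_peak(ext_spec, k)
        for k in detect_peaks(ext_spec, opts.rel_threshold, opts.min_separation_bins)
    ]
    realised = extended.L / signal.L
    logger.debug(
        "resolve_msw: p=%d L=%d extended=%d rss=%.3g root moduli=%s "
        "raw peaks=%d extended peaks=%d",
        p, signal.L, extended.L, model.training_rss,
        np.round(np.abs(characteristic_roots(model)), 6).tolist(),
        len(raw_peaks), len(ext_peaks),
    )
    return ResolutionReport(
        raw_peaks=raw_peaks,
        extended_peaks=ext_peaks,
        raw_resolution=raw_spec.resolution,
        extended_resolution=ext_spec.resolution,
        extension_factor=realised,
        model=model,
        warnings=notes,
    )


def build_compensation(
    estimates: Iterable[PeakEstimate | object],
    fs: float,
    n_samples: int,
) -> SignalRecord:
    """Synthesise the sum of estimated tones ``A cos(2 pi f n / fs + phi)``.

    Accepts any objects exposing ``frequency``, ``amplitude`` and ``phase``
    attributes (peak estimates or sinusoid components); uses the same cosine
    convention as the generators, so subtracting the compensation from a
    measurement cancels the estimated tones.
    """
    if n_samples < 1:
        raise ArspecError("n_samples must be >= 1")
    n = np.arange(int(n_samples))
    x = np.zeros(int(n_samples))
    for est in estimates:
        f = float(est.frequency)
        if f >= fs / 2:
            raise NyquistError(
                f"estimate frequency {f} Hz at or above Nyquist ({fs / 2} Hz)"
            )
        x += est.amplitude * np.cos(2.0 * np.pi * f * n / fs + est.phase)
    return SignalRecord(x, fs)


def remove_interference(
    signal: SignalRecord,
    band: tuple[float, float],
    p: int,
    extension_factor: float = 10.0,
    peak_options: PeakOptions | None = None,
) -> tuple[SignalRecord, list[PeakEstimate]]:
    """Subtract in-band tones identified on the AR-extended spectrum.

    Runs :func:`resolve_msw`, keeps the extended-spectrum peaks whose
    corrected frequency lies in the closed band ``[f_lo, f_hi]`` (all
    removed jointly — power-line pickup may carry sidebands), synthesises
    their compensation over the original ``L`` samples only, and subtracts
    it. The extension exists solely to sharpen the parameter estimates; the
    subtraction targets the measurement. With no in-band peak the input is
    returned unchanged with an empty removed list.
    """
    f_lo, f_hi = band
    if not 0 <= f_lo < f_hi <= signal.fs / 2:
        raise ArspecError(
            f"band must satisfy 0 <= f_lo < f_hi <= fs/2, got ({f_lo}, {f_hi})"
        )
    report = resolve_msw(signal, p, extension_factor, peak_options)
    removed = [pk for pk in report.extended_peaks if f_lo <= pk.frequency <= f_hi]
    if not removed:
        logger.info("remove_interference: no peak found in band [%g, %g] Hz", f_lo, f_hi)
        return SignalRecord(signal.samples.copy(), signal.fs), []
    comp = build_compensation(removed, signal.fs, signal.L)
    cleaned = SignalRecord(signal.samples - comp.samples, signal.fs)
    logger.debug(
        "remove_interference: removed %d tone(s) at %s Hz",
        len(removed), [round(pk.frequency, 6) for pk in removed],
    )
    return cleaned, removed
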