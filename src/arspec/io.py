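"""Signal, model, report and configuration file formats.

Signal files are plain CSV in one of two dialects: a single column of
sample values (the sampling rate must then come from a flag or config), or
two columns ``(t, x)`` with uniform time spacing from which the rate is
inferred. Comma and whitespace separation and an optional header line are
auto-detected. All numeric output is written with 17 significant digits so
that write/read round-trips are exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ar_engine import ARModel, characteristic_roots
from .pipeline import PeakOptions, ResolutionReport
from .spectrum import PeakEstimate, Spectrum
from .types import ArspecError, SignalFormatError, SignalRecord

__all__ = [
    "read_signal",
    "write_signal",
    "write_model",
    "read_model",
    "write_report",
    "read_report",
    "write_spectrum_csv",
    "RunConfig",
]

#: Relative tolerance for uniformity of an explicit time column.
_T_UNIFORMITY_RTOL = 1e-9
#: Relative tolerance for agreement between a --fs flag and an inferred rate.
_FS_CONFLICT_RTOL = 1e-6


def _sniff(path: Path) -> tuple[str | None, bool]:
    """Return (separator-for-pandas, has_header) for a signal file."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    if not first:
        raise SignalFormatError(f"{path}: file is empty")
    sep = "," if "," in first else r"\s+"
    tokens = [t for t in first.replace(",", " ").split() if t]
    try:
        [float(t) for t in tokens]
        header = False
    except ValueError:
        header = True
    return sep, header


def read_signal(path: str | Path, fs: float | None = None) -> SignalRecord:
    """Read a signal CSV, resolving the sampling rate from flag or time column.

    Raises :class:`SignalFormatError` for non-numeric rows (with the row
    number), a non-uniform time column, a missing rate (single-column file
    without ``fs``), or a conflict between ``fs`` and the inferred rate.
    """
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"{path}: no such file")
    sep, header = _sniff(path)
    df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str,
                     comment=None, skip_blank_lines=True)
    if df.shape[1] not in (1, 2):
        raise SignalFormatError(
            f"{path}: expected 1 or 2 columns, found {df.shape[1]}"
        )
    try:
        # astype(float) parses via the C library strtod and is round-trip exact,
        # unlike pandas' default CSV float path
        numeric = df.astype(float)
    except ValueError:
        for r in range(len(df)):
            for v in df.iloc[r]:
                try:
                    float(v)
                except (TypeError, ValueError):
                    row = r + (2 if header else 1)  # 1-based file line
                    raise SignalFormatError(
                        f"{path}: non-numeric value at data row {row}"
                    ) from None
        raise
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax()) + (2 if header else 1)
        raise SignalFormatError(f"{path}: non-numeric value at data row {row}")
    if df.shape[1] == 1:
        if fs is None:
            raise SignalFormatError(
                f"{path}: single-column file needs an explicit sampling rate"
            )
        return SignalRecord(numeric.iloc[:, 0].to_numpy(), fs)
    t = numeric.iloc[:, 0].to_numpy()
    x = numeric.iloc[:, 1].to_numpy()
    if t.size < 2:
        raise SignalFormatError(f"{path}: need at least 2 rows to infer the rate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise SignalFormatError(f"{path}: time column is not increasing")
    if np.max(np.abs(dt - med)) > _T_UNIFORMITY_RTOL * med:
        raise SignalFormatError(
            f"{path}: time column is not uniformly spaced "
            f"(max deviation {np.max(np.abs(dt - med)):.3g} s from {med:.6g} s)"
        )
    inferred = 1.0 / med
    if fs is not None and abs(fs - inferred) > _FS_CONFLICT_RTOL * inferred:
        raise SignalFormatError(
            f"{path}: sampling-rate flag {fs} Hz conflicts with inferred "
            f"{inferred} Hz from the time column"
        )
    return SignalRecord(x, inferred)


def write_signal(
    record: SignalRecord, path: str | Path, include_time: bool = False
) -> None:
    """Write a signal CSV (single-column, or two-column ``t,x`` on request)."""
    path = Path(path)
    if include_time:
        df = pd.DataFrame({"t": record.times, "x": record.samples})
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        np.savetxt(path, record.samples, fmt="%.17g")


def _model_dict(model: ARModel) -> dict:
    return {
        "order": model.order,
        "intercept": model.intercept,
        "coefficients": model.coefficients.tolist(),
        "training_rss": model.training_rss,
        "root_moduli": np.abs(characteristic_roots(model)).tolist(),
    }


def write_model(model: ARModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_dict(model), fh, indent=2)
        fh.write("\n")


def read_model(path: str | Path) -> ARModel:
    with open(path) as fh:
        d = json.load(fh)
    return ARModel(
        order=int(d["order"]),
        coefficients=np.asarray(d["coefficients"], dtype=float),
        intercept=float(d.get("intercept", 0.0)),
        training_rss=float(d.get("training_rss", 0.0)),
    )


def _peak_dict(pk: PeakEstimate) -> dict:
    return {
        "bin_index": pk.bin_index,
        "fractional_offset": pk.fractional_offset,
        "frequency_hz": pk.frequency,
        "amplitude": pk.amplitude,
        "phase_rad": pk.phase,
    }


def write_report(report: ResolutionReport, path: str | Path) -> None:
    """Serialise a resolution report as JSON with stable key ordering."""
    doc = {
        "raw_resolution_hz": report.raw_resolution,
        "extended_resolution_hz": report.extended_resolution,
        "extension_factor": report.extension_factor,
        "raw_peaks": [_peak_dict(pk) for pk in report.raw_peaks],
        "extended_peaks": [_peak_dict(pk) for pk in report.extended_peaks],
        "model": _model_dict(report.model),
        "warnings": list(report.warnings),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """One-sided spectrum table: bin, frequency, amplitude, phase."""
    half = spectrum.N // 2
    bins = np.arange(half + 1)
    df = pd.DataFrame(
        {
            "bin": bins,
            "frequency_hz": bins * spectrum.fs / spectrum.N,
            "one_sided_amplitude": spectrum.one_sided_amplitude(),
            "phase_rad": np.angle(spectrum.coefficients[: half + 1]),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Analysis settings mirroring the CLI flags; YAML-loadable.

    CLI flags override config-file values; every field is validated against
    the preconditions of the operation it feeds when that operation runs.
    """

    order: int = 4
    intercept: bool = False
    trainer: str = "lms"
    learning_rate: float = 0.01
    epochs: int = 200
    init: str = "zeros"
    seed: int = 0
    extension_factor: float = 10.0
    window: str = "rectangular"
    rel_threshold: float = 0.05
    min_separation_bins: int = 1
    band: tuple[float, float] | None = None
    fs: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ArspecError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ArspecError(f"{path}: unknown config keys {sorted(unknown)}")
        if "band" in data and data["band"] is not None:
            band = data["band"]
            if not (isinstance(band, (list, tuple)) and len(band) == 2):
                raise ArspecError(f"{path}: band must be a [f_lo, f_hi] pair")
            data["band"] = (float(band[0]), float(band[1]))
        return cls(**data)

    def peak_options(self) -> PeakOptions:
        return PeakOptions(
            rel_threshold=self.rel_threshold,
            min_separation_bins=self.min_separation_bins,
        )
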