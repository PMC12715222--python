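"""Welch power spectra, normalization schemes and band power.

PSDs are estimated with Welch's method (2048-sample segments, Hann taper,
1024-point overlap; ~0.488 Hz resolution at 1 kHz).  Two normalizations
are supported, matching how open-field and fear-extinction sessions are
treated differently: dividing by the mean raw power across 1-120 Hz
(whole-spectrum), or by the scalar mean of the same animal's 180 s
baseline PSD across 0-120 Hz (baseline).  Band power is the mean of
normalized PSD bins inside a band — a "relative power" that is comparable
across bands of different widths; the integral is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    FrequencyBand,
    NormalizationStateError,
    SignalTrace,
    ValidationError,
    get_band,
)


@dataclass(frozen=True)
class WelchParams:
    nperseg: int = 2048
    window: str = "hann"
    noverlap: int = 1024

    def __post_init__(self) -> None:
        if not 0 <= self.noverlap < self.nperseg:
            raise ValidationError("need 0 <= noverlap < nperseg")


class ShortSegmentError(ValidationError):
    """Trace shorter than one Welch segment."""


@dataclass(frozen=True)
class PSDResult:
    """One-sided power spectral density with its estimation provenance."""

    freqs: np.ndarray
    power: np.ndarray
    params: WelchParams
    normalization: str = "none"  # none | whole_spectrum | baseline
    reference: str = ""

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        power = np.asarray(self.power, dtype=np.float64)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.shape != power.shape:
            raise ValidationError("freqs and power must align")
        if np.any(np.diff(freqs) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if np.any(power < 0):
            raise ValidationError("power must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"freq_hz": self.freqs, "power": self.power}).to_csv(path, index=False)
        meta = {
            "nperseg": self.params.nperseg,
            "window": self.params.window,
            "noverlap": self.params.noverlap,
            "normalization": self.normalization,
            "reference": self.reference,
        }
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def welch_psd(trace: SignalTrace, params: WelchParams = WelchParams()) -> PSDResult:
    """Welch PSD of a trace (one-sided, density scaling, uV^2/Hz)."""
    if trace.n_samples < params.nperseg:
        raise ShortSegmentError(
            f"trace of {trace.n_samples} samples shorter than nperseg={params.nperseg}"
        )
    freqs, power = signal.welch(
        trace.samples,
        fs=trace.sampling_rate_hz,
        window=params.window,
        nperseg=params.nperseg,
        noverlap=params.noverlap,
        detrend="constant",
        scaling="density",
    )
    return PSDResult(freqs, power, params)


def average_psds(psds: list[PSDResult]) -> PSDResult:
    """Bin-wise mean of PSDs sharing one frequency grid and normalization."""
    if not psds:
        raise ValidationError("no PSDs to average")
    first = psds[0]
    for p in psds[1:]:
        if not np.array_equal(p.freqs, first.freqs):
            raise ValidationError("PSD frequency grids differ")
        if p.normalization != first.normalization:
            raise ValidationError("cannot average PSDs with different normalizations")
    power = np.mean([p.power for p in psds], axis=0)
    return replace(first, power=power)


def normalize_whole_spectrum(
    psd: PSDResult, band: tuple[float, float] = (1.0, 120.0)
) -> PSDResult:
    """Divide by the mean raw power over ``band``; that band then averages to 1."""
    if psd.normalization != "none":
        raise NormalizationStateError(f"PSD already normalized ({psd.normalization})")
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not mask.any():
        raise ValidationError("normalization band contains no frequency bins")
    denom = psd.power[mask].mean()
    if denom <= 0:
        raise ZeroDivisionError("mean power over normalization band is zero")
    return replace(
        psd,
        power=psd.power / denom,
        normalization="whole_spectrum",
        reference=f"mean[{band[0]:g},{band[1]:g}]Hz",
    )


def normalize_to_baseline(
    psd: PSDResult,
    baseline_psd: PSDResult,
    band: tuple[float, float] = (0.0, 120.0),
) -> PSDResult:
    """Divide by the scalar mean of the baseline PSD over ``band`` (0-120 Hz).

    The baseline PSD must come from the same animal's pre-tone baseline
    period, estimated with identical Welch parameters.  ``band`` includes
    the DC bin by convention; pass ``(0.5, 120)`` or similar to exclude a
    DC bin zeroed by prior high-pass filtering.
    """
    if psd.normalization != "none":
        raise NormalizationStateError(f"PSD already normalized ({psd.normalization})")
    if not np.array_equal(psd.freqs, baseline_psd.freqs):
        raise ValidationError("PSD and baseline PSD frequency grids differ")
    if psd.params != baseline_psd.params:
        raise ValidationError("baseline PSD estimated with different Welch parameters")
    mask = (baseline_psd.freqs >= band[0]) & (baseline_psd.freqs <= band[1])
    if not mask.any():
        raise ValidationError("normalization band contains no frequency bins")
    denom = baseline_psd.power[mask].mean()
    if denom <= 0:
        raise ZeroDivisionError("baseline mean power over normalization band is zero")
    return replace(
        psd,
        power=psd.power / denom,
        normalization="baseline",
        reference=f"baseline mean[{band[0]:g},{band[1]:g}]Hz",
    )


def band_power(
    psd: PSDResult,
    band: FrequencyBand | str | tuple[float, float],
    mode: str = "mean",
) -> float:
    """Relative power in a band: mean (default) or integral of PSD bins.

    Band edges are inclusive: a bin belongs to the band iff
    ``low <= f <= high``.
    """
    b = get_band(band)
    mask = b.mask(psd.freqs)
    if not mask.any():
        raise ValidationError(f"band {b.name} contains no frequency bins")
    if mode == "mean":
        return float(psd.power[mask].mean())
    if mode == "integral":
        return float(np.trapezoid(psd.power[mask], psd.freqs[mask]))
    raise ValidationError(f"unknown band power mode {mode!r}")


@dataclass(frozen=True)
class Spectrogram:
    times: np.ndarray  # window centers, seconds
    freqs: np.ndarray
    power: np.ndarray  # (n_freqs, n_times)


def spectrogram(
    trace: SignalTrace,
    params: WelchParams = WelchParams(),
    step_s: float = 1.0,
) -> Spectrogram:
    """Sliding-window periodogram grid with columns at window centers."""
    if step_s <= 0:
        raise ValidationError("step must be positive")
    if trace.n_samples < params.nperseg:
        raise ShortSegmentError("trace shorter than one spectrogram window")
    step = int(round(step_s * trace.sampling_rate_hz))
    noverlap = params.nperseg - step
    if noverlap < 0:
        noverlap = 0
    freqs, times, power = signal.spectrogram(
        trace.samples,
        fs=trace.sampling_rate_hz,
        window=params.window,
        nperseg=params.nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    return Spectrogram(times + trace.t0, freqs, power)
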