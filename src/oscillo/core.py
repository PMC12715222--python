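"""Core containers shared across the analysis chain.

A :class:`SignalTrace` is the substrate of every DSP stage: a uniformly
sampled voltage series (microvolts) with its sampling rate, a time origin
and an append-only provenance list recording every transform applied to it.
:class:`FrequencyBand` instances name the oscillation bands used throughout:
theta (4-12 Hz), gamma (30-90 Hz) and its low (30-45 Hz) / high (55-90 Hz)
sub-bands, separated by a 45-55 Hz gap that keeps 50 Hz line-noise leakage
out of both gamma estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class DataQualityError(ValueError):
    """Raised when data content (NaN, non-finite, empty) makes a stage unsafe."""


class NormalizationStateError(RuntimeError):
    """Raised when a PSD normalization is applied twice or to the wrong state."""


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled continuous voltage series.

    Parameters
    ----------
    samples
        Voltage samples in microvolts, one channel.
    sampling_rate_hz
        Sampling rate in Hz; must be positive.
    t0
        Time of the first sample in seconds.
    provenance
        Ordered tuple of transform descriptions already applied.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    t0: float = 0.0
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValidationError("SignalTrace requires a 1-D sample vector")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate_hz

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise DataQualityError("trace contains non-finite samples")

    def with_samples(
        self,
        samples: np.ndarray,
        *,
        sampling_rate_hz: float | None = None,
        step: str | None = None,
    ) -> "SignalTrace":
        """Return a copy with new samples, appending ``step`` to provenance."""
        prov = self.provenance + ((step,) if step else ())
        return replace(
            self,
            samples=np.asarray(samples, dtype=np.float64),
            sampling_rate_hz=sampling_rate_hz or self.sampling_rate_hz,
            provenance=prov,
        )


@dataclass(frozen=True)
class FrequencyBand:
    """Named frequency band [low, high] in Hz; edges inclusive."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"band {self.name}: low must be < high")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequency bins inside the band (inclusive edges)."""
        return (freqs >= self.low) & (freqs <= self.high)

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: Canonical band registry used throughout the pipeline.
BANDS: dict[str, FrequencyBand] = {
    "theta": FrequencyBand("theta", 4.0, 12.0),
    "gamma": FrequencyBand("gamma", 30.0, 90.0),
    "low_gamma": FrequencyBand("low_gamma", 30.0, 45.0),
    "high_gamma": FrequencyBand("high_gamma", 55.0, 90.0),
}


def get_band(band: "FrequencyBand | str | tuple[float, float]") -> FrequencyBand:
    """Resolve a band from the registry, a (low, high) pair, or pass through."""
    if isinstance(band, FrequencyBand):
        return band
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ValidationError(
                f"unknown band {band!r}; registry: {sorted(BANDS)}"
            ) from None
    low, high = band
    return FrequencyBand(f"{low:g}-{high:g}Hz", float(low), float(high))
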