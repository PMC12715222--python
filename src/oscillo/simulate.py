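"""Synthetic LFP cohorts with known ground truth.

The generator emulates a prefrontal LFP recording during a fear-extinction
retrieval session: a 1/f aperiodic background, a theta oscillation
(4-12 Hz), gamma carriers whose amplitude is modulated by theta phase
(phase-amplitude coupling of depth ``m``), 50 Hz line contamination and
white sensor noise, plus the session's event schedule (180 s baseline,
40 tones of 30 s separated by 5 s ITIs), freezing-correlated motion-index
traces and per-group amplitude gains.  Every draw is seeded and
bit-reproducible, and a :class:`GroundTruth` record books the true band
amplitudes, coupling depth and freezing fraction per interval so that each
analysis stage can be validated against what was actually injected.

The gamma envelope is ``base_amp * (1 + m*cos(theta_phase - phi0)) / (1+m)``:
dividing by ``(1+m)`` keeps the envelope peak — and hence mean gamma power
at fixed carrier — comparable across coupling depths, so band-power and
PAC effects can be manipulated independently.
"""

from __future__ import annotations

import fnmatch
import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .behavior import FreezingParams, MotionTrace
from .core import SignalTrace, ValidationError
from .session import EventSchedule, Interval


def condition_of_label(label: str) -> str:
    """Default interval-label -> condition mapping: strip the trial index."""
    import re

    return re.sub(r"_\d+$", "", label)


@dataclass(frozen=True)
class SessionDesign:
    """Timing of a tone-extinction session.

    ``baseline_s`` of silence, then ``n_tones`` tones of ``tone_s`` seconds
    separated by ``iti_s``-second inter-trial intervals.  The session ends
    with the last tone (40 tones have 39 separating ITIs); set
    ``trailing_iti`` to append a final ITI.  With ``conditioning`` set, each
    tone's last ``shock_s`` seconds are split off as a ``shock_k`` marker
    interval (the foot shock is delivered at tone offset).
    """

    baseline_s: float = 180.0
    n_tones: int = 40
    tone_s: float = 30.0
    iti_s: float = 5.0
    conditioning: bool = False
    shock_s: float = 2.0
    trailing_iti: bool = False

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.tone_s, self.iti_s) <= 0:
            raise ValidationError("all durations must be positive")
        if self.n_tones < 1:
            raise ValidationError("n_tones must be >= 1")
        if self.conditioning and not 0 < self.shock_s < self.tone_s:
            raise ValidationError("shock_s must lie inside the tone duration")

    @property
    def total_duration_s(self) -> float:
        n_itis = self.n_tones if self.trailing_iti else self.n_tones - 1
        return self.baseline_s + self.n_tones * self.tone_s + n_itis * self.iti_s


def generate_schedule(design: SessionDesign) -> EventSchedule:
    """Expand a :class:`SessionDesign` into labeled, contiguous intervals."""
    ivs: list[Interval] = [Interval("baseline", 0.0, design.baseline_s)]
    t = design.baseline_s
    for k in range(1, design.n_tones + 1):
        if design.conditioning:
            ivs.append(Interval(f"tone_{k}", t, t + design.tone_s - design.shock_s))
            ivs.append(Interval(f"shock_{k}", t + design.tone_s - design.shock_s, t + design.tone_s))
        else:
            ivs.append(Interval(f"tone_{k}", t, t + design.tone_s))
        t += design.tone_s
        if k < design.n_tones or design.trailing_iti:
            ivs.append(Interval(f"iti_{k}", t, t + design.iti_s))
            t += design.iti_s
    kind = "conditioning" if design.conditioning else "retrieval"
    return EventSchedule(tuple(ivs), session_kind=kind)


@dataclass(frozen=True)
class GammaSpec:
    """One gamma carrier: registry band name, carrier frequency, base amplitude (uV)."""

    band: str
    carrier_hz: float
    base_amp: float


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic LFP generator.

    Amplitudes are in microvolts.  ``group_gain`` maps a condition-label
    glob pattern to per-band multiplicative amplitude factors (e.g.
    ``{"tone": {"low_gamma": 0.7}}``); ``pac_depth_by_condition`` overrides
    the global coupling depth per condition pattern.  ``max_samples`` is the
    memory budget: a requested trace longer than this is refused.
    """

    sampling_rate_hz: float = 30000.0
    aperiodic_exponent: float = 1.5
    aperiodic_amp: float = 30.0
    theta_hz: float = 8.0
    theta_amp: float = 40.0
    gamma_bands: tuple[GammaSpec, ...] = (
        GammaSpec("low_gamma", 40.0, 12.0),
        GammaSpec("high_gamma", 70.0, 10.0),
    )
    pac_depth: float = 0.5
    pac_preferred_phase: float = 0.0
    pac_depth_by_condition: dict = field(default_factory=dict)
    line_noise_amp: float = 10.0
    group_gain: dict = field(default_factory=dict)
    noise_sd: float = 5.0
    seed: int = 0
    max_samples: int = 200_000_000

    def __post_init__(self) -> None:
        gb = tuple(
            g if isinstance(g, GammaSpec) else GammaSpec(*g) for g in self.gamma_bands
        )
        object.__setattr__(self, "gamma_bands", gb)
        depths = [self.pac_depth, *self.pac_depth_by_condition.values()]
        if any(not 0 <= m <= 1 for m in depths):
            raise ValidationError("pac depth m must lie in [0, 1]")
        if not 4 <= self.theta_hz <= 12:
            raise ValidationError("theta_hz must lie in the 4-12 Hz theta band")
        carriers = [g.carrier_hz for g in gb]
        if carriers and self.sampling_rate_hz <= 2 * max(carriers):
            raise ValidationError("sampling rate must exceed twice the highest carrier")
        for cond, gains in self.group_gain.items():
            for band, gain in gains.items():
                if gain <= 0:
                    raise ValidationError(f"gain for ({cond}, {band}) must be positive")

    def gain_for(self, condition: str, band: str) -> float:
        for pattern, gains in self.group_gain.items():
            if fnmatch.fnmatch(condition, pattern) and band in gains:
                return float(gains[band])
        return 1.0

    def depth_for(self, condition: str) -> float:
        for pattern, m in self.pac_depth_by_condition.items():
            if fnmatch.fnmatch(condition, pattern):
                return float(m)
        return float(self.pac_depth)


@dataclass
class GroundTruth:
    """What was actually injected, one record per schedule interval."""

    intervals: list[dict] = field(default_factory=list)
    pac_preferred_phase: float = 0.0

    def amplitude(self, label: str, band: str) -> float:
        for rec in self.intervals:
            if rec["label"] == label:
                return rec["band_amp"].get(band, 0.0)
        raise KeyError(label)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def powerlaw_noise(
    n: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent.

    White Gaussian noise is shaped in the frequency domain (each rFFT bin
    scaled by f^(-exponent/2), DC zeroed), which hits the target exponent
    exactly rather than approximating it with an AR filter.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_lfp(
    config: SimulationConfig,
    schedule: EventSchedule,
    condition_map: dict[str, str] | None = None,
) -> tuple[SignalTrace, GroundTruth]:
    """Synthesize one session-long LFP trace plus its ground-truth record.

    The trace is the sum of 1/f background, a theta cosine, gamma carriers
    with theta-phase-locked envelopes (scaled per interval by the condition's
    group gain), a 50 Hz line component and white noise.
    """
    fs = config.sampling_rate_hz
    n = int(round(schedule.end_s * fs))
    if n > config.max_samples:
        raise ValidationError(
            f"trace of {n} samples exceeds configured budget {config.max_samples}"
        )
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs

    theta_phase = 2 * np.pi * config.theta_hz * t
    x = config.theta_amp * np.cos(theta_phase)
    x += config.aperiodic_amp * powerlaw_noise(n, fs, config.aperiodic_exponent, rng)
    if config.line_noise_amp:
        x += config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t)
    if config.noise_sd:
        x += config.noise_sd * rng.standard_normal(n)

    cond_map = condition_map or {}
    truth = GroundTruth(pac_preferred_phase=config.pac_preferred_phase)
    pac_mod = np.cos(theta_phase - config.pac_preferred_phase)
    for iv in schedule:
        cond = cond_map.get(iv.label, condition_of_label(iv.label))
        i0 = int(round(iv.start_s * fs))
        i1 = i0 + int(np.floor(iv.duration_s * fs + 1e-9))
        m = config.depth_for(cond)
        band_amp = {}
        for g in config.gamma_bands:
            amp = g.base_amp * config.gain_for(cond, g.band)
            band_amp[g.band] = amp
            envelope = amp * (1.0 + m * pac_mod[i0:i1]) / (1.0 + m)
            x[i0:i1] += envelope * np.cos(2 * np.pi * g.carrier_hz * t[i0:i1])
        truth.intervals.append(
            {
                "label": iv.label,
                "condition": cond,
                "start_s": iv.start_s,
                "end_s": iv.end_s,
                "band_amp": band_amp,
                "pac_depth": m,
                "theta_amp": config.theta_amp,
            }
        )
    trace = SignalTrace(x, fs, provenance=(f"simulated(seed={config.seed})",))
    return trace, truth


def generate_motion_trace(
    schedule: EventSchedule,
    freezing_profile: float | dict,
    frame_rate: float = 30.0,
    params: FreezingParams = FreezingParams(),
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
) -> MotionTrace:
    """Motion-index trace whose scored freezing matches per-interval targets.

    ``freezing_profile`` is a target freezing fraction in [0, 1], either a
    scalar for all intervals or a mapping of label glob patterns to targets
    (e.g. ``{"tone_*": 0.6, "iti_*": 0.4}``).  Within each interval one
    contiguous sub-threshold bout of ``round(target * n_frames)`` frames is
    placed at a random offset; a bout that would be shorter than the
    scorer's minimum duration is dropped (scored as 0) with a warning.
    Achieved fractions are appended to ``ground_truth`` when given.
    """
    if frame_rate <= 0:
        raise ValidationError("frame_rate must be positive")

    def target_for(label: str) -> float:
        if isinstance(freezing_profile, dict):
            for pattern, v in freezing_profile.items():
                if fnmatch.fnmatch(label, pattern):
                    return float(v)
            return 0.0
        return float(freezing_profile)

    rng = np.random.default_rng(seed)
    n_total = int(round(schedule.end_s * frame_rate))
    # moving frames sit safely above threshold; frozen frames strictly below
    motion = params.threshold * (1.5 + rng.exponential(0.5, n_total))
    truth_by_label: dict[str, float] = {}
    for iv in schedule:
        target = target_for(iv.label)
        if not 0 <= target <= 1:
            raise ValidationError(f"freezing target for {iv.label} outside [0, 1]")
        i0 = int(round(iv.start_s * frame_rate))
        n = int(np.floor(iv.duration_s * frame_rate + 1e-9))
        n_freeze = int(round(target * n))
        if 0 < n_freeze < params.min_freeze_frames:
            warnings.warn(
                f"{iv.label}: target bout of {n_freeze} frames is below the "
                f"{params.min_freeze_frames}-frame minimum; scoring 0",
                stacklevel=2,
            )
            n_freeze = 0
        if n_freeze > 0:
            offset = int(rng.integers(0, n - n_freeze + 1))
            lo = i0 + offset
            motion[lo : lo + n_freeze] = params.threshold * rng.uniform(
                0.1, 0.8, n_freeze
            )
        truth_by_label[iv.label] = n_freeze / n if n else 0.0
    if ground_truth is not None:
        for rec in ground_truth.intervals:
            rec["freezing_frac"] = truth_by_label.get(rec["label"], 0.0)
    return MotionTrace(motion, frame_rate)


@dataclass
class AnimalRecord:
    """One simulated animal: signals, behavior and bookkeeping."""

    animal_id: str
    group: str
    trace: SignalTrace
    motion: MotionTrace | None
    ground_truth: GroundTruth
    config: SimulationConfig


def animal_seed(master_seed: int, group_index: int, animal_index: int) -> int:
    """Deterministic per-animal seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, animal_index))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_per_group: int,
    group_specs: dict[str, dict],
    design: SessionDesign = SessionDesign(),
    master_seed: int = 0,
    base_config: SimulationConfig = SimulationConfig(),
    freezing_profile: float | dict | None = None,
) -> tuple[list[AnimalRecord], EventSchedule]:
    """Simulate ``n_per_group`` animals for each group.

    ``group_specs`` maps each group label to :class:`SimulationConfig`
    field overrides (e.g. ``{"control": {}, "mutant": {"group_gain":
    {"*": {"low_gamma": 0.6}}}}``).  Per-animal seeds are spawned
    deterministically from ``master_seed`` so identical calls give
    identical cohorts while animals remain independent streams.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if not group_specs:
        raise ValidationError("group_specs must name at least one group")
    valid_fields = set(SimulationConfig.__dataclass_fields__)
    for group, overrides in group_specs.items():
        unknown = set(overrides) - valid_fields
        if unknown:
            raise ValidationError(f"group {group!r}: unknown config fields {sorted(unknown)}")
    schedule = generate_schedule(design)
    cohort: list[AnimalRecord] = []
    for gi, (group, overrides) in enumerate(sorted(group_specs.items())):
        for ai in range(n_per_group):
            seed = animal_seed(master_seed, gi, ai)
            cfg = replace(base_config, seed=seed, **overrides)
            trace, truth = generate_lfp(cfg, schedule)
            motion = None
            if freezing_profile is not None:
                motion = generate_motion_trace(
                    schedule, freezing_profile, seed=seed + 1, ground_truth=truth
                )
            cohort.append(
                AnimalRecord(f"{group}_{ai + 1:02d}", group, trace, motion, truth, cfg)
            )
    return cohort, schedule
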