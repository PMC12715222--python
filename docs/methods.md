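# Methods

## Signal model

The simulator and the analysis share one signal model. A session-long LFP
trace is the sum of

1. an aperiodic 1/f^α background: white Gaussian noise shaped in the
   frequency domain (each rFFT bin scaled by f^(−α/2), DC zeroed), then
   normalized to a target RMS. Spectral shaping hits the target exponent
   exactly, unlike AR approximations; the PSD slope of the generated noise
   recovers −α within ±0.3 over 5–100 Hz (property-tested).
2. a theta oscillation: `A_θ · cos(2π f_θ t)` with f_θ ∈ [4, 12] Hz.
3. gamma carriers: for each band (carrier f_c, base amplitude a), the
   envelope is `a · (1 + m·cos(φ_θ − φ₀)) / (1 + m)` where φ_θ is the true
   theta phase, m ∈ [0, 1] the coupling depth and φ₀ the preferred phase.
   The 1/(1+m) normalization keeps the envelope peak comparable across
   depths so that coupling strength and band power can be manipulated
   independently — PAC effects do not masquerade as band-power effects.
4. 50 Hz line contamination (sinusoid) and white sensor noise.

Default amplitudes (µV): aperiodic 30 RMS, theta 40, low gamma 12, high
gamma 10, line 10, white noise 5, α = 1.5 — proportions chosen once as a
realistic mPFC LFP mixture in which theta dominates, gamma is an order of
magnitude weaker in power, and line noise is visible but not dominant.
Carriers default to 40 Hz (inside 30–45) and 70 Hz (inside 55–90).

Group- and condition-specific manipulations are multiplicative amplitude
gains keyed by condition-label pattern and band, plus per-condition
coupling depths. Per-animal seeds are spawned deterministically from a
master seed (`SeedSequence(master, spawn_key=(group, animal))`), giving
reproducible yet independent streams.

### What the generator does not emulate

No spikes, no biophysics, no non-stationarity beyond the scripted
condition structure, no movement or chewing artifacts, no electrode drift,
and a strictly periodic theta (real theta has cycle-to-cycle frequency and
amplitude jitter). Consequences: passing tests demonstrate that the
estimators recover what they claim from signals with the assumed
structure; they do not certify robustness to artifacts or to
non-sinusoidal theta, and surrogate-based PAC inference behaves
differently here (see below).

## Preprocessing

Band-pass: order-5 IIR Butterworth, 1–120 Hz, applied forward–backward
(`sosfiltfilt`), because undistorted phase is mandatory for downstream PAC;
the direction of application is a free choice and zero-phase is the
defensible default for phase analyses. Notch: second-order IIR notch at
50 Hz with −3 dB bandwidth 0.1 Hz (Q = 500), also zero-phase. Edge
stability: reflective padding of ~3 impulse-response lengths, with the IR
timescale taken as 1/(π·narrowest-feature-Hz) — the narrow notch needs
seconds of padding, the band-pass ~1 s. Downsampling is integer decimation
only; if the trace's provenance shows no prior low-pass covering the new
Nyquist, an explicit order-8 anti-alias low-pass at 0.4× the target rate is
inserted, so the stages are alias-safe when used à la carte. Arbitrary-rate
resampling is out of scope.

## Spectra

Welch PSD: 2048-sample segments, periodic Hann taper, 1024-sample overlap,
per-segment mean removal, one-sided density scaling — verified against a
hand-enumerated tapered-periodogram average at 1e-10 relative tolerance.
At 1 kHz this gives ~0.488 Hz resolution and ≥ 3 segments within a 5 s ITI.

Two normalizations, recorded exactly once in the result's state (double
normalization is a state error):

- whole-spectrum: divide by the mean raw power over 1–120 Hz; the
  normalized mean over that band is exactly 1.
- baseline: divide by the scalar mean of the same animal's baseline-period
  PSD over 0–120 Hz (identical Welch parameters enforced). The band
  includes the DC bin by convention; since the band-pass drives DC toward
  0, a config switch excludes it.

Band power is the **mean** (not the integral) of normalized PSD bins with
`low ≤ f ≤ high` (edges inclusive) — bands of different widths become
comparable relative-power values; the integral is available via
`mode="integral"`. The 45–55 Hz gap between the gamma sub-bands keeps
50 Hz leakage out of both. Per-condition PSDs are computed per interval and
averaged across same-label intervals (not concatenated), avoiding spurious
segment-boundary artifacts; concatenation is easy to compose from
`segment()` if wanted.

## Phase-amplitude coupling

Phase and envelope come from a windowed-sinc FIR band-pass (transition
width 25% of the lower band edge, Hamming-windowed length ≈ 3.3/Δf_norm,
odd taps) followed by the Hilbert transform. The zero-phase FIR is applied
as one FFT convolution with the taps' autocorrelation — mathematically the
forward–backward filter, at O(n log n). Phase convention: cosine phase,
0 at the oscillation peak, reported in (−π, π].

Coupling strength is the entropy-based modulation index: mean envelope per
theta-phase bin (18 bins), normalized to a distribution p, and
`MI = (log N + Σ p log p)/log N` ∈ [0, 1]. MI is invariant to amplitude
scaling (to floating-point summation error, ~1e-12 relative — binned sums
do not commute exactly with scalar multiplication). Empty phase bins are
dropped with a warning. The preferred phase is the amplitude-weighted
circular mean. An amplitude-normalized mean-vector-length metric is
available behind `metric="mvl"`; metrics are never mixed in a comparison.

Per-condition PAC pools samples from all intervals matching a label
pattern, with phase/envelope computed once on the continuous trace — the
intervals are contiguous cuts of one recording, so filtering the whole
trace first introduces no boundary transients at all and no edge samples
need discarding. Pooling matters because a single 5 s ITI under-samples
theta phase space. The tone/ITI coupling ratio is `MI(tone)/MI(ITI)`; an
ITI MI of zero makes it undefined (signaled, not infinity).

Surrogate caveat: with the simulator's strictly periodic theta, circularly
shifting the envelope relative to phase rotates the preferred phase but
leaves MI unchanged, so shift surrogates only provide a null for the m = 0
case here (the test asserts exactly that). On real, jittered theta they
also degrade MI at m > 0.

## Session structure and behavior

Intervals are half-open `[start, end)`; starts map to the nearest sample
and lengths to `floor(duration·rate)`, so adjacent tone/ITI segments never
share a sample. Stages for the 40-trial protocol are hard-coded
(1–13 / 14–26 / 27–39, trial 40 excluded); other trial counts fall back to
thirds with the remainder excluded from the end.

Freezing: a frame is immobile iff its motion index is **strictly below**
the threshold (the boundary value counts as motion — a deterministic
tie-break, fixed because the commercial scorer's rule is unknowable);
maximal immobile runs ≥ 30 frames count as freezing. Runs are evaluated on
the uncut trace so bouts spanning a tone onset survive, then frames are
attributed per interval. The scorer is property-tested against an explicit
run-enumeration oracle. The motion-trace generator places one contiguous
sub-threshold bout per interval sized `round(target·frames)`; a bout below
the scorer's minimum is dropped with a warning, so scored output equals the
bookkept truth exactly.

Open field: the center is a concentric square of the configured inner area
(default 900 cm² in a 50 cm arena, i.e. [10, 40] cm on each axis); the
periphery is the remainder of the arena (the two zone fractions sum to 1 by
construction). Time accrues per inter-sample step attributed to the
starting sample's zone; a crossing is an entry event into the center.

## Statistics

Two-group comparisons are gated: Shapiro–Wilk on each group at α = 0.05
(α is a fixed choice; constant samples are treated as non-normal); both
normal → t test, with an F-ratio variance-equality test at 0.05 choosing
Student vs Welch; otherwise Mann–Whitney U; all two-tailed. The gate's
type-I error is calibrated (1000 null replicates, within 0.05 ± 2 SE).
Animals, not trials, are the experimental unit: trial-level values are
averaged per animal before any group test. Factorial designs use ordinary
two-way ANOVA with Šidák-adjusted pairwise contrasts
(`p_adj = 1 − (1−p)^m`); Šidák is the default post-hoc, exposed
explicitly. Linear mixed models (random intercept per animal, ML fits,
likelihood-ratio test) are delegated to statsmodels behind a thin
contract.

## Detection-power workflow and problem sizes

`gamma_cohort_measures` is the lean simulate → Welch → baseline-normalize →
band-power path used for replicate-cohort studies: 5 animals per group,
sessions of 20 s baseline + 6 × 10 s tones + 5 s ITIs synthesized directly
at 1 kHz — sizes chosen so that 100-replicate studies run at desk scale
while preserving the effect structure (≥ 3 Welch segments per ITI, stable
baseline denominator). With a 0.6 low-gamma amplitude gain in one group,
sign recovery is 100% in both conditions and the untouched high-gamma band
false-detects at the nominal 5% rate.

One genuine confound surfaced here and is worth knowing about: if the
attenuated group's gain also applies to the **baseline** period, the 0–120
Hz baseline-normalization denominator shrinks, inflating every normalized
band — including high gamma — in that group (measured: sign bias 0.89 and
13% false detection at N = 5). Baseline normalization is only
band-specific when the groups share a comparable baseline spectrum; the
shipped study condition therefore applies gains to task periods with a
common baseline.

## Known limitations

- Filters assume stationary, artifact-free traces; there is no artifact
  rejection or re-referencing.
- The MI noise floor depends on trace length; MI values are comparable
  only at matched durations and settings (the coupling ratio enforces
  this).
- The freezing scorer consumes an abstract motion index; it does not
  compute one from video.
- Mixed-model support is a thin contract, not a modeling framework.
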