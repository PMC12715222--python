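import numpy as np
import pytest

from oscillo import SessionDesign, SignalTrace, generate_schedule


@pytest.fixture
def sinusoid():
    """Factory for pure-sinusoid traces: (freq_hz, fs, duration_s, amp)."""

    def make(freq_hz, fs=1000.0, duration_s=10.0, amp=1.0, phase=0.0):
        t = np.arange(int(round(duration_s * fs))) / fs
        return SignalTrace(amp * np.cos(2 * np.pi * freq_hz * t + phase), fs)

    return make


@pytest.fixture
def retrieval_schedule():
    """The canonical extinction-retrieval session: 180 s baseline, 40x30 s
    tones, 5 s ITIs."""
    return generate_schedule(SessionDesign(180.0, 40, 30.0, 5.0))


@pytest.fixture
def small_design():
    """A desk-scale session used where full-length sessions are unnecessary."""
    return SessionDesign(baseline_s=20.0, n_tones=6, tone_s=10.0, iti_s=5.0)


def reference_welch(x, fs, nperseg=2048, noverlap=1024):
    """Independent Welch reference: explicit segment enumeration, mean
    removal per segment, periodic Hann taper, one-sided density scaling,
    mean over tapered periodograms."""
    x = np.asarray(x, dtype=np.float64)
    step = nperseg - noverlap
    n_seg = (len(x) - noverlap) // step
    k = np.arange(nperseg)
    win = 0.5 - 0.5 * np.cos(2 * np.pi * k / nperseg)  # periodic Hann
    scale = 1.0 / (fs * np.sum(win**2))
    psds = []
    for i in range(n_seg):
        seg = x[i * step : i * step + nperseg]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * win)
        p = scale * np.abs(spec) ** 2
        p[1:-1] *= 2.0  # one-sided; DC and Nyquist not doubled (even nperseg)
        psds.append(p)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, np.mean(psds, axis=0)
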