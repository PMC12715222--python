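"""Measure theta-phase -> gamma-amplitude coupling and the tone/ITI ratio.

Simulates a session in which coupling depth is stronger during tones
(m=0.8) than during ITIs (m=0.2), then recovers that asymmetry as a
modulation-index ratio > 1.
"""

import numpy as np

from oscillo import (
    SessionDesign,
    SimulationConfig,
    coupling_ratio,
    generate_lfp,
    generate_schedule,
    pac_for_condition,
)

schedule = generate_schedule(SessionDesign(baseline_s=30.0, n_tones=8, tone_s=10.0, iti_s=5.0))
config = SimulationConfig(
    sampling_rate_hz=1000.0,
    pac_preferred_phase=np.pi / 3,
    pac_depth_by_condition={"tone": 0.8, "iti": 0.2, "baseline": 0.2},
    seed=7,
)
trace, _ = generate_lfp(config, schedule)

pac_tone = pac_for_condition(trace, schedule, "tone_*", "theta", "low_gamma")
pac_iti = pac_for_condition(trace, schedule, "iti_*", "theta", "low_gamma")

print(f"MI(tone) = {pac_tone.mi:.5f}, preferred phase {np.degrees(pac_tone.preferred_phase):.0f} deg")
print(f"MI(ITI)  = {pac_iti.mi:.5f}")
print(f"tone/ITI coupling ratio = {coupling_ratio(pac_tone, pac_iti):.2f}")

# MI is the normalized KL divergence of the phase-binned gamma-amplitude
# profile from uniform (0 = no coupling).  A ratio > 1 says coupling
# strengthens during tone presentation; the preferred phase should sit near
# the injected 60 degrees.
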