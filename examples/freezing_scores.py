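"""Score freezing behavior from a motion-index trace.

Generates a motion trace whose freezing targets rise across the session
(as extinction-resistant animals would show), scores it with the standard
threshold/minimum-duration rule (18 a.u., 30 frames at 30 fps) and prints
per-trial percentages and 5-trial block means.
"""

import numpy as np

from oscillo import (
    FreezingParams,
    SessionDesign,
    block_means,
    generate_motion_trace,
    generate_schedule,
    score_freezing,
)

schedule = generate_schedule(SessionDesign(baseline_s=60.0, n_tones=10, tone_s=30.0, iti_s=5.0))
profile = {"baseline": 0.1}
profile.update({f"tone_{k}": 0.7 - 0.05 * k for k in range(1, 11)})  # extinction curve
motion = generate_motion_trace(schedule, profile, seed=3)

summary = score_freezing(motion, FreezingParams(), schedule)
tones = summary[summary["label"].str.startswith("tone_")]
print(summary.head(4).to_string(index=False))
print("...")

blocks = block_means(tones["freezing_pct"].to_numpy(), block_size=5)
for i, b in enumerate(blocks, 1):
    print(f"block {i}: {b:.1f}% freezing")

# Freezing % per interval is the fraction of frames inside immobile runs of
# >= 30 frames; the declining block means mirror within-session extinction.
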