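"""Detect a group-specific low-gamma attenuation in a simulated cohort.

Simulates 5 control vs 5 "attenuated" animals (low-gamma amplitude scaled
by 0.6 during tones and ITIs), runs the spectral chain per animal, and
applies the normality-gated two-group test per band and condition.
"""

from oscillo import compare_two_groups
from oscillo.pipeline import gamma_cohort_measures

table = gamma_cohort_measures(seed=11, n_per_group=5, low_gamma_gain=0.6)

for measure, sub in table.groupby("measure"):
    control = sub.loc[sub["group"] == "control", "value"].to_numpy()
    attenuated = sub.loc[sub["group"] == "attenuated", "value"].to_numpy()
    report = compare_two_groups(control, attenuated)
    print(
        f"{measure:<24} control={control.mean():.3f} attenuated={attenuated.mean():.3f} "
        f"{report.test_name}: p={report.p_value:.4f}"
    )

# Expected: a large, significant drop in low_gamma_power in the attenuated
# group for both conditions, and no significant difference in
# high_gamma_power -- the band-specificity the analysis is built to resolve.
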