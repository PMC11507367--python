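"""Generate a synthetic raw-milk storage study and look at its structure.

The generator emulates the design the analysis assumes: 10 storage days x 5
replicate preparations, a minority of features whose intensity drifts
monotonically with day (the planted spoilage markers), multiplicative
replicate noise and detector dropout.
"""

import numpy as np

import spoilmark as sm

config = sm.SyntheticConfig(seed=1)
table, truth = sm.generate_timecourse(config)

print(f"feature table: {table.n_features} features x {table.n_samples} samples")
print(f"planted markers: {truth.marker_directions}")

days = table.samples["day"].to_numpy()
for fid, direction in list(truth.marker_directions.items())[:2]:
    per_day = [table.intensities[fid][days == d].mean() for d in (1, 5, 10)]
    print(f"{fid} ({direction:>4}): mean intensity day 1/5/10 = "
          + " / ".join(f"{v:,.0f}" for v in per_day))

# A marker planted "up" roughly doubles over the study (trend 0.10/day);
# a "down" marker decays toward zero. Non-marker features stay flat on
# average, which is what the chemometric selection must see through.
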