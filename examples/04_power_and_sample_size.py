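"""Sample-size calculation for the composite score design assumption.

How many animals per group are needed to detect a 50% reduction of a mean
composite of 17 (SD 4) with 80% power at alpha = 0.05?
"""

from qorscore import required_sample_size

n = required_sample_size(mean=17, sd=4, reduction_fraction=0.5,
                         power=0.8, alpha=0.05)
print(f"required n per group: {n}")
for power in (0.8, 0.9, 0.95):
    n = required_sample_size(17, 4, 0.5, power=power)
    print(f"  power {power:.2f}: n = {n}/group")
# The effect size d = 8.5/4 ~ 2.1 is very large, so a handful of animals
# per group suffices for the day-level comparison.
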