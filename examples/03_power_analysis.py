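"""A-priori sample size for a paired method-comparison study.

How many feet are needed to detect a 1-degree (or 1-mm) mean difference
between two measurement methods, given a 1-degree within-group SD, at 80%
power and two-sided alpha 0.05?
"""

from footmetry import PowerSpec, required_sample_size

spec = PowerSpec(alpha=0.05, power=0.80, delta=1.0, sigma=1.0)
print("design point: delta = sigma = 1.0, alpha 0.05, power 0.80")
print("two-group normal approximation :", required_sample_size(spec), "feet")
print("paired-design formula          :",
      required_sample_size(spec, design="paired"), "feet")

spec90 = PowerSpec(alpha=0.05, power=0.90, delta=1.0, sigma=1.0)
print("at 90% power (two-group)       :", required_sample_size(spec90), "feet")
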