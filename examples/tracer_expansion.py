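"""Estimate the anatomical expansion of an inhibitory output nucleus.

Generates a synthetic tracer study with a known ground-truth ratio of
target neurons to source neurons (154 upper bound, 13 density-weighted
lower bound), then runs the full threshold-sweep estimation pipeline and
compares its asymptotic estimates against the truth.
"""

import numpy as np

from bgbottleneck import GeneratorConfig, generate_study, ratio_sweep
from bgbottleneck.estimation import proportion_of_source_injected

config = GeneratorConfig(target_ratio=154.0, target_weighted_ratio=13.0, seed=7)
catalog, experiments, truth = generate_study(config)
print(f"synthetic study: {len(catalog)} regions, "
      f"{len(experiments)} injections, "
      f"ground truth upper {truth['upper_ratio']:.0f}:1, "
      f"weighted lower {truth['weighted_ratio']:.0f}:1")

sweep = ratio_sweep(experiments, catalog, config.source)
print("\n theta   upper ratio   lower ratio")
for theta, up, lo in zip(sweep.thresholds, sweep.upper_ratios,
                         sweep.lower_ratios):
    print(f" {theta:5.3f}   {up:11.1f}   {lo:11.2f}")
print(f"\nasymptotes: upper {sweep.asymptote_upper:.1f}, "
      f"lower {sweep.asymptote_lower:.2f}")
i = int(np.searchsorted(sweep.thresholds, 0.005))
print(f"at theta=0.005 (one step above the noise floor): "
      f"upper {sweep.upper_ratios[i]:.1f} vs truth 154, "
      f"lower {sweep.lower_ratios[i]:.2f} vs truth 13")

print("\nWithout a threshold (theta=0) every region shows spurious tracer,")
print("inflating the ratio; above the noise floor the estimate stabilises.")

print("\nInjection coverage arithmetic on the real experiment metadata:")
for vol, prop in [(0.23, 0.95), (0.17, 0.96)]:
    frac = proportion_of_source_injected(vol, prop, 0.69)
    print(f"  volume {vol} mm^3, proportion in source {prop} -> "
          f"{frac:.2f} of the nucleus")
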