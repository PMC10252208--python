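"""Group statistics on per-cone outgrowth speeds.

Draws two pools of per-cone speeds (healthy-control and mutant laws), runs
the normality screen and the auto-selected omnibus + Bonferroni pairwise
comparison, and prints the tidy result table with star tiers.
"""

import numpy as np

from axoquant import compare_groups, normality_check, results_table

rng = np.random.default_rng(0)
groups = {
    "Ctrl untreated": np.clip(rng.normal(0.0666, 0.0224, 60), 0, None),
    "FUS untreated": np.clip(rng.normal(0.0530, 0.0210, 60), 0, None),
    "FUS 10Hz": np.clip(rng.normal(0.0616, 0.0242, 60), 0, None),
}

for name, values in groups.items():
    ok, stat, p = normality_check(values)
    print(f"normality {name:15s} KS stat {stat:.3f}  p {p:.3f}  -> {'pass' if ok else 'fail'}")

omnibus, results = compare_groups(groups, design="auto")
print("\nomnibus:", omnibus.to_string(index=False))
print("\npairwise (Bonferroni-adjusted):")
print(results_table(results)[["group_a", "group_b", "p_adjusted", "significance"]].to_string(index=False))
print("(the mutant pool separates from control, while the rescued 10 Hz condition is")
print(" statistically indistinguishable from control at this sample size)")
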