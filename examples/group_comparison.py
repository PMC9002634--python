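"""Group sensitivity: older adults vs young non-active vs elite athletes.

Simulates the three-group study design (group-level stiffness distributions
49.4 +- 11.5, 73.9 +- 18.3 and 96.3 +- 11.7 kN/strain), applies the
conservative trial-selection rule (older adults: four strongest trials;
athletes: four weakest; young: all eight of one leg) and runs the one-way
ANOVA with Bonferroni post-hocs on the stiffness index.
"""

import tendonmetrics as tm

dataset, _ = tm.simulate_cohort(tm.default_group_configs(seed=5), seed=5)
results, _ = tm.analyze_session(dataset, method="two_frame")

comparison, values = tm.compare_groups(results)
for group in ("older", "young_nonactive", "elite_athlete"):
    v = values[group]
    print(f"{group:16s} n={v.size:2d} mean stiffness {v.mean():6.1f} kN/strain")
print(f"\none-way ANOVA: F = {comparison.anova_f:.2f}, p = {comparison.anova_p:.2e}")
print(comparison.pairwise.to_string(index=False))
print()
print("Stiffer tendons in the athletes and more compliant tendons in the")
print("older adults: the expected ordering, with pairwise significance")
print("after Bonferroni correction when the group effect is present.")
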