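"""Three-metric group comparison across simulated cohorts.

Simulates small cohorts from the normotensive-like and hypertensive-like
presets, analyzes every specimen, and prints the mean ± SEM comparison
table with Bonferroni-corrected significance flags — the tabular analogue
of at-MAP bar plots in arterial mechanics studies.
"""

from arterymech.pipeline import MechanicsRunConfig, run_mechanics

cfg = MechanicsRunConfig(n_specimens=5, master_seed=2024)
res = run_mechanics(cfg)

table = res["group_table"]
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nStars name the group an entry differs from at Bonferroni-adjusted "
    "p < 0.05: stresses and stretches separate the cohorts cleanly, while "
    "the tangent modulus — the noisiest derived metric — may not reach "
    "significance at n = 5. The hypertensive-like cohort carries higher "
    "stresses at MAP and a higher in vivo stretch, the pattern hypertension "
    "produces in elastic arteries."
)
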