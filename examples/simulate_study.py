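"""Simulate a two-arm PDX efficacy study and look at the raw growth curves.

Each mouse grows exponentially from its enrollment volume; treatment scales
the growth rate down by the arm effect, and mice are sacrificed when the
observed volume reaches 500 mm3.
"""

from pdxefficacy import SimConfig, simulate_study

config = SimConfig(n_per_arm=5, seed=None)
study = simulate_study(config, {"control": 0.0, "drug": 0.7}, seed=42)

for arm in study.arms:
    print(f"\narm {arm.name!r} ({arm.n_mice} mice):")
    for curve in arm.curves:
        vols = ", ".join(f"{v:.0f}" for v in curve.volumes)
        print(f"  {curve.mouse_id}: days {curve.days[0]}..{curve.days[-1]}, "
              f"volumes [{vols}] mm3 ({curve.terminal_status})")

# A strong treatment keeps treated mice on study longer: control mice hit
# the 500 mm3 sacrifice threshold first.
control_end = max(c.days[-1] for c in study.arm("control").curves)
drug_end = max(c.days[-1] for c in study.arm("drug").curves)
print(f"\nlast control measurement: day {control_end}; "
      f"last drug measurement: day {drug_end}")
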