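"""Per-mouse responder classification (RTVV / ORR).

A mouse's RTVV is its own RTV divided by the median control RTV at the
evaluation day; ORR = RTVV - 1, and the mouse is a responder only when
ORR < -0.5 strictly (RTVV exactly 0.5 does not qualify).
"""

from pdxefficacy import (
    SimConfig,
    classify_response,
    last_common_day,
    orr_table,
    simulate_study,
)

study = simulate_study(SimConfig(n_per_arm=7),
                       {"control": 0.0, "drug": 0.8}, seed=11)
control = study.control_arm
drug = study.arm("drug")
day = last_common_day(drug, control)

print(f"per-mouse classification (evaluation at last common day, day {day}):")
for curve in drug.curves:
    rec = classify_response(curve, control, day)
    tag = "responder" if rec.responder else "non-responder"
    print(f"  {rec.mouse_id}: RTVV={rec.rtvv:.3f}, ORR={rec.orr:+.3f} -> {tag}"
          + ("  (last available day used)" if rec.used_last_available else ""))

(row,) = orr_table([drug], control)
print(f"\narm {row.arm!r}: {row.n_responders}/{row.n_mice} responders "
      f"= {row.responder_pct}% (evaluated on day {row.evaluation_day})")
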