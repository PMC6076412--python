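"""Base-case two-arm run: per-arm cost components, QALYs and the increment.

Uses the packaged default configuration (FOLFOX4 vs sorafenib for advanced
HCC in China).  The sorafenib PFS median was never published, so it must be
supplied; 2.8 months is this example's assumption.  Because the survivor
curves here are exponential stand-ins rather than the trials' actual KM
curves, the absolute totals differ from the published ones — the pipeline,
not the curves, is what this example demonstrates.
"""

from pscea import default_model, inhb, WTP_3X_GDP

model = default_model(sorafenib_pfs_median=2.8)
outcome = model.evaluate()

for res in (outcome.intervention, outcome.comparator):
    comps = res.discounted
    print(f"{res.arm_name:>10}: drug ${comps['drug']:8.0f}  ward ${comps['ward']:5.0f}  "
          f"AE ${comps['ae']:5.0f}  tests ${comps['tests']:6.0f}  "
          f"total ${comps['total']:8.0f}  QALY {res.qaly:.3f}  "
          f"mean survival {res.life_months:.1f} mo")

icer = outcome.icer
print(f"\nincrement (FOLFOX4 - sorafenib): dCost ${icer.delta_cost:,.0f}, "
      f"dQALY {icer.delta_effect:+.4f} -> {icer.label}"
      + (f" (ICER ${icer.icer:,.0f}/QALY)" if icer.icer is not None else ""))
print(f"INHB at the 3x-GDP threshold (${WTP_3X_GDP:,.0f}/QALY): "
      f"{inhb(icer.delta_effect, icer.delta_cost, WTP_3X_GDP):+.3f} QALY")
print("  -> positive INHB means FOLFOX4 is preferred at that willingness-to-pay")
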