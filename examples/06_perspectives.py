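"""Healthcare-system vs patient-copayment perspective.

Applies the copayment map (15% inpatient, 25% outpatient shares) to the
published per-arm cost components, reproducing the published patient-borne
totals of $1395 (FOLFOX4) and $3200 (sorafenib).
"""

from pscea import apply_perspective, incremental, reconciled_copay_map
from pscea.engine import EconResult


def published(arm, **comps):
    comps["total"] = sum(comps.values())
    return EconResult(arm, dict(comps), dict(comps), 0.0, 0.0, 0.0)


folfox = published("folfox4", drug=6972, ward=145, ae=69, tests=1242)
soraf = published("sorafenib", drug=12289, ward=0, ae=4, tests=504)
copay = reconciled_copay_map("folfox4", "sorafenib")

print(f"{'':>10}{'system total':>14}{'patient total':>15}")
for res in (folfox, soraf):
    patient = apply_perspective(res, copay)
    print(f"{res.arm_name:>10}{res.discounted['total']:>14,.0f}"
          f"{patient.discounted['total']:>15,.1f}")
print("\n  -> published patient-perspective totals: $1395 and $3200; the gap between")
print("     arms narrows but FOLFOX4 stays cheaper from the patient's pocket too")

delta = apply_perspective(folfox, copay).discounted["total"] - \
    apply_perspective(soraf, copay).discounted["total"]
print(f"patient-borne saving with FOLFOX4: ${-delta:,.0f} per patient")
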