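"""BSA dosing and monthly drug costs, reproducing the published figures.

The reference patient (161.5 cm, 61.8 kg — an average Chinese adult) gives
a BSA of 1.623 m2; per-cycle FOLFOX4 doses and monthly drug costs for both
arms follow from the packaged unit costs.
"""

from pscea import bsa, default_model, monthly_drug_cost, per_cycle_doses

model = default_model(sorafenib_pfs_median=2.8)
patient = model.patient

print(f"BSA({patient.height_cm} cm, {patient.weight_kg} kg) = {bsa(patient):.5f} m2")
for line in per_cycle_doses(model.intervention.regimen, patient):
    print(f"  {line.drug:>12}: {line.mg:5d} mg per treatment cycle")
print("  -> the published 138 / 649 / 3247 mg per cycle")

folfox = monthly_drug_cost(model.intervention.regimen, patient)
soraf = monthly_drug_cost(model.comparator.regimen, patient)
print(f"\nFOLFOX4 drug cost:   ${folfox:7.1f}/month in PFS (published $1865, "
      "difference is the published 5-FU unit-cost rounding)")
print(f"sorafenib drug cost: ${soraf:7.1f}/month in PFS (published $3777)")

whole_pack = monthly_drug_cost(model.intervention.regimen, patient, "whole_pack")
print(f"FOLFOX4 with whole-pack (wastage) pricing: ${whole_pack:7.1f}/month")
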