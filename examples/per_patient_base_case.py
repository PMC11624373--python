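"""Per-patient discounted 6-year Medicare costs for the three device profiles.

Loads the built-in base-case inputs, runs the cohort engine for each
battery capacity, and prints the cost breakdown table plus the savings of
the 2.1-Ah device over the lower-capacity alternatives.
"""

from crtdcost import builtin_base_case, compare_devices
from crtdcost.report import per_patient_frame

params = builtin_base_case()
print(per_patient_frame(params, reference="2.1 Ah").to_string(index=False))

for comparator in ("1.0 Ah", "1.6 Ah"):
    saving = compare_devices(params, "2.1 Ah", comparator).absolute["total"]
    print(f"\nChoosing 2.1 Ah over {comparator} saves ${saving:,.0f} per patient "
          "over 6 years (discounted 2023 USD).")

# The rows are discounted expected costs per implanted patient: the initial
# implant block is identical across devices, so the entire difference comes
# from the expected number (and timing) of battery replacements.
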