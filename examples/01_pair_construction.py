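"""Build all patient-matched intracranial/extracranial sample pairs.

Uses the published 16-patient cohort layout (one brain sample per
patient, 1-3 extracranial samples): every (intracranial, extracranial)
combination within a patient becomes one analysis pair.
"""

import pairhmm as ph

sheet = ph.study_design_sheet()
pairs = ph.build_pairs(sheet)

print(f"{sheet['patient_id'].nunique()} patients, {len(sheet)} samples "
      f"-> {len(pairs)} matched pairs")
print(pairs.pairs.head(8).to_string(index=False))
print("Each pair compares one brain metastasis with one extracranial "
      "metastasis of the same patient; patients with several extracranial "
      "samples contribute several pairs (e.g. P08 contributes 3).")
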