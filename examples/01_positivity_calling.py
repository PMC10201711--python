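"""Replicate-consensus positivity calling on a tiny binding table.

Builds a 3-sample x 5-peptide quadruplicate RFU tensor by hand, applies
the 2-of-4-replicates-over-20,000-RFU rule, and shows how the
prevalence filter restricts the peptide universe to peptides positive
in enough cohort samples.
"""

import numpy as np

import seroselect as ss

rng = np.random.default_rng(0)
samples = ["patient_A", "patient_B", "patient_C"]
peptides = [f"FSP{i}" for i in range(5)]

# lognormal background around 400 RFU, ~50-fold under the threshold
rfu = rng.lognormal(np.log(400), 0.5, size=(3, 5, 4))
rfu[:, 0, :] = [[30000, 31000, 500, 29000],   # A: 3 of 4 hot -> positive
                [25000, 21000, 400, 300],     # B: 2 of 4 hot -> positive
                [19000, 25000, 100, 50]]      # C: only 1 over -> negative
rfu[0, 1, :] = [45000, 52000, 48000, 50000]   # A binds FSP1 strongly

tensor = ss.BindingTensor(samples, peptides, rfu, n_replicates=4)
pos = ss.call_positivity(tensor)  # default: >20,000 RFU in >=2 of 4
print("patient-positive calls (samples x peptides):")
print(pos.to_frame())

cohort = ss.ContrastCohort(
    "demo", samples,
    {"patient_A": "g+", "patient_B": "g+", "patient_C": "g-"}, "g+", "g-",
)
kept = ss.prevalence_filter(pos, cohort, ss.PositivityConfig(min_prevalence=2))
print("\npeptides positive in >=2 cohort samples:", kept)
# FSP0 is positive in A and B (2 samples) and survives; FSP1 is positive
# only in A and is dropped — rare reactivities cannot support a contrast.
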