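"""Clear-response model with a stable-disease holdout.

Stable-disease (SD) patients are an ambiguous response category, so a
cleaner responder/non-responder contrast drops them from model building.
The excluded SD samples are then scored against the finished model; on
real cohorts their predictions scatter across both poles, matching
their mixed radiologic assessments.
"""

import seroselect as ss

tensor, annotations, _ = ss.simulate_cohort(ss.SimConfig(seed=42))
pos = ss.call_positivity(tensor)

cohort = ss.build_cohort(annotations, "response_noSD")
print(f"training cohort without SD: {cohort.n_samples} samples")

candidates = ss.prevalence_filter(pos, cohort)
model = ss.build_model(pos, cohort, candidates, ss.SelectionConfig(seed=7))
report = ss.evaluate(ss.score_cohort(pos, cohort, model), cohort)
print(report)

holdout = ss.sd_holdout_ids(annotations)
preds = ss.score_cohort(pos, holdout, model)
frame = ss.predictions_frame(preds)
print(f"\n{len(holdout)} SD holdout samples scored against the model:")
print(frame["predicted"].value_counts().to_string())
# Each SD sample receives a responder / non-responder / indeterminate
# call from markers it never contributed to.
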