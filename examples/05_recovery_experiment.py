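"""Multi-seed parameter-recovery experiment.

Runs the entire pipeline on freshly simulated cohorts across seeds and
reports how reliably stability selection recovers the planted markers
(recall), how often it admits unplanted peptides (null admission), and
how well the resulting models classify holdout samples generated by the
same process but excluded from selection.
"""

import seroselect as ss

sim = ss.SimConfig(
    n_group_pos=25, n_group_neg=25, n_short_treatment=0,
    n_irae_symptomatic=15, n_irae_unknown=0, seed=0,
)
summary = ss.recovery_experiment(
    sim, ss.SelectionConfig(seed=0), n_seeds=10, holdout_per_group=10, base_seed=2024
)
print(summary.per_seed[["sim_seed", "n_candidates", "recall",
                        "null_admission", "holdout_accuracy"]].to_string(index=False))
print(f"\nmean planted recall:   {summary.mean_recall:.3f}")
print(f"mean null admission:   {summary.mean_null_admission:.5f}")
print(f"mean holdout accuracy: {summary.mean_holdout_accuracy:.3f}")
print(f"mean holdout coverage: {summary.mean_holdout_coverage:.3f}")
# Recall ~1 with null admission ~0 shows the 70-of-100 recurrence rule is
# a stringent error control at this effect size (prevalence 0.5 vs 0.03).
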