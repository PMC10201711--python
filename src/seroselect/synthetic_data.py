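"""Synthetic peptide-array cohorts with planted outcome-associated peptides.

The generator emulates the statistical structure of frameshift-peptide
array serology: sparse, bimodal, positively skewed RFU distributions in
which a serum sample reproducibly binds only ~0.3% of peptides at
signal ~50-fold above background. Unbound (sample, peptide) pairs draw
from a lognormal background (median ~400 RFU); truly bound pairs draw a
signal level uniform in [25,000, 60,000] RFU, far over the 20,000-RFU
positivity threshold. Replicates jitter the level multiplicatively with
a fixed coefficient of variation, and values saturate at the scanner
ceiling (65,535).

Outcome structure is planted: disjoint peptide sets are elevated from a
small out-group prevalence to a larger in-group prevalence for samples
in one pole of the response contrast (both poles carry markers) or of
the adverse-event contrast (one-sided, mirroring toxicity-only
markers). Ground truth is returned so selection recall, null admission
and holdout performance are measurable.

Defaults mirror the cohort margins of the motivating lung-cancer
checkpoint-inhibitor study: 74 samples (39 non-progressors = 1 CR +
25 PR + 13 SD, 27 progressors, 8 with under six weeks of therapy; 18
grade 2-4 adverse events, 42 grade 0-1, 14 unknown), quadruplicate
arrays, and a 5,000-peptide desk-scale array (full-scale generation is
supported but not the default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluation import evaluate
from .io_cohort import BindingTensor, ContrastCohort, SampleAnnotation, build_cohort
from .positivity import PositivityConfig, call_positivity, prevalence_filter
from .scoring import score_cohort
from .selection import SelectionConfig, assign_directions, resample_select

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Sample-structure counts default to the motivating study's margins;
    signal parameters default to the array's qualitative behaviour
    (lognormal background with median ~400 RFU, bound signal 25-60k RFU,
    replicate CV 0.15, 16-bit scanner saturation).
    """

    n_peptides: int = 5000
    n_group_pos: int = 39          # response-evaluable non-progressors
    n_group_neg: int = 27          # response-evaluable progressors
    n_short_treatment: int = 8     # under six weeks of therapy, response unused
    n_irae_symptomatic: int = 18   # grade 2-4 adverse events
    n_irae_unknown: int = 14       # no adverse-event annotation
    cr_fraction: float = 1 / 39    # of non-progressors with complete response
    sd_fraction: float = 13 / 39   # of non-progressors with stable disease
    combination_fraction: float = 0.4
    sclc_fraction: float = 0.14
    n_egfr_mutant: int = 2
    n_replicates: int = 4
    background_log_mean: float = math.log(400.0)
    background_log_sd: float = 0.5
    positive_rfu_low: float = 25_000.0
    positive_rfu_high: float = 60_000.0
    saturation: float = 65_535.0
    replicate_cv: float = 0.15
    baseline_positive_rate: float = 0.003
    n_informative_pos: int = 30
    n_informative_neg: int = 30
    n_informative_irae: int = 11
    prevalence_in_group: float = 0.5
    prevalence_out_group: float = 0.03
    replicate_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_informative_pos + self.n_informative_neg + self.n_informative_irae
        if planted > self.n_peptides:
            raise ConfigError(
                f"{planted} planted peptides exceed n_peptides={self.n_peptides}"
            )
        if not self.prevalence_in_group > self.prevalence_out_group:
            raise ConfigError("prevalence_in_group must exceed prevalence_out_group")
        if not 0 <= self.baseline_positive_rate <= 1:
            raise ConfigError("baseline_positive_rate must be in [0, 1]")
        if self.n_irae_symptomatic + self.n_irae_unknown > self.n_total_samples:
            raise ConfigError("irAE structure exceeds total sample count")
        if self.n_replicates < 1 or self.n_peptides < 1:
            raise ConfigError("n_replicates and n_peptides must be positive")

    @property
    def n_total_samples(self) -> int:
        return self.n_group_pos + self.n_group_neg + self.n_short_treatment


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort: planted peptide sets and the
    per-sample true-binding indicator matrix (samples x peptides)."""

    sample_ids: list[str]
    peptide_ids: list[str]
    planted_pos: list[str]
    planted_neg: list[str]
    planted_irae: list[str]
    bound: np.ndarray

    @property
    def planted_response(self) -> list[str]:
        return self.planted_pos + self.planted_neg

    def null_peptides(self, contrast: str = "response") -> list[str]:
        """Peptides carrying no planted signal for the given contrast."""
        planted = set(self.planted_response if contrast == "response" else self.planted_irae)
        return [p for p in self.peptide_ids if p not in planted]


def _replicate_sigma(cv: float) -> float:
    # lognormal sigma giving multiplicative jitter with unit mean and the
    # requested coefficient of variation
    return math.sqrt(math.log(1.0 + cv * cv))


def simulate_cohort(
    config: SimConfig | None = None,
) -> tuple[BindingTensor, list[SampleAnnotation], SyntheticTruth]:
    """Draw a complete synthetic cohort: binding tensor, annotations, truth.

    The draw is bit-stable for a fixed ``config.seed``. Sample layout:
    non-progressor pole first (CR, then PR, then SD), then the
    progressor pole, then short-treatment samples (response unused).
    Therapy, subtype, adverse-event grade and EGFR status are assigned
    by seeded draws at the configured marginal counts; the adverse-event
    structure is independent of the response poles, as in the assay's
    real cohorts.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_total_samples
    P = cfg.n_peptides
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    peptide_ids = [f"FSP{i + 1:05d}" for i in range(P)]

    # --- clinical annotations -------------------------------------------
    n_cr = round(cfg.cr_fraction * cfg.n_group_pos)
    n_sd = round(cfg.sd_fraction * cfg.n_group_pos)
    if n_cr + n_sd > cfg.n_group_pos:
        raise ConfigError("cr_fraction + sd_fraction exceed the non-progressor pole")
    responses: list[str | None] = (
        ["CR"] * n_cr
        + ["PR"] * (cfg.n_group_pos - n_cr - n_sd)
        + ["SD"] * n_sd
        + ["PD"] * cfg.n_group_neg
        + [None] * cfg.n_short_treatment
    )
    weeks = np.concatenate(
        [
            rng.uniform(6.0, 104.0, cfg.n_group_pos + cfg.n_group_neg),
            rng.uniform(1.0, 6.0, cfg.n_short_treatment),
        ]
    )
    n_comb = round(cfg.combination_fraction * n)
    therapy = np.array(["monotherapy"] * n, dtype=object)
    therapy[rng.choice(n, size=n_comb, replace=False)] = "combination"
    n_sclc = round(cfg.sclc_fraction * n)
    subtype = np.array(["NSCLC"] * n, dtype=object)
    subtype[rng.choice(n, size=n_sclc, replace=False)] = "SCLC"

    irae: np.ndarray = np.empty(n, dtype=object)
    order = rng.permutation(n)
    unknown_idx = order[: cfg.n_irae_unknown]
    sympt_idx = order[cfg.n_irae_unknown : cfg.n_irae_unknown + cfg.n_irae_symptomatic]
    asympt_idx = order[cfg.n_irae_unknown + cfg.n_irae_symptomatic :]
    irae[unknown_idx] = "unknown"
    irae[sympt_idx] = rng.integers(2, 5, size=len(sympt_idx))
    irae[asympt_idx] = rng.integers(0, 2, size=len(asympt_idx))

    egfr = np.zeros(n, dtype=bool)
    pd_idx = [i for i, r in enumerate(responses) if r == "PD"]
    if cfg.n_egfr_mutant and pd_idx:
        k = min(cfg.n_egfr_mutant, len(pd_idx))
        egfr[rng.choice(pd_idx, size=k, replace=False)] = True

    annotations = [
        SampleAnnotation(
            sample_id=sample_ids[i],
            best_response=responses[i],
            treatment_weeks=float(weeks[i]),
            therapy=str(therapy[i]),
            subtype=str(subtype[i]),
            irae_grade=irae[i] if irae[i] == "unknown" else int(irae[i]),
            egfr_mutant=bool(egfr[i]),
        )
        for i in range(n)
    ]

    # --- planted peptides and true binding ------------------------------
    total_planted = cfg.n_informative_pos + cfg.n_informative_neg + cfg.n_informative_irae
    chosen = rng.choice(P, size=total_planted, replace=False)
    planted_pos = chosen[: cfg.n_informative_pos]
    planted_neg = chosen[cfg.n_informative_pos : cfg.n_informative_pos + cfg.n_informative_neg]
    planted_irae = chosen[cfg.n_informative_pos + cfg.n_informative_neg :]

    prob = np.full((n, P), cfg.baseline_positive_rate)
    in_pos_pole = np.array([r in ("CR", "PR", "SD") for r in responses])
    in_neg_pole = np.array([r == "PD" for r in responses])
    sympt_mask = np.zeros(n, dtype=bool)
    sympt_mask[sympt_idx] = True

    prob[np.ix_(in_pos_pole, planted_pos)] = cfg.prevalence_in_group
    prob[np.ix_(~in_pos_pole, planted_pos)] = cfg.prevalence_out_group
    prob[np.ix_(in_neg_pole, planted_neg)] = cfg.prevalence_in_group
    prob[np.ix_(~in_neg_pole, planted_neg)] = cfg.prevalence_out_group
    prob[np.ix_(sympt_mask, planted_irae)] = cfg.prevalence_in_group
    prob[np.ix_(~sympt_mask, planted_irae)] = cfg.prevalence_out_group

    bound = rng.random((n, P)) < prob

    # --- RFU generation --------------------------------------------------
    background = rng.lognormal(cfg.background_log_mean, cfg.background_log_sd, (n, P))
    signal = rng.uniform(cfg.positive_rfu_low, cfg.positive_rfu_high, (n, P))
    level = np.where(bound, signal, background)
    sigma = _replicate_sigma(cfg.replicate_cv)
    jitter = rng.lognormal(-0.5 * sigma * sigma, sigma, (n, P, cfg.n_replicates))
    rfu = level[:, :, None] * jitter
    if cfg.replicate_dropout_rate > 0:
        drop = bound[:, :, None] & (
            rng.random((n, P, cfg.n_replicates)) < cfg.replicate_dropout_rate
        )
        rfu[drop] = rng.lognormal(
            cfg.background_log_mean, cfg.background_log_sd, int(drop.sum())
        )
    np.clip(rfu, 0.0, cfg.saturation, out=rfu)

    tensor = BindingTensor(sample_ids, peptide_ids, rfu, n_replicates=cfg.n_replicates)
    truth = SyntheticTruth(
        sample_ids=sample_ids,
        peptide_ids=peptide_ids,
        planted_pos=[peptide_ids[i] for i in planted_pos],
        planted_neg=[peptide_ids[i] for i in planted_neg],
        planted_irae=[peptide_ids[i] for i in planted_irae],
        bound=bound,
    )
    return tensor, annotations, truth


# ---------------------------------------------------------------------------
# Reference cohort margins
# ---------------------------------------------------------------------------

def reference_cohort_annotations() -> list[SampleAnnotation]:
    """Deterministic 74-sample annotation table with the marginal outcome
    distribution of the motivating lung-cancer cohort.

    Margins: 1 CR, 25 PR, 13 SD, 27 PD, 8 under six weeks of therapy;
    adverse events 18 grade 2-4, 42 grade 0-1, 14 unknown; 26
    combination-therapy samples among the 66 response-evaluable (40
    monotherapy) plus 4 among the short-treatment samples (30 total,
    ~40%); 9 SCLC among the evaluable plus 1 short-treatment; 2
    EGFR-mutant progressors. The binding data accompanying a real cohort
    are not bundled; only the annotation margins are reproduced, so
    cohort-construction arithmetic is checkable end to end.
    """
    ann: list[SampleAnnotation] = []
    # response categories for the 66 evaluable, then 8 short-treatment
    responses = ["CR"] + ["PR"] * 25 + ["SD"] * 13 + ["PD"] * 27 + [None] * 8
    weeks = [26.0] * 66 + [3.0] * 8
    # 26 combination among the evaluable, 4 among short-treatment
    therapy = (
        ["combination"] * 26 + ["monotherapy"] * 40 + ["combination"] * 4 + ["monotherapy"] * 4
    )
    # 9 SCLC among the evaluable (placed across both poles), 1 short
    subtype = ["NSCLC"] * 74
    for i in [2, 10, 18, 26, 34, 42, 50, 58, 64, 70]:
        subtype[i] = "SCLC"
    # adverse events: 14 unknown, 18 symptomatic, 42 grade 0-1, spread
    # independently of the response filter (4 unknown among short-treatment)
    irae: list[int | str] = []
    for i in range(74):
        if i % 7 == 3 and irae.count("unknown") < 14:
            irae.append("unknown")
        else:
            irae.append(-1)  # placeholder
    while irae.count("unknown") < 14:  # top up deterministically
        irae[irae.index(-1)] = "unknown"
    grades = [2, 3, 4] * 6  # 18 symptomatic
    known_slots = [i for i, g in enumerate(irae) if g == -1]
    for slot, grade in zip(known_slots[::3], grades):
        irae[slot] = grade
    for i, g in enumerate(irae):
        if g == -1:
            irae[i] = i % 2  # grades 0/1
    egfr = [False] * 74
    egfr[40] = egfr[52] = True  # two progressors
    for i in range(74):
        ann.append(
            SampleAnnotation(
                sample_id=f"P{i + 1:03d}",
                best_response=responses[i],
                treatment_weeks=weeks[i],
                therapy=therapy[i],
                subtype=subtype[i],
                irae_grade=irae[i],
                egfr_mutant=egfr[i],
            )
        )
    return ann


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

@dataclass
class RecoverySummary:
    """Multi-seed parameter-recovery results for stability selection."""

    per_seed: pd.DataFrame
    mean_recall: float
    mean_null_admission: float
    mean_holdout_accuracy: float
    mean_holdout_coverage: float
    n_failures: int
    n_seeds: int


def recovery_experiment(
    sim_config: SimConfig,
    selection_config: SelectionConfig,
    n_seeds: int = 20,
    *,
    holdout_per_group: int = 10,
    base_seed: int | None = None,
    positivity_config: PositivityConfig | None = None,
) -> RecoverySummary:
    """Run the full pipeline across seeds and measure recovery of planted
    response-associated peptides.

    Per seed: a cohort is simulated with ``holdout_per_group`` extra
    samples per response pole; selection runs on the training samples
    only (positivity calling, a study-wide prevalence >= 1 pre-filter
    over all samples, the within-cohort prevalence filter, resampled
    chi-square selection, direction assignment); the holdout samples —
    generated by the same process but excluded from selection — are then
    scored and evaluated against their true poles.

    Reported per seed: planted recall (retained / planted, over both
    response poles), null admission (retained non-planted peptides over
    all non-planted peptides), and holdout accuracy/coverage. Seeds with
    an empty model are recorded as failures (NaN metrics) rather than
    raised.
    """
    pos_cfg = positivity_config or PositivityConfig()
    root = np.random.SeedSequence(sim_config.seed if base_seed is None else base_seed)
    seed_pairs = [
        (int(s.generate_state(2)[0] % 2**31), int(s.generate_state(2)[1] % 2**31))
        for s in root.spawn(n_seeds)
    ]
    records = []
    for sim_seed, sel_seed in seed_pairs:
        cfg = replace(
            sim_config,
            seed=sim_seed,
            n_group_pos=sim_config.n_group_pos + holdout_per_group,
            n_group_neg=sim_config.n_group_neg + holdout_per_group,
        )
        tensor, annotations, truth = simulate_cohort(cfg)
        # last holdout_per_group samples of each pole are held out
        pos_ids = [a.sample_id for a in annotations if a.best_response in ("CR", "PR", "SD")]
        neg_ids = [a.sample_id for a in annotations if a.best_response == "PD"]
        holdout = set(pos_ids[-holdout_per_group:] + neg_ids[-holdout_per_group:])
        train_ann = [a for a in annotations if a.sample_id not in holdout]
        cohort = build_cohort(train_ann, "progression")

        pos = call_positivity(tensor, pos_cfg)
        prefilter = prevalence_filter(
            pos, tensor.sample_ids, replace(pos_cfg, min_prevalence=1)
        )
        candidates = prevalence_filter(pos, cohort, pos_cfg, peptides=prefilter)

        planted = set(truth.planted_response)
        null = [p for p in truth.peptide_ids if p not in planted]
        rec = {
            "sim_seed": sim_seed,
            "n_candidates": len(candidates),
            "recall": np.nan,
            "null_admission": np.nan,
            "holdout_accuracy": np.nan,
            "holdout_coverage": np.nan,
            "failed": False,
        }
        if candidates:
            recurrence = resample_select(
                pos, cohort, candidates, replace(selection_config, seed=sel_seed)
            )
            retained = [
                p
                for p in candidates
                if recurrence[p] >= selection_config.recurrence_threshold
            ]
            rec["recall"] = len(planted & set(retained)) / len(planted) if planted else np.nan
            rec["null_admission"] = len(set(retained) - planted) / len(null) if null else 0.0
            if retained:
                try:
                    model = assign_directions(pos, cohort, retained, recurrence)
                except Exception:
                    rec["failed"] = True
                    model = None
                if model is not None:
                    truth_labels = {
                        s: cohort.group_pos if s in set(pos_ids) else cohort.group_neg
                        for s in holdout
                    }
                    preds = score_cohort(pos, sorted(holdout), model)
                    report = evaluate(
                        preds,
                        truth_labels,
                        group_pos=cohort.group_pos,
                        group_neg=cohort.group_neg,
                    )
                    rec["holdout_accuracy"] = report.accuracy_classified
                    rec["holdout_coverage"] = report.coverage
            else:
                rec["failed"] = True
        else:
            rec["failed"] = True
        records.append(rec)

    frame = pd.DataFrame(records)
    return RecoverySummary(
        per_seed=frame,
        mean_recall=float(frame["recall"].mean()),
        mean_null_admission=float(frame["null_admission"].mean()),
        mean_holdout_accuracy=float(frame["holdout_accuracy"].mean()),
        mean_holdout_coverage=float(frame["holdout_coverage"].mean()),
        n_failures=int(frame["failed"].sum()),
        n_seeds=n_seeds,
    )
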