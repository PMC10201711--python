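"""Indeterminate-aware performance reporting and model-overlap counts.

The performance matrix is observed group x (predicted group_pos,
predicted group_neg, indeterminate). Accuracy is reported among
classified samples — the convention for classifiers with an abstention
class — alongside *coverage*, the fraction of samples classified at
all. An intent-to-classify accuracy that counts indeterminates as
errors is also computed for transparency. Sensitivity and specificity
treat group_pos as the positive class, excluding indeterminates from
both (they are reported separately through coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_cohort import ContrastCohort
from .scoring import INDETERMINATE, SamplePrediction
from .selection import ContrastModel

logger = logging.getLogger(__name__)


@dataclass
class PerformanceReport:
    """Confusion counts plus indeterminate-aware summary metrics.

    ``counts`` is a 2x3 DataFrame: rows are the observed groups
    (group_pos first), columns the predicted group_pos / group_neg /
    indeterminate. ``accuracy_classified`` and sensitivity/specificity
    are NaN when their denominators are empty.
    """

    counts: pd.DataFrame
    group_pos: str
    group_neg: str
    accuracy_classified: float
    accuracy_intent: float
    coverage: float
    sensitivity: float
    specificity: float
    n_total: int

    @classmethod
    def from_counts(
        cls,
        counts,
        group_pos: str = "group_pos",
        group_neg: str = "group_neg",
    ) -> "PerformanceReport":
        """Build a report from a 2x3 (or 2x2, no-indeterminate) count table.

        Rows: observed (group_pos, group_neg); columns: predicted
        group_pos, predicted group_neg[, indeterminate].
        """
        arr = np.asarray(counts, dtype=int)
        if arr.shape == (2, 2):
            arr = np.hstack([arr, np.zeros((2, 1), dtype=int)])
        if arr.shape != (2, 3):
            raise ConfigError(f"counts must be 2x3 (or 2x2), got {arr.shape}")
        frame = pd.DataFrame(
            arr,
            index=pd.Index([group_pos, group_neg], name="observed"),
            columns=pd.Index([group_pos, group_neg, INDETERMINATE], name="predicted"),
        )
        n_total = int(arr.sum())
        n_ind = int(arr[:, 2].sum())
        n_classified = n_total - n_ind
        correct = int(arr[0, 0] + arr[1, 1])
        acc = correct / n_classified if n_classified else float("nan")
        acc_intent = correct / n_total if n_total else float("nan")
        coverage = n_classified / n_total if n_total else float("nan")
        sens_den = int(arr[0, 0] + arr[0, 1])
        spec_den = int(arr[1, 0] + arr[1, 1])
        sens = arr[0, 0] / sens_den if sens_den else float("nan")
        spec = arr[1, 1] / spec_den if spec_den else float("nan")
        return cls(
            counts=frame,
            group_pos=group_pos,
            group_neg=group_neg,
            accuracy_classified=acc,
            accuracy_intent=acc_intent,
            coverage=coverage,
            sensitivity=sens,
            specificity=spec,
            n_total=n_total,
        )

    @property
    def n_indeterminate(self) -> int:
        return int(self.counts[INDETERMINATE].sum())

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_numpy().tolist(),
            "group_pos": self.group_pos,
            "group_neg": self.group_neg,
            "accuracy_classified": self.accuracy_classified,
            "accuracy_intent": self.accuracy_intent,
            "coverage": self.coverage,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_total": self.n_total,
        }

    def __str__(self) -> str:  # human-readable summary, percentages to 1 d.p.
        lines = [self.counts.to_string(), ""]
        lines.append(f"accuracy (classified): {100 * self.accuracy_classified:.1f}%")
        lines.append(f"coverage:              {100 * self.coverage:.1f}%")
        if np.isfinite(self.sensitivity):
            lines.append(f"sensitivity:           {100 * self.sensitivity:.1f}%")
        if np.isfinite(self.specificity):
            lines.append(f"specificity:           {100 * self.specificity:.1f}%")
        return "\n".join(lines)


def evaluate(
    predictions: Sequence[SamplePrediction],
    observed: ContrastCohort | Mapping[str, str],
    *,
    group_pos: str | None = None,
    group_neg: str | None = None,
) -> PerformanceReport:
    """Tabulate predictions against observed labels.

    ``observed`` is a :class:`ContrastCohort` (pole names taken from it)
    or a sample_id -> label mapping with the pole names given
    explicitly. Every prediction must have an observed label; offending
    sample ids are listed otherwise. The report is invariant to
    prediction order.
    """
    if isinstance(observed, ContrastCohort):
        labels: Mapping[str, str] = observed.labels
        group_pos, group_neg = observed.group_pos, observed.group_neg
    else:
        labels = observed
        if group_pos is None or group_neg is None:
            raise ConfigError("group_pos/group_neg required with a label mapping")
    missing = [p.sample_id for p in predictions if p.sample_id not in labels]
    if missing:
        raise ConfigError(f"no observed label for samples {missing}")
    bad = {
        p.sample_id: labels[p.sample_id]
        for p in predictions
        if labels[p.sample_id] not in (group_pos, group_neg)
    }
    if bad:
        raise ConfigError(f"observed labels outside contrast poles: {bad}")

    arr = np.zeros((2, 3), dtype=int)
    rows = {group_pos: 0, group_neg: 1}
    cols = {group_pos: 0, group_neg: 1, INDETERMINATE: 2}
    for p in predictions:
        arr[rows[labels[p.sample_id]], cols[p.predicted]] += 1
    return PerformanceReport.from_counts(arr, group_pos, group_neg)


def model_overlap(models: Sequence[ContrastModel]) -> dict:
    """Exact-subset peptide counts across models (Venn-diagram counts).

    For every non-empty subset of model names, counts the peptides coded
    in *exactly* those models; also returns per-model totals. Exclusive
    counts partition the union of all models' peptide sets.
    """
    if len(models) < 2:
        raise ConfigError("model_overlap requires at least 2 models")
    names = [m.contrast_name for m in models]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate model names: {names}")
    sets = {m.contrast_name: set(m.peptide_codes) for m in models}
    universe = set().union(*sets.values())
    exclusive: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            inside = set(subset)
            members = set.intersection(*(sets[n] for n in subset)) - set().union(
                *(sets[n] for n in names if n not in inside), set()
            )
            exclusive[subset] = len(members)
    return {
        "exclusive": exclusive,
        "totals": {n: len(sets[n]) for n in names},
        "union_size": len(universe),
    }
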