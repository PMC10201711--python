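"""Contrast scoring of samples against a model, with an indeterminate class.

A sample's score is the sum of the codes of the model peptides it binds
(+1 or -1 each; unbound peptides contribute zero). Under bidirectional
scoring the sign of the sum classifies the sample and a zero sum —
either no model peptide bound or balanced binding — is *indeterminate*.
Under unidirectional scoring (one-sided models) a sample binding at
least ``unidirectional_threshold`` model peptides is assigned to the
associated pole and every other sample to the opposite pole; there are
no indeterminates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .io_cohort import ContrastCohort
from .positivity import PositivityMatrix
from .selection import ContrastModel

INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SamplePrediction:
    """Score and predicted pole for one sample."""

    sample_id: str
    score: int
    predicted: str
    n_model_peptides_positive: int


def _classify(score: int, n_positive: int, model: ContrastModel) -> str:
    group_pos, group_neg = model.pole_names
    if model.scoring_mode == "unidirectional":
        return group_pos if n_positive >= model.unidirectional_threshold else group_neg
    if score > 0:
        return group_pos
    if score < 0:
        return group_neg
    return INDETERMINATE


def score_sample(pos_row, model: ContrastModel, sample_id: str = "") -> SamplePrediction:
    """Score one sample's positivity calls against a contrast model.

    ``pos_row`` is a boolean vector aligned to ``model.peptide_ids``, or
    a mapping / pandas Series keyed by peptide id (which is aligned
    here; missing model peptides raise :class:`AlignmentError`).
    """
    if isinstance(pos_row, Mapping):
        pos_row = pd.Series(pos_row)
    if isinstance(pos_row, pd.Series):
        missing = [p for p in model.peptide_ids if p not in pos_row.index]
        if missing:
            raise AlignmentError(f"positivity row lacks model peptides {missing}")
        row = pos_row.reindex(model.peptide_ids).to_numpy(dtype=bool)
    else:
        row = np.asarray(pos_row, dtype=bool)
        if row.shape != (model.n_peptides,):
            raise AlignmentError(
                f"positivity row length {row.shape} does not match "
                f"{model.n_peptides} model peptides"
            )
    score = int(model.codes_array()[row].sum())
    n_positive = int(row.sum())
    return SamplePrediction(
        sample_id=sample_id,
        score=score,
        predicted=_classify(score, n_positive, model),
        n_model_peptides_positive=n_positive,
    )


def score_cohort(
    pos: PositivityMatrix,
    samples: ContrastCohort | Sequence[str],
    model: ContrastModel,
) -> list[SamplePrediction]:
    """Score a set of samples against a model, preserving order.

    Samples need not belong to the model-building cohort, so holdout
    sets (e.g. stable-disease patients left out of a clear-response
    model) are scored with the same call. Positivity is sample-local, so
    no re-thresholding occurs. A sample absent from the positivity
    matrix raises a lookup error naming it.
    """
    sample_ids = samples.sample_ids if isinstance(samples, ContrastCohort) else list(samples)
    missing = [p for p in model.peptide_ids if p not in pos.peptide_ids]
    if missing:
        raise AlignmentError(f"positivity matrix lacks model peptides {missing}")
    calls = pos.submatrix(sample_ids, model.peptide_ids)
    codes = model.codes_array()
    scores = calls @ codes
    n_positive = calls.sum(axis=1)
    return [
        SamplePrediction(
            sample_id=s,
            score=int(sc),
            predicted=_classify(int(sc), int(np_), model),
            n_model_peptides_positive=int(np_),
        )
        for s, sc, np_ in zip(sample_ids, scores, n_positive)
    ]


def predictions_frame(predictions: Sequence[SamplePrediction]) -> pd.DataFrame:
    """Tabulate predictions (sample_id, score, n positive model peptides, call)."""
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in predictions],
            "score": [p.score for p in predictions],
            "n_positive_model_peptides": [p.n_model_peptides_positive for p in predictions],
            "predicted": [p.predicted for p in predictions],
        }
    )
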