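"""Iterated-subsample chi-square stability selection.

The screening loop draws a fixed fraction of the cohort without
replacement (default 80%), tests every candidate peptide's positivity
against the two-group contrast with a Pearson chi-square on the 2x2
table (positive/negative x pole), and repeats (default 100 times).
Peptides significant (p < 0.05 by default) in at least
``recurrence_threshold`` iterations (default 70) are retained; each is
then contrast-coded +1 or -1 according to which pole has more positive
samples in the full cohort. Recurrence across subsamples — not a
multiple-testing correction — is the error control.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .errors import ConfigError, DegenerateTableError, EmptyModelError
from .io_cohort import ContrastCohort
from .positivity import PositivityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Stability-selection parameters.

    subsample_fraction
        Fraction of cohort samples drawn (without replacement) per
        iteration; the subsample size is the floor of fraction x n.
    n_iterations
        Number of resampling iterations.
    p_threshold
        Per-iteration chi-square significance level.
    recurrence_threshold
        Minimum significant iterations for a peptide to be retained.
    yates
        Apply the Yates continuity correction to the chi-square
        statistic (off by default; the plain Pearson statistic is the
        more liberal screen).
    stratified
        Draw the subsample per pole instead of from the pooled cohort.
    """

    subsample_fraction: float = 0.8
    n_iterations: int = 100
    p_threshold: float = 0.05
    recurrence_threshold: int = 70
    seed: int = 0
    yates: bool = False
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ConfigError("subsample_fraction must be in (0, 1]")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")
        if not 1 <= self.recurrence_threshold <= self.n_iterations:
            raise ConfigError("recurrence_threshold must be in [1, n_iterations]")


@dataclass
class ContrastModel:
    """Retained peptides with their contrast codes and recurrence counts.

    ``peptide_codes`` maps peptide id to +1 (associated with
    ``pole_names[0]``, the group coded +1) or -1 (``pole_names[1]``).
    ``scoring_mode`` is ``"bidirectional"`` (signed sum with an
    indeterminate zero class) or ``"unidirectional"`` (count of positive
    model peptides against a threshold, no indeterminates; only valid
    when every code shares one sign).
    """

    contrast_name: str
    peptide_codes: dict[str, int]
    recurrence: dict[str, int]
    pole_names: tuple[str, str]
    scoring_mode: str = "bidirectional"
    unidirectional_threshold: int = 1

    def __post_init__(self) -> None:
        bad = {p: c for p, c in self.peptide_codes.items() if c not in (1, -1)}
        if bad:
            raise ConfigError(f"contrast codes must be +1 or -1, got {bad}")
        if self.scoring_mode not in ("bidirectional", "unidirectional"):
            raise ConfigError(f"unknown scoring_mode {self.scoring_mode!r}")
        if self.scoring_mode == "unidirectional":
            signs = set(self.peptide_codes.values())
            if len(signs) > 1:
                raise ConfigError("unidirectional mode requires codes of one sign")
            if self.unidirectional_threshold < 1:
                raise ConfigError("unidirectional_threshold must be >= 1")

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.peptide_codes)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_codes)

    def codes_array(self) -> np.ndarray:
        return np.array(list(self.peptide_codes.values()), dtype=int)

    def negated(self) -> "ContrastModel":
        """The model with poles exchanged and every code negated."""
        return ContrastModel(
            contrast_name=self.contrast_name + "_swapped",
            peptide_codes={p: -c for p, c in self.peptide_codes.items()},
            recurrence=dict(self.recurrence),
            pole_names=(self.pole_names[1], self.pole_names[0]),
            scoring_mode=self.scoring_mode,
            unidirectional_threshold=self.unidirectional_threshold,
        )

    def to_json(self, path=None) -> str:
        payload = {
            "contrast_name": self.contrast_name,
            "peptide_codes": self.peptide_codes,
            "recurrence": self.recurrence,
            "pole_names": list(self.pole_names),
            "scoring_mode": self.scoring_mode,
            "unidirectional_threshold": self.unidirectional_threshold,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ContrastModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            contrast_name=payload["contrast_name"],
            peptide_codes={p: int(c) for p, c in payload["peptide_codes"].items()},
            recurrence={p: int(c) for p, c in payload["recurrence"].items()},
            pole_names=tuple(payload["pole_names"]),
            scoring_mode=payload["scoring_mode"],
            unidirectional_threshold=int(payload["unidirectional_threshold"]),
        )


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def chisq_2x2(a: int, b: int, c: int, d: int, *, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, 1 degree of freedom.

    The table is (positive, negative) x (group_pos, group_neg):
    ``a`` = positive in group_pos, ``b`` = negative in group_pos,
    ``c`` = positive in group_neg, ``d`` = negative in group_neg.

    Any zero marginal yields statistic 0 and p-value 1 (an uninformative
    peptide simply fails the screen); an all-zero table raises
    :class:`DegenerateTableError`.
    """
    if min(a, b, c, d) < 0:
        raise ConfigError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise DegenerateTableError("all four counts are zero")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2.sf(stat, df=1))


def _chisq_vec(a, b, c, d, *, yates: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson chi-square over aligned count arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    ok = denom > 0
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    stat = np.zeros_like(n)
    np.divide(n * diff * diff, denom, out=stat, where=ok)
    p = np.ones_like(n)
    p[ok] = chi2.sf(stat[ok], df=1)
    return stat, p


# ---------------------------------------------------------------------------
# Resampled selection
# ---------------------------------------------------------------------------

def resample_select(
    pos: PositivityMatrix,
    cohort: ContrastCohort,
    peptides: Sequence[str],
    config: SelectionConfig,
) -> dict[str, int]:
    """Count, per peptide, the subsample iterations reaching significance.

    Each iteration draws ``floor(subsample_fraction * n)`` cohort samples
    without replacement from an iteration-specific random stream spawned
    from the master seed (so extending ``n_iterations`` never perturbs
    earlier draws), tests every candidate peptide with the Pearson
    chi-square, and counts p-values under ``p_threshold``. The returned
    map covers every candidate, including zero counts.
    """
    peptides = list(peptides)
    calls = pos.submatrix(cohort.sample_ids, peptides)
    labels = cohort.label_array()
    n = len(cohort.sample_ids)
    n_sub = math.floor(config.subsample_fraction * n)
    if n_sub < 1:
        raise ConfigError("subsample too small: floor(fraction * n) < 1")

    recurrence = np.zeros(len(peptides), dtype=int)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    pos_idx = np.nonzero(labels)[0]
    neg_idx = np.nonzero(~labels)[0]

    for stream in streams:
        rng = np.random.default_rng(stream)
        if config.stratified:
            k_pos = math.floor(config.subsample_fraction * len(pos_idx))
            k_neg = math.floor(config.subsample_fraction * len(neg_idx))
            idx = np.concatenate(
                [
                    rng.choice(pos_idx, size=k_pos, replace=False),
                    rng.choice(neg_idx, size=k_neg, replace=False),
                ]
            )
        else:
            idx = rng.choice(n, size=n_sub, replace=False)
        sub_labels = labels[idx]
        n_pos = int(sub_labels.sum())
        n_neg = len(idx) - n_pos
        if n_pos == 0 or n_neg == 0:
            logger.warning("subsample emptied one contrast pole; iteration uninformative")
            continue  # every table has a zero marginal -> p = 1 for all peptides
        sub = calls[idx]
        a = sub[sub_labels].sum(axis=0)
        c = sub[~sub_labels].sum(axis=0)
        _, p = _chisq_vec(a, n_pos - a, c, n_neg - c, yates=config.yates)
        recurrence += p < config.p_threshold

    return {pep: int(r) for pep, r in zip(peptides, recurrence)}


def assign_directions(
    pos: PositivityMatrix,
    cohort: ContrastCohort,
    retained: Sequence[str],
    recurrence: Mapping[str, int] | None = None,
) -> ContrastModel:
    """Contrast-code retained peptides by their majority pole.

    A peptide is coded +1 when more full-cohort positive samples fall in
    ``cohort.group_pos`` than in ``cohort.group_neg``, -1 for the
    reverse, and is dropped (with a logged warning) on a tie — a tied
    peptide has no majority pole.
    """
    retained = list(retained)
    if not retained:
        raise EmptyModelError("no peptides retained by stability selection")
    calls = pos.submatrix(cohort.sample_ids, retained)
    labels = cohort.label_array()
    pos_counts = calls[labels].sum(axis=0)
    neg_counts = calls[~labels].sum(axis=0)
    codes: dict[str, int] = {}
    for pep, np_, nn_ in zip(retained, pos_counts, neg_counts):
        if np_ > nn_:
            codes[pep] = 1
        elif nn_ > np_:
            codes[pep] = -1
        else:
            logger.warning("peptide %s tied between poles; dropped from model", pep)
    if not codes:
        raise EmptyModelError("all retained peptides tied between poles")
    recurrence = recurrence or {}
    return ContrastModel(
        contrast_name=cohort.name,
        peptide_codes=codes,
        recurrence={p: int(recurrence.get(p, 0)) for p in codes},
        pole_names=(cohort.group_pos, cohort.group_neg),
    )


def build_model(
    pos: PositivityMatrix,
    cohort: ContrastCohort,
    peptides: Sequence[str],
    config: SelectionConfig,
    *,
    auto_unidirectional: bool = True,
    unidirectional_threshold: int = 1,
) -> ContrastModel:
    """Run stability selection end to end and return the contrast model.

    When every surviving code shares one sign and ``auto_unidirectional``
    is set, the model switches to unidirectional scoring (samples binding
    at least ``unidirectional_threshold`` model peptides are assigned to
    the associated pole; no indeterminate class).
    """
    recurrence = resample_select(pos, cohort, peptides, config)
    retained = [p for p in peptides if recurrence[p] >= config.recurrence_threshold]
    if not retained:
        raise EmptyModelError(
            f"no peptide reached recurrence {config.recurrence_threshold}"
            f"/{config.n_iterations} for cohort {cohort.name!r}"
        )
    model = assign_directions(pos, cohort, retained, recurrence)
    signs = set(model.peptide_codes.values())
    if auto_unidirectional and len(signs) == 1:
        model = replace(
            model,
            scoring_mode="unidirectional",
            unidirectional_threshold=unidirectional_threshold,
        )
        if signs == {-1}:
            # orient the model so its single pole is the coded-positive one
            model = model.negated()
        logger.info(
            "model %s is one-sided; switched to unidirectional scoring",
            model.contrast_name,
        )
    return model


def model_jaccard(m1: ContrastModel, m2: ContrastModel) -> float:
    """Jaccard overlap of two models' peptide sets (seed-robustness check)."""
    s1, s2 = set(m1.peptide_codes), set(m2.peptide_codes)
    if not s1 and not s2:
        return 1.0
    return len(s1 & s2) / len(s1 | s2)
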