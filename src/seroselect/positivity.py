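"""Patient-positive calling and cohort-prevalence filtering.

A peptide is called *patient-positive* for a sample when enough
replicate arrays show signal strictly over an RFU threshold — by
default at least 2 of 4 replicates over 20,000 RFU (roughly 50-fold
above background on these arrays). The prevalence filter then restricts
the peptide universe for downstream statistics to peptides positive in
a minimum number of cohort samples (default 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_cohort import BindingTensor, ContrastCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositivityConfig:
    """Thresholds for positivity calling and prevalence filtering.

    rfu_threshold
        Signal must be strictly over this value to count (RFU).
    min_positive_replicates
        Replicates over threshold needed for a patient-positive call.
    min_prevalence
        Minimum positive cohort samples for a peptide to be retained.
    """

    rfu_threshold: float = 20_000.0
    min_positive_replicates: int = 2
    min_prevalence: int = 3

    def __post_init__(self) -> None:
        if self.rfu_threshold <= 0:
            raise ConfigError("rfu_threshold must be positive")
        if self.min_positive_replicates < 1:
            raise ConfigError("min_positive_replicates must be >= 1")
        if self.min_prevalence < 1:
            raise ConfigError("min_prevalence must be >= 1")


@dataclass
class PositivityMatrix:
    """Boolean sample x peptide patient-positive calls."""

    sample_ids: list[str]
    peptide_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        expected = (len(self.sample_ids), len(self.peptide_ids))
        if self.calls.shape != expected:
            raise ConfigError(
                f"calls shape {self.calls.shape} does not match {expected}"
            )
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._peptide_index = {p: i for i, p in enumerate(self.peptide_ids)}

    def sample_rows(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._sample_index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in positivity matrix") from None
        return self.calls[idx]

    def peptide_columns(self, peptide_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._peptide_index[p] for p in peptide_ids]
        except KeyError as exc:
            raise KeyError(f"peptide {exc.args[0]!r} not in positivity matrix") from None
        return self.calls[:, idx]

    def submatrix(self, sample_ids: Sequence[str], peptide_ids: Sequence[str]) -> np.ndarray:
        rows = [self._sample_index[s] for s in sample_ids]
        cols = [self._peptide_index[p] for p in peptide_ids]
        return self.calls[np.ix_(rows, cols)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls.astype(int), index=self.sample_ids, columns=self.peptide_ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("sample").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PositivityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            sample_ids=[str(s) for s in frame.index],
            peptide_ids=[str(p) for p in frame.columns],
            calls=frame.to_numpy(dtype=bool),
        )


def call_positivity(binding: BindingTensor, config: PositivityConfig | None = None) -> PositivityMatrix:
    """Convert replicate RFU measurements into patient-positive calls.

    ``call(sample, peptide)`` is true iff the number of replicates with
    RFU strictly over ``config.rfu_threshold`` is at least
    ``config.min_positive_replicates``. Missing replicates contribute
    nothing: a pair with fewer available replicates than the minimum is
    necessarily negative.
    """
    config = config or PositivityConfig()
    if config.min_positive_replicates > binding.n_replicates:
        raise ConfigError(
            f"min_positive_replicates={config.min_positive_replicates} exceeds "
            f"n_replicates={binding.n_replicates}"
        )
    with np.errstate(invalid="ignore"):
        over = binding.rfu > config.rfu_threshold  # NaN compares False
    calls = over.sum(axis=2) >= config.min_positive_replicates
    return PositivityMatrix(
        sample_ids=list(binding.sample_ids),
        peptide_ids=list(binding.peptide_ids),
        calls=calls,
    )


def prevalence_filter(
    pos: PositivityMatrix,
    cohort: ContrastCohort | Sequence[str],
    config: PositivityConfig | None = None,
    *,
    peptides: Sequence[str] | None = None,
) -> list[str]:
    """Peptides patient-positive in at least ``min_prevalence`` cohort samples.

    Counting is restricted to the cohort's samples; positives outside the
    cohort do not contribute. ``peptides`` optionally restricts the
    candidate universe (e.g. a study-wide pre-filter applied before a
    cohort-specific one). Input peptide order is preserved. An empty
    result is returned with a logged warning rather than an error.
    """
    config = config or PositivityConfig()
    sample_ids = cohort.sample_ids if isinstance(cohort, ContrastCohort) else list(cohort)
    candidates = list(pos.peptide_ids) if peptides is None else list(peptides)
    counts = pos.submatrix(sample_ids, candidates).sum(axis=0)
    retained = [p for p, c in zip(candidates, counts) if c >= config.min_prevalence]
    if not retained:
        logger.warning(
            "prevalence filter retained no peptides (min_prevalence=%d, %d samples)",
            config.min_prevalence,
            len(sample_ids),
        )
    return retained
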