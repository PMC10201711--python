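"""Binding-data I/O and analysis-cohort construction.

Binding data are per-sample, per-peptide, per-replicate relative
fluorescence units (RFU) from a peptide-microarray serological assay.
Two tabular text layouts are supported:

* **wide** — TSV with a leading ``peptide`` column and one column per
  ``<sample>_<replicate>`` pair (replicate indices are 1-based).
* **long** — TSV with columns ``sample``, ``peptide``, ``replicate``,
  ``rfu``.

Clinical annotations are a CSV with columns ``sample_id``,
``best_response``, ``treatment_weeks``, ``therapy``, ``subtype``,
``irae_grade``, ``egfr_mutant``.

A :class:`ContrastCohort` is the sample subset and binary labelling for
one two-group analysis, built by :func:`build_cohort` from a named
contrast (tumour progression, clear response, or immune-related adverse
events) plus optional homogeneity filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BindingValidationError, ConfigError, EmptyGroupError

logger = logging.getLogger(__name__)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
THERAPIES = ("monotherapy", "combination")
SUBTYPES = ("NSCLC", "SCLC")

#: Minimum weeks on checkpoint-inhibitor therapy for a radiologic best
#: response to count as evaluable. The boundary itself is included
#: ("at least 6 weeks").
MIN_TREATMENT_WEEKS = 6.0


# ---------------------------------------------------------------------------
# Binding tensor
# ---------------------------------------------------------------------------

@dataclass
class BindingTensor:
    """Raw RFU values indexed by sample x peptide x replicate.

    Missing replicate measurements are stored as NaN; all present values
    must be finite and non-negative. ``rfu`` has shape
    ``(n_samples, n_peptides, n_replicates)``.
    """

    sample_ids: list[str]
    peptide_ids: list[str]
    rfu: np.ndarray
    n_replicates: int = 4

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.peptide_ids = [str(p) for p in self.peptide_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise BindingValidationError("duplicate sample identifiers")
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise BindingValidationError("duplicate peptide identifiers")
        self.rfu = np.asarray(self.rfu, dtype=float)
        expected = (len(self.sample_ids), len(self.peptide_ids), self.n_replicates)
        if self.rfu.shape != expected:
            raise BindingValidationError(
                f"rfu shape {self.rfu.shape} does not match "
                f"(samples, peptides, replicates) = {expected}"
            )
        finite = np.isfinite(self.rfu)
        missing = np.isnan(self.rfu)
        if np.any(~finite & ~missing):
            raise BindingValidationError("rfu contains non-finite values")
        bad = finite & (self.rfu < 0)
        if np.any(bad):
            s, p, r = (int(i[0]) for i in np.nonzero(bad))
            raise BindingValidationError(
                f"negative RFU at sample={self.sample_ids[s]} "
                f"peptide={self.peptide_ids[p]} replicate={r + 1}"
            )
        if np.any(missing):
            n_pairs = int(np.any(missing, axis=2).sum())
            logger.warning(
                "%d (sample, peptide) pairs have missing replicates", n_pairs
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (sample, peptide) mask of pairs with any missing replicate."""
        return np.isnan(self.rfu).any(axis=2)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None


def _parse_wide_columns(columns: Sequence[str]) -> list[tuple[str, int]]:
    parsed = []
    for col in columns:
        sample, sep, rep = str(col).rpartition("_")
        if not sep or not sample or not rep.isdigit() or int(rep) < 1:
            raise BindingValidationError(
                f"malformed wide-format column {col!r}: expected <sample>_<replicate>"
            )
        parsed.append((sample, int(rep)))
    return parsed


def read_binding(path, layout: str = "wide") -> BindingTensor:
    """Read a binding TSV in ``wide`` or ``long`` layout into a tensor.

    Raises :class:`BindingValidationError` for malformed headers or
    negative / non-numeric RFU values (the offending column or row is
    named). Incomplete replicate sets are flagged missing with a logged
    warning.
    """
    if layout == "wide":
        frame = pd.read_csv(path, sep="\t", dtype={0: str})
        if frame.columns[0] != "peptide":
            raise BindingValidationError(
                f"wide layout must start with a 'peptide' column, got {frame.columns[0]!r}"
            )
        peptide_ids = frame["peptide"].astype(str).tolist()
        parsed = _parse_wide_columns(frame.columns[1:])
        sample_ids = list(dict.fromkeys(s for s, _ in parsed))
        n_rep = max(r for _, r in parsed)
        rfu = np.full((len(sample_ids), len(peptide_ids), n_rep), np.nan)
        for col, (sample, rep) in zip(frame.columns[1:], parsed):
            values = pd.to_numeric(frame[col], errors="coerce").to_numpy(float)
            raw_na = frame[col].isna().to_numpy()
            bad = np.isnan(values) & ~raw_na
            if bad.any():
                row = int(np.nonzero(bad)[0][0])
                raise BindingValidationError(
                    f"non-numeric RFU in column {col!r}, row {row}"
                )
            rfu[sample_ids.index(sample), :, rep - 1] = values
        return BindingTensor(sample_ids, peptide_ids, rfu, n_replicates=n_rep)

    if layout == "long":
        frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "peptide": str})
        required = {"sample", "peptide", "replicate", "rfu"}
        if not required.issubset(frame.columns):
            missing = sorted(required - set(frame.columns))
            raise BindingValidationError(f"long layout missing columns {missing}")
        values = pd.to_numeric(frame["rfu"], errors="coerce")
        bad = values.isna() & frame["rfu"].notna()
        if bad.any():
            raise BindingValidationError(
                f"non-numeric RFU at row {int(np.nonzero(bad.to_numpy())[0][0])}"
            )
        sample_ids = list(dict.fromkeys(frame["sample"]))
        peptide_ids = list(dict.fromkeys(frame["peptide"]))
        reps = frame["replicate"].astype(int)
        if (reps < 1).any():
            raise BindingValidationError("replicate indices must be 1-based")
        n_rep = int(reps.max())
        rfu = np.full((len(sample_ids), len(peptide_ids), n_rep), np.nan)
        si = {s: i for i, s in enumerate(sample_ids)}
        pi = {p: i for i, p in enumerate(peptide_ids)}
        rfu[
            frame["sample"].map(si).to_numpy(),
            frame["peptide"].map(pi).to_numpy(),
            reps.to_numpy() - 1,
        ] = values.to_numpy(float)
        return BindingTensor(sample_ids, peptide_ids, rfu, n_replicates=n_rep)

    raise ConfigError(f"unknown binding layout {layout!r}; expected 'wide' or 'long'")


def write_binding(path, tensor: BindingTensor, layout: str = "wide") -> None:
    """Write a binding tensor as TSV in the requested layout."""
    if layout == "wide":
        data = {"peptide": tensor.peptide_ids}
        for i, sample in enumerate(tensor.sample_ids):
            for r in range(tensor.n_replicates):
                data[f"{sample}_{r + 1}"] = tensor.rfu[i, :, r]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    elif layout == "long":
        s_idx, p_idx, r_idx = np.meshgrid(
            np.arange(tensor.n_samples),
            np.arange(tensor.n_peptides),
            np.arange(tensor.n_replicates),
            indexing="ij",
        )
        values = tensor.rfu.ravel()
        keep = ~np.isnan(values)
        frame = pd.DataFrame(
            {
                "sample": np.array(tensor.sample_ids)[s_idx.ravel()[keep]],
                "peptide": np.array(tensor.peptide_ids)[p_idx.ravel()[keep]],
                "replicate": r_idx.ravel()[keep] + 1,
                "rfu": values[keep],
            }
        )
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ConfigError(f"unknown binding layout {layout!r}")


# ---------------------------------------------------------------------------
# Clinical annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleAnnotation:
    """Clinical annotation for one serum sample.

    ``best_response`` is a RECIST best radiologic response category
    (CR/PR/SD/PD) or ``None`` when unavailable (permitted for samples
    with under six weeks of therapy, whose response is never used).
    ``irae_grade`` is 0-4 or the string ``"unknown"``.
    """

    sample_id: str
    best_response: str | None
    treatment_weeks: float | None
    therapy: str
    subtype: str
    irae_grade: int | str
    egfr_mutant: bool | None = None

    def __post_init__(self) -> None:
        if self.best_response is not None and self.best_response not in RESPONSE_CATEGORIES:
            raise ConfigError(f"invalid best_response {self.best_response!r}")
        if self.therapy not in THERAPIES:
            raise ConfigError(f"invalid therapy {self.therapy!r}")
        if self.subtype not in SUBTYPES:
            raise ConfigError(f"invalid subtype {self.subtype!r}")
        if self.irae_grade != "unknown" and self.irae_grade not in (0, 1, 2, 3, 4):
            raise ConfigError(f"invalid irae_grade {self.irae_grade!r}")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read sample annotations from CSV (columns as in the module docstring)."""
    frame = pd.read_csv(path, dtype={"sample_id": str})
    out = []
    for _, row in frame.iterrows():
        grade = row["irae_grade"]
        if pd.isna(grade) or str(grade) == "unknown":
            grade = "unknown"
        else:
            grade = int(grade)
        egfr = row.get("egfr_mutant")
        out.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                best_response=None if pd.isna(row["best_response"]) else str(row["best_response"]),
                treatment_weeks=None if pd.isna(row["treatment_weeks"]) else float(row["treatment_weeks"]),
                therapy=str(row["therapy"]),
                subtype=str(row["subtype"]),
                irae_grade=grade,
                egfr_mutant=None if pd.isna(egfr) else bool(egfr),
            )
        )
    return out


def write_annotations(path, annotations: Iterable[SampleAnnotation]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "best_response": a.best_response,
                "treatment_weeks": a.treatment_weeks,
                "therapy": a.therapy,
                "subtype": a.subtype,
                "irae_grade": a.irae_grade,
                "egfr_mutant": a.egfr_mutant,
            }
            for a in annotations
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Contrast cohorts
# ---------------------------------------------------------------------------

@dataclass
class ContrastCohort:
    """Sample subset, binary labels and filter provenance for one analysis."""

    name: str
    sample_ids: list[str]
    labels: dict[str, str]
    group_pos: str
    group_neg: str
    filters_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        poles = {self.group_pos, self.group_neg}
        bad = {s: l for s, l in self.labels.items() if l not in poles}
        if bad:
            raise ConfigError(f"labels outside contrast poles: {bad}")
        if set(self.sample_ids) != set(self.labels):
            raise ConfigError("sample_ids and labels disagree")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def pole_samples(self, pole: str) -> list[str]:
        return [s for s in self.sample_ids if self.labels[s] == pole]

    def label_array(self) -> np.ndarray:
        """Boolean array aligned to ``sample_ids``; True = group_pos."""
        return np.array([self.labels[s] == self.group_pos for s in self.sample_ids])

    def swapped(self) -> "ContrastCohort":
        """The same cohort with the two poles exchanged."""
        return ContrastCohort(
            name=self.name + "_swapped",
            sample_ids=list(self.sample_ids),
            labels=dict(self.labels),
            group_pos=self.group_neg,
            group_neg=self.group_pos,
            filters_applied=list(self.filters_applied) + ["poles_swapped"],
        )


#: Named contrasts: pole names and the annotation predicate for each pole.
CONTRASTS = {
    "progression": {
        "group_pos": "non_progressor",
        "group_neg": "progressor",
        "pos": lambda a: a.best_response in ("CR", "PR", "SD"),
        "neg": lambda a: a.best_response == "PD",
        "kind": "response",
    },
    "response_noSD": {
        "group_pos": "responder",
        "group_neg": "non_responder",
        "pos": lambda a: a.best_response in ("CR", "PR"),
        "neg": lambda a: a.best_response == "PD",
        "kind": "response",
    },
    "irae": {
        "group_pos": "symptomatic",
        "group_neg": "asymptomatic",
        "pos": lambda a: a.irae_grade != "unknown" and a.irae_grade >= 2,
        "neg": lambda a: a.irae_grade != "unknown" and a.irae_grade <= 1,
        "kind": "irae",
    },
}


def build_cohort(
    annotations: Sequence[SampleAnnotation],
    contrast: str,
    *,
    monotherapy_only: bool = False,
    nsclc_only: bool = False,
) -> ContrastCohort:
    """Build a labelled analysis cohort by applying inclusion filters.

    Filters are applied in a fixed order: (a) response contrasts drop
    samples with under :data:`MIN_TREATMENT_WEEKS` weeks of therapy (or
    unknown duration); (b) the adverse-event contrast drops samples with
    unknown irAE grade; (c) optional homogeneity filters
    (``monotherapy_only``, ``nsclc_only``); (d) pole labels are assigned
    from the contrast definition. Every filter is recorded in
    ``filters_applied`` so membership is reproducible from the
    annotations alone.
    """
    try:
        spec = CONTRASTS[contrast]
    except KeyError:
        raise ConfigError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
        ) from None

    filters: list[str] = []
    kept = list(annotations)

    if spec["kind"] == "response":
        before = len(kept)
        kept = [
            a
            for a in kept
            if a.treatment_weeks is not None
            and a.treatment_weeks >= MIN_TREATMENT_WEEKS
        ]
        filters.append(
            f"treatment_weeks>={MIN_TREATMENT_WEEKS:g} (dropped {before - len(kept)})"
        )
    else:  # irae
        before = len(kept)
        kept = [a for a in kept if a.irae_grade != "unknown"]
        filters.append(f"irae_grade known (dropped {before - len(kept)})")

    if monotherapy_only:
        before = len(kept)
        kept = [a for a in kept if a.therapy == "monotherapy"]
        filters.append(f"monotherapy_only (dropped {before - len(kept)})")
    if nsclc_only:
        before = len(kept)
        kept = [a for a in kept if a.subtype == "NSCLC"]
        filters.append(f"nsclc_only (dropped {before - len(kept)})")

    labels: dict[str, str] = {}
    dropped_unlabelled = 0
    for a in kept:
        if spec["pos"](a):
            labels[a.sample_id] = spec["group_pos"]
        elif spec["neg"](a):
            labels[a.sample_id] = spec["group_neg"]
        else:
            dropped_unlabelled += 1
    if dropped_unlabelled:
        filters.append(f"outside contrast poles (dropped {dropped_unlabelled})")
        logger.warning(
            "%d samples fit neither pole of contrast %s and were dropped",
            dropped_unlabelled,
            contrast,
        )

    sample_ids = [a.sample_id for a in kept if a.sample_id in labels]
    cohort = ContrastCohort(
        name=contrast
        + ("_monotherapy" if monotherapy_only else "")
        + ("_nsclc" if nsclc_only else ""),
        sample_ids=sample_ids,
        labels=labels,
        group_pos=spec["group_pos"],
        group_neg=spec["group_neg"],
        filters_applied=filters,
    )
    for pole in (cohort.group_pos, cohort.group_neg):
        if not cohort.pole_samples(pole):
            raise EmptyGroupError(
                f"contrast {contrast!r}: pole {pole!r} has no samples after filters {filters}"
            )
    return cohort


def sd_holdout_ids(annotations: Sequence[SampleAnnotation]) -> list[str]:
    """Treatment-evaluable samples with stable disease.

    These are excluded from the clear-response (``response_noSD``)
    contrast and typically scored afterwards as a holdout set.
    """
    return [
        a.sample_id
        for a in annotations
        if a.treatment_weeks is not None
        and a.treatment_weeks >= MIN_TREATMENT_WEEKS
        and a.best_response == "SD"
    ]
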