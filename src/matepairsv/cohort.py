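"""Cohort-level mutation summaries: per-patient effect-class tallies and
cross-patient gene recurrence frequencies.

The effect-class vocabulary is the closed set of functional consequence
categories used for small-cohort WGS landscape tables; records with any
other class are rejected rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

#: closed effect-class vocabulary, in canonical display order
EFFECT_CLASSES = (
    "nonsynonymous coding",
    "synonymous coding",
    "insertion/deletion",
    "stop gained",
    "start gained",
    "codon insertion",
    "codon deletion",
    "splice site donor",
    "splice site acceptor",
)


@dataclass(frozen=True)
class MutationRecord:
    patient: str
    gene: str
    effect_class: str

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(
                f"unknown effect class {self.effect_class!r}; "
                f"expected one of {EFFECT_CLASSES}"
            )


@dataclass
class CohortSummary:
    class_matrix: pd.DataFrame     # classes x patients, plus Total row
    total: int
    mean: float
    min: int
    max: int
    recurrence: pd.DataFrame       # gene, n_patients, percent


def tally_classes(
    records: Iterable[MutationRecord],
    patients: Sequence[str],
) -> pd.DataFrame:
    """Count mutations by (effect class, patient), zero-filled, with totals.

    Returns a DataFrame indexed by effect class (plus a ``Total`` row) with
    one column per declared patient, in declared order.  Records naming an
    undeclared patient are rejected.
    """
    counts = pd.DataFrame(0, index=list(EFFECT_CLASSES), columns=list(patients))
    declared = set(patients)
    for rec in records:
        if rec.patient not in declared:
            raise ValueError(f"record for undeclared patient {rec.patient!r}")
        counts.loc[rec.effect_class, rec.patient] += 1
    counts.loc["Total"] = counts.sum(axis=0)
    return counts


def summarize_totals(matrix: pd.DataFrame) -> tuple[int, float, int, int]:
    """(cohort total, mean/patient, min, max) from a tally matrix."""
    if matrix.shape[1] < 1:
        raise ValueError("need at least one patient")
    totals = matrix.loc["Total"] if "Total" in matrix.index else matrix.sum(axis=0)
    return (
        int(totals.sum()),
        float(totals.mean()),
        int(totals.min()),
        int(totals.max()),
    )


def _round_half_up(x: float, places: int = 1) -> float:
    return float(Decimal(str(x)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


def recurrence_frequency(
    records: Iterable[MutationRecord],
    cohort_size: int,
) -> pd.DataFrame:
    """Per-gene percent of patients carrying a mutation in the gene.

    Counts *distinct patients* (two hits in one patient count once); percent
    = patients / cohort_size * 100 rounded half-up to one decimal.  Sorted
    by descending frequency then gene name.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    carriers: dict[str, set[str]] = {}
    for rec in records:
        carriers.setdefault(rec.gene, set()).add(rec.patient)
    rows = [
        {
            "gene": gene,
            "n_patients": len(pats),
            "percent": _round_half_up(len(pats) / cohort_size * 100.0),
        }
        for gene, pats in carriers.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_patients", "percent"])
    return df.sort_values(
        ["percent", "gene"], ascending=[False, True], ignore_index=True
    )


def summarize_cohort(
    records: Sequence[MutationRecord],
    patients: Sequence[str],
) -> CohortSummary:
    matrix = tally_classes(records, patients)
    total, mean, mn, mx = summarize_totals(matrix)
    rec = recurrence_frequency(records, len(patients))
    return CohortSummary(
        class_matrix=matrix, total=total, mean=mean, min=mn, max=mx, recurrence=rec
    )
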