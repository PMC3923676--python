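"""Allele-specific expression: DNA vs RNA allele fractions at a variant site.

A heterozygous (or subclonal) somatic variant present in a fraction of the
DNA reads but a much larger fraction of the RNA reads from the same
specimen is preferentially expressed — the motivating case being a
loss-of-function nonsense mutation whose allele made up 11% of DNA reads
but 78% of RNA reads, implying near-complete silencing of the wild-type
copy.

The comparison is formalized as a two-sided Fisher exact test on the 2x2
table (dna_ref, dna_alt / rna_ref, rna_alt), Benjamini-Hochberg corrected
across sites.  A site is flagged when q <= alpha AND the absolute VAF
shift |rna_vaf - dna_vaf| reaches ``min_delta`` (default 0.2), so that
sampling noise at modest depth cannot flag on significance alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DELTA = 0.2

DIRECTION_OVER = "over-expressed alt"
DIRECTION_UNDER = "under-expressed alt"


@dataclass
class AseRecord:
    """Per-site DNA and RNA allele counts plus the ASE test result."""

    contig: str
    pos: int             # 0-based
    ref: str
    alt: str
    dna_ref_count: int
    dna_alt_count: int
    rna_ref_count: int
    rna_alt_count: int
    p_value: float | None = None
    q_value: float | None = None
    ase_flag: bool = False
    direction: str | None = None

    def __post_init__(self) -> None:
        for c in (
            self.dna_ref_count,
            self.dna_alt_count,
            self.rna_ref_count,
            self.rna_alt_count,
        ):
            if c < 0:
                raise ValueError("allele counts must be non-negative")

    @property
    def dna_vaf(self) -> float:
        return compute_vaf(self.dna_ref_count, self.dna_alt_count)

    @property
    def rna_vaf(self) -> float:
        return compute_vaf(self.rna_ref_count, self.rna_alt_count)

    @property
    def site(self) -> str:
        return f"{self.contig}:{self.pos + 1}{self.ref}>{self.alt}"


def compute_vaf(ref_count: int, alt_count: int) -> float:
    """Variant allele fraction alt/(ref+alt), exact rational before float."""
    depth = ref_count + alt_count
    if depth <= 0:
        raise ValueError("zero depth: VAF undefined")
    return float(Fraction(alt_count, depth))


def test_ase(
    record: AseRecord,
    alpha: float = DEFAULT_ALPHA,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> AseRecord:
    """Two-sided exact test of DNA vs RNA allele counts for one site.

    Sets ``p_value``, a provisional single-site flag (using p in place of q;
    :func:`adjust_multiplicity` finalizes it across a cohort) and the
    direction of the shift.  Requires non-zero DNA and RNA depth.
    """
    if record.dna_ref_count + record.dna_alt_count == 0:
        raise ValueError(f"{record.site}: zero DNA depth")
    if record.rna_ref_count + record.rna_alt_count == 0:
        raise ValueError(f"{record.site}: zero RNA depth")
    table = [
        [record.dna_ref_count, record.dna_alt_count],
        [record.rna_ref_count, record.rna_alt_count],
    ]
    record.p_value = float(fisher_exact(table, alternative="two-sided")[1])
    delta = record.rna_vaf - record.dna_vaf
    record.direction = DIRECTION_OVER if delta >= 0 else DIRECTION_UNDER
    record.ase_flag = record.p_value <= alpha and abs(delta) >= min_delta
    return record


def adjust_multiplicity(
    records: Sequence[AseRecord],
    alpha: float = DEFAULT_ALPHA,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> list[AseRecord]:
    """Benjamini-Hochberg step-up over all tested sites; re-derives flags.

    Records missing a p-value are tested first.  The flag requires both
    q <= alpha and a VAF shift of at least ``min_delta``.
    """
    if not records:
        raise ValueError("no records to adjust")
    for r in records:
        if r.p_value is None:
            test_ase(r, alpha=alpha, min_delta=min_delta)
    pvals = [r.p_value for r in records]
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for r, q in zip(records, qvals):
        r.q_value = float(q)
        r.ase_flag = r.q_value <= alpha and abs(r.rna_vaf - r.dna_vaf) >= min_delta
    return list(records)
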