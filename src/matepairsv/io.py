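"""Readers, writers and run configuration for the pipeline's file formats.

Canonical alignment input is a plain-TSV "fragment table" (one long-insert
fragment per row) so the whole pipeline runs with zero binary
dependencies; SAM export is available for interoperability.  BED, bedGraph
and BEDPE outputs are 0-based half-open per their conventions; GTF input
and VCF-style positions are 1-based and converted at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ase import AseRecord
from .coverage import CnvSegment, CoverageTrack, FragmentAlignment, Log2RatioTrack
from .svcall import TranslocationCall

FRAGMENT_COLUMNS = (
    "fragment_id",
    "contig1",
    "pos1",
    "strand1",
    "contig2",
    "pos2",
    "strand2",
    "read_len",
    "sample",
)

ASE_COLUMNS = (
    "contig",
    "pos",
    "ref",
    "alt",
    "dna_ref_count",
    "dna_alt_count",
    "rna_ref_count",
    "rna_alt_count",
)


class FormatError(ValueError):
    """Malformed input with file/line context for the diagnostic."""

    def __init__(self, path: str | Path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# fragment tables

def write_fragment_table(fragments: Iterable[FragmentAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FRAGMENT_COLUMNS) + "\n")
        for f in fragments:
            fh.write(
                f"{f.fragment_id}\t{f.contig1}\t{f.pos1}\t{f.strand1}\t"
                f"{f.contig2}\t{f.pos2}\t{f.strand2}\t{f.read_len}\t{f.sample}\n"
            )


def read_fragment_table(path: str | Path) -> list[FragmentAlignment]:
    """Parse a fragment TSV; errors carry the offending line number."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != FRAGMENT_COLUMNS:
            missing = set(FRAGMENT_COLUMNS) - set(header)
            raise FormatError(
                path, 1,
                f"bad header; missing column(s) {sorted(missing)}" if missing
                else f"bad header order {header}",
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(FRAGMENT_COLUMNS):
                raise FormatError(
                    path, lineno,
                    f"expected {len(FRAGMENT_COLUMNS)} columns, got {len(parts)}",
                )
            try:
                out.append(
                    FragmentAlignment(
                        fragment_id=parts[0],
                        contig1=parts[1],
                        pos1=int(parts[2]),
                        strand1=parts[3],
                        contig2=parts[4],
                        pos2=int(parts[5]),
                        strand2=parts[6],
                        read_len=int(parts[7]),
                        sample=parts[8],
                    )
                )
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
    return out


def write_fragment_sam(
    fragments: Iterable[FragmentAlignment],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Export fragments as SAM with proper mate flags (reads are unbased)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": l} for c, l in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        tid = {c: i for i, c in enumerate(contig_lengths)}
        for f in fragments:
            for which, (contig, pos, strand, mcontig, mpos, mstrand) in enumerate(
                (
                    (f.contig1, f.pos1, f.strand1, f.contig2, f.pos2, f.strand2),
                    (f.contig2, f.pos2, f.strand2, f.contig1, f.pos1, f.strand1),
                )
            ):
                a = pysam.AlignedSegment()
                a.query_name = f.fragment_id
                flag = 0x1 | 0x2 if f.is_intra_contig and f.is_fr_inward() else 0x1
                flag |= 0x40 if which == 0 else 0x80
                if strand == "-":
                    flag |= 0x10
                if mstrand == "-":
                    flag |= 0x20
                a.flag = flag
                a.reference_id = tid[contig]
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{f.read_len}M"
                a.next_reference_id = tid[mcontig]
                a.next_reference_start = mpos
                sam.write(a)


# ---------------------------------------------------------------------------
# coverage / CNV outputs

def write_bedgraph(tracks: dict[str, Log2RatioTrack] | dict[str, CoverageTrack], path: str | Path) -> None:
    """Log2-ratio (or raw coverage) per bin as bedGraph; masked bins skipped."""
    import numpy as np

    with open(path, "w") as fh:
        for contig in sorted(tracks):
            t = tracks[contig]
            values = t.ratio if isinstance(t, Log2RatioTrack) else t.values
            mask = t.mask if isinstance(t, Log2RatioTrack) else np.zeros(values.size, bool)
            for i, v in enumerate(values):
                if mask[i]:
                    continue
                fh.write(f"{contig}\t{i * t.bin_width}\t{(i + 1) * t.bin_width}\t{v:.6g}\n")


def write_cnv_bed(segments: Sequence[CnvSegment], path: str | Path) -> None:
    """CNV segments as BED with state and mean log2 in columns 4-5."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.state}\t{s.mean_log2:.4f}\n")


# ---------------------------------------------------------------------------
# translocation calls (BEDPE)

BEDPE_COLUMNS = (
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "somatic", "reciprocal_partner",
)


def write_bedpe(calls: Sequence[TranslocationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for c in calls:
            partner = c.reciprocal_partner.name if c.reciprocal_partner else "."
            fh.write(
                f"{c.contig_a}\t{c.interval_a[0]}\t{c.interval_a[1]}\t"
                f"{c.contig_b}\t{c.interval_b[0]}\t{c.interval_b[1]}\t"
                f"{c.name}\t{c.support}\t{c.strand_a}\t{c.strand_b}\t"
                f"{'yes' if c.somatic else 'no'}\t{partner}\n"
            )


def read_bedpe(path: str | Path) -> list[dict]:
    """Read a BEDPE written by :func:`write_bedpe` back into plain dicts."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BEDPE_COLUMNS):
                raise FormatError(path, lineno, f"expected {len(BEDPE_COLUMNS)} columns")
            row = dict(zip(BEDPE_COLUMNS, parts))
            for k in ("start1", "end1", "start2", "end2", "score"):
                row[k] = int(row[k])
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# ASE count tables

def write_ase_counts(rows: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ASE_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in ASE_COLUMNS) + "\n")


def read_ase_counts(path: str | Path) -> list[AseRecord]:
    out = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != ASE_COLUMNS:
            raise FormatError(path, 1, f"bad header; expected {ASE_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(ASE_COLUMNS):
                raise FormatError(path, lineno, f"expected {len(ASE_COLUMNS)} columns")
            try:
                out.append(
                    AseRecord(
                        contig=parts[0],
                        pos=int(parts[1]),
                        ref=parts[2],
                        alt=parts[3],
                        dna_ref_count=int(parts[4]),
                        dna_alt_count=int(parts[5]),
                        rna_ref_count=int(parts[6]),
                        rna_alt_count=int(parts[7]),
                    )
                )
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
    return out


def write_ase_results(records: Sequence[AseRecord], path: str | Path) -> None:
    cols = ASE_COLUMNS + ("dna_vaf", "rna_vaf", "p_value", "q_value", "ase_flag", "direction")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.contig, str(r.pos), r.ref, r.alt,
                        str(r.dna_ref_count), str(r.dna_alt_count),
                        str(r.rna_ref_count), str(r.rna_alt_count),
                        f"{r.dna_vaf:.6g}", f"{r.rna_vaf:.6g}",
                        f"{r.p_value:.6g}" if r.p_value is not None else ".",
                        f"{r.q_value:.6g}" if r.q_value is not None else ".",
                        "yes" if r.ase_flag else "no",
                        r.direction or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# fusion annotations

def write_fusion_table(annotations: Sequence, path: str | Path) -> None:
    cols = (
        "call", "gene5p", "gene3p", "break_location_5p", "break_location_3p",
        "kinase_domain_retained", "last_intron_break", "chrom_class",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            fh.write(
                f"{a.call_name}\t{a.gene5p}\t{a.gene3p}\t{a.break_location_5p}\t"
                f"{a.break_location_3p}\t{'yes' if a.kinase_domain_retained else 'no'}\t"
                f"{'yes' if a.last_intron_break else 'no'}\t{a.chrom_class}\n"
            )


# ---------------------------------------------------------------------------
# cohort tables

def load_class_counts(path: str | Path):
    """Read a per-patient effect-class count matrix (Table-1 layout TSV)."""
    import pandas as pd

    from .cohort import EFFECT_CLASSES

    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = set(df.index) - set(EFFECT_CLASSES) - {"Total"}
    if unknown:
        raise ValueError(f"unknown effect class(es) in {path}: {sorted(unknown)}")
    df = df.reindex([c for c in EFFECT_CLASSES if c in df.index])
    df.loc["Total"] = df.sum(axis=0)
    return df


def load_mutation_records(path: str | Path):
    from .cohort import MutationRecord

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["patient", "gene", "effect_class"]:
            raise FormatError(path, 1, "expected header: patient, gene, effect_class")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(path, lineno, f"expected 3 columns, got {len(parts)}")
            try:
                out.append(MutationRecord(patient=parts[0], gene=parts[1], effect_class=parts[2]))
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
    return out


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run; written beside its outputs."""

    bin_width: int = 100
    fragment_len_mean: float = 1000.0
    fragment_len_sd: float = 50.0
    read_len: int = 100
    min_support_exclusive: int = 7
    max_normal_support: int = 0
    k_sd: float = 5.0
    gain_thr: float = 0.3
    loss_thr: float = -0.3
    min_bins: int = 5
    smooth_window: int = 5
    repeat_quantile: float = 0.99
    reciprocal_tolerance_bp: int = 5000
    ase_alpha: float = 0.05
    ase_min_delta: float = 0.2
    seed: int = 0

    @property
    def max_span(self) -> float:
        return self.fragment_len_mean + 5 * self.fragment_len_sd

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)
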