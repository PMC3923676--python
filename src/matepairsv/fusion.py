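"""Gene-fusion consequence annotation of translocation calls.

Given a translocation call and transcript models, this module decides
which gene contributes the 5' (promoter-bearing) and which the 3' portion
of the chimeric product, which intron each breakpoint falls in, whether
the 5' partner's protein-tyrosine-kinase domain survives intact on the
retained side, and whether the event is intra- or inter-chromosomal.

The archetype is an FGFR2 fusion: the breakpoint sits in the last intron
of the transcript, so the entire kinase domain (5' of that intron) is
retained and fused to the partner's downstream exons.

Partner-order logic.  A call side's strand encodes which segment the
junction retains ('+' = left of the breakpoint, '-' = right).  A gene is
the 5' partner when the retained segment contains its transcription start:
for a '+'-strand gene that is the left segment, for a '-'-strand gene the
right one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .svcall import TranslocationCall


@dataclass(frozen=True)
class Domain:
    """A named protein domain located by its genomic footprint."""

    name: str
    start: int  # 0-based half-open genomic interval
    end: int


@dataclass
class GeneModel:
    """One transcript of a gene: ordered exons plus domain annotations.

    ``exons`` are genomic half-open intervals ordered 5'->3' along the
    transcript (decreasing genomic coordinate for '-' strand genes).
    """

    gene: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    domains: list[Domain]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.gene}")
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        genomic = sorted(self.exons)
        if ordered != genomic:
            raise ValueError(
                f"{self.gene}/{self.transcript_id}: exons must be ordered 5'->3'"
            )
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene}: overlapping exons")
        lo, hi = self.span
        for d in self.domains:
            if d.start < lo or d.end > hi:
                raise ValueError(f"{self.gene}: domain {d.name} outside transcript span")

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos < hi

    def tss_side_is_left(self) -> bool:
        """True if the transcription start sits at the genomic-left end."""
        return self.strand == "+"

    def locate(self, pos: int) -> tuple[str, int | None]:
        """Classify a genomic position against this transcript.

        Returns ("exonic", exon_ordinal) | ("intronic", intron_ordinal) |
        ("intergenic", None); ordinals are 1-based from the 5' end of the
        transcript.
        """
        if not self.contains(pos):
            return ("intergenic", None)
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos < e:
                return ("exonic", i)
        for i, (a, b) in enumerate(zip(self.exons, self.exons[1:]), start=1):
            lo = min(a[1], b[1])
            hi = max(a[0], b[0])
            if lo <= pos < hi:
                return ("intronic", i)
        return ("intergenic", None)

    def kinase_domain(self) -> Domain | None:
        for d in self.domains:
            if "kinase" in d.name.lower():
                return d
        return None


@dataclass(frozen=True)
class FusionAnnotation:
    """Gene-level consequence of one translocation call."""

    call_name: str
    gene5p: str
    gene3p: str
    break_location_5p: str   # e.g. "intron 17" / "exonic 3" / "intergenic"
    break_location_3p: str
    kinase_domain_retained: bool
    last_intron_break: bool
    chrom_class: str         # intra | inter


class AmbiguousBreakpointError(ValueError):
    """Raised when a breakpoint cannot be assigned to a unique gene."""


def select_isoform(
    models: Sequence[GeneModel],
    evidence: str | None = None,
) -> GeneModel:
    """Pick the transcript isoform supported by expression evidence.

    With no evidence the first (reference-order) transcript is returned;
    an unknown label raises ``KeyError`` listing the available transcripts.
    """
    if not models:
        raise ValueError("no transcripts supplied")
    genes = {m.gene for m in models}
    if len(genes) != 1:
        raise ValueError(f"models span multiple genes: {sorted(genes)}")
    if evidence is None:
        return models[0]
    for m in models:
        if m.transcript_id == evidence:
            return m
    raise KeyError(
        f"no transcript {evidence!r} for {models[0].gene}; "
        f"available: {sorted(m.transcript_id for m in models)}"
    )


def _assign_gene(
    contig: str, pos: int, models: Sequence[GeneModel], margin: int
) -> GeneModel | None:
    hits = [m for m in models if m.contig == contig and m.contains(pos)]
    if len(hits) > 1:
        raise AmbiguousBreakpointError(
            f"{contig}:{pos} falls in multiple genes: {sorted(m.gene for m in hits)}"
        )
    if hits:
        return hits[0]
    if margin > 0:
        near = [
            (min(abs(pos - m.span[0]), abs(pos - m.span[1])), m.gene, m)
            for m in models
            if m.contig == contig
        ]
        near = [t for t in near if t[0] <= margin]
        if near:
            return min(near)[2]
    return None


def _retained_left(strand_of_side: str) -> bool:
    return strand_of_side == "+"


def _is_5prime_partner(gene: GeneModel, side_strand: str) -> bool:
    return gene.tss_side_is_left() == _retained_left(side_strand)


def _break_label(gene: GeneModel | None, pos: int) -> str:
    if gene is None:
        return "intergenic"
    kind, ordinal = gene.locate(pos)
    if kind == "intergenic":
        return "intergenic"
    word = "intron" if kind == "intronic" else "exon"
    return f"{word} {ordinal}"


def annotate_fusion(
    call: TranslocationCall,
    models: Sequence[GeneModel],
    margin: int = 0,
) -> FusionAnnotation:
    """Annotate one translocation call against transcript models.

    Each breakpoint point estimate is assigned to the gene whose span
    contains it (or the nearest within ``margin`` bp).  The 5'/3' partner
    order is chosen so transcription reads through the junction; the kinase
    domain is retained iff its genomic footprint lies entirely on the
    retained side of the 5'-partner's breakpoint.
    """
    sides = [
        (call.contig_a, call.point_a, call.strand_a),
        (call.contig_b, call.point_b, call.strand_b),
    ]
    assigned = [(_assign_gene(c, p, models, margin), c, p, s) for c, p, s in sides]
    five = [t for t in assigned if t[0] is not None and _is_5prime_partner(t[0], t[3])]
    three = [t for t in assigned if t not in five]
    if len(five) != 1 or len(three) != 1:
        raise ValueError(
            f"cannot orient fusion for {call.name}: "
            f"{len(five)} candidate 5' partner(s)"
        )
    g5, _, p5, s5 = five[0]
    g3, _, p3, _ = three[0]

    kind5, ordinal5 = g5.locate(p5)
    last_intron = kind5 == "intronic" and ordinal5 == g5.n_introns

    kin = g5.kinase_domain()
    retained = False
    if kin is not None:
        if _retained_left(s5):
            retained = kin.end <= p5
        else:
            retained = kin.start >= p5

    return FusionAnnotation(
        call_name=call.name,
        gene5p=g5.gene,
        gene3p=g3.gene if g3 is not None else "intergenic",
        break_location_5p=_break_label(g5, p5),
        break_location_3p=_break_label(g3, p3),
        kinase_domain_retained=retained,
        last_intron_break=last_intron,
        chrom_class=call.chrom_class,
    )


# ---------------------------------------------------------------------------
# model loading (GTF + domain TSV)

def load_gene_models(gtf_path: str | Path, domains_path: str | Path | None = None) -> list[GeneModel]:
    """Load transcript models from a GTF plus an optional domain TSV.

    The GTF must carry ``gene_name`` and ``transcript_id`` attributes on its
    exon features (1-based inclusive coordinates, converted internally).
    The domain TSV has four columns — gene, domain, start, end — 1-based
    inclusive, applied to every transcript of the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    domain_map: dict[str, list[Domain]] = {}
    if domains_path is not None:
        with open(domains_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("gene\t"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(
                        f"{domains_path}:{lineno}: expected 4 columns, got {len(parts)}"
                    )
                gene, name, start, end = parts
                domain_map.setdefault(gene, []).append(
                    Domain(name=name, start=int(start) - 1, end=int(end))
                )
    models = []
    transcripts: dict[tuple[str, str], dict] = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        gene = exon.attributes["gene_name"][0]
        tx = exon.attributes["transcript_id"][0]
        rec = transcripts.setdefault(
            (gene, tx),
            {"contig": exon.seqid, "strand": exon.strand, "exons": []},
        )
        rec["exons"].append((exon.start - 1, exon.end))
    for (gene, tx), rec in sorted(transcripts.items()):
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        models.append(
            GeneModel(
                gene=gene,
                transcript_id=tx,
                contig=rec["contig"],
                strand=rec["strand"],
                exons=exons,
                domains=domain_map.get(gene, []),
            )
        )
    return models
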