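"""Somatic translocation calling from discordant long-insert read pairs.

A concordant ~1 kb fragment maps both 100 bp reads to the same contig,
inward-facing (forward read left of reverse read), with an implied span
near the library insert size.  Any violation — different contigs, span
outside the insert envelope, or wrong orientation — makes the pair
*discordant* and potential evidence for a structural rearrangement.

Discordant pairs sharing a contig pair and orientation class are grouped
by single linkage into two-sided breakpoint clusters.  A cluster becomes a
somatic translocation call when strictly more than ``min_support_exclusive``
tumor pairs (default 7, i.e. >= 8) support both sides of the junction and
the matched normal contributes at most ``max_normal_support`` compatible
pairs (default 0).

Side-strand convention: a junction side's strand is the orientation of the
sequenced reads approaching the junction from that side — ``+`` means the
retained segment lies left of (before) the breakpoint, ``-`` means right.
The two products of a reciprocal exchange therefore have both side strands
flipped relative to each other.

Because the two reads flank an ~800 bp unsequenced interior
(fragment_len_mean - 2 * read_len), a read pair straddling a junction
brackets the breakpoint without crossing it: each member pair confines the
breakpoint to an interior-width interval, and the cluster's breakpoint
interval is the intersection of its members' intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .coverage import FragmentAlignment

DEFAULT_MIN_SUPPORT_EXCLUSIVE = 7  # ">7 read pairs": a call needs >= 8
DEFAULT_MAX_NORMAL_SUPPORT = 0
DEFAULT_K_SD = 5.0


@dataclass(frozen=True)
class BreakpointSide:
    """One side of a discordant pair: the read placement nearest a junction."""

    contig: str
    start: int       # 0-based leftmost read coordinate
    end: int         # start + read_len, half-open
    strand: str

    def key(self) -> tuple[str, int]:
        return (self.contig, self.start)


@dataclass(frozen=True)
class DiscordantPair:
    """A fragment whose read placements violate concordance."""

    fragment_id: str
    side1: BreakpointSide
    side2: BreakpointSide
    sample: str

    @property
    def contig_pair(self) -> tuple[str, str]:
        return (self.side1.contig, self.side2.contig)

    @property
    def orientation_class(self) -> tuple[str, str]:
        return (self.side1.strand, self.side2.strand)


@dataclass
class BreakpointCluster:
    """Mutually compatible discordant pairs defining one putative junction."""

    pairs: list[DiscordantPair]
    normal_support: int = 0

    @property
    def contig_pair(self) -> tuple[str, str]:
        return self.pairs[0].contig_pair

    @property
    def orientation_class(self) -> tuple[str, str]:
        return self.pairs[0].orientation_class

    @property
    def support(self) -> int:
        """Distinct fragments; each contributes one read to each side."""
        return len({p.fragment_id for p in self.pairs})

    # every member fragment places one read on each side, so per-side
    # support equals the distinct-fragment count on both sides
    support_side_a = support
    support_side_b = support

    def member_ids(self) -> list[str]:
        return sorted({p.fragment_id for p in self.pairs})


@dataclass
class TranslocationCall:
    """A somatic junction call with per-side breakpoint intervals."""

    cluster: BreakpointCluster
    contig_a: str
    interval_a: tuple[int, int]   # breakpoint confidence interval, half-open
    contig_b: str
    interval_b: tuple[int, int]
    strand_a: str
    strand_b: str
    support: int
    somatic: bool
    chrom_class: str              # intra | inter
    localization_fallback: bool = False
    reciprocal_partner: "TranslocationCall | None" = field(
        default=None, repr=False, compare=False
    )

    @property
    def point_a(self) -> int:
        return (self.interval_a[0] + self.interval_a[1]) // 2

    @property
    def point_b(self) -> int:
        return (self.interval_b[0] + self.interval_b[1]) // 2

    @property
    def name(self) -> str:
        return (
            f"{self.contig_a}:{self.point_a}{self.strand_a}"
            f"__{self.contig_b}:{self.point_b}{self.strand_b}"
        )

    def contig_pair_key(self) -> tuple[str, str]:
        return (self.contig_a, self.contig_b)


def _ordered_sides(frag: FragmentAlignment) -> tuple[BreakpointSide, BreakpointSide]:
    s1 = BreakpointSide(frag.contig1, frag.pos1, frag.pos1 + frag.read_len, frag.strand1)
    s2 = BreakpointSide(frag.contig2, frag.pos2, frag.pos2 + frag.read_len, frag.strand2)
    return (s1, s2) if s1.key() <= s2.key() else (s2, s1)


def find_discordant(
    fragments: Iterable[FragmentAlignment],
    expected_len_mean: float,
    expected_len_sd: float,
    k_sd: float = DEFAULT_K_SD,
) -> list[DiscordantPair]:
    """Classify fragments against the concordance envelope.

    A pair is discordant iff it is inter-contig, or its implied fragment
    length falls outside ``mean +/- k_sd * sd``, or its orientation is not
    forward/reverse inward.
    """
    lo = expected_len_mean - k_sd * expected_len_sd
    hi = expected_len_mean + k_sd * expected_len_sd
    out = []
    for frag in fragments:
        if frag.is_intra_contig:
            concordant = frag.is_fr_inward() and lo <= frag.implied_length() <= hi
            if concordant:
                continue
        s1, s2 = _ordered_sides(frag)
        out.append(DiscordantPair(frag.fragment_id, s1, s2, frag.sample))
    return out


def cluster_pairs(
    discordant: Sequence[DiscordantPair],
    max_span: float,
) -> list[BreakpointCluster]:
    """Single-linkage clustering of compatible discordant pairs.

    Two pairs link iff they share contig pair and orientation class and
    their read starts are within ``max_span`` on *both* sides.  Output
    clusters (and their members) are deterministically ordered by
    coordinates then fragment_id.
    """
    groups: dict[tuple, list[DiscordantPair]] = {}
    for p in discordant:
        groups.setdefault((p.contig_pair, p.orientation_class), []).append(p)
    clusters: list[BreakpointCluster] = []
    for key in sorted(groups):
        members = sorted(
            groups[key],
            key=lambda p: (p.side1.start, p.side2.start, p.fragment_id),
        )
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = members[i], members[j]
                if b.side1.start - a.side1.start > max_span:
                    break
                if abs(a.side2.start - b.side2.start) <= max_span:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        by_root: dict[int, list[DiscordantPair]] = {}
        for i, p in enumerate(members):
            by_root.setdefault(find(i), []).append(p)
        for root in sorted(by_root):
            clusters.append(BreakpointCluster(pairs=by_root[root]))
    clusters.sort(
        key=lambda c: (
            c.contig_pair,
            c.orientation_class,
            c.pairs[0].side1.start,
            c.pairs[0].side2.start,
        )
    )
    return clusters


def attach_normal_support(
    clusters: Sequence[BreakpointCluster],
    normal_discordant: Sequence[DiscordantPair],
    max_span: float,
) -> None:
    """Count matched-normal discordant pairs compatible with each cluster."""
    for cl in clusters:
        count = 0
        for p in normal_discordant:
            if p.contig_pair != cl.contig_pair:
                continue
            if p.orientation_class != cl.orientation_class:
                continue
            if any(
                abs(p.side1.start - m.side1.start) <= max_span
                and abs(p.side2.start - m.side2.start) <= max_span
                for m in cl.pairs
            ):
                count += 1
        cl.normal_support = count


def localize_breakpoint(
    cluster: BreakpointCluster,
    fragment_len_mean: float,
    read_len: int,
) -> tuple[tuple[int, int], tuple[int, int], bool]:
    """Intersect member-implied breakpoint intervals on each side.

    The unsequenced interior of a fragment spans
    ``inner = fragment_len_mean - 2 * read_len`` (~800 bp at the 1 kb / 100 bp
    geometry).  For a ``+`` side the junction lies within ``inner`` bp right
    of the read end; for a ``-`` side within ``inner`` bp left of the read
    start.  Returns (interval_a, interval_b, fallback_flag); on an empty
    intersection the union midpoint +/- inner/2 is used and flagged.
    """
    if not cluster.pairs:
        raise ValueError("cannot localize an empty cluster")
    inner = int(round(fragment_len_mean)) - 2 * read_len
    if inner <= 0:
        raise ValueError("fragment length too short for flanking-read geometry")

    def side_interval(side: BreakpointSide) -> tuple[int, int]:
        if side.strand == "+":
            return (side.end, side.end + inner)
        return (side.start - inner, side.start)

    fallback = False
    intervals = []
    for getter in (lambda p: p.side1, lambda p: p.side2):
        implied = [side_interval(getter(p)) for p in cluster.pairs]
        lo = max(s for s, _ in implied)
        hi = min(e for _, e in implied)
        if lo >= hi:
            ulo = min(s for s, _ in implied)
            uhi = max(e for _, e in implied)
            mid = (ulo + uhi) // 2
            lo, hi = mid - inner // 2, mid + inner // 2
            fallback = True
        intervals.append((lo, hi))
    return intervals[0], intervals[1], fallback


def call_translocations(
    clusters: Sequence[BreakpointCluster],
    fragment_len_mean: float,
    read_len: int,
    min_support_exclusive: int = DEFAULT_MIN_SUPPORT_EXCLUSIVE,
    max_normal_support: int = DEFAULT_MAX_NORMAL_SUPPORT,
) -> list[TranslocationCall]:
    """Emit a somatic call for every sufficiently supported tumor cluster.

    Support must be strictly greater than ``min_support_exclusive`` distinct
    read pairs on both sides of the breakpoint, and the matched normal must
    contribute at most ``max_normal_support`` compatible pairs.
    """
    calls = []
    for cl in clusters:
        if cl.support_side_a <= min_support_exclusive:
            continue
        if cl.support_side_b <= min_support_exclusive:
            continue
        if cl.normal_support > max_normal_support:
            continue
        ia, ib, fb = localize_breakpoint(cl, fragment_len_mean, read_len)
        ca, cb = cl.contig_pair
        sa, sb = cl.orientation_class
        calls.append(
            TranslocationCall(
                cluster=cl,
                contig_a=ca,
                interval_a=ia,
                contig_b=cb,
                interval_b=ib,
                strand_a=sa,
                strand_b=sb,
                support=cl.support,
                somatic=True,
                chrom_class="intra" if ca == cb else "inter",
                localization_fallback=fb,
            )
        )
    return calls


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def pair_reciprocal(
    calls: Sequence[TranslocationCall],
    tolerance_bp: int = 5000,
) -> None:
    """Link the two products of one reciprocal exchange.

    Two calls are reciprocal iff their contig pairs match, their orientation
    classes are complementary (both side strands flipped), and both
    breakpoint point estimates agree within ``tolerance_bp``.  Linkage is
    symmetric and exclusive; when several candidates qualify the closest
    (summed breakpoint distance) wins.
    """
    candidates = []
    for i, a in enumerate(calls):
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if a.contig_pair_key() != b.contig_pair_key():
                continue
            if (b.strand_a, b.strand_b) != (_flip(a.strand_a), _flip(a.strand_b)):
                continue
            da = abs(a.point_a - b.point_a)
            db = abs(a.point_b - b.point_b)
            if da <= tolerance_bp and db <= tolerance_bp:
                candidates.append((da + db, i, j))
    used: set[int] = set()
    for _, i, j in sorted(candidates):
        if i in used or j in used:
            continue
        calls[i].reciprocal_partner = calls[j]
        calls[j].reciprocal_partner = calls[i]
        used.update((i, j))
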