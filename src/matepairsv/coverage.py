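"""Physical-coverage copy-number analysis for long-insert tumor/normal WGS.

Physical (clonal) coverage counts, at every position, the number of
sequenced *fragments* whose genomic span — both reads plus the unsequenced
interior — overlaps that position.  With ~1 kb inserts this multiplies the
effective depth available for copy-number detection far beyond the base
coverage of the 100 bp reads alone.  The pipeline here is:

    physical_coverage  ->  normalize  ->  repeat_mask / smooth  ->
    log2_ratio  ->  call_cnv_segments

All coordinates are 0-based, half-open.  Bins are ``bin_width`` bp wide
(default 100) and a bin's value is the total overlap length of fragment
spans with the bin divided by the bin width, i.e. the mean per-base
fragment depth inside the bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 100

#: mask-reason codes stored per bin in Log2RatioTrack
MASK_NONE = ""
MASK_REPEAT = "repeat-filtered"
MASK_ZERO_NORMAL = "zero-normal"


@dataclass(frozen=True)
class FragmentAlignment:
    """One long-insert fragment: the placements of its two flanking reads.

    ``pos1``/``pos2`` are 0-based leftmost coordinates of each read;
    the fragment's physical span is ``[min(pos), max(pos) + read_len)``.
    """

    fragment_id: str
    contig1: str
    pos1: int
    strand1: str
    contig2: str
    pos2: int
    strand2: str
    read_len: int
    sample: str

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError(f"negative read position in {self.fragment_id}")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError(f"bad strand in {self.fragment_id}")
        if self.read_len <= 0:
            raise ValueError(f"read_len must be positive in {self.fragment_id}")

    @property
    def is_intra_contig(self) -> bool:
        return self.contig1 == self.contig2

    def span(self) -> tuple[int, int]:
        """Physical span on the (shared) contig, half-open."""
        if not self.is_intra_contig:
            raise ValueError("span undefined for inter-contig pair")
        lo = min(self.pos1, self.pos2)
        hi = max(self.pos1, self.pos2) + self.read_len
        return lo, hi

    def implied_length(self) -> int:
        lo, hi = self.span()
        return hi - lo

    def is_fr_inward(self) -> bool:
        """True if the leftmost read is forward and the rightmost reverse."""
        if not self.is_intra_contig:
            return False
        if self.pos1 <= self.pos2:
            left_strand, right_strand = self.strand1, self.strand2
        else:
            left_strand, right_strand = self.strand2, self.strand1
        return left_strand == "+" and right_strand == "-"


@dataclass
class CoverageTrack:
    """Binned physical coverage on one contig for one sample."""

    contig: str
    bin_width: int
    values: np.ndarray  # float, one entry per bin
    sample: str

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def scaled(self, factor: float) -> "CoverageTrack":
        return replace(self, values=self.values * factor)


@dataclass
class Log2RatioTrack:
    """Masked log2(tumor/normal) of normalized physical coverage."""

    contig: str
    bin_width: int
    ratio: np.ndarray        # float; NaN where masked
    mask: np.ndarray         # bool; True = masked
    mask_reason: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ratio.shape != self.mask.shape:
            raise ValueError("ratio/mask geometry mismatch")
        if not self.mask_reason:
            self.mask_reason = [MASK_NONE] * self.ratio.size
        # invariant: masked bins carry no value, unmasked bins are finite
        assert not np.any(np.isfinite(self.ratio[self.mask]))
        assert np.all(np.isfinite(self.ratio[~self.mask]))


@dataclass(frozen=True)
class CnvSegment:
    """A maximal run of bins in one discrete copy-number state."""

    contig: str
    start: int
    end: int
    state: str  # gain | loss | neutral
    mean_log2: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.state not in ("gain", "loss", "neutral"):
            raise ValueError(f"unknown CNV state {self.state!r}")


def n_bins_for(contig_length: int, bin_width: int) -> int:
    return -(-contig_length // bin_width)  # ceil


def physical_coverage(
    fragments: Iterable[FragmentAlignment],
    contig_lengths: dict[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
    sample: str | None = None,
) -> dict[str, CoverageTrack]:
    """Bin the physical span of every concordant intra-contig fragment.

    Each bin's value is sum over fragments of (overlap of the fragment span
    with the bin) / bin_width.  Inter-contig pairs are skipped (they carry
    no well-defined span); fragments running past the contig end are
    clipped with a warning.

    Returns one :class:`CoverageTrack` per contig.
    """
    accs = {
        c: np.zeros(n_bins_for(length, bin_width), dtype=float)
        for c, length in contig_lengths.items()
    }
    label = sample
    n_clipped = 0
    for frag in fragments:
        if label is None:
            label = frag.sample
        if not frag.is_intra_contig:
            continue
        contig = frag.contig1
        if contig not in accs:
            raise KeyError(f"fragment {frag.fragment_id} on unknown contig {contig}")
        lo, hi = frag.span()
        clen = contig_lengths[contig]
        if hi > clen:
            n_clipped += 1
            hi = clen
        if lo >= hi:
            continue
        acc = accs[contig]
        first = lo // bin_width
        last = (hi - 1) // bin_width
        if first == last:
            acc[first] += (hi - lo) / bin_width
        else:
            acc[first] += ((first + 1) * bin_width - lo) / bin_width
            acc[last] += (hi - last * bin_width) / bin_width
            if last - first > 1:
                acc[first + 1 : last] += 1.0
    if n_clipped:
        logger.warning("%d fragment(s) extended past contig end; clipped", n_clipped)
    return {
        c: CoverageTrack(contig=c, bin_width=bin_width, values=v, sample=label or "")
        for c, v in accs.items()
    }


def _genome_median(tracks: dict[str, CoverageTrack] | CoverageTrack) -> float:
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.contig: tracks}
    allv = np.concatenate([t.values for t in tracks.values()])
    return float(np.median(allv))


def normalize(
    tumor: dict[str, CoverageTrack],
    normal: dict[str, CoverageTrack],
) -> tuple[dict[str, CoverageTrack], dict[str, CoverageTrack]]:
    """Divide each sample by its own genome-wide median coverage.

    After normalization each sample's genome-wide median is 1, which removes
    library-size differences between tumor and normal before the log2
    comparison.  A zero median (degenerate input) raises ``ValueError``.
    """
    if set(tumor) != set(normal):
        raise ValueError("tumor and normal cover different contigs")
    for c in tumor:
        if tumor[c].bin_width != normal[c].bin_width or tumor[c].n_bins != normal[c].n_bins:
            raise ValueError(f"geometry mismatch on contig {c}")
    out = []
    for tracks in (tumor, normal):
        med = _genome_median(tracks)
        if med == 0:
            raise ValueError("genome-wide median coverage is zero; cannot normalize")
        out.append({c: t.scaled(1.0 / med) for c, t in tracks.items()})
    return out[0], out[1]


def repeat_mask(
    normal: dict[str, CoverageTrack],
    quantile_hi: float = 0.99,
    zero_ok: bool = False,
) -> dict[str, np.ndarray]:
    """Mask bins whose *normal* coverage marks them unreliable.

    Highly repetitive regions attract excess mappings in both samples; bins
    above the ``quantile_hi`` genome-wide quantile of normal coverage are
    masked, as are zero-coverage bins (no denominator) unless ``zero_ok``.
    """
    if not 0 < quantile_hi <= 1:
        raise ValueError("quantile_hi must be in (0, 1]")
    allv = np.concatenate([t.values for t in normal.values()])
    cutoff = float(np.quantile(allv, quantile_hi))
    masks = {}
    for c, t in normal.items():
        m = t.values > cutoff
        if not zero_ok:
            m |= t.values == 0
        masks[c] = m
    return masks


def smooth(
    track: CoverageTrack,
    window_bins: int = 5,
    mask: np.ndarray | None = None,
) -> CoverageTrack:
    """Centered moving median over unmasked bins; window 1 is the identity.

    Masked bins are excluded from every window and keep their input value.
    An even window has no center and is rejected.
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be odd and >= 1")
    if window_bins == 1:
        return replace(track, values=track.values.copy())
    half = window_bins // 2
    v = track.values
    n = v.size
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    out = v.copy()
    for i in np.flatnonzero(~mask):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = v[lo:hi][~mask[lo:hi]]
        out[i] = np.median(win)
    return replace(track, values=out)


def log2_ratio(
    tumor_norm: CoverageTrack,
    normal_norm: CoverageTrack,
    mask: np.ndarray | None = None,
) -> Log2RatioTrack:
    """log2(tumor/normal) per bin; repeat-masked and zero-normal bins masked."""
    if (
        tumor_norm.contig != normal_norm.contig
        or tumor_norm.bin_width != normal_norm.bin_width
        or tumor_norm.n_bins != normal_norm.n_bins
    ):
        raise ValueError("tumor/normal track geometry mismatch")
    n = tumor_norm.n_bins
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != n:
        raise ValueError("mask geometry mismatch")
    zero_normal = normal_norm.values == 0
    full = mask | zero_normal
    ratio = np.full(n, np.nan)
    ok = ~full
    ratio[ok] = np.log2(tumor_norm.values[ok] / normal_norm.values[ok])
    reasons = [
        MASK_REPEAT if m else (MASK_ZERO_NORMAL if z else MASK_NONE)
        for m, z in zip(mask, zero_normal)
    ]
    return Log2RatioTrack(
        contig=tumor_norm.contig,
        bin_width=tumor_norm.bin_width,
        ratio=ratio,
        mask=full,
        mask_reason=reasons,
    )


def call_cnv_segments(
    track: Log2RatioTrack,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
    min_bins: int = 5,
) -> list[CnvSegment]:
    """Dual-threshold run-length segmentation of the log2 track.

    Maximal runs of >= ``min_bins`` consecutive *unmasked* bins above
    ``gain_thr`` are gains, below ``loss_thr`` losses; masked bins break
    runs; everything else is merged into neutral segments so segments tile
    the contig.
    """
    if not (gain_thr > 0 > loss_thr):
        raise ValueError("need gain_thr > 0 > loss_thr")
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    r, m, w = track.ratio, track.mask, track.bin_width
    n = r.size
    state = np.zeros(n, dtype=int)  # 0 neutral, 1 gain, -1 loss
    ok = ~m
    state[ok & (r > gain_thr)] = 1
    state[ok & (r < loss_thr)] = -1
    # demote gain/loss runs shorter than min_bins to neutral
    labels = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j < n and state[j] == state[i] and m[j] == m[i]:
            j += 1
        if state[i] != 0 and (j - i) >= min_bins:
            labels[i:j] = state[i]
        i = j
    segments: list[CnvSegment] = []
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        member = r[i:j][~m[i:j]]
        mean = float(np.mean(member)) if member.size else float("nan")
        st = {1: "gain", -1: "loss", 0: "neutral"}[int(labels[i])]
        segments.append(
            CnvSegment(
                contig=track.contig,
                start=i * w,
                end=j * w,
                state=st,
                mean_log2=mean,
                n_bins=j - i,
            )
        )
        i = j
    return segments
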