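"""Synthetic long-insert tumor/normal fragment data with known ground truth.

The generator emulates the statistical structure a long-insert (mate-pair
style) library presents to the downstream analysis: ~1 kb fragments whose
two 100 bp reads flank an ~800 bp unsequenced interior, uniform background
fragment density at a configurable physical depth, copy-number segments
that scale tumor fragment density, repeat-like regions that inflate
coverage in both samples, engineered translocation junctions with an exact
number of supporting discordant pairs per side, and paired DNA/RNA allele
counts with divergent mutant fractions.

Only alignment placements are generated — no base sequences — because
every downstream stage consumes placements and counts.  Coordinates are
0-based half-open throughout.  Each sample draws from its own random
stream seeded from (config.seed, role), so tumor and normal are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .coverage import FragmentAlignment

ROLE_TUMOR = "tumor"
ROLE_NORMAL = "normal"
_ROLE_CODE = {ROLE_TUMOR: 1, ROLE_NORMAL: 2}
_ASE_STREAM = 3


@dataclass(frozen=True)
class CnvSpec:
    contig: str
    start: int
    end: int
    tumor_copy_ratio: float


@dataclass(frozen=True)
class SvSideSpec:
    contig: str
    pos: int
    strand: str  # '+': retained segment left of breakpoint; '-': right


@dataclass(frozen=True)
class SvSpec:
    side_a: SvSideSpec
    side_b: SvSideSpec
    per_side_support: int
    reciprocal: bool = False


@dataclass(frozen=True)
class RepeatSpec:
    contig: str
    start: int
    end: int
    coverage_multiplier: float


@dataclass(frozen=True)
class AseSpec:
    contig: str
    pos: int
    ref: str
    alt: str
    dna_mut_fraction: float
    rna_mut_fraction: float
    dna_depth: int
    rna_depth: int


@dataclass
class SimulationConfig:
    """Full recipe for one tumor/normal pair on a miniature genome."""

    contigs: list[tuple[str, int]]
    fragment_length_mean: float = 1000.0
    fragment_length_sd: float = 50.0
    read_length: int = 100
    haploid_depth: float = 20.0
    cnv_specs: list[CnvSpec] = field(default_factory=list)
    sv_specs: list[SvSpec] = field(default_factory=list)
    repeat_specs: list[RepeatSpec] = field(default_factory=list)
    ase_specs: list[AseSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def inner_span(self) -> int:
        """Unsequenced interior of a mean-length fragment (~800 bp)."""
        return int(round(self.fragment_length_mean)) - 2 * self.read_length

    def validate(self) -> None:
        lengths = self.contig_lengths
        if not lengths:
            raise ValueError("at least one contig required")
        if self.fragment_length_mean <= 2 * self.read_length:
            raise ValueError(
                "fragment_length_mean must exceed 2 x read_length "
                "(flanking reads must not overlap)"
            )
        if self.fragment_length_sd < 0 or self.read_length <= 0:
            raise ValueError("bad fragment geometry")
        if self.haploid_depth <= 0:
            raise ValueError("haploid_depth must be positive")
        for spec in self.cnv_specs:
            self._check_interval(spec.contig, spec.start, spec.end, lengths)
            if spec.tumor_copy_ratio < 0:
                raise ValueError("tumor_copy_ratio must be >= 0")
        for spec in self.repeat_specs:
            self._check_interval(spec.contig, spec.start, spec.end, lengths)
            if spec.coverage_multiplier <= 0:
                raise ValueError("coverage_multiplier must be positive")
        for spec in self.sv_specs:
            for side in (spec.side_a, spec.side_b):
                if side.contig not in lengths:
                    raise ValueError(f"sv side on unknown contig {side.contig}")
                if not 0 <= side.pos < lengths[side.contig]:
                    raise ValueError(f"sv breakpoint {side.pos} outside {side.contig}")
                if side.strand not in "+-":
                    raise ValueError("sv side strand must be + or -")
            if spec.per_side_support < 0:
                raise ValueError("per_side_support must be >= 0")
        self._check_sv_conflicts()
        for spec in self.ase_specs:
            if not 0 <= spec.dna_mut_fraction <= 1 or not 0 <= spec.rna_mut_fraction <= 1:
                raise ValueError("mutant fractions must lie in [0, 1]")
            if spec.dna_depth < 0 or spec.rna_depth < 0:
                raise ValueError("depths must be non-negative")

    @staticmethod
    def _check_interval(contig: str, start: int, end: int, lengths: dict[str, int]) -> None:
        if contig not in lengths:
            raise ValueError(f"interval on unknown contig {contig}")
        if not (0 <= start < end <= lengths[contig]):
            raise ValueError(f"bad interval {contig}:{start}-{end}")

    def _check_sv_conflicts(self) -> None:
        """Reject sv_specs that place contradictory junctions at one locus."""
        seen: list[tuple[SvSideSpec, SvSpec]] = []
        window = 2 * self.read_length
        for spec in self.sv_specs:
            for side in (spec.side_a, spec.side_b):
                for other_side, other in seen:
                    if other is spec:
                        continue
                    if (
                        other_side.contig == side.contig
                        and abs(other_side.pos - side.pos) < window
                        and other_side.strand == side.strand
                    ):
                        raise ValueError(
                            f"contradictory sv_specs share side "
                            f"{side.contig}:{side.pos}{side.strand} "
                            f"(within {window} bp, same orientation)"
                        )
                seen.append((side, spec))


@dataclass
class TruthManifest:
    """Planted ground truth, serializable losslessly to JSON."""

    seed: int
    contigs: list[tuple[str, int]]
    fragment_length_mean: float
    fragment_length_sd: float
    read_length: int
    haploid_depth: float
    cnvs: list[CnvSpec] = field(default_factory=list)
    svs: list[SvSpec] = field(default_factory=list)
    repeats: list[RepeatSpec] = field(default_factory=list)
    ase_sites: list[AseSpec] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            contigs=[tuple(c) for c in d["contigs"]],
            fragment_length_mean=d["fragment_length_mean"],
            fragment_length_sd=d["fragment_length_sd"],
            read_length=d["read_length"],
            haploid_depth=d["haploid_depth"],
            cnvs=[CnvSpec(**c) for c in d["cnvs"]],
            svs=[
                SvSpec(
                    side_a=SvSideSpec(**s["side_a"]),
                    side_b=SvSideSpec(**s["side_b"]),
                    per_side_support=s["per_side_support"],
                    reciprocal=s["reciprocal"],
                )
                for s in d["svs"]
            ],
            repeats=[RepeatSpec(**r) for r in d["repeats"]],
            ase_sites=[AseSpec(**a) for a in d["ase_sites"]],
        )

    def to_config(self) -> SimulationConfig:
        return SimulationConfig(
            contigs=list(self.contigs),
            fragment_length_mean=self.fragment_length_mean,
            fragment_length_sd=self.fragment_length_sd,
            read_length=self.read_length,
            haploid_depth=self.haploid_depth,
            cnv_specs=list(self.cnvs),
            sv_specs=list(self.svs),
            repeat_specs=list(self.repeats),
            ase_specs=list(self.ase_sites),
            seed=self.seed,
        )


def manifest_for(config: SimulationConfig) -> TruthManifest:
    return TruthManifest(
        seed=config.seed,
        contigs=list(config.contigs),
        fragment_length_mean=config.fragment_length_mean,
        fragment_length_sd=config.fragment_length_sd,
        read_length=config.read_length,
        haploid_depth=config.haploid_depth,
        cnvs=list(config.cnv_specs),
        svs=list(config.sv_specs),
        repeats=list(config.repeat_specs),
        ase_sites=list(config.ase_specs),
    )


def _draw_lengths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Truncated-normal fragment lengths on [2*read_len, 2*mean]."""
    if n == 0:
        return np.zeros(0, dtype=int)
    mean, sd = config.fragment_length_mean, config.fragment_length_sd
    lo, hi = 2 * config.read_length, 2 * mean
    if sd == 0:
        return np.full(n, int(round(mean)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    vals = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.rint(vals).astype(int)


def _weight_profile(
    contig: str,
    length: int,
    config: SimulationConfig,
    role: str,
) -> list[tuple[int, int, float]]:
    """Piecewise-constant fragment-density multiplier along a contig.

    Copy-ratio scaling applies to the tumor only; repeat-like multipliers
    apply to both samples (a repeat attracts excess mappings regardless of
    the somatic genotype).
    """
    cuts = {0, length}
    for spec in config.cnv_specs:
        if spec.contig == contig:
            cuts.update((spec.start, spec.end))
    for spec in config.repeat_specs:
        if spec.contig == contig:
            cuts.update((spec.start, spec.end))
    edges = sorted(cuts)
    pieces = []
    for s, e in zip(edges, edges[1:]):
        w = 1.0
        if role == ROLE_TUMOR:
            for spec in config.cnv_specs:
                if spec.contig == contig and spec.start <= s and e <= spec.end:
                    w *= spec.tumor_copy_ratio
        for spec in config.repeat_specs:
            if spec.contig == contig and spec.start <= s and e <= spec.end:
                w *= spec.coverage_multiplier
        pieces.append((s, e, w))
    return pieces


def _background_fragments(
    config: SimulationConfig, role: str, rng: np.random.Generator
) -> list[FragmentAlignment]:
    frags = []
    mean_len = config.fragment_length_mean
    read_len = config.read_length
    counter = 0
    for contig, length in config.contigs:
        for s, e, w in _weight_profile(contig, length, config, role):
            lam = config.haploid_depth * w * (e - s) / mean_len
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            mids = rng.integers(s, e, size=n)
            lens = _draw_lengths(rng, n, config)
            for mid, ln in zip(mids, lens):
                ln = int(min(ln, length))
                start = int(mid) - ln // 2
                start = max(0, min(start, length - ln))
                frags.append(
                    FragmentAlignment(
                        fragment_id=f"{role[0]}bg{counter:07d}",
                        contig1=contig,
                        pos1=start,
                        strand1="+",
                        contig2=contig,
                        pos2=start + ln - read_len,
                        strand2="-",
                        read_len=read_len,
                        sample=role,
                    )
                )
                counter += 1
    return frags


def _junction_fragments(
    config: SimulationConfig, rng: np.random.Generator
) -> list[FragmentAlignment]:
    """Exactly per_side_support discordant pairs per planted junction.

    Each pair places one read on each side, oriented toward the junction,
    with the read within one inner-span of the breakpoint so that
    flanking-read localization brackets the true breakpoint.
    """
    inner = config.inner_span
    read_len = config.read_length
    lengths = config.contig_lengths
    frags = []
    for k, spec in enumerate(config.sv_specs):
        for j in range(spec.per_side_support):
            placements = []
            for side in (spec.side_a, spec.side_b):
                u = int(rng.integers(0, inner))
                if side.strand == "+":
                    # read ends within `inner` bp left of the breakpoint
                    end = side.pos - u
                    start = end - read_len
                else:
                    # read starts within `inner` bp right of the breakpoint
                    start = side.pos + 1 + u
                start = max(0, min(start, lengths[side.contig] - read_len))
                placements.append((side.contig, start, side.strand))
            (c1, p1, s1), (c2, p2, s2) = placements
            frags.append(
                FragmentAlignment(
                    fragment_id=f"tsv{k:02d}_{j:04d}",
                    contig1=c1,
                    pos1=p1,
                    strand1=s1,
                    contig2=c2,
                    pos2=p2,
                    strand2=s2,
                    read_len=read_len,
                    sample=ROLE_TUMOR,
                )
            )
    return frags


def simulate_sample(
    config: SimulationConfig, role: str
) -> tuple[list[FragmentAlignment], TruthManifest]:
    """Generate one sample's fragment alignments plus the truth manifest.

    The normal carries background (and repeat) structure only; the tumor
    additionally expresses cnv_specs as scaled fragment density and each
    sv_spec as exactly ``per_side_support`` discordant junction pairs.
    Deterministic given (config.seed, role).
    """
    if role not in _ROLE_CODE:
        raise ValueError(f"role must be {ROLE_TUMOR!r} or {ROLE_NORMAL!r}")
    rng = np.random.default_rng([config.seed, _ROLE_CODE[role]])
    frags = _background_fragments(config, role, rng)
    if role == ROLE_TUMOR:
        frags.extend(_junction_fragments(config, rng))
    return frags, manifest_for(config)


def simulate_ase_counts(config: SimulationConfig) -> list[dict]:
    """Draw DNA and RNA allele counts binomially for every ase_spec.

    Returns one dict per site with ref/alt counts for both assays;
    deterministic given config.seed.
    """
    if not config.ase_specs:
        raise ValueError("no ase_specs configured")
    rng = np.random.default_rng([config.seed, _ASE_STREAM])
    rows = []
    for spec in config.ase_specs:
        if spec.dna_depth == 0 or spec.rna_depth == 0:
            raise ValueError(f"zero depth at {spec.contig}:{spec.pos}")
        dna_alt = int(rng.binomial(spec.dna_depth, spec.dna_mut_fraction))
        rna_alt = int(rng.binomial(spec.rna_depth, spec.rna_mut_fraction))
        rows.append(
            {
                "contig": spec.contig,
                "pos": spec.pos,
                "ref": spec.ref,
                "alt": spec.alt,
                "dna_ref_count": spec.dna_depth - dna_alt,
                "dna_alt_count": dna_alt,
                "rna_ref_count": spec.rna_depth - rna_alt,
                "rna_alt_count": rna_alt,
            }
        )
    return rows
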