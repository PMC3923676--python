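"""The bundled six-patient demonstration cohort on a miniature genome.

The cohort mirrors the geometry of the motivating study: six tumor/normal
pairs, of which patients 4-6 carry FGFR2-analogue fusion translocations —
an intra-chromosomal FGFR2-MGEA5 event (patient 4), a reciprocal
FGFR2-BICC1 / BICC1-FGFR2 pair (patient 5), and an inter-chromosomal
FGFR2-TACC3 event (patient 6) — while patients 1-3 are fusion-negative.
Patient 2 carries a deliberately sub-threshold junction (5 supporting
pairs) and patient 3 an allele-specific-expression site whose mutant
allele is at 11% in DNA but 78% in RNA, the ERRFI1-style scenario.

The genome is two contigs (a 60 kb chr10 analogue, a 30 kb chr4 analogue)
with gene models whose topology matches the real loci: the FGFR2 analogue
sits on the minus strand with its protein-tyrosine-kinase domain 5' of the
last intron, where every fusion breakpoint falls.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

from .simulate import (
    AseSpec,
    CnvSpec,
    RepeatSpec,
    SimulationConfig,
    SvSideSpec,
    SvSpec,
)

#: miniature genome
CONTIGS: list[tuple[str, int]] = [("chr10", 60_000), ("chr4", 30_000)]

#: FGFR2-analogue gene span (minus strand); all fusion breakpoints fall in
#: its last intron (40_500, 41_500)
FGFR2_SPAN = ("chr10", 40_000, 46_000)

PATIENTS = ["patient1", "patient2", "patient3", "patient4", "patient5", "patient6"]

#: shared genome feature: a repeat-like high-coverage region
_REPEAT = RepeatSpec(contig="chr10", start=50_000, end=50_500, coverage_multiplier=10.0)

_SV = {
    # patient 2: real junction but only 5 supporting pairs -> below threshold
    "patient2": [
        SvSpec(
            side_a=SvSideSpec("chr10", 35_000, "+"),
            side_b=SvSideSpec("chr4", 20_000, "-"),
            per_side_support=5,
        )
    ],
    # patient 4: FGFR2 -> MGEA5, intra-chromosomal
    "patient4": [
        SvSpec(
            side_a=SvSideSpec("chr10", 41_000, "-"),
            side_b=SvSideSpec("chr10", 11_000, "-"),
            per_side_support=10,
        )
    ],
    # patient 5: reciprocal FGFR2 -> BICC1 and BICC1 -> FGFR2
    "patient5": [
        SvSpec(
            side_a=SvSideSpec("chr10", 41_000, "-"),
            side_b=SvSideSpec("chr10", 21_000, "-"),
            per_side_support=9,
            reciprocal=True,
        ),
        SvSpec(
            side_a=SvSideSpec("chr10", 22_000, "+"),
            side_b=SvSideSpec("chr10", 41_050, "+"),
            per_side_support=12,
            reciprocal=True,
        ),
    ],
    # patient 6: FGFR2 -> TACC3, inter-chromosomal
    "patient6": [
        SvSpec(
            side_a=SvSideSpec("chr10", 41_000, "-"),
            side_b=SvSideSpec("chr4", 6_000, "-"),
            per_side_support=14,
        )
    ],
}

_CNV = {
    "patient2": [CnvSpec("chr4", 10_000, 15_000, 0.5)],
    "patient3": [CnvSpec("chr10", 5_000, 10_000, 2.0)],
}

_ASE = {
    # ERRFI1-style site: nonsense allele at 11% of DNA reads, 78% of RNA reads
    "patient3": [
        AseSpec(
            contig="chr4",
            pos=25_000,
            ref="G",
            alt="T",
            dna_mut_fraction=0.11,
            rna_mut_fraction=0.78,
            dna_depth=500,
            rna_depth=500,
        )
    ],
}


def patient_config(patient: str, seed: int = 0, haploid_depth: float = 20.0) -> SimulationConfig:
    """Simulation recipe for one cohort patient.

    Each patient draws from an independent stream derived from the cohort
    seed and the patient's ordinal.
    """
    if patient not in PATIENTS:
        raise KeyError(f"unknown patient {patient!r}; cohort is {PATIENTS}")
    ordinal = PATIENTS.index(patient) + 1
    return SimulationConfig(
        contigs=list(CONTIGS),
        haploid_depth=haploid_depth,
        cnv_specs=list(_CNV.get(patient, [])),
        sv_specs=list(_SV.get(patient, [])),
        repeat_specs=[_REPEAT],
        ase_specs=list(_ASE.get(patient, [])),
        seed=(seed * 1009 + ordinal) % (2**31 - 1),
    )


def cohort_configs(seed: int = 0, haploid_depth: float = 20.0) -> dict[str, SimulationConfig]:
    return {p: patient_config(p, seed=seed, haploid_depth=haploid_depth) for p in PATIENTS}


def fusion_positive_patients() -> list[str]:
    """Patients engineered to carry an FGFR2-analogue fusion."""
    span_lo, span_hi = FGFR2_SPAN[1], FGFR2_SPAN[2]
    out = []
    for p in PATIENTS:
        for spec in _SV.get(p, []):
            hits_fgfr2 = any(
                s.contig == FGFR2_SPAN[0] and span_lo <= s.pos < span_hi
                for s in (spec.side_a, spec.side_b)
            )
            if hits_fgfr2 and spec.per_side_support >= 8:
                out.append(p)
                break
    return out


def data_path(name: str) -> Path:
    """Path to a bundled data file (toy GTF, domain TSV, mutation tables)."""
    ref = importlib.resources.files("matepairsv") / "data" / name
    return Path(str(ref))


def write_fixture_cohort(out_dir: str | Path, seed: int = 0, haploid_depth: float = 20.0) -> dict:
    """Materialize the six-patient cohort as files on disk.

    Writes per-patient tumor/normal fragment tables, ASE count tables where
    configured, the truth manifests, and copies of the toy gene models
    (GTF + domain TSV) and cohort mutation tables.  Idempotent for a fixed
    seed.  Returns a manifest of written paths.
    """
    from . import io as mio
    from .simulate import manifest_for, simulate_ase_counts, simulate_sample

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, str]] = {}
    for patient, config in cohort_configs(seed=seed, haploid_depth=haploid_depth).items():
        pdir = out / patient
        pdir.mkdir(exist_ok=True)
        entry: dict[str, str] = {}
        for role in ("tumor", "normal"):
            frags, _ = simulate_sample(config, role)
            path = pdir / f"{role}.fragments.tsv"
            mio.write_fragment_table(frags, path)
            entry[role] = str(path)
        manifest_path = pdir / "truth.json"
        manifest_for(config).save(manifest_path)
        entry["truth"] = str(manifest_path)
        if config.ase_specs:
            ase_path = pdir / "ase_counts.tsv"
            mio.write_ase_counts(simulate_ase_counts(config), ase_path)
            entry["ase"] = str(ase_path)
        written[patient] = entry
    for name in ("toy_genes.gtf", "toy_domains.tsv", "mutation_classes.tsv", "mutations.tsv"):
        (out / name).write_text(data_path(name).read_text())
    return written
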