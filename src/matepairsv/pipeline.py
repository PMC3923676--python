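"""End-to-end tumor/normal analysis: coverage/CNV, translocations, fusions.

Thin orchestration over the stage modules so the CLI, the tests and the
bundled cohort demonstration all run the identical code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import coverage as cov
from . import fusion as fus
from . import svcall as sv
from .coverage import FragmentAlignment
from .io import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    """Everything one tumor/normal comparison produces."""

    log2: dict[str, cov.Log2RatioTrack]
    cnv_segments: list[cov.CnvSegment]
    calls: list[sv.TranslocationCall]
    fusions: list[fus.FusionAnnotation] = field(default_factory=list)


def run_pair(
    tumor: Sequence[FragmentAlignment],
    normal: Sequence[FragmentAlignment],
    contig_lengths: dict[str, int],
    config: PipelineConfig | None = None,
    gene_models: Sequence[fus.GeneModel] | None = None,
) -> SampleResult:
    """Run coverage -> CNV -> translocation -> fusion on one pair."""
    cfg = config or PipelineConfig()

    # --- copy number from physical coverage of concordant fragments
    tum_disc = sv.find_discordant(tumor, cfg.fragment_len_mean, cfg.fragment_len_sd, cfg.k_sd)
    nor_disc = sv.find_discordant(normal, cfg.fragment_len_mean, cfg.fragment_len_sd, cfg.k_sd)
    disc_ids = {p.fragment_id for p in tum_disc}
    nor_disc_ids = {p.fragment_id for p in nor_disc}
    tum_conc = [f for f in tumor if f.fragment_id not in disc_ids]
    nor_conc = [f for f in normal if f.fragment_id not in nor_disc_ids]

    tum_cov = cov.physical_coverage(tum_conc, contig_lengths, cfg.bin_width)
    nor_cov = cov.physical_coverage(nor_conc, contig_lengths, cfg.bin_width)
    tum_norm, nor_norm = cov.normalize(tum_cov, nor_cov)
    masks = cov.repeat_mask(nor_norm, quantile_hi=cfg.repeat_quantile)
    log2 = {}
    segments: list[cov.CnvSegment] = []
    for contig in sorted(contig_lengths):
        t_s = cov.smooth(tum_norm[contig], cfg.smooth_window, masks[contig])
        n_s = cov.smooth(nor_norm[contig], cfg.smooth_window, masks[contig])
        track = cov.log2_ratio(t_s, n_s, masks[contig])
        log2[contig] = track
        segments.extend(
            cov.call_cnv_segments(track, cfg.gain_thr, cfg.loss_thr, cfg.min_bins)
        )
    logger.info(
        "coverage: %d tumor / %d normal concordant fragments, %d CNV segments",
        len(tum_conc), len(nor_conc), len(segments),
    )

    # --- translocations from discordant evidence
    clusters = sv.cluster_pairs(tum_disc, cfg.max_span)
    sv.attach_normal_support(clusters, nor_disc, cfg.max_span)
    calls = sv.call_translocations(
        clusters,
        cfg.fragment_len_mean,
        cfg.read_len,
        min_support_exclusive=cfg.min_support_exclusive,
        max_normal_support=cfg.max_normal_support,
    )
    sv.pair_reciprocal(calls, tolerance_bp=cfg.reciprocal_tolerance_bp)
    logger.info(
        "svcall: %d discordant pairs -> %d clusters -> %d somatic calls",
        len(tum_disc), len(clusters), len(calls),
    )

    # --- fusion consequences
    fusions = []
    if gene_models:
        for call in calls:
            try:
                fusions.append(fus.annotate_fusion(call, gene_models))
            except ValueError:
                logger.info("call %s not annotatable against gene models", call.name)
    return SampleResult(log2=log2, cnv_segments=segments, calls=calls, fusions=fusions)


def run_cohort_dir(
    cohort_dir: str | Path,
    config: PipelineConfig | None = None,
    isoform_evidence: str | None = "IIIb",
) -> dict[str, SampleResult]:
    """Run every patient in a fixture-cohort directory tree."""
    from . import io as mio
    from .fixtures import CONTIGS

    cfg = config or PipelineConfig()
    cohort_dir = Path(cohort_dir)
    models = fus.load_gene_models(
        cohort_dir / "toy_genes.gtf", cohort_dir / "toy_domains.tsv"
    )
    # collapse multi-isoform genes to the expression-supported transcript
    by_gene: dict[str, list[fus.GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene, []).append(m)
    selected = []
    for gene, ms in sorted(by_gene.items()):
        if len(ms) > 1 and isoform_evidence is not None:
            try:
                selected.append(fus.select_isoform(ms, isoform_evidence))
                continue
            except KeyError:
                pass
        selected.append(fus.select_isoform(ms))

    results = {}
    for pdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        tumor = mio.read_fragment_table(pdir / "tumor.fragments.tsv")
        normal = mio.read_fragment_table(pdir / "normal.fragments.tsv")
        results[pdir.name] = run_pair(
            tumor, normal, dict(CONTIGS), cfg, gene_models=selected
        )
    return results
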