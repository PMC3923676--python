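# Methods

This note records the models, parameter choices and numerical decisions
behind `matepairsv`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Library geometry

The analysis assumes a long-insert paired-end library: fragments of mean
length μ = 1000 bp (sd σ = 50 bp), sequenced with ℓ = 100 bp reads from both
ends, leaving an unsequenced interior of μ − 2ℓ = 800 bp. Two consequences
drive the design:

- *Physical coverage* counts the whole fragment span, so copy-number signal
  accumulates at ~10× the rate of base coverage for the same sequencing cost.
- A read pair straddling a rearrangement junction almost never has a read
  crossing the junction, so discordant pairs are clean evidence and each pair
  brackets the breakpoint within one interior width.

## Synthetic data generator

The simulator emits alignment *placements*, not base sequences, because every
downstream computation consumes coordinates and counts only.

- **Fragment lengths**: truncated normal on [2ℓ, 2μ]. The library targets a
  900–1000 bp fragment size; a concrete distribution must be chosen, and a
  truncated normal with σ = 50 keeps essentially all mass inside the
  concordance envelope μ ± 5σ (the tails outside it have mass ~6·10⁻⁷), so a
  null simulation is concordant in practice as well as in expectation.
- **Background density**: fragment midpoints are drawn per contig region with
  Poisson counts of mean `depth · weight · region_length / μ`, giving
  physical coverage ≈ `depth · weight` away from contig ends. Fragments are
  shifted (not clipped) to fit the contig, so implied lengths are never
  truncated; mean coverage dips only within ~μ/2 of contig ends.
- **Copy-number regions** scale the tumor's density weight by the configured
  ratio; **repeat-like regions** scale *both* samples, since repeats attract
  excess mappings regardless of somatic genotype.
- **Junctions**: each planted translocation emits exactly `per_side_support`
  discordant pairs; each read is placed uniformly within one interior width
  of the breakpoint on its side, oriented toward the junction. By
  construction the true breakpoint always lies inside each member's implied
  interval, which is what the localization-soundness benchmark verifies
  end-to-end through clustering.
- **Allele counts** are binomial draws at the configured depths and mutant
  fractions.
- **Streams**: each sample draws from `default_rng([seed, role])`; ASE counts
  from a third stream. Tumor, normal and counts are therefore independently
  reproducible, and all fixture files are byte-identical across re-runs.

The generator does **not** model base-call errors, mapping ambiguity, GC
bias, chimeric artifacts, subclonality or purity. Passing benchmarks
demonstrate the pipeline's statistical logic (thresholds, geometry,
normalization, test calibration), not robustness to alignment artifacts of
real genomes.

## Copy number

Physical coverage is binned at 100 bp (each bin holds mean per-base fragment
depth). The tumor/normal comparison is `log2(t/n)` after:

1. **Normalization** by each sample's genome-wide median (robust to planted
   CNVs; a per-chromosome variant was considered and rejected because toy
   genomes have too few contigs for stable per-contig medians).
2. **Repeat masking** on the *normal*: bins above the 0.99 genome-wide
   coverage quantile, plus zero-coverage bins. No pseudocount is added —
   zero-normal bins are masked instead, keeping unmasked ratios exact.
3. **Smoothing** by a 5-bin centered moving median over unmasked bins
   (median resists single-bin outliers; window 1 is the identity).

Discrete calls are maximal runs of ≥ 5 consecutive unmasked bins beyond
±0.3; masked bins break runs; the remainder tiles the contig as neutral
segments.

Two quantified caveats at demonstration scale:

- With ~1 kb fragments, adjacent 100 bp bins are strongly correlated
  (decorrelation length ≈ 10 bins), so at physical depth 20 the per-bin log2
  noise (~0.45 sd) produces short spurious gain/loss runs. The planted-truth
  benchmarks therefore assert *recovery of planted segments* (≥ 90% overlap
  at depth 30), not an empirical false-discovery rate; callers for real data
  add segmentation strength (e.g. CBS) that is out of scope here.
- When a planted segment occupies a large fraction of a miniature genome
  (20% in the benchmark), the sample's median normalizer is biased upward a
  few percent, shrinking the measured segment mean log2 below the ideal
  log2(ratio) (≈ 0.51–0.52 observed vs log2 1.5 = 0.585, within the 0.1
  tolerance asserted). On genome-scale data planted fractions are far
  smaller and the bias vanishes.

## Translocation calling

- **Discordance**: inter-contig, implied length outside μ ± 5σ, or
  orientation other than forward/reverse inward.
- **Clustering**: single linkage among pairs sharing contig pair and
  orientation class with read starts within `max_span = μ + 5σ` on both
  sides; members and clusters are ordered by coordinate then fragment id, so
  output is deterministic regardless of input order.
- **Call rule**: strictly more than 7 distinct supporting pairs — i.e. ≥ 8 —
  on *both* sides of the junction. Support is counted in the tumor only, and
  a somatic call additionally requires ≤ 0 compatible pairs in the matched
  normal (both knobs configurable).
- **Localization**: per side, intersect member-implied intervals (read end →
  read end + 800 for `+` sides, mirrored for `−`). An empty intersection
  falls back to the union midpoint ± 400 bp and is flagged. The point
  estimate is the interval midpoint.
- **Reciprocal pairing**: two calls are the two products of one exchange iff
  contig pairs match, both side strands are flipped, and both point
  estimates agree within 5 kb (default); linkage is exclusive, closest
  summed distance first. The side-strand convention is that `+` retains the
  segment left of the breakpoint and `−` the right, i.e. the strand of the
  reads approaching the junction.

## Fusion annotation

Each breakpoint point estimate is assigned to the transcript whose genomic
span contains it (strict containment by default; a near-gene margin is
available but defaults to 0 to avoid silent misassignment on small genomes).
A gene is the 5′ partner when the junction retains the segment containing
its transcription start — left segment for `+` genes, right for `−` genes —
so transcription reads through the junction. The broken intron/exon ordinal
is counted from the transcript's 5′ end; the kinase domain is "retained" iff
its genomic footprint lies entirely on the retained side of the 5′-partner
breakpoint. Multi-isoform genes are collapsed to the expression-supported
transcript (e.g. the epithelial FGFR2-IIIb analogue) before annotation.
Reading-frame analysis is deliberately excluded: the model captures domain
retention, not codon phase.

The bundled toy gene models reproduce the topology of the real loci (FGFR2
analogue on the minus strand, tyrosine-kinase domain 5′ of the last intron,
partners on the same and on a different contig) at miniature coordinates;
they are synthetic analogues, not GRCh37 annotations. Real GTF + domain-TSV
input is supported for users with genuine annotations.

## Allele-specific expression

Fisher's exact test (two-sided) on the table (dna_ref, dna_alt / rna_ref,
rna_alt); exact rather than asymptotic because clinical variant sites can
have modest depth. Benjamini–Hochberg across sites. A site is flagged only
if `q ≤ α = 0.05` *and* `|VAF_RNA − VAF_DNA| ≥ 0.2`: the effect-size gate
prevents statistically significant but biologically trivial shifts (e.g.
0.45 vs 0.50 at depth 10⁵) from being reported. Type-I calibration is
verified by simulation (2000 null draws at depth 100) and power on the
11%/78% divergent-site scenario exceeds 99% at depth 500. DNA and RNA are
assumed drawn from the same specimen; no purity or mapping-bias correction
is attempted.

## Cohort summaries

Effect classes form a closed vocabulary (nonsynonymous coding … splice site
acceptor); unknown classes are rejected loudly. Recurrence counts *distinct
patients* per gene (two hits in one patient count once) and reports
`patients / cohort_size × 100` rounded half-up to one decimal. The bundled
six-patient class-count table yields per-patient totals
(34, 51, 35, 52, 112, 42): total 326, mean 54.3, range 34–112. Summaries are
always computed from the input records; a source that separately quotes a
total of 327 (mean 55) for the same table is a one-count discrepancy in that
source, which this package surfaces rather than reconciles.

## Problem sizes

Benchmarks run on two-contig genomes of 30–100 kb at physical depths 2–60:
large enough that every statistical behavior being asserted (threshold
exactness, envelope classification, localization soundness over 500
simulations, ASE calibration over 2000 draws, planted-segment recovery) is
exercised with real sampling noise, and small enough that the full suite
plus the acceptance script completes in well under a minute.
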