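# matepairsv

Integrative tumor/normal analysis of **long-insert (mate-pair style) whole-genome
sequencing**, built for finding therapeutically actionable structural events in
solid tumors — the setting where a handful of patients are sequenced deeply and
every copy-number change, translocation, gene fusion and allele-specific
expression signal matters.

A long-insert library yields ~1 kb fragments in which two 100 bp reads flank an
~800 bp unsequenced interior. Two properties follow:

- **Physical (clonal) coverage** — counting the *entire fragment span*, not just
  the sequenced bases, multiplies the depth available for copy-number detection.
- **Breakpoint-safe pairs** — reads rarely cross a rearrangement junction, so a
  discordant pair brackets a breakpoint without being corrupted by it.

The package implements the full analysis around those two ideas:

| stage | what it computes |
|---|---|
| `matepairsv.simulate` | miniature tumor/normal cohorts with known planted truth |
| `matepairsv.coverage` | binned physical coverage; normalized, smoothed, repeat-masked log2(T/N); discrete gain/loss segments |
| `matepairsv.svcall` | discordant-pair clustering; somatic translocation calls requiring **> 7 supporting pairs per side**; fragment-geometry breakpoint intervals; reciprocal-event pairing |
| `matepairsv.fusion` | gene-fusion consequences: 5′/3′ partners, broken intron, kinase-domain retention, intra/inter class |
| `matepairsv.ase` | DNA-vs-RNA allele-specific expression (Fisher exact + Benjamini–Hochberg) |
| `matepairsv.cohort` | per-patient mutation-class tallies and cross-patient gene recurrence |

## The core statistics

**Copy number.** Per 100 bp bin `i`, physical coverage is
`c_i = Σ_f |span(f) ∩ bin_i| / w`. Each sample is scaled by its genome-wide
median, median-smoothed, masked where the normal is repeat-like
(coverage above the 0.99 quantile) or zero, and compared as
`r_i = log2(t_i / n_i)`. Runs of ≥ 5 bins with `r_i > +0.3` (`< −0.3`) become
gain (loss) segments.

**Translocations.** A pair is discordant if inter-contig, outside the insert
envelope `μ ± 5σ`, or not forward/reverse-inward. Compatible pairs are
single-linkage clustered; a cluster becomes a somatic call iff tumor support is
**≥ 8 distinct pairs on both sides** and the matched normal contributes 0
compatible pairs. Each member pair confines the breakpoint to an interval of
width `μ − 2·ℓ_read` (800 bp); the call's interval is the intersection over
members. Two calls with matched loci and complementary orientations are linked
as one reciprocal exchange.

**Allele-specific expression.** For a variant with DNA counts
`(ref_D, alt_D)` and RNA counts `(ref_R, alt_R)`, a two-sided Fisher exact test
on the 2×2 table is BH-corrected across sites; a site is flagged when
`q ≤ 0.05` **and** `|VAF_RNA − VAF_DNA| ≥ 0.2`.

## Worked example

The bundled six-patient demonstration cohort lives on a two-contig miniature
genome with FGFR2/MGEA5/BICC1/TACC3 gene analogues. Patients 4–6 carry
engineered FGFR2 fusions; patient 2 carries a junction with only 5 supporting
pairs (below threshold); patient 3 carries an allele-specific-expression site
(mutant allele 11% in DNA, 78% in RNA).

```bash
matepairsv run-all --out demo --seed 1 --depth 20
```

```
INFO matepairsv: patient1: 76 CNV segments, 0 somatic calls, 0 fusions
INFO matepairsv: patient2: 73 CNV segments, 0 somatic calls, 0 fusions
INFO matepairsv: patient3: 64 CNV segments, 0 somatic calls, 0 fusions
INFO matepairsv: patient4: 65 CNV segments, 1 somatic calls, 1 fusions
INFO matepairsv: patient5: 68 CNV segments, 2 somatic calls, 2 fusions
INFO matepairsv: patient6: 63 CNV segments, 1 somatic calls, 1 fusions
```

Only the three engineered fusion patients produce somatic calls — patient 2's
5-pair junction is correctly rejected by the > 7-pair rule. Patient 5's two
calls are recognized as one reciprocal exchange (`demo/results/patient5/sv.bedpe`):

```
chr10  21871  22017  chr10  40992  41051  chr10:21944+__chr10:41021+  12  +  +  yes  chr10:20859-__chr10:41046-
chr10  20695  21023  chr10  40948  41145  chr10:20859-__chr10:41046-   9  -  -  yes  chr10:21944+__chr10:41021+
```

and annotate as mirrored fusion products (`fusions.tsv`): the FGFR2→BICC1
product breaks in FGFR2's **last intron** (intron 4) with the tyrosine-kinase
domain retained, while the reciprocal BICC1→FGFR2 product carries BICC1 exons
1–2:

```
call                         gene5p  gene3p  break_location_5p  ...  kinase_domain_retained  last_intron_break  chrom_class
chr10:21944+__chr10:41021+   BICC1   FGFR2   intron 2                no                      no                 intra
chr10:20859-__chr10:41046-   FGFR2   BICC1   intron 4                yes                     yes                intra
```

Testing patient 3's ASE site:

```bash
matepairsv ase --counts demo/cohort/patient3/ase_counts.tsv --out ase.tsv
# INFO matepairsv: 1/1 sites flagged -> ase.tsv
```

flags the site as `over-expressed alt` — the formalized version of observing a
mutant allele at ~11% of DNA reads but ~78% of RNA reads, the signature of
near-complete silencing of the wild-type copy.

### Fragment table dialect

Canonical alignment input is a plain TSV, one fragment per row:

```
fragment_id  contig1  pos1  strand1  contig2  pos2  strand2  read_len  sample
```

with 0-based leftmost read coordinates (SAM export is available via
`matepairsv.io.write_fragment_sam`). All BED/BEDPE/bedGraph outputs are 0-based
half-open; GTF input is 1-based per its specification.

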