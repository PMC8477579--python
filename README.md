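# slabir

Nucleosome metagene profiles, broad H3K4me3 "slab" domains, and intron
retention in human lncRNA genes — as one tested pipeline.

## The problem

Internal exons of protein-coding genes sit preferentially in nucleosomes.
The same is true of long non-coding RNA (lncRNA) exons, but lncRNA genes
show two extra features: broad (≥ 1 kb) domains of uniformly high
H3K4me3-marked nucleosome occupancy — *slabs*, as opposed to point peaks —
lying over unusually short first introns, and frequent retention of exactly
those introns in the mature transcripts. This package reimplements the
analysis chain that establishes and quantifies that three-way association,
for anyone who wants to rerun it on their own annotations and tag/coverage
files or to study its statistical behaviour on simulated data:

1. **annotation** — parse GENCODE-dialect GTF gene models; select internal
   exons; derive non-overlapping introns; stratify by neighbour distance,
   leading-exon removal, first-intron length and exonic GC.
2. **coverage** — extend sequencing tags to the 150 bp nucleosome footprint
   in the 3′ direction, accumulate per-base coverage, and average it over
   windows of 500 bp flanking intron + 80 bp exon edge (580 positions per
   side), normalized per exon window and per million library tags.
3. **slabs** — call maximal runs of supra-threshold signal, merge
   sub-nucleosome gaps, keep runs ≥ 1 kb; flag query regions (the M flag).
4. **intron_retention** — score each intron as
   `SIR = intron / (intron + mean flanking-exon depth)` from RNA-seq
   coverage; an intron is *retained* iff SIR > 0 (any level of retention).
5. **association** — the 2×2 slab × IR contingency table with Pearson's
   chi-squared test (no continuity correction), concordance, intron-length
   summaries and first-intron frequencies per retention class.
6. **simulate** — a seeded generator of gene models, phased-nucleosome tag
   libraries, slab domains and RNA coverage with full truth tables, so
   every stage is testable without downloads.

The headline statistic: over 200 surveyed lncRNA intronic regions with
slab/retention cells (57, 10, 52, 81), Pearson's chi-squared is

χ² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)) ≈ 37.98, p ≈ 7×10⁻¹⁰,

with 69 % concordance between the two flags.

## Worked example

Simulate a small study and run the full survey (slab calling → retention
calling → contingency test):

```sh
slabir simulate --out demo --seed 11 --n-lncrna 60 --n-mrna 0 --n-tags 40000
slabir all --fixture demo --out demo_out
```

```
Slab (M) x intron retention (IR) contingency
              IR present   IR absent
M present             13           1
M absent              22          24
n = 60
chi-squared = 8.9547 (1 df, no continuity correction)
p-value = 3e-03
concordance = 61.7%
IR prevalence = 58.3%
IR present: n=35, median length=269 bp, mean=471 +/- 116 bp, first introns=22 (63%)
IR absent: n=25, median length=1924 bp, mean=2926 +/- 520 bp, first introns=10 (40%)
```

Sixty surveyed introns were each flagged for slab presence (from the
simulated H3K4me3 coverage) and retention (from the simulated RNA
coverage); even at this small size the association is significant
(p ≈ 3×10⁻³), retained introns are short (median 269 bp vs 1924 bp) and
enriched for first introns — the structure the generator programs in and
the pipeline recovers.

The published-scale table reproduces directly from its cell counts:

```sh
slabir associate --cells 57 10 52 81
```

```
chi-squared = 37.9811 (1 df, no continuity correction)
p-value = 7e-10
concordance = 69.0%
IR prevalence = 54.5%
```

Other subcommands: `slabir profile` (exon-anchored metagene TSVs and
optional plots, with `--isolated-only` and `--drop-leading` stratification
flags), `slabir slabs` (domain calls + per-region M flags), `slabir ir`
(per-intron retention TSV, optional per-ordinal profiles).

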