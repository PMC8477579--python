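# Methods

## Coordinates and annotation processing

All internal coordinates are 0-based half-open; GTF (1-based closed)
converts at the file boundary only. Exon and intron ordinals count in
transcription direction, so ordinal 1 of a minus-strand transcript is the
genomically rightmost feature.

A transcript is labelled `lncRNA` when its `transcript_type` (falling back
to `gene_type`) is in a configurable label set covering the current and
legacy lncRNA biotypes; every other transcript is `mRNA`, i.e. "all
annotated exons except lncRNA exons". *Internal* exons (1 < ordinal < n)
are selected per transcript and then deduplicated by exact coordinates;
an exon that is internal in one isoform but terminal in another is
retained, because the counts of interest are over exons, not
exon–isoform pairs. *Non-overlapping introns* are the inter-exon gaps of
each transcript that intersect no annotated exon of any transcript;
coordinate-identical survivors are deduplicated, keeping the ordinal of
the first (sorted) transcript they derive from. Stratifications:

* isolation filter — keep exons whose flanking introns are both
  ≥ `min_gap` (default 500 bp; the boundary is inclusive);
* leading-exon removal — drop ordinals ≤ k (default 2);
* first-intron length split at 500 bp, ties to the long (≥) group, one
  consistent "at least" boundary rule throughout;
* GC split of an exon set at its median GC fraction — the only
  parameter-free cut when no absolute threshold is given.

## Coverage and metagene profiles

Sequenced tags mark fragment ends, and plus/minus reads from the same
nucleosome start ~150 bp apart, so each tag is extended to 150 bp in its
3′ direction (plus strand: from its start rightward; minus strand: from
its end leftward), clipped at chromosome edges. Coverage at a base is the
number of extended tags containing it.

A metagene profile averages coverage over windows anchored at exon
boundaries: 500 bp of flanking intron plus the first (upstream side) or
last (downstream side) 80 bp of exon — 580 positions ordered 5′→3′ in
transcription direction. Windows are excluded per side (not zero-padded)
when the exon is shorter than 80 bp or the window leaves the chromosome;
zero-padding would deflate densities, and per-side exclusion is why the
two sides can poll different window counts. Values are

    profile[i] = Σ_windows coverage[pos_i] / n_windows / (library_tags / 10⁶)

so duplicating every tag, or every exon record, leaves the profile
unchanged (both invariances are tested). The *exonic enrichment* statistic
is the percent excess of the mean over all 160 exon-edge positions above
the mean over all 1000 intronic positions of an upstream/downstream pair.
This window-mean operationalization is one of several possible readings of
"percent increase at exons" (peak height is another); it is the stated
definition here and the generator is calibrated to it.

## Slab calling

A slab is a contiguous run of bases with signal ≥ `threshold`, after
merging runs separated by ≤ `max_gap` sub-threshold bases, kept when the
merged span is ≥ `min_length`:

* `min_length` = 1000 bp — the defining scale of the domain;
* `max_gap` = 100 bp — sub-nucleosome linker scale, tolerating MNase
  sampling dropouts;
* `threshold` — deliberately a required parameter. The original visual
  definition ("saturating a browser display over several cell lines") has
  no portable analysis-unit equivalent. A quantile helper (default 0.99 of
  nonzero values) suits sparse real tracks; for dense simulated tracks the
  pipeline uses half the designed slab signal level times the genome-wide
  median of nonzero coverage, i.e. a value halfway between background and
  domain signal.

Slabs are strandless; region flags (M) use half-open overlap with
`min_overlap` = 1 bp. The caller is property-tested against a per-base
scanline oracle, and is monotone (covered bases non-increasing in
threshold, non-decreasing in max_gap) and idempotent on indicator tracks.

## Intron retention

The per-intron retention score from RNA-seq coverage is

    SIR = intron_depth / (intron_depth + mean(upstream_exon, downstream_exon depth))

with SIR = 0 when the intron has zero coverage and SIR = 1 when only the
intron is covered. The score is bounded, scale-free (invariant to
multiplying the track by any c > 0) and monotone in intronic depth. The
classification rule is dichotomous: retained ⇔ SIR > 0, i.e. any level of
retention counts. The exact formula behind the original score is not
published; any definition positive exactly when intronic coverage is
positive reproduces the same dichotomy, and this one is declared rather
than inferred. Junction reads are not used — coverage only. An optional
`min_depth` floor (default 0) guards against single-read noise without
changing the default rule.

## Association statistics

The 2×2 slab × IR table is tested with Pearson's chi-squared, **without**
Yates continuity correction — the single most important numerical choice
in the module: the uncorrected statistic on cells (57, 10, 52, 81) gives
χ² ≈ 37.98 and p ≈ 7×10⁻¹⁰, whereas the corrected one gives ≈ 2×10⁻⁹.
Zero row/column margins are an error (test undefined). The statistic is
cross-checked in tests against the closed form n(ad−bc)²/(r₁r₂c₁c₂) and
against a label-permutation Monte-Carlo null; the permutation distribution
is discrete, and the asymptotic p corresponds to its mid-p tail (ties at
the observed statistic take half weight). Concordance is
(n₁₁ + n₀₀)/n. Group summaries report median, mean and standard error
(sample sd/√n; a single observation reports 0) of intron lengths and
first-intron fractions per retention class. p-values print at one
significant digit in reports and full precision in machine output.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with truth
tables for every layer.

**Gene models.** Non-overlapping single-isoform genes laid out
sequentially with random intergenic gaps (1–2.5 kb) on a small genome
(default 3 × 1.6 Mb). Exon counts 3–6; exon lengths are multiples of the
150 bp nucleosome footprint (150–450 bp), for the reason given below.
Intron lengths are lognormal: lncRNA non-first median 2 kb, mRNA median
6 kb. Each lncRNA gene contributes one *surveyed* intron: a joint (M, IR)
label is drawn from a 2×2 probability table whose default reproduces the
observed survey proportions 57:10:52:81 over 200 regions, and the
surveyed ordinal is first with probability 73/109 (IR-present) or 24/91
(IR-absent). Surveyed intron lengths come from the two observed length
classes — lognormal median 192 bp for retained and 2181 bp for
non-retained, with log-sd back-derived from the published median/mean
pairs (354 and 5323 bp): σ = √(2 ln(mean/median)) = 1.106 and 1.336.
Non-surveyed first introns are short with probability
`frac_lncrna_short_first` (default 0.545, the survey's retention
prevalence).

**Tag libraries.** Fragment (150 bp footprint) start positions are drawn
from a weighted discrete distribution: a uniform background rate;
multiplied by `slab_signal_level` (default 10) over slab intervals
(surveyed intron ± 600 bp, guaranteeing ≥ 1.2 kb domains) in the
H3K4me3 library; plus one positioned-nucleosome spike per 150 bp of exon
with mass (f − 1) × 150, f the exonic enrichment factor (default 1.28).
Each sampled footprint [u, u+150) is emitted as a 25 bp tag from a
uniformly chosen end, so the pipeline's 3′ extension reconstructs the
footprint exactly. The phased-spike construction, with exon lengths
quantized to the footprint, is the exact discrete deconvolution of the
coverage step through the 150 bp extension: expected coverage is exactly
f × background over exons and background elsewhere. A plain per-base
intensity step would be smeared ± 75 bp by the extension and attenuate
the measured window-mean enrichment (a programmed 1.28 would read ~1.20);
phased exonic nucleosome arrays are also the more faithful picture of the
phenomenon being emulated. Signal levels and library depths were chosen
from this forward model so that slab coverage sits ≥ 3.8σ above the
calling threshold — domains are meant to emulate saturating, visually
unambiguous signal, not marginal peaks.

**RNA coverage.** Constant exonic depth per gene (default 10×);
retention-labelled introns get `ir_depth_fraction` (default 0.3) of the
gene's exonic depth; everything else is exactly zero, so truth recovery by
the SIR > 0 rule is exact by construction. An optional Poisson mode
resamples every base as an independent Poisson count (zero means stay
zero), used for the 20×-depth noise-robustness checks.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mappability and MNase sequence bias, duplicate
reads, isoform mixtures and overlapping genes on the tag side; spliced
junction reads, expression variation across genes, and spurious intronic
background on the RNA side (so the SIR > 0 rule is exact here but would
over-call retention on noisy real coverage — the `min_depth` guard exists
for that case); and replicate structure everywhere.

## Problem sizes and runtime choices

The test and reproduction workloads use scaled study conditions chosen to
estimate each quantity well on one CPU: the enrichment calibration fixture
packs 120 four/five-exon lncRNA genes into 2 × 430 kb with 10⁵ tags
(≈ 600 windows; per-fixture sd of the measured enrichment ≈ 1 percentage
point; the reproduction script averages three fixtures); the association
fixture surveys 200 regions on 2 × 780 kb with 10⁵ tags; replicated
rejection-rate estimates use 100 replicates in the test suite and 50 in
the reproduction script. The slab caller is verified against the scanline
oracle on 200 random 100 kb tracks.

## Known limitations

* The chi-squared p-value is asymptotic; for small surveyed samples an
  exact or permutation test would be preferable (one is used as a test
  oracle but not exposed as the primary statistic).
* Profiles weight every admissible window equally; no GC or mappability
  correction is applied to coverage.
* bedGraph inputs with overlapping intervals are rejected rather than
  summed; strand-specific RNA coverage is out of scope (provide one track
  per strand upstream if needed).
* The slab threshold remains a judgement call on real data; the quantile
  helper is a starting point, not a calibration.
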