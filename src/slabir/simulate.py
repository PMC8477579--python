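"""Seeded synthetic genomes, tag libraries and RNA coverage with truth tables.

The generator emulates the statistical structure the analysis assumes:

* multi-exonic lncRNA and mRNA gene models in which lncRNA first introns
  are short (lognormal, median 192 bp) for retention-labelled genes and
  long (median 2181 bp) otherwise — the length classes of the surveyed
  intron population;
* nucleosome tag libraries whose expected coverage is exactly
  ``exon_enrichment_factor`` x background over exons.  Exonic enrichment is
  realized as a phased array of positioned nucleosomes (one fragment-start
  spike per 150 bp of exon, with exon lengths quantized to the 150 bp
  footprint) on top of a uniform background fragment-start rate.  The
  phased construction is the exact inverse of the 150 bp 3' tag extension:
  a plain per-base intensity step would be smeared +/-75 bp by the
  extension and would attenuate window-mean enrichment estimates;
* >=1 kb high-signal slab domains over the first introns of slab-labelled
  genes (intron +/- ``slab_extension``);
* RNA-seq coverage with constant exonic depth per gene, proportional
  nonzero depth over retention-labelled introns, and exact zero elsewhere,
  optionally resampled per-base as Poisson counts.

Joint slab/retention labels are drawn from a configurable 2x2 probability
table whose default reproduces the observed survey proportions
57 : 10 : 52 : 81 over 200 regions.

All functions are deterministic given (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import GeneModelSet, GenomicInterval, Transcript
from .coverage import CoverageTrack, TagLibrary, TagRecord, build_coverage
from .io import PathLike, write_chrom_sizes, write_gtf

FOOTPRINT = 150  # nucleosome-protected fragment length, bp

#: observed survey proportions of the default joint (M, IR) table:
#: rows = slab present/absent, columns = IR present/absent
SURVEY_CELLS = (57, 10, 52, 81)


@dataclass(frozen=True)
class LogNormalLength:
    """Lognormal length distribution parameterized by its median.

    ``sigma`` is the log-scale standard deviation; samples are rounded to
    integers and clipped to [minimum, maximum].
    """

    median: float
    sigma: float
    minimum: int = 75
    maximum: int = 30000

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raw = self.median * np.exp(self.sigma * rng.standard_normal(n))
        return np.clip(np.rint(raw).astype(int), self.minimum, self.maximum)


# Sigmas back-derived from the surveyed length classes' median/mean pairs
# (192/354 bp retained, 2181/5323 bp non-retained): mean = median*exp(s^2/2).
SHORT_FIRST_INTRON = LogNormalLength(median=192.0, sigma=1.106, minimum=75, maximum=3000)
LONG_FIRST_INTRON = LogNormalLength(median=2181.0, sigma=1.336, minimum=300, maximum=20000)


@dataclass(frozen=True)
class SimSpec:
    """Study-condition parameters for the synthetic genome.

    The defaults encode the surveyed conditions: 200 lncRNA loci whose
    first introns carry joint slab/retention labels in the observed
    57:10:52:81 proportions, short retained first introns (median 192 bp)
    versus long non-retained ones (median 2181 bp), a 1.28x exonic
    nucleosome enrichment, and >=1 kb slab domains.
    """

    n_chroms: int = 3
    chrom_length: int = 1_600_000
    n_lncrna: int = 200
    n_mrna: int = 40
    exon_count_range: Tuple[int, int] = (3, 6)
    exon_length_range: Tuple[int, int] = (150, 450)
    lncrna_first_intron_short: LogNormalLength = SHORT_FIRST_INTRON
    lncrna_first_intron_long: LogNormalLength = LONG_FIRST_INTRON
    lncrna_other_intron: LogNormalLength = LogNormalLength(2000.0, 0.6, 600, 12000)
    mrna_intron: LogNormalLength = LogNormalLength(6000.0, 0.8, 600, 30000)
    #: P(short first intron) for lncRNA genes when no joint M/IR table is used
    frac_lncrna_short_first: float = 0.545
    #: P(surveyed intron is the first intron | IR class): 73/109 and 24/91
    first_intron_prob_ir: float = 73 / 109
    first_intron_prob_no_ir: float = 24 / 91
    exon_enrichment_factor: float = 1.28
    slab_signal_level: float = 10.0
    slab_extension: int = 600
    n_tags: int = 250_000
    read_length: int = 25
    rna_exon_depth: float = 10.0
    ir_depth_fraction: float = 0.3
    rna_noise: Optional[str] = None  # None (deterministic) or "poisson"
    #: joint P(M, IR) as ((mp_irp, mp_ira), (ma_irp, ma_ira)); None disables
    #: slab/retention labelling entirely (profile-only fixtures)
    ir_conditional_on_slab: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = (
        (57 / 200, 10 / 200),
        (52 / 200, 81 / 200),
    )
    intergene_gap_range: Tuple[int, int] = (1000, 2500)
    edge_margin: int = 1000

    def __post_init__(self) -> None:
        if self.n_lncrna < 0 or self.n_mrna < 0 or self.n_lncrna + self.n_mrna == 0:
            raise ValueError("need at least one gene")
        if not (0.0 <= self.frac_lncrna_short_first <= 1.0):
            raise ValueError("frac_lncrna_short_first must be in [0, 1]")
        if self.exon_enrichment_factor < 1.0:
            raise ValueError("exon_enrichment_factor must be >= 1")
        if self.ir_conditional_on_slab is not None:
            probs = np.asarray(self.ir_conditional_on_slab, dtype=float)
            if probs.shape != (2, 2) or np.any(probs < 0):
                raise ValueError("ir_conditional_on_slab must be a 2x2 table")
            if abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError("ir_conditional_on_slab must sum to 1")

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @classmethod
    def null_association(cls, **overrides) -> "SimSpec":
        """Same marginals as the default joint table, but M and IR independent."""
        probs = np.asarray(((57, 10), (52, 81)), dtype=float) / 200.0
        p_m = probs[0].sum()
        p_ir = probs[:, 0].sum()
        joint = (
            (p_m * p_ir, p_m * (1 - p_ir)),
            ((1 - p_m) * p_ir, (1 - p_m) * (1 - p_ir)),
        )
        return cls(ir_conditional_on_slab=joint, **overrides)

    @classmethod
    def association_fixture(cls, null: bool = False, **overrides) -> "SimSpec":
        """A lean 200-region survey fixture for replicated association runs.

        Keeps the surveyed-intron length classes and joint M/IR table of
        the default conditions but drops mRNA genes and trims non-surveyed
        intron lengths so one replicate stays small.
        """
        defaults = dict(
            n_chroms=2,
            chrom_length=780_000,
            n_lncrna=200,
            n_mrna=0,
            exon_count_range=(3, 4),
            lncrna_other_intron=LogNormalLength(1200.0, 0.3, 700, 4000),
            lncrna_first_intron_long=LogNormalLength(2181.0, 1.336, 300, 12000),
            n_tags=100_000,
            intergene_gap_range=(1000, 1600),
        )
        defaults.update(overrides)
        if null:
            return cls.null_association(**defaults)
        return cls(**defaults)

    @classmethod
    def profile_fixture(cls, exon_enrichment_factor: float = 1.28, **overrides) -> "SimSpec":
        """A dense slab-free fixture for calibrating metagene enrichment.

        Introns are kept comfortably longer than the 500 bp flank (so
        windows sample pure intron) and the genome is packed tightly so a
        10^5-tag library concentrates sampling in the profiled windows.
        """
        defaults = dict(
            n_chroms=2,
            chrom_length=430_000,
            n_lncrna=120,
            n_mrna=0,
            exon_count_range=(4, 5),
            lncrna_other_intron=LogNormalLength(1200.0, 0.3, 700, 5000),
            frac_lncrna_short_first=0.0,
            exon_enrichment_factor=exon_enrichment_factor,
            ir_conditional_on_slab=None,
            n_tags=100_000,
            intergene_gap_range=(800, 1200),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TruthTable:
    """Generator ground truth, mutually consistent with the emitted files."""

    genes: pd.DataFrame
    introns: pd.DataFrame
    regions: pd.DataFrame
    slabs: List[GenomicInterval] = field(default_factory=list)


def _draw_gene_lengths(
    spec: SimSpec, rng: np.random.Generator, biotype: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Exon and intron lengths in transcription order for one gene.

    lncRNA first introns are short (the 192 bp-median distribution) for a
    ``frac_lncrna_short_first`` fraction of genes; surveyed-intron length
    overrides are applied by the caller, which knows the IR label.
    """
    lo, hi = spec.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    max_mult = max(1, spec.exon_length_range[1] // FOOTPRINT)
    min_mult = max(1, spec.exon_length_range[0] // FOOTPRINT)
    exon_lengths = FOOTPRINT * rng.integers(min_mult, max_mult + 1, size=n_exons)
    n_introns = n_exons - 1
    if biotype == "mRNA":
        intron_lengths = spec.mrna_intron.sample(rng, n_introns)
    else:
        intron_lengths = spec.lncrna_other_intron.sample(rng, n_introns)
        if n_introns > 0 and rng.random() < spec.frac_lncrna_short_first:
            intron_lengths[0] = spec.lncrna_first_intron_short.sample(rng, 1)[0]
    return exon_lengths, intron_lengths


def simulate_gene_models(
    spec: SimSpec, seed: int
) -> Tuple[GeneModelSet, TruthTable]:
    """Place non-overlapping single-isoform genes and assign M/IR labels.

    Genes are laid out sequentially with random intergenic gaps; running
    out of chromosome is an error suggesting a larger ``chrom_length``.
    """
    rng = np.random.default_rng(seed)
    biotypes = ["lncRNA"] * spec.n_lncrna + ["mRNA"] * spec.n_mrna
    rng.shuffle(biotypes)

    joint = (
        None
        if spec.ir_conditional_on_slab is None
        else np.asarray(spec.ir_conditional_on_slab, dtype=float).ravel()
    )

    chrom_names = list(spec.chrom_sizes)
    chrom_idx = 0
    cursor = spec.edge_margin

    transcripts: List[Transcript] = []
    gene_rows, intron_rows, region_rows = [], [], []
    slab_intervals: List[GenomicInterval] = []

    for g, biotype in enumerate(biotypes):
        gene_id = f"G{g:04d}"
        tx_id = f"T{g:04d}"
        m_label, ir_label, surveyed_index = False, None, None
        if biotype == "lncRNA" and joint is not None:
            cell = int(rng.choice(4, p=joint))
            m_label = cell in (0, 1)
            ir_label = cell in (0, 2)

        exon_lengths, intron_lengths = _draw_gene_lengths(spec, rng, biotype)
        n_introns = len(intron_lengths)
        if biotype == "lncRNA" and joint is not None and n_introns > 0:
            p_first = (
                spec.first_intron_prob_ir
                if ir_label
                else spec.first_intron_prob_no_ir
            )
            if n_introns == 1 or rng.random() < p_first:
                surveyed_index = 1
            else:
                surveyed_index = int(rng.integers(2, n_introns + 1))
            dist = (
                spec.lncrna_first_intron_short
                if ir_label
                else spec.lncrna_first_intron_long
            )
            intron_lengths[surveyed_index - 1] = dist.sample(rng, 1)[0]
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(exon_lengths.sum() + intron_lengths.sum())

        gap = int(rng.integers(*spec.intergene_gap_range))
        while cursor + gap + span + spec.edge_margin > spec.chrom_length:
            chrom_idx += 1
            cursor = spec.edge_margin
            if chrom_idx >= len(chrom_names):
                raise ValueError(
                    "gene placement exhausted the genome; increase chrom_length "
                    "or n_chroms"
                )
        chrom = chrom_names[chrom_idx]
        gene_start = cursor + gap
        cursor = gene_start + span

        # lay segments genomically; transcription order reverses on minus
        seg_exons = list(exon_lengths)
        seg_introns = list(intron_lengths)
        if strand == "-":
            seg_exons = seg_exons[::-1]
            seg_introns = seg_introns[::-1]
        exon_coords = []
        pos = gene_start
        for k, e_len in enumerate(seg_exons):
            exon_coords.append((pos, pos + int(e_len)))
            pos += int(e_len)
            if k < len(seg_introns):
                pos += int(seg_introns[k])
        tx = Transcript(
            transcript_id=tx_id,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            biotype=biotype,
            exons=tuple(exon_coords),
        )
        transcripts.append(tx)

        gene_rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": tx_id,
                "chrom": chrom,
                "start": gene_start,
                "end": gene_start + span,
                "strand": strand,
                "biotype": biotype,
                "n_exons": len(exon_lengths),
                "surveyed_intron": surveyed_index if surveyed_index else 0,
                "m_truth": bool(m_label),
                "ir_truth": bool(ir_label) if ir_label is not None else False,
            }
        )

        for rec in tx.intron_records():
            surveyed = rec.intron_index == surveyed_index
            intron_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tx_id,
                    "chrom": chrom,
                    "start": rec.interval.start,
                    "end": rec.interval.end,
                    "strand": strand,
                    "intron_index": rec.intron_index,
                    "length": rec.length,
                    "surveyed": surveyed,
                    "ir_truth": bool(ir_label) if surveyed else False,
                    "m_truth": bool(m_label) if surveyed else False,
                }
            )
            if surveyed:
                region_rows.append(
                    {
                        "region_id": gene_id,
                        "chrom": chrom,
                        "start": rec.interval.start,
                        "end": rec.interval.end,
                        "intron_index": rec.intron_index,
                        "m_truth": bool(m_label),
                        "ir_truth": bool(ir_label),
                    }
                )
                if m_label:
                    slab_intervals.append(
                        GenomicInterval(
                            chrom,
                            rec.interval.start - spec.slab_extension,
                            rec.interval.end + spec.slab_extension,
                            ".",
                        )
                    )

    models = GeneModelSet(
        transcripts=transcripts, chrom_sizes=dict(spec.chrom_sizes)
    )
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        introns=pd.DataFrame(intron_rows),
        regions=pd.DataFrame(region_rows),
        slabs=slab_intervals,
    )
    return models, truth


def simulate_nucleosome_tags(
    models: GeneModelSet,
    truth: TruthTable,
    spec: SimSpec,
    seed: int,
    mark: str = "h3k4me3",
) -> TagLibrary:
    """Sample a tag library from the phased-nucleosome forward model.

    Fragment (footprint) start positions are drawn from: a uniform
    background rate; multiplied by ``slab_signal_level`` inside slab
    domains (``mark="h3k4me3"`` only); plus one positioned-nucleosome spike
    of mass (f - 1) x 150 per 150 bp of exon, f the exonic enrichment
    factor.  Each sampled footprint [u, u+150) is reported as a
    ``read_length`` bp tag from a uniformly chosen end, so 3'-extending
    tags by 150 bp reconstructs the footprint exactly.
    """
    if mark not in ("h3k4me3", "total"):
        raise ValueError("mark must be 'h3k4me3' or 'total'")
    rng = np.random.default_rng(seed)
    sizes = models.chrom_sizes
    chroms = list(sizes)

    base: Dict[str, np.ndarray] = {}
    spike_pos: Dict[str, np.ndarray] = {}
    spike_mass: Dict[str, np.ndarray] = {}
    for chrom, size in sizes.items():
        w = np.ones(size)
        w[max(0, size - FOOTPRINT + 1):] = 0.0  # footprint must fit
        base[chrom] = w
    if mark == "h3k4me3":
        for slab in truth.slabs:
            lo = max(0, slab.start - FOOTPRINT // 2)
            hi = max(0, slab.end - FOOTPRINT // 2)
            base[slab.chrom][lo:hi] *= spec.slab_signal_level

    f = spec.exon_enrichment_factor
    for chrom in chroms:
        positions, masses = [], []
        if f > 1.0:
            for tx in models.transcripts:
                if tx.chrom != chrom:
                    continue
                for start, end in tx.exons:
                    for p in range(start, end - FOOTPRINT + 1, FOOTPRINT):
                        positions.append(p)
                        masses.append((f - 1.0) * FOOTPRINT)
        spike_pos[chrom] = np.asarray(positions, dtype=int)
        spike_mass[chrom] = np.asarray(masses, dtype=float)

    chrom_totals = np.array(
        [base[c].sum() + spike_mass[c].sum() for c in chroms]
    )
    counts = rng.multinomial(spec.n_tags, chrom_totals / chrom_totals.sum())

    tags: List[TagRecord] = []
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        weights = np.concatenate([base[chrom], spike_mass[chrom]])
        cum = np.cumsum(weights)
        draws = rng.random(n) * cum[-1]
        idx = np.searchsorted(cum, draws, side="right")
        size = sizes[chrom]
        spikes = spike_pos[chrom]
        if len(spikes):
            starts = np.where(
                idx < size, idx, spikes[np.clip(idx - size, 0, len(spikes) - 1)]
            )
        else:
            starts = idx
        plus = rng.random(n) < 0.5
        rl = spec.read_length
        for u, is_plus in zip(starts, plus):
            u = int(u)
            if is_plus:
                tags.append(TagRecord(chrom, u, u + rl, "+"))
            else:
                tags.append(TagRecord(chrom, u + FOOTPRINT - rl, u + FOOTPRINT, "-"))
    tags.sort(key=lambda t: (t.chrom, t.start, t.end, t.strand))
    return TagLibrary(tags=tags, source=f"simulated:{mark}")


def expected_coverage_background(spec: SimSpec, models: GeneModelSet,
                                 truth: TruthTable, mark: str = "h3k4me3") -> float:
    """Expected per-base background coverage of a simulated library.

    Derived from the sampling weights: background bases draw footprints at
    rate n_tags / total_weight, each covering 150 bp.
    """
    total = 0.0
    f = spec.exon_enrichment_factor
    for tx in models.transcripts:
        for start, end in tx.exons:
            n_spikes = max(0, (end - start - FOOTPRINT) // FOOTPRINT + 1)
            total += (f - 1.0) * FOOTPRINT * n_spikes
    genome = float(sum(models.chrom_sizes.values()))
    total += genome
    if mark == "h3k4me3":
        for slab in truth.slabs:
            total += (spec.slab_signal_level - 1.0) * slab.length
    return FOOTPRINT * spec.n_tags / total


def simulate_rnaseq_coverage(
    models: GeneModelSet, truth: TruthTable, spec: SimSpec, seed: int
) -> CoverageTrack:
    """RNA-seq coverage: constant exonic depth per gene, nonzero depth over
    retention-labelled introns, exact zero elsewhere.

    With ``spec.rna_noise == "poisson"`` the deterministic mean track is
    resampled per-base as independent Poisson counts (zero means stay zero).
    """
    track = CoverageTrack.zeros(models.chrom_sizes)
    ir_by_key = {
        (r.gene_id, r.intron_index): bool(r.ir_truth)
        for r in truth.introns.itertuples()
    }
    for tx in models.transcripts:
        depth = spec.rna_exon_depth
        arr = track.data[tx.chrom]
        for start, end in tx.exons:
            arr[start:end] = depth
        for rec in tx.intron_records():
            if ir_by_key.get((tx.gene_id, rec.intron_index), False):
                arr[rec.interval.start : rec.interval.end] = (
                    spec.ir_depth_fraction * depth
                )
    if spec.rna_noise == "poisson":
        rng = np.random.default_rng(seed)
        for chrom in track.data:
            track.data[chrom] = rng.poisson(track.data[chrom]).astype(float)
    elif spec.rna_noise is not None:
        raise ValueError(f"unknown rna_noise mode {spec.rna_noise!r}")
    return track


@dataclass
class StudyBundle:
    """In-memory end-to-end fixture: models, truth, tracks and libraries."""

    spec: SimSpec
    seed: int
    models: GeneModelSet
    truth: TruthTable
    nucleosome_library: TagLibrary
    h3k4me3_library: TagLibrary
    h3k4me3_track: CoverageTrack
    rna_track: CoverageTrack


def simulate_study(spec: SimSpec, seed: int) -> StudyBundle:
    """Generate every layer of the synthetic study from one master seed."""
    child = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child]
    models, truth = simulate_gene_models(spec, seeds[0])
    nuc = simulate_nucleosome_tags(models, truth, spec, seeds[1], mark="total")
    h3k = simulate_nucleosome_tags(models, truth, spec, seeds[2], mark="h3k4me3")
    h3k_track = build_coverage(h3k, models.chrom_sizes)
    rna = simulate_rnaseq_coverage(models, truth, spec, seeds[3])
    return StudyBundle(
        spec=spec,
        seed=seed,
        models=models,
        truth=truth,
        nucleosome_library=nuc,
        h3k4me3_library=h3k,
        h3k4me3_track=h3k_track,
        rna_track=rna,
    )


def end_to_end_fixture(
    spec: SimSpec, outdir: PathLike, seed: int, force: bool = False
) -> Dict[str, Path]:
    """Emit a mutually consistent fixture directory.

    Files: genes.gtf, chrom.sizes, nucleosome_tags.bed (total MNase
    library), h3k4me3.bedgraph (extended-tag coverage), rnaseq.bedgraph,
    truth tables, and a manifest recording spec and seed.
    """
    from .coverage import write_tags, write_track

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = simulate_study(spec, seed)
    paths = {
        "gtf": outdir / "genes.gtf",
        "chrom_sizes": outdir / "chrom.sizes",
        "tags": outdir / "nucleosome_tags.bed",
        "h3k4me3": outdir / "h3k4me3.bedgraph",
        "rna": outdir / "rnaseq.bedgraph",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_introns": outdir / "truth_introns.tsv",
        "truth_regions": outdir / "truth_regions.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_gtf(bundle.models, paths["gtf"])
    write_chrom_sizes(bundle.models.chrom_sizes, paths["chrom_sizes"])
    write_tags(bundle.nucleosome_library, paths["tags"])
    write_track(bundle.h3k4me3_track, paths["h3k4me3"], dialect="bedGraph")
    write_track(bundle.rna_track, paths["rna"], dialect="bedGraph")
    bundle.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    bundle.truth.introns.to_csv(paths["truth_introns"], sep="\t", index=False)
    bundle.truth.regions.to_csv(paths["truth_regions"], sep="\t", index=False)

    def _jsonable(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        return obj

    manifest = {"seed": seed, "spec": _jsonable(spec)}
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
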