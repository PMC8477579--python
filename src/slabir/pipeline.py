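"""End-to-end orchestration: profiles, slab survey, IR calls, association.

These functions tie the stage modules together so the command-line
interface and the reproduction scripts stay thin.  Each takes explicit
inputs (model sets, tracks) or a synthetic-study bundle and returns the
domain objects of the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import association as assoc
from .annotation import derive_nonoverlapping_introns, select_internal_exons
from .core import GeneModelSet, GenomicInterval
from .coverage import (
    CoverageTrack,
    MetaProfile,
    TagLibrary,
    build_coverage,
    exon_enrichment,
    metagene_profile,
)
from .intron_retention import IRCall, classify_ir
from .slabs import SlabCall, SlabParams, call_slabs, region_has_slab
from .simulate import StudyBundle, expected_coverage_background


@dataclass
class ProfileStudy:
    """Paired upstream/downstream profiles and their enrichment statistic."""

    up: MetaProfile
    down: MetaProfile

    @property
    def enrichment_pct(self) -> float:
        return exon_enrichment(self.up, self.down)


def profile_internal_exons(
    track: CoverageTrack,
    models: GeneModelSet,
    library_size: int,
    biotype: Optional[str] = "lncRNA",
    flank: int = 500,
    edge: int = 80,
    min_gap: Optional[int] = None,
    drop_leading: int = 0,
) -> ProfileStudy:
    """Metagene profiles anchored on internal exons of one biotype.

    ``min_gap`` applies the isolation filter (exons separated from their
    neighbours by at least that many bases); ``drop_leading`` removes
    exons with ordinal <= k before profiling.
    """
    from .annotation import drop_leading_exons, filter_isolated_exons

    exons = select_internal_exons(models, biotype=biotype)
    if min_gap is not None:
        exons = filter_isolated_exons(exons, min_gap=min_gap)
    if drop_leading:
        exons = drop_leading_exons(exons, k=drop_leading)
    up = metagene_profile(track, exons, "upstream", flank, edge, library_size)
    down = metagene_profile(track, exons, "downstream", flank, edge, library_size)
    return ProfileStudy(up=up, down=down)


def slab_threshold_for_bundle(bundle: StudyBundle) -> float:
    """Slab threshold halfway between background and slab coverage levels.

    The genome-wide median of nonzero coverage estimates the background
    level; the design's slab_signal_level places domain coverage at a known
    multiple of it.
    """
    nonzero = np.concatenate(
        [a[a > 0] for a in bundle.h3k4me3_track.data.values() if np.any(a > 0)]
    )
    background = float(np.median(nonzero))
    return 0.5 * bundle.spec.slab_signal_level * background


@dataclass
class SurveyResult:
    """The slab x IR survey over first-intron regions, with diagnostics."""

    contingency: assoc.ContingencyResult
    summaries: Dict[str, assoc.GroupSummary]
    calls: List[IRCall]
    slabs: List[SlabCall]
    m_flags: List[bool]
    ir_flags: List[bool]
    region_gene_ids: List[str]


def survey_regions(
    models: GeneModelSet,
    h3k4me3: CoverageTrack,
    rna: CoverageTrack,
    slab_params: SlabParams,
    regions: Sequence,
    min_depth: float = 0.0,
) -> SurveyResult:
    """Flag each surveyed intron for slab presence and retention, then test.

    ``regions`` are the surveyed introns (IntronRecord, e.g. randomly
    selected intronic regions of lncRNA loci).  M comes from slab calls on
    the histone track; IR from the retention classifier on the RNA track.
    """
    slabs = call_slabs(h3k4me3, slab_params)
    ir_calls = classify_ir(list(regions), rna, models, min_depth=min_depth)
    m_flags = [
        region_has_slab(slabs, c.intron.interval) for c in ir_calls
    ]
    ir_flags = [c.retained for c in ir_calls]
    contingency = assoc.contingency_table(m_flags, ir_flags)
    summaries = assoc.group_length_stats(ir_calls)
    return SurveyResult(
        contingency=contingency,
        summaries=summaries,
        calls=ir_calls,
        slabs=slabs,
        m_flags=m_flags,
        ir_flags=ir_flags,
        region_gene_ids=[c.intron.gene_id for c in ir_calls],
    )


def match_regions_to_introns(models: GeneModelSet, regions_df) -> List:
    """Resolve surveyed-region coordinates to non-overlapping intron records.

    ``regions_df`` needs chrom/start/end columns (e.g. the survey design
    table of a simulated fixture); regions that do not match a
    non-overlapping intron are dropped.
    """
    introns = derive_nonoverlapping_introns(models)
    by_coord = {
        (i.interval.chrom, i.interval.start, i.interval.end): i for i in introns
    }
    out = []
    for row in regions_df.itertuples():
        rec = by_coord.get((row.chrom, row.start, row.end))
        if rec is not None:
            out.append(rec)
    return out


def survey_bundle(bundle: StudyBundle, min_depth: float = 0.0) -> SurveyResult:
    params = SlabParams(threshold=slab_threshold_for_bundle(bundle))
    regions = match_regions_to_introns(bundle.models, bundle.truth.regions)
    return survey_regions(
        bundle.models,
        bundle.h3k4me3_track,
        bundle.rna_track,
        params,
        regions,
        min_depth=min_depth,
    )


def simulate_association_replicate(spec, seed: int) -> SurveyResult:
    """One seeded survey replicate: genome, histone track, RNA, then survey.

    Skips the total-nucleosome library, which the survey does not consume.
    """
    from .simulate import (
        simulate_gene_models,
        simulate_nucleosome_tags,
        simulate_rnaseq_coverage,
    )

    child = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child]
    models, truth = simulate_gene_models(spec, seeds[0])
    h3k_lib = simulate_nucleosome_tags(models, truth, spec, seeds[1], mark="h3k4me3")
    h3k = build_coverage(h3k_lib, models.chrom_sizes)
    rna = simulate_rnaseq_coverage(models, truth, spec, seeds[2])
    nonzero = np.concatenate([a[a > 0] for a in h3k.data.values()])
    threshold = 0.5 * spec.slab_signal_level * float(np.median(nonzero))
    regions = match_regions_to_introns(models, truth.regions)
    return survey_regions(
        models, h3k, rna, SlabParams(threshold=threshold), regions
    )


def slab_truth_jaccard(
    called: Sequence[SlabCall],
    truth: Sequence[GenomicInterval],
    chrom_sizes: Dict[str, int],
) -> float:
    """Base-level Jaccard index between called and true slab intervals."""
    inter = 0
    union = 0
    called_mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    truth_mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for call in called:
        iv = call.interval
        called_mask[iv.chrom][iv.start : iv.end] = True
    for iv in truth:
        truth_mask[iv.chrom][max(0, iv.start) : iv.end] = True
    for chrom in chrom_sizes:
        inter += int(np.sum(called_mask[chrom] & truth_mask[chrom]))
        union += int(np.sum(called_mask[chrom] | truth_mask[chrom]))
    if union == 0:
        return 1.0
    return inter / union


def ir_confusion(
    calls: Sequence[IRCall], truth_lookup: Dict[Tuple[str, int], bool]
) -> Dict[str, float]:
    """Sensitivity/specificity of retention calls against generator truth."""
    tp = fp = tn = fn = 0
    for call in calls:
        key = (call.intron.gene_id, call.intron.intron_index)
        if key not in truth_lookup:
            continue
        true = truth_lookup[key]
        if call.retained and true:
            tp += 1
        elif call.retained and not true:
            fp += 1
        elif not call.retained and not true:
            tn += 1
        else:
            fn += 1
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def truth_ir_lookup(bundle: StudyBundle) -> Dict[Tuple[str, int], bool]:
    return {
        (r.gene_id, r.intron_index): bool(r.ir_truth)
        for r in bundle.truth.introns.itertuples()
    }
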