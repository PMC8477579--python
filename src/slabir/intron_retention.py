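"""Intron retention calling from RNA-seq coverage.

A per-intron retention score compares mean intronic read depth against the
mean depth of the two adjacent exons:

    sir_ratio = intron / (intron + mean(upstream exon, downstream exon))

The score is bounded in [0, 1], scale-free, and positive exactly when the
intron shows any intronic coverage — the property the dichotomous
retained / non-retained classification rests on (retained iff
sir_ratio > 0, i.e. any level of retention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .core import ExonRecord, GeneModelSet, GenomicInterval, IntronRecord
from .coverage import CoverageTrack, MetaProfile, metagene_profile


@dataclass(frozen=True)
class IRCall:
    """Retention call for one intron."""

    intron: IntronRecord
    sir_ratio: float
    intron_depth: float
    flank_exon_depth: float
    retained: bool


def region_mean_depth(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Arithmetic mean of per-base track values over [start, end)."""
    values = track.region(interval)
    if values.size == 0:
        raise ValueError(f"empty interval {interval}")
    return float(values.mean())


def sir_ratio(
    rna: CoverageTrack,
    intron: IntronRecord,
    upstream_exon: ExonRecord,
    downstream_exon: ExonRecord,
) -> float:
    """Retention score of one intron against its two flanking exons.

    0 when the intron has no coverage; 1 when only the intron is covered.
    """
    i_depth = region_mean_depth(rna, intron.interval)
    if i_depth == 0:
        return 0.0
    e_depth = 0.5 * (
        region_mean_depth(rna, upstream_exon.interval)
        + region_mean_depth(rna, downstream_exon.interval)
    )
    return i_depth / (i_depth + e_depth)


def _flanking_exons(models: GeneModelSet, intron: IntronRecord):
    tx = models.by_transcript_id().get(intron.transcript_id)
    if tx is None or intron.intron_index >= tx.n_exons:
        return None
    records = {rec.exon_index: rec for rec in tx.exon_records()}
    return records[intron.intron_index], records[intron.intron_index + 1]


def classify_ir(
    introns: Sequence[IntronRecord],
    rna: CoverageTrack,
    models: GeneModelSet,
    min_depth: float = 0.0,
) -> List[IRCall]:
    """One retention call per intron; retained iff sir_ratio > 0.

    ``min_depth`` optionally requires the mean intronic depth to reach a
    floor before a positive score counts as retention (default 0 keeps the
    pure any-level-of-retention rule).  Introns whose flanking exons cannot
    be resolved are skipped with a warning.
    """
    tx_lookup = models.by_transcript_id()
    calls: List[IRCall] = []
    skipped = 0
    for intron in introns:
        tx = tx_lookup.get(intron.transcript_id)
        if tx is None or intron.intron_index >= tx.n_exons:
            skipped += 1
            continue
        flanks = _flanking_exons(models, intron)
        up_exon, down_exon = flanks
        i_depth = region_mean_depth(rna, intron.interval)
        e_depth = 0.5 * (
            region_mean_depth(rna, up_exon.interval)
            + region_mean_depth(rna, down_exon.interval)
        )
        ratio = 0.0 if i_depth == 0 else i_depth / (i_depth + e_depth)
        calls.append(
            IRCall(
                intron=intron,
                sir_ratio=ratio,
                intron_depth=i_depth,
                flank_exon_depth=e_depth,
                retained=ratio > 0 and i_depth >= min_depth,
            )
        )
    if skipped:
        warnings.warn(
            f"skipped {skipped} introns without resolvable flanking exons",
            stacklevel=2,
        )
    return calls


def profiles_by_intron_index(
    track: CoverageTrack,
    models: GeneModelSet,
    calls: Sequence[IRCall],
    indices: Iterable[int] = (1, 2, 3, 4, 5),
    retained_flag: bool = True,
    library_size: Optional[int] = None,
    flank: int = 500,
    edge: int = 80,
) -> Dict[int, MetaProfile]:
    """Downstream-side metagene profiles anchored on exon i, stratified by
    the retention class of intron i.

    For each ordinal i, the anchor set is exon i (in transcription
    direction) of every transcript whose intron i carries the requested
    retention flag.  Ordinals with no qualifying windows are omitted with a
    warning.
    """
    tx_lookup = models.by_transcript_id()
    by_index: Dict[int, List[ExonRecord]] = {}
    for call in calls:
        if call.retained != retained_flag:
            continue
        tx = tx_lookup.get(call.intron.transcript_id)
        if tx is None:
            continue
        i = call.intron.intron_index
        exon = next(
            rec for rec in tx.exon_records() if rec.exon_index == i
        )
        by_index.setdefault(i, []).append(exon)
    profiles: Dict[int, MetaProfile] = {}
    for i in indices:
        exons = by_index.get(i, [])
        if not exons:
            warnings.warn(
                f"no exons with a {'retained' if retained_flag else 'non-retained'}"
                f" intron at ordinal {i}",
                stacklevel=2,
            )
            continue
        try:
            profiles[i] = metagene_profile(
                track,
                exons,
                side="downstream",
                flank=flank,
                edge=edge,
                library_size=library_size,
            )
        except ValueError:
            warnings.warn(f"no admissible windows at ordinal {i}", stacklevel=2)
    return profiles


def calls_to_frame(calls: Sequence[IRCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [c.intron.gene_id for c in calls],
            "transcript_id": [c.intron.transcript_id for c in calls],
            "chrom": [c.intron.interval.chrom for c in calls],
            "start": [c.intron.interval.start for c in calls],
            "end": [c.intron.interval.end for c in calls],
            "strand": [c.intron.interval.strand for c in calls],
            "intron_index": [c.intron.intron_index for c in calls],
            "length": [c.intron.length for c in calls],
            "intron_depth": [c.intron_depth for c in calls],
            "flank_exon_depth": [c.flank_exon_depth for c in calls],
            "sir_ratio": [c.sir_ratio for c in calls],
            "retained": [c.retained for c in calls],
        }
    )
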