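"""Gene-model parsing and the exon/intron selections the profiles anchor on.

The analysis operates on internal exons (neither first nor last in their
transcript) and on non-overlapping introns: inter-exon gaps that do not
intersect any annotated exon of any transcript.  Several stratifications of
those sets are provided — isolation from neighbouring exons, leading-exon
removal, first-intron length classes, and a GC-content median split.
"""

from __future__ import annotations

import bisect
import warnings
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import gffutils

from .core import (
    ExonRecord,
    GeneModelSet,
    GenomicInterval,
    IntronRecord,
    Transcript,
)
from .io import PathLike, open_text

#: transcript_type / gene_type labels treated as lncRNA; everything else is
#: labelled "mRNA" (i.e. "all exons annotated in the genome except lncRNA").
DEFAULT_LNCRNA_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "3prime_overlapping_ncRNA",
        "bidirectional_promoter_lncRNA",
        "macro_lncRNA",
        "non_coding",
    }
)


class GTFParseError(ValueError):
    """Raised for a structurally malformed GTF line, naming the line number."""


def _validate_gtf_lines(path: PathLike) -> None:
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"{path}:{lineno}: invalid 1-based closed interval "
                    f"[{start}, {end}]"
                )
            if fields[6] not in ("+", "-", "."):
                raise GTFParseError(f"{path}:{lineno}: bad strand {fields[6]!r}")


def parse_gene_models(
    gtf_path: PathLike,
    lncrna_biotypes: Iterable[str] = DEFAULT_LNCRNA_BIOTYPES,
    chrom_sizes: Optional[dict] = None,
) -> GeneModelSet:
    """Parse exon features from a GENCODE-dialect GTF into a model set.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    A transcript is labelled ``lncRNA`` when its transcript_type (falling
    back to gene_type) is in ``lncrna_biotypes`` and ``mRNA`` otherwise.
    Transcripts with overlapping exons are rejected with a warning.
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(gtf_path)
    _validate_gtf_lines(gtf_path)
    lncrna_biotypes = frozenset(lncrna_biotypes)

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    grouped: dict = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        info = grouped.setdefault(
            tid,
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype_label": (
                    feat.attributes.get("transcript_type")
                    or feat.attributes.get("gene_type")
                    or ["unknown"]
                )[0],
                "exons": [],
            },
        )
        # gffutils keeps GTF 1-based closed; convert here.
        info["exons"].append((feat.start - 1, feat.end))

    transcripts: List[Transcript] = []
    for tid, info in grouped.items():
        exons = sorted(info["exons"])
        if any(exons[k + 1][0] < exons[k][1] for k in range(len(exons) - 1)):
            warnings.warn(
                f"transcript {tid} has overlapping exons; record rejected",
                stacklevel=2,
            )
            continue
        biotype = (
            "lncRNA" if info["biotype_label"] in lncrna_biotypes else "mRNA"
        )
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                biotype=biotype,
                exons=tuple(exons),
            )
        )
    transcripts.sort(key=lambda tx: (tx.chrom, tx.start, tx.transcript_id))
    return GeneModelSet(transcripts=transcripts, chrom_sizes=chrom_sizes or {})


def select_internal_exons(
    models: GeneModelSet, biotype: Optional[str] = None
) -> List[ExonRecord]:
    """Exons that are neither first nor last in their transcript.

    Coordinate-identical exons arising from multiple isoforms are collapsed
    to a single record (the first transcript encountered is retained), with
    the flanking-gap metadata of that transcript.
    """
    seen = set()
    out: List[ExonRecord] = []
    for tx in models.transcripts:
        if biotype is not None and tx.biotype != biotype:
            continue
        for rec in tx.exon_records():
            if not rec.is_internal:
                continue
            key = (rec.interval.chrom, rec.interval.start, rec.interval.end,
                   rec.interval.strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(rec)
    return out


def _merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def derive_nonoverlapping_introns(
    models: GeneModelSet, biotype: Optional[str] = None
) -> List[IntronRecord]:
    """Inter-exon gaps that overlap no annotated exon of any transcript.

    Candidate introns come from each transcript's consecutive exon pairs and
    keep that transcript's ordinal; candidates intersecting any exon of any
    transcript (any gene, either strand) are discarded, and coordinate-
    identical survivors are deduplicated.
    """
    exons_by_chrom = {
        chrom: _merge_intervals(ivs)
        for chrom, ivs in models.all_exon_intervals().items()
    }
    starts_by_chrom = {
        chrom: [s for s, _ in merged] for chrom, merged in exons_by_chrom.items()
    }

    def hits_exon(chrom: str, start: int, end: int) -> bool:
        merged = exons_by_chrom.get(chrom, [])
        idx = bisect.bisect_left(starts_by_chrom.get(chrom, []), end)
        # merged[idx - 1] is the last block starting before `end`
        return idx > 0 and merged[idx - 1][1] > start

    seen = set()
    out: List[IntronRecord] = []
    for tx in models.transcripts:
        if biotype is not None and tx.biotype != biotype:
            continue
        for rec in tx.intron_records():
            iv = rec.interval
            if hits_exon(iv.chrom, iv.start, iv.end):
                continue
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                continue
            seen.add(key)
            out.append(rec)
    return out


def filter_isolated_exons(
    exons: Iterable[ExonRecord], min_gap: int = 500
) -> List[ExonRecord]:
    """Keep exons separated from both neighbouring exons by >= ``min_gap`` bp."""
    return [
        e
        for e in exons
        if e.upstream_gap is not None
        and e.downstream_gap is not None
        and e.upstream_gap >= min_gap
        and e.downstream_gap >= min_gap
    ]


def drop_leading_exons(
    exons: Iterable[ExonRecord], k: int = 2
) -> List[ExonRecord]:
    """Remove exons with transcription-order ordinal <= ``k``."""
    return [e for e in exons if e.exon_index > k]


def partition_first_introns_by_length(
    introns: Iterable[IntronRecord], cutoff: int = 500
) -> Tuple[List[IntronRecord], List[IntronRecord]]:
    """Split first introns into (length < cutoff, length >= cutoff) groups.

    Ties at the cutoff go to the long group (the "at least" convention);
    non-first introns appear in neither group.
    """
    short = [i for i in introns if i.is_first and i.length < cutoff]
    long = [i for i in introns if i.is_first and i.length >= cutoff]
    return short, long


def gc_fraction(
    exons: Sequence[ExonRecord], genome_fasta: PathLike
) -> List[float]:
    """Per-exon G+C fraction of the genomic sequence under the exon."""
    from pyfaidx import Fasta

    fasta = Fasta(str(genome_fasta))
    values: List[float] = []
    for exon in exons:
        iv = exon.interval
        if iv.chrom not in fasta:
            raise ValueError(f"exon {iv} on chromosome absent from genome")
        seq = str(fasta[iv.chrom][iv.start : iv.end])
        if len(seq) < iv.length:
            raise ValueError(f"exon {iv} extends past end of genome sequence")
        gc = sum(1 for b in seq.upper() if b in "GC")
        values.append(gc / iv.length)
    return values


def partition_exons_by_gc(
    exons: Sequence[ExonRecord], genome_fasta: PathLike
) -> Tuple[List[ExonRecord], List[ExonRecord]]:
    """Split exons at the median GC fraction of the input set.

    Returns (below-median, at-or-above-median) collections.
    """
    import numpy as np

    exons = list(exons)
    if not exons:
        return [], []
    gc = gc_fraction(exons, genome_fasta)
    median = float(np.median(gc))
    low = [e for e, g in zip(exons, gc) if g < median]
    high = [e for e, g in zip(exons, gc) if g >= median]
    return low, high
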