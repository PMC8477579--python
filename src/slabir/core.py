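"""Core coordinate types shared by every stage of the pipeline.

All coordinates are 0-based half-open (BED convention).  GTF input/output
converts to and from 1-based closed coordinates at the file boundary only.
Exon and intron ordinals are 1-based and counted in transcription direction,
so ordinal 1 of a minus-strand transcript is the genomically rightmost
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_bp(other) >= min_overlap


@dataclass(frozen=True)
class ExonRecord:
    """An exon with its transcript context and flanking-gap metadata.

    ``upstream_gap``/``downstream_gap`` are the intron lengths immediately
    5' and 3' of the exon in transcription direction, or ``None`` for
    terminal exons.
    """

    interval: GenomicInterval
    gene_id: str
    transcript_id: str
    exon_index: int
    n_exons_in_transcript: int
    biotype: str
    upstream_gap: Optional[int] = None
    downstream_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.exon_index <= self.n_exons_in_transcript):
            raise ValueError(
                f"exon_index {self.exon_index} outside "
                f"1..{self.n_exons_in_transcript}"
            )
        for gap in (self.upstream_gap, self.downstream_gap):
            if gap is not None and gap < 0:
                raise ValueError("gaps must be >= 0 when present")

    @property
    def is_internal(self) -> bool:
        return 1 < self.exon_index < self.n_exons_in_transcript


@dataclass(frozen=True)
class IntronRecord:
    """An intron with its transcript context and 1-based ordinal."""

    interval: GenomicInterval
    gene_id: str
    transcript_id: str
    intron_index: int

    def __post_init__(self) -> None:
        if self.intron_index < 1:
            raise ValueError("intron_index must be >= 1")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def is_first(self) -> bool:
        return self.intron_index == 1


@dataclass(frozen=True)
class Transcript:
    """One transcript: ordered, non-overlapping exons on one chromosome.

    ``exons`` are (start, end) pairs sorted by genomic coordinate regardless
    of strand; transcription-direction ordinals are derived on demand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: tuple

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("transcript strand must be + or -")
        prev_end = -1
        for start, end in self.exons:
            if start < 0 or end <= start:
                raise ValueError(f"bad exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_tx_order(self) -> Sequence[tuple]:
        """Exon (start, end) pairs ordered 5'->3' in transcription direction."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def exon_records(self) -> Iterator[ExonRecord]:
        n = self.n_exons
        ordered = self.exons_tx_order()
        for i, (start, end) in enumerate(ordered, start=1):
            if self.strand == "+":
                up = start - ordered[i - 2][1] if i > 1 else None
                down = ordered[i][0] - end if i < n else None
            else:
                up = ordered[i - 2][0] - end if i > 1 else None
                down = start - ordered[i][1] if i < n else None
            yield ExonRecord(
                interval=GenomicInterval(self.chrom, start, end, self.strand),
                gene_id=self.gene_id,
                transcript_id=self.transcript_id,
                exon_index=i,
                n_exons_in_transcript=n,
                biotype=self.biotype,
                upstream_gap=up,
                downstream_gap=down,
            )

    def intron_records(self) -> Iterator[IntronRecord]:
        gaps = [
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(self.n_exons - 1)
            if self.exons[k + 1][0] > self.exons[k][1]
        ]
        if self.strand == "-":
            gaps = list(reversed(gaps))
        for i, (start, end) in enumerate(gaps, start=1):
            yield IntronRecord(
                interval=GenomicInterval(self.chrom, start, end, self.strand),
                gene_id=self.gene_id,
                transcript_id=self.transcript_id,
                intron_index=i,
            )


@dataclass
class GeneModelSet:
    """A collection of transcripts plus the chromosome-size table."""

    transcripts: list
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom_sizes:
            for tx in self.transcripts:
                size = self.chrom_sizes.get(tx.chrom)
                if size is not None and tx.end > size:
                    raise ValueError(
                        f"{tx.transcript_id} extends past end of {tx.chrom}"
                    )

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_transcript_id(self) -> Mapping[str, Transcript]:
        return {tx.transcript_id: tx for tx in self.transcripts}

    def subset(self, biotype: Optional[str] = None) -> "GeneModelSet":
        txs = [
            tx
            for tx in self.transcripts
            if biotype is None or tx.biotype == biotype
        ]
        return GeneModelSet(transcripts=txs, chrom_sizes=self.chrom_sizes)

    def all_exon_intervals(self) -> Mapping[str, list]:
        """Per-chromosome sorted list of (start, end) over all transcripts."""
        out: dict = {}
        for tx in self.transcripts:
            out.setdefault(tx.chrom, []).extend(tx.exons)
        for chrom in out:
            out[chrom].sort()
        return out


def mirror_models(models: GeneModelSet) -> GeneModelSet:
    """Reflect every transcript through its chromosome midpoint, flipping strand.

    Used by symmetry property tests: a genome-wide mirror must leave intron
    lengths, ordinal structure and all derived cardinalities unchanged.
    """
    txs = []
    for tx in models.transcripts:
        size = models.chrom_sizes[tx.chrom]
        exons = tuple(
            sorted((size - end, size - start) for start, end in tx.exons)
        )
        txs.append(
            replace(
                tx,
                strand="-" if tx.strand == "+" else "+",
                exons=exons,
            )
        )
    return GeneModelSet(transcripts=txs, chrom_sizes=dict(models.chrom_sizes))
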