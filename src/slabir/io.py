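"""Readers and writers for annotation-side text formats.

GTF is read through :mod:`gffutils`; the light-weight writers here emit the
GENCODE attribute dialect (gene_id, transcript_id, transcript_type) so a
written model set re-parses identically.  Coverage-track formats (bedGraph,
wiggle, BED6 tags) live in :mod:`slabir.coverage`.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Union

from .core import ExonRecord, GeneModelSet, GenomicInterval, IntronRecord

PathLike = Union[str, Path]


def open_text(path: PathLike, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz`` paths."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_chrom_sizes(path: PathLike) -> dict:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: dict = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_bed6(
    records: Iterable, path: PathLike, name_attr: str = "gene_id"
) -> None:
    """Write exon/intron records (or bare intervals) as BED6.

    The score column carries the feature ordinal when the record has one.
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                iv, name, score = rec, ".", 0
            elif isinstance(rec, ExonRecord):
                iv, name, score = rec.interval, getattr(rec, name_attr), rec.exon_index
            elif isinstance(rec, IntronRecord):
                iv, name, score = rec.interval, getattr(rec, name_attr), rec.intron_index
            else:
                raise TypeError(f"cannot write {type(rec).__name__} as BED6")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed(path: PathLike):
    """Read a BED file into (intervals, names); name defaults to 'regionN'."""
    intervals, names = [], []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
            names.append(fields[3] if len(fields) >= 4 else f"region{lineno}")
    return intervals, names


def write_gtf(models: GeneModelSet, path: PathLike, source: str = "slabir") -> None:
    """Write exon features of a model set as GENCODE-dialect GTF.

    Coordinates convert from the internal 0-based half-open convention to
    GTF's 1-based closed convention.
    """
    with open(path, "w") as fh:
        for tx in models.transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_type "{tx.biotype}"; transcript_type "{tx.biotype}";'
            )
            fh.write(
                f"{tx.chrom}\t{source}\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}\n"
            )
            for start, end in tx.exons:
                fh.write(
                    f"{tx.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
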