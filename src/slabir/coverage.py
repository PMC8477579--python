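"""Per-base coverage tracks and exon-anchored metagene density profiles.

Sequencing tags (MNase or ChIP fragments sequenced from one end) are
extended to the expected 150 bp fragment length in the 3' direction before
coverage is accumulated, because plus- and minus-strand reads from the same
nucleosome start ~150 bp apart.  Profiles average the track over windows
spanning 500 bp of flanking intron plus the first (or last) 80 bp of each
exon — 580 positions per side — and are normalized by the number of exon
windows polled and by library depth (counts per million tags).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import ExonRecord, GenomicInterval
from .io import PathLike, open_text

FLANK = 500
EDGE = 80
TAG_EXTENSION = 150


@dataclass(frozen=True)
class TagRecord:
    """One sequenced tag: a stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"tag start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError("tag strand must be + or -")


@dataclass
class TagLibrary:
    """A tag collection with its depth (total tag count)."""

    tags: List[TagRecord]
    source: str = ""

    @property
    def total_tags(self) -> int:
        return len(self.tags)


class CoverageTrack:
    """Per-chromosome per-base non-negative signal arrays."""

    def __init__(self, data: Dict[str, np.ndarray]):
        self.data = {chrom: np.asarray(arr, dtype=float) for chrom, arr in data.items()}
        for chrom, arr in self.data.items():
            if arr.ndim != 1:
                raise ValueError(f"track for {chrom} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"track for {chrom} has negative values")

    @classmethod
    def zeros(cls, chrom_sizes: Dict[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n) for c, n in chrom_sizes.items()})

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def region(self, interval: GenomicInterval) -> np.ndarray:
        arr = self.data[interval.chrom]
        if interval.end > len(arr):
            raise ValueError(f"{interval} outside chromosome of length {len(arr)}")
        return arr[interval.start : interval.end]

    def mass(self) -> float:
        """Total signal: the sum of all per-base values."""
        return float(sum(a.sum() for a in self.data.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack({c: a * factor for c, a in self.data.items()})


# ---------------------------------------------------------------------------
# tag input and coverage construction
# ---------------------------------------------------------------------------


def load_tags(path: PathLike, dialect: str = "BED6") -> TagLibrary:
    """Load a BED6 or tagAlign tag file (plain or gzipped).

    The two dialects are column-compatible (tagAlign carries the read
    sequence where BED carries a name); both must provide a strand in
    column 6.  An empty file or a record without a strand is an error.
    """
    if dialect not in ("BED6", "tagAlign"):
        raise ValueError(f"unknown tag dialect {dialect!r}")
    tags: List[TagRecord] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: tag record needs 6 columns (no strand?)"
                )
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing or bad strand {strand!r}")
            tags.append(
                TagRecord(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    if not tags:
        raise ValueError(f"{path}: no tag records")
    return TagLibrary(tags=tags, source=str(path))


def write_tags(library: TagLibrary, path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(library.tags):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\ttag{i}\t0\t{t.strand}\n")


def extend_tag(
    tag: TagRecord, length: int = TAG_EXTENSION, chrom_len: Optional[int] = None
) -> GenomicInterval:
    """Extend a tag to ``length`` bp in its 3' direction, clipped to the chromosome.

    Plus-strand tags anchor at their start and extend rightward; minus-strand
    tags anchor at their end and extend leftward.
    """
    if tag.strand == "+":
        start, end = tag.start, tag.start + length
    else:
        start, end = tag.end - length, tag.end
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return GenomicInterval(tag.chrom, start, end, tag.strand)


def build_coverage(
    library: TagLibrary,
    chrom_sizes: Dict[str, int],
    extension: int = TAG_EXTENSION,
) -> CoverageTrack:
    """Per-base count of extended tag intervals covering each position."""
    starts: Dict[str, list] = {c: [] for c in chrom_sizes}
    ends: Dict[str, list] = {c: [] for c in chrom_sizes}
    dropped = 0
    for tag in library.tags:
        size = chrom_sizes.get(tag.chrom)
        if size is None:
            dropped += 1
            continue
        iv = extend_tag(tag, extension, size)
        starts[tag.chrom].append(iv.start)
        ends[tag.chrom].append(iv.end)
    if dropped:
        warnings.warn(
            f"dropped {dropped} tags on chromosomes absent from chrom_sizes",
            stacklevel=2,
        )
    data = {}
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1)
        if starts[chrom]:
            np.add.at(diff, np.asarray(starts[chrom]), 1.0)
            np.add.at(diff, np.asarray(ends[chrom]), -1.0)
        data[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(data)


# ---------------------------------------------------------------------------
# track text formats
# ---------------------------------------------------------------------------


def load_bedgraph(path: PathLike, chrom_sizes: Dict[str, int]) -> CoverageTrack:
    """Load a bedGraph (0-based half-open) into per-base arrays.

    Overlapping intervals make the per-base value ambiguous and are an error.
    Uncovered bases are zero.
    """
    intervals: Dict[str, list] = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise ValueError(f"{path}:{lineno}: interval out of bounds")
            intervals.setdefault(chrom, []).append((start, end, value))
    track = CoverageTrack.zeros(chrom_sizes)
    for chrom, ivs in intervals.items():
        ivs.sort()
        prev_end = 0
        arr = track.data[chrom]
        for start, end, value in ivs:
            if start < prev_end:
                raise ValueError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {start}"
                )
            arr[start:end] = value
            prev_end = end
    return track


def _runs(arr: np.ndarray) -> Iterable[Tuple[int, int, float]]:
    """Yield (start, end, value) runs of constant value, skipping zero runs."""
    if len(arr) == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate(([0], change, [len(arr)]))
    for i in range(len(bounds) - 1):
        start, end = int(bounds[i]), int(bounds[i + 1])
        value = float(arr[start])
        if value != 0.0:
            yield start, end, value


def write_track(track: CoverageTrack, path: PathLike, dialect: str = "bedGraph") -> None:
    """Write a track as run-length-encoded bedGraph or fixed-step wiggle.

    Zero runs are omitted; values are formatted to 6 significant digits.
    """
    if dialect not in ("bedGraph", "wiggle"):
        raise ValueError(f"unknown track dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "wiggle":
            fh.write("track type=wiggle_0\n")
        for chrom in track.data:
            for start, end, value in _runs(track.data[chrom]):
                if dialect == "bedGraph":
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")
                else:
                    fh.write(f"fixedStep chrom={chrom} start={start + 1} step=1 span=1\n")
                    fh.writelines(f"{value:.6g}\n" for _ in range(end - start))


def load_wiggle(path: PathLike, chrom_sizes: Dict[str, int]) -> CoverageTrack:
    """Load a fixedStep (step=1) or variableStep wiggle file."""
    track = CoverageTrack.zeros(chrom_sizes)
    chrom = None
    pos = 0
    mode = None
    span = 1
    with open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                parts = dict(p.split("=") for p in line.split()[1:])
                chrom = parts["chrom"]
                span = int(parts.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    pos = int(parts["start"]) - 1
                    if int(parts.get("step", 1)) != 1:
                        raise ValueError("only step=1 fixedStep wiggle is supported")
                else:
                    mode = "variable"
                continue
            if chrom is None:
                raise ValueError(f"{path}: data line before wiggle header")
            arr = track.data[chrom]
            if mode == "fixed":
                arr[pos : pos + span] = float(line)
                pos += span
            else:
                p, v = line.split()
                start = int(p) - 1
                arr[start : start + span] = float(v)
    return track


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetaProfile:
    """A normalized exon-anchored density series.

    ``values`` holds flank+edge positions ordered 5'->3' in transcription
    direction: for the upstream side, 500 intronic positions then the first
    80 bp of the exon; for the downstream side, the last 80 bp of the exon
    then 500 intronic positions.  Units are mean tags-per-million-library-
    tags per window.
    """

    side: str
    values: np.ndarray
    n_windows: int
    library_size: int
    flank: int = FLANK
    edge: int = EDGE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.side not in ("upstream", "downstream"):
            raise ValueError("side must be 'upstream' or 'downstream'")
        if len(self.values) != self.flank + self.edge:
            raise ValueError("profile length must equal flank + edge")
        if self.n_windows <= 0:
            raise ValueError("n_windows must be positive")

    def positions(self) -> np.ndarray:
        """Signed positions: negative = intronic upstream / exonic before the
        3' edge, matching the figure axis convention."""
        if self.side == "upstream":
            return np.concatenate(
                [np.arange(-self.flank, 0), np.arange(1, self.edge + 1)]
            )
        return np.concatenate(
            [np.arange(-self.edge, 0), np.arange(1, self.flank + 1)]
        )

    def exonic(self) -> np.ndarray:
        return (
            self.values[self.flank :]
            if self.side == "upstream"
            else self.values[: self.edge]
        )

    def intronic(self) -> np.ndarray:
        return (
            self.values[: self.flank]
            if self.side == "upstream"
            else self.values[self.edge :]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "side": self.side,
                "position": self.positions(),
                "density": self.values,
                "n_windows": self.n_windows,
            }
        )


def anchor_window(
    exon: ExonRecord,
    side: str,
    flank: int = FLANK,
    edge: int = EDGE,
    chrom_len: Optional[int] = None,
) -> Optional[np.ndarray]:
    """Genomic positions of one side's window, ordered in transcription direction.

    Returns ``None`` (exclusion, not failure) when the exon is shorter than
    ``edge`` or the window would leave the chromosome.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    iv = exon.interval
    if iv.length < edge:
        return None
    plus = iv.strand != "-"
    # The 5' boundary of the exon is iv.start on plus, iv.end on minus.
    if (side == "upstream") == plus:
        # window at the genomic-left exon boundary
        intron = np.arange(iv.start - flank, iv.start)
        exonic = np.arange(iv.start, iv.start + edge)
        lo, hi = iv.start - flank, iv.start + edge
    else:
        intron = np.arange(iv.end, iv.end + flank)
        exonic = np.arange(iv.end - edge, iv.end)
        lo, hi = iv.end - edge, iv.end + flank
    if lo < 0 or (chrom_len is not None and hi > chrom_len):
        return None
    if not plus:
        # traverse each segment 5'->3' on the minus strand
        intron = intron[::-1]
        exonic = exonic[::-1]
    if side == "upstream":
        return np.concatenate([intron, exonic])
    return np.concatenate([exonic, intron])


def metagene_profile(
    track: CoverageTrack,
    exons: Sequence[ExonRecord],
    side: str,
    flank: int = FLANK,
    edge: int = EDGE,
    library_size: Optional[int] = None,
) -> MetaProfile:
    """Average track density over one side's windows of an exon set.

    values[i] = sum over admissible windows of the track value at the
    window's i-th position, divided by the number of windows and by
    library depth in millions.
    """
    if library_size is None or library_size <= 0:
        raise ValueError("library_size (total tags) must be a positive count")
    sums = np.zeros(flank + edge)
    n_windows = 0
    sizes = track.chrom_sizes
    for exon in exons:
        chrom = exon.interval.chrom
        if chrom not in sizes:
            continue
        window = anchor_window(exon, side, flank, edge, chrom_len=sizes[chrom])
        if window is None:
            continue
        sums += track.data[chrom][window]
        n_windows += 1
    if n_windows == 0:
        raise ValueError(f"no admissible exon windows on side {side!r}")
    values = sums / n_windows / (library_size / 1e6)
    return MetaProfile(
        side=side,
        values=values,
        n_windows=n_windows,
        library_size=library_size,
        flank=flank,
        edge=edge,
    )


def exon_enrichment(up: MetaProfile, down: MetaProfile) -> float:
    """Percent excess of mean exonic density over mean intronic density.

    Pools the 2 x 80 exon-edge positions against the 2 x 500 intronic
    positions of the paired upstream/downstream profiles.
    """
    exonic = np.concatenate([up.exonic(), down.exonic()])
    intronic = np.concatenate([up.intronic(), down.intronic()])
    intron_mean = float(intronic.mean())
    if intron_mean == 0:
        raise ValueError("intronic mean density is zero; enrichment undefined")
    return 100.0 * (float(exonic.mean()) / intron_mean - 1.0)


def write_profiles_tsv(profiles: Iterable[MetaProfile], path: PathLike) -> None:
    import pandas as pd

    frames = [p.to_frame() for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
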