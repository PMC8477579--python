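"""Shared builders for compact genomic fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from slabir.core import GeneModelSet, Transcript
from slabir.coverage import CoverageTrack


def make_transcript(
    exons,
    strand="+",
    chrom="chr1",
    tid="T1",
    gid="G1",
    biotype="lncRNA",
):
    return Transcript(
        transcript_id=tid,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        biotype=biotype,
        exons=tuple(tuple(e) for e in exons),
    )


def make_models(transcripts, chrom_sizes=None):
    return GeneModelSet(
        transcripts=list(transcripts),
        chrom_sizes=chrom_sizes or {"chr1": 1_000_000},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def uniform_track():
    """A constant-value track on one 100 kb chromosome."""

    def _make(value=2.0, length=100_000, chrom="chr1"):
        return CoverageTrack({chrom: np.full(length, float(value))})

    return _make
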