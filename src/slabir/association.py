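"""Slab x intron-retention contingency analysis.

Builds the 2x2 table of slab presence (M) against intron retention (IR)
over a set of surveyed intronic regions, tests independence with Pearson's
chi-squared statistic (no continuity correction: the uncorrected statistic
is what the headline p-value of this analysis corresponds to), and
summarizes intron lengths and first-intron frequencies per IR class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intron_retention import IRCall


@dataclass(frozen=True)
class ContingencyResult:
    """The M x IR 2x2 table with its test statistics.

    Cell naming: m/a = slab present/absent, irp/ira = retention
    present/absent.  Concordance is the fraction of regions where the two
    flags agree.
    """

    n_mp_irp: int
    n_mp_ira: int
    n_ma_irp: int
    n_ma_ira: int
    chi2: float
    p_value: float
    concordance: float

    @property
    def n_total(self) -> int:
        return self.n_mp_irp + self.n_mp_ira + self.n_ma_irp + self.n_ma_ira

    @property
    def cells(self) -> Tuple[int, int, int, int]:
        return (self.n_mp_irp, self.n_mp_ira, self.n_ma_irp, self.n_ma_ira)

    @property
    def ir_prevalence(self) -> float:
        """Fraction of surveyed regions with intron retention."""
        return (self.n_mp_irp + self.n_ma_irp) / self.n_total


@dataclass(frozen=True)
class GroupSummary:
    """Length and first-intron summary for one IR class."""

    group: str
    n: int
    median_length: float
    mean_length: float
    se_length: float
    n_first: int

    @property
    def first_fraction(self) -> float:
        return self.n_first / self.n


def pearson_chi2(cells: Sequence[int]) -> Tuple[float, float]:
    """Pearson chi-squared test of independence for a 2x2 table.

    ``cells`` are (a, b, c, d) in row-major order.  No continuity
    correction is applied; the p-value is the upper tail of chi-squared
    with 1 degree of freedom.  Zero row or column margins leave the test
    undefined and raise.
    """
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("chi-squared test undefined: zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=False
    )
    return float(chi2), float(p)


def contingency_table(
    m_flags: Sequence[bool], ir_flags: Sequence[bool]
) -> ContingencyResult:
    """Count the four M x IR cells and test independence."""
    if len(m_flags) != len(ir_flags):
        raise ValueError(
            f"flag sequences differ in length: {len(m_flags)} vs {len(ir_flags)}"
        )
    if len(m_flags) == 0:
        raise ValueError("empty flag sequences")
    m = np.asarray(m_flags, dtype=bool)
    ir = np.asarray(ir_flags, dtype=bool)
    cells = (
        int(np.sum(m & ir)),
        int(np.sum(m & ~ir)),
        int(np.sum(~m & ir)),
        int(np.sum(~m & ~ir)),
    )
    chi2, p = pearson_chi2(cells)
    concordance = (cells[0] + cells[3]) / len(m)
    return ContingencyResult(*cells, chi2=chi2, p_value=p, concordance=concordance)


def _summarize(group: str, lengths: np.ndarray, n_first: int) -> GroupSummary:
    n = len(lengths)
    # sample sd / sqrt(n); a single observation has no spread
    se = float(lengths.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(
        group=group,
        n=n,
        median_length=float(np.median(lengths)),
        mean_length=float(lengths.mean()),
        se_length=se,
        n_first=n_first,
    )


def group_length_stats(calls: Sequence[IRCall]) -> Dict[str, GroupSummary]:
    """Median/mean/SE intron length and first-intron counts per IR class.

    Returns a mapping with keys 'IR present' and 'IR absent'; empty classes
    are omitted with a warning.
    """
    import warnings

    out: Dict[str, GroupSummary] = {}
    for group, flag in (("IR present", True), ("IR absent", False)):
        members = [c for c in calls if c.retained == flag]
        if not members:
            warnings.warn(f"no introns in class {group!r}; summary omitted",
                          stacklevel=2)
            continue
        lengths = np.array([c.intron.length for c in members], dtype=float)
        n_first = sum(1 for c in members if c.intron.is_first)
        out[group] = _summarize(group, lengths, n_first)
    return out


def first_intron_frequency(calls: Sequence[IRCall]) -> Dict[str, float]:
    """Per IR class, the fraction of its introns that are first introns."""
    summaries = group_length_stats(calls)
    return {group: s.first_fraction for group, s in summaries.items()}


def format_report(
    result: ContingencyResult,
    summaries: Optional[Dict[str, GroupSummary]] = None,
) -> str:
    """Human-readable report mirroring the contingency-table layout."""
    lines = [
        "Slab (M) x intron retention (IR) contingency",
        f"{'':12s}{'IR present':>12s}{'IR absent':>12s}",
        f"{'M present':12s}{result.n_mp_irp:>12d}{result.n_mp_ira:>12d}",
        f"{'M absent':12s}{result.n_ma_irp:>12d}{result.n_ma_ira:>12d}",
        f"n = {result.n_total}",
        f"chi-squared = {result.chi2:.4f} (1 df, no continuity correction)",
        f"p-value = {result.p_value:.0e}",
        f"concordance = {100 * result.concordance:.1f}%",
        f"IR prevalence = {100 * result.ir_prevalence:.1f}%",
    ]
    if summaries:
        for group, s in summaries.items():
            lines.append(
                f"{group}: n={s.n}, median length={s.median_length:.0f} bp, "
                f"mean={s.mean_length:.0f} +/- {s.se_length:.0f} bp, "
                f"first introns={s.n_first} ({100 * s.first_fraction:.0f}%)"
            )
    return "\n".join(lines)


def result_to_dict(
    result: ContingencyResult,
    summaries: Optional[Dict[str, GroupSummary]] = None,
) -> dict:
    out = {
        "cells": {
            "m_present_ir_present": result.n_mp_irp,
            "m_present_ir_absent": result.n_mp_ira,
            "m_absent_ir_present": result.n_ma_irp,
            "m_absent_ir_absent": result.n_ma_ira,
        },
        "n_total": result.n_total,
        "chi2": result.chi2,
        "p_value": result.p_value,
        "concordance": result.concordance,
        "ir_prevalence": result.ir_prevalence,
    }
    if summaries:
        out["groups"] = {
            group: {
                "n": s.n,
                "median_length": s.median_length,
                "mean_length": s.mean_length,
                "se_length": s.se_length,
                "n_first": s.n_first,
                "first_fraction": s.first_fraction,
            }
            for group, s in summaries.items()
        }
    return out
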