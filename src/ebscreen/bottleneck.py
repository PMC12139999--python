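"""Clonal-complexity and guide-representation diagnostics.

Quantifies the clonal bottleneck observed in individually picked mosaic
EBs: after UMI deduplication of amplicon reads, per-EB guide abundances
are summarised by the number of distinct guides, the cumulative abundance
curve over ranked guides, and the "dominance" count — the minimal number
of top guides covering a fraction (default 90%) of the reads.  Jackpotted
EBs show dominance counts of 2-10 despite hundreds of founders.  Guide
frequencies can also be compared against a reference (e.g. plasmid)
library as per-guide log2 fold changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClonalComplexityReport",
    "dedup_reads_by_umi",
    "clonal_complexity",
    "guide_log2fc",
]

_UMI_RE = re.compile(r"^[ACGT]+$")


def dedup_reads_by_umi(read_table: pd.DataFrame) -> tuple[pd.Series, int]:
    """Collapse amplicon reads to distinct (UMI, guide) pairs.

    ``read_table`` has columns ``umi`` and ``guide_id``.  The
    deduplicated count of a guide is its number of distinct UMIs; the
    same UMI seen with different guides counts once per guide.  Records
    with malformed UMIs (non-ACGT, or length differing from the first
    valid record) are skipped; the skip count is returned alongside.
    """
    umis = read_table["umi"].astype(str)
    valid = umis.str.match(_UMI_RE)
    if valid.any():
        length = len(umis[valid].iloc[0])
        valid &= umis.str.len() == length
    n_skipped = int((~valid).sum())
    dedup = read_table.loc[valid, ["umi", "guide_id"]].drop_duplicates()
    counts = dedup.groupby("guide_id").size().sort_index()
    return counts, n_skipped


@dataclass
class ClonalComplexityReport:
    n_distinct: int
    dominance: int                 # minimal top guides covering `fraction`
    fraction: float
    cumulative: pd.Series          # rank (1-based) -> cumulative share
    top_to_median_ratio: float

    def __post_init__(self) -> None:
        assert 1 <= self.dominance <= self.n_distinct


def clonal_complexity(counts: pd.Series, f: float = 0.9) -> ClonalComplexityReport:
    """Summarise one EB's per-guide counts. Ties break by guide id."""
    counts = counts[counts > 0]
    if len(counts) == 0:
        raise ValueError("all counts are zero")
    if not 0 < f <= 1:
        raise ValueError("coverage fraction must lie in (0, 1]")
    ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
    shares = ordered / ordered.sum()
    cumulative = shares.cumsum()
    cumulative.index = pd.RangeIndex(1, len(cumulative) + 1, name="rank")
    dominance = int(np.argmax(cumulative.to_numpy() >= f - 1e-12) + 1)
    return ClonalComplexityReport(
        n_distinct=len(ordered),
        dominance=dominance,
        fraction=f,
        cumulative=cumulative,
        top_to_median_ratio=float(ordered.iloc[0] / np.median(ordered)),
    )


def guide_log2fc(
    sample_counts: pd.Series,
    ref_counts: pd.Series,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-guide log2 fold change of sample vs reference frequencies.

    Both series are raw counts over the same guide universe; a small
    pseudocount added before renormalisation keeps guides that dropped
    out of the sample finite (strongly negative).
    """
    diff = set(sample_counts.index) ^ set(ref_counts.index)
    if diff:
        raise ValueError(f"guide universes differ: {sorted(diff)[:10]}")
    s = sample_counts.sort_index().astype(float) + pseudocount
    r = ref_counts.sort_index().astype(float) + pseudocount
    return pd.Series(
        np.log2(s / s.sum()) - np.log2(r / r.sum()),
        index=s.index,
        name="log2fc",
    )
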