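"""Per-cell gRNA assignment from UMI and read counts.

Two empirically derived threshold rules are supported, named after the
screens they were tuned on:

``pilot``   assign a guide to a cell iff log2(UMI + 1) >= 2 and
            log2(reads + 1) >= 5.
``alltf``   assign iff log2(UMI + 1) >= 2 and
            log2(UMI + 1) < 1.25 * log2(reads + 1) - 5.

All logarithms are base 2; comparisons are inclusive/strict exactly as
written.  Multi-guide cells are resolved by policy: the strict pilot
policy keeps only single-guide cells, while the permissive policy drops
NTC guides from mixed TF/NTC cells and retains multiple TF guides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_qc import CountsTriplet

__all__ = [
    "GuideCallTable",
    "assign_guides",
    "resolve_multi_guides",
    "filter_guides_prevalence",
]

STATUS_UNIQUE = "unique_tf"
STATUS_MULTI = "multi_tf"
STATUS_NTC = "ntc"
STATUS_UNASSIGNED = "unassigned"


@dataclass
class GuideCallTable:
    """Per-cell guide calls: ``calls`` maps cell_id -> sorted guide tuple."""

    table: pd.DataFrame  # cell_id, guide_ids (tuple), status
    rule: str

    def status_counts(self) -> pd.Series:
        return self.table["status"].value_counts()

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out["guide_ids"] = [",".join(g) for g in out["guide_ids"]]
        out.to_csv(path, sep="\t", index=False)


def _classify(guides: tuple[str, ...], ntc_guides: set[str]) -> str:
    if not guides:
        return STATUS_UNASSIGNED
    tf = [g for g in guides if g not in ntc_guides]
    if not tf:
        return STATUS_NTC
    return STATUS_UNIQUE if len(tf) == 1 and len(guides) == 1 else STATUS_MULTI


def assign_guides(
    counts: CountsTriplet,
    rule: str,
    ntc_guides: Iterable[str] = (),
) -> GuideCallTable:
    """Threshold-based guide assignment (pre multi-guide resolution)."""
    if rule not in ("pilot", "alltf"):
        raise ValueError(f"unknown rule {rule!r}")
    gv = counts.class_view("guide")
    if gv.reads is None:
        raise ValueError("guide features need both UMI and read counts")
    umi = gv.umi.toarray().astype(float)
    reads = gv.reads.toarray().astype(float)
    if umi.min() < 0 or reads.min() < 0:
        raise ValueError("negative counts")

    lu = np.log2(umi + 1.0)
    lr = np.log2(reads + 1.0)
    if rule == "pilot":
        mask = (lu >= 2.0) & (lr >= 5.0)
    else:
        mask = (lu >= 2.0) & (lu < 1.25 * lr - 5.0)

    guide_ids = gv.features["feature_id"].to_numpy(object)
    ntc = set(ntc_guides)
    rows = []
    for i, cell in enumerate(counts.cell_ids):
        assigned = tuple(sorted(guide_ids[mask[i]]))
        rows.append((cell, assigned, _classify(assigned, ntc)))
    return GuideCallTable(
        table=pd.DataFrame(rows, columns=["cell_id", "guide_ids", "status"]),
        rule=rule,
    )


def resolve_multi_guides(
    calls: GuideCallTable,
    policy: str,
    ntc_guides: Iterable[str] = (),
) -> GuideCallTable:
    """Resolve cells that carry several assigned guides.

    ``pilot_strict``: any cell with other than exactly one guide becomes
    unassigned.  ``alltf_keep``: NTC guides are dropped from cells that
    also carry a TF guide; multiple TF guides are all retained; cells
    whose guides are all NTC stay NTC.
    """
    if policy not in ("pilot_strict", "alltf_keep"):
        raise ValueError(f"unknown policy {policy!r}")
    ntc = set(ntc_guides)
    rows = []
    for cell, guides, _ in calls.table.itertuples(index=False):
        if policy == "pilot_strict":
            kept = guides if len(guides) == 1 else ()
        else:
            tf = tuple(g for g in guides if g not in ntc)
            kept = tf if tf else guides
        rows.append((cell, kept, _classify(kept, ntc)))
    return GuideCallTable(
        table=pd.DataFrame(rows, columns=["cell_id", "guide_ids", "status"]),
        rule=calls.rule,
    )


def filter_guides_prevalence(
    counts: CountsTriplet, min_cell_fraction: float = 0.01
) -> CountsTriplet:
    """Drop guide features expressed in fewer than a fraction of cells.

    Guides whose nonzero-UMI prevalence is below ``min_cell_fraction``
    likely derive from floating cells in the medium rather than the
    profiled aggregates; features of other classes are untouched.
    """
    if not 0.0 <= min_cell_fraction < 1.0:
        raise ValueError("min_cell_fraction must lie in [0, 1)")
    is_guide = counts.feature_mask("guide")
    prevalence = np.asarray((counts.umi > 0).sum(axis=0)).ravel()
    keep = ~is_guide | (prevalence >= min_cell_fraction * counts.n_cells)
    return counts.subset_features(keep)
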