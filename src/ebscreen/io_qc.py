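"""Sparse count containers, 10x-triplet I/O, lookup tables and per-cell QC.

The universal input for the screen analyses is a cells-by-features sparse
count matrix in MatrixMarket triplet form (``matrix.mtx`` + ``barcodes.tsv``
+ ``features.tsv``), where features are tagged with a class: ordinary
``gene`` expression features, directly captured CRISPR ``guide`` features,
or expressed clonal ``organoid_bc`` (organoid barcode) features.  Guide and
organoid-BC features carry a parallel *read*-count matrix in addition to the
UMI matrix, because the assignment rules threshold on both.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FEATURE_CLASSES = ("gene", "guide", "organoid_bc")

QC_COLUMNS = {
    "min_umi": "total_umi",
    "top_umi_quantile": "total_umi",
    "max_umi": "total_umi",
    "max_doublet": "doublet_score",
    "max_mt": "pct_mt",
    "max_ribo": "pct_ribo",
}


@dataclass
class CountsTriplet:
    """Cells x features UMI counts, with read counts for guide/BC features.

    Attributes
    ----------
    cell_ids : array of str, one per row.
    features : DataFrame with columns ``feature_id`` and ``feature_class``
        (one of ``gene``, ``guide``, ``organoid_bc``), one row per column
        of the matrices.
    umi : CSR matrix of UMI counts (cells x features).
    reads : CSR matrix of read counts, or None.  Where present, entries are
        meaningful for guide and organoid-BC features and satisfy
        ``reads >= umi`` entrywise.
    """

    cell_ids: np.ndarray
    features: pd.DataFrame
    umi: sp.csr_matrix
    reads: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.umi = sp.csr_matrix(self.umi)
        if self.reads is not None:
            self.reads = sp.csr_matrix(self.reads)
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.umi.shape[0]

    @property
    def n_features(self) -> int:
        return self.umi.shape[1]

    def validate(self) -> None:
        if self.features.shape[0] != self.umi.shape[1]:
            raise ValueError("feature table and UMI matrix disagree on feature count")
        if len(self.cell_ids) != self.umi.shape[0]:
            raise ValueError("cell_ids and UMI matrix disagree on cell count")
        unknown = set(self.features["feature_class"]) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.umi.nnz and self.umi.data.min() < 0:
            raise ValueError("negative UMI counts")
        if self.reads is not None:
            if self.reads.shape != self.umi.shape:
                raise ValueError("reads and UMI matrices differ in shape")
            diff = self.reads - self.umi
            if diff.nnz and diff.data.min() < 0:
                raise ValueError("read count < UMI count for some entry")

    def feature_mask(self, feature_class: str) -> np.ndarray:
        return (self.features["feature_class"] == feature_class).to_numpy()

    def class_view(self, feature_class: str) -> "CountsTriplet":
        """Restrict to one feature class (matrices are sliced, not copied deep)."""
        return self.subset_features(self.feature_mask(feature_class))

    def subset_features(self, mask: np.ndarray) -> "CountsTriplet":
        mask = np.asarray(mask)
        return CountsTriplet(
            cell_ids=self.cell_ids,
            features=self.features.loc[mask].reset_index(drop=True),
            umi=self.umi[:, mask],
            reads=None if self.reads is None else self.reads[:, mask],
        )

    def subset_cells(self, mask: np.ndarray) -> "CountsTriplet":
        mask = np.asarray(mask)
        return CountsTriplet(
            cell_ids=self.cell_ids[mask],
            features=self.features,
            umi=self.umi[mask],
            reads=None if self.reads is None else self.reads[mask],
        )


# ---------------------------------------------------------------------------
# MatrixMarket triplet I/O
# ---------------------------------------------------------------------------

def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(directory: str, name: str) -> str:
    """Return the plain or gzipped variant of ``name`` inside ``directory``."""
    for candidate in (name, name + ".gz"):
        path = os.path.join(directory, candidate)
        if os.path.exists(path):
            return path
    raise FileNotFoundError(f"{name}[.gz] not found in {directory}")


def write_counts_triplet(counts: CountsTriplet, directory: str) -> None:
    """Write ``matrix.mtx`` / ``reads.mtx`` / ``barcodes.tsv`` / ``features.tsv``.

    MatrixMarket coordinate files are 1-based on disk (the format's
    convention); everything in memory stays 0-based.
    """
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), counts.umi.tocoo())
    if counts.reads is not None:
        scipy.io.mmwrite(os.path.join(directory, "reads.mtx"), counts.reads.tocoo())
    pd.Series(counts.cell_ids).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    counts.features.to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )


def read_counts_triplet(directory: str) -> CountsTriplet:
    """Read a triplet directory written by :func:`write_counts_triplet`.

    Gzipped variants of each member file are accepted transparently.
    """
    with _open_text(_find(directory, "matrix.mtx"), "rb") as fh:
        umi = sp.csr_matrix(scipy.io.mmread(fh))
    reads = None
    try:
        with _open_text(_find(directory, "reads.mtx"), "rb") as fh:
            reads = sp.csr_matrix(scipy.io.mmread(fh))
    except FileNotFoundError:
        pass
    cell_ids = pd.read_csv(
        _find(directory, "barcodes.tsv"), sep="\t", header=None
    )[0].to_numpy(dtype=object)
    features = pd.read_csv(
        _find(directory, "features.tsv"),
        sep="\t",
        header=None,
        names=["feature_id", "feature_class"],
    )
    return CountsTriplet(cell_ids=cell_ids, features=features, umi=umi, reads=reads)


# ---------------------------------------------------------------------------
# Lookup table: organoid BC (or its fixed prefix) -> guide
# ---------------------------------------------------------------------------

@dataclass
class LookupTable:
    """Mapping from organoid-BC key (full BC or fixed prefix) to guide id."""

    mapping: dict[str, str]
    ambiguous: list[str] = field(default_factory=list)
    provenance: str = "sequenced"

    def get(self, key: str) -> str | None:
        return self.mapping.get(key)


_DNA = set("ACGT")


def load_lookup_table(path: str, provenance: str = "sequenced") -> LookupTable:
    """Parse a two-column TSV of (barcode key, guide id).

    Duplicate identical rows collapse to one entry.  A key associated with
    two distinct guides cannot be used as a lookup key at all; it is dropped
    from the mapping and listed in ``ambiguous``.
    """
    seen: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed lookup row at line {lineno}")
            key, guide = parts[0], parts[1]
            if set(key) - _DNA:
                raise ValueError(
                    f"{path}: non-ACGT barcode key {key!r} at line {lineno}"
                )
            seen.setdefault(key, set()).add(guide)
    mapping = {k: next(iter(v)) for k, v in seen.items() if len(v) == 1}
    ambiguous = sorted(k for k, v in seen.items() if len(v) > 1)
    return LookupTable(mapping=mapping, ambiguous=ambiguous, provenance=provenance)


# ---------------------------------------------------------------------------
# Per-cell QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    kept: pd.Index
    removed: pd.Index
    reasons: pd.Series  # removed cell -> list of violated rules
    resolved_thresholds: dict

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def filter_cells_qc(metrics: pd.DataFrame, thresholds: Mapping[str, float]) -> QCResult:
    """Apply the standard per-cell QC rules and record why each cell fell.

    Rules (any violation removes the cell; all rules are evaluated against
    the full input, so the outcome does not depend on evaluation order):

    - ``min_umi``: total UMI strictly below the floor ("fewer than" the
      stated count; a cell exactly at the floor is kept).
    - ``top_umi_quantile``: total UMI strictly above the empirical
      ``1 - q`` quantile (``lower`` interpolation, so exactly the top
      ``q`` fraction of distinct values is removed: 5 cells of 1000 at
      q=0.005).  The resolved absolute cutoff is reported, and may be
      supplied directly as ``max_umi`` on re-runs.
    - ``max_doublet`` / ``max_mt`` / ``max_ribo``: strictly above the cap
      ("over" the stated value).

    Doublet scores and MT/Ribo percentages are consumed as given; this
    module never computes them.
    """
    if metrics.shape[0] == 0:
        raise ValueError("empty QC metrics table")
    for rule in thresholds:
        if rule not in QC_COLUMNS:
            raise ValueError(f"unknown QC rule {rule!r}")
        col = QC_COLUMNS[rule]
        if col not in metrics.columns:
            raise ValueError(f"QC metrics table is missing column {col!r}")
    for col in ("pct_mt", "pct_ribo"):
        if col in metrics.columns:
            vals = metrics[col]
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"{col} outside [0, 100]")

    resolved = dict(thresholds)
    if "top_umi_quantile" in resolved:
        q = resolved.pop("top_umi_quantile")
        cutoff = float(
            np.quantile(metrics["total_umi"].to_numpy(), 1.0 - q, method="lower")
        )
        # keep the stricter cap if an absolute one was also given
        resolved["max_umi"] = min(cutoff, resolved.get("max_umi", np.inf))

    violations: dict[str, pd.Series] = {}
    if "min_umi" in resolved:
        violations["min_umi"] = metrics["total_umi"] < resolved["min_umi"]
    if "max_umi" in resolved:
        violations["max_umi"] = metrics["total_umi"] > resolved["max_umi"]
    if "max_doublet" in resolved:
        violations["max_doublet"] = metrics["doublet_score"] > resolved["max_doublet"]
    if "max_mt" in resolved:
        violations["max_mt"] = metrics["pct_mt"] > resolved["max_mt"]
    if "max_ribo" in resolved:
        violations["max_ribo"] = metrics["pct_ribo"] > resolved["max_ribo"]

    if violations:
        viol = pd.DataFrame(violations)
        removed_mask = viol.any(axis=1)
    else:
        viol = pd.DataFrame(index=metrics.index)
        removed_mask = pd.Series(False, index=metrics.index)

    removed = metrics.index[removed_mask]
    reasons = pd.Series(
        [list(viol.columns[viol.loc[i].to_numpy(dtype=bool)]) for i in removed],
        index=removed,
        dtype=object,
    )
    return QCResult(
        kept=metrics.index[~removed_mask],
        removed=removed,
        reasons=reasons,
        resolved_thresholds=resolved,
    )
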