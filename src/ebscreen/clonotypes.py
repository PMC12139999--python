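"""Clonotype deconvolution from expressed organoid barcodes.

In a pooled monoclonal EB screen every cell of an EB inherits the founding
cell's organoid barcode (BC), so cells can be regrouped into "clonotypes"
— inferred individual EBs — from the BC count matrix alone.  The pipeline:

1. :func:`correct_barcodes` — drop BCs below UMI/read floors, then collapse
   likely sequencing-error BCs into their unique Hamming-distance-1,
   higher-abundance parent.
2. :func:`assign_bcs_to_cells` — restrict to high-abundance BCs (log2 total
   reads >= 15 by default) and assign a BC to a cell when its UMI count
   and within-cell UMI share clear the floors.
3. :func:`merge_correlated_bcs` — BCs whose per-cell normalised abundances
   correlate (Pearson r > 0.1) across cells are merged; these are EBs
   founded by a multi-integrant cell carrying several BCs.  Multi-BC cells
   whose BCs do not all correlate are excluded.
4. :func:`call_clonotypes` — group cells by (merged) BC, drop groups below
   50 cells, and number the rest deterministically.
5. :func:`assign_guide_to_clonotype` — average per-cell guide UMI
   proportions within each clonotype; one guide above 70% is a unique
   assignment, otherwise the top two are kept as a double assignment;
   clonotypes with too few guide-bearing cells are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import CountsTriplet, LookupTable

__all__ = [
    "ClonotypeMap",
    "correct_barcodes",
    "assign_bcs_to_cells",
    "merge_correlated_bcs",
    "call_clonotypes",
    "assign_guide_to_clonotype",
    "deconvolve_clonotypes",
    "bc_guide_lookup_call",
]


# ---------------------------------------------------------------------------
# Hamming correction
# ---------------------------------------------------------------------------

def _hamming_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def correct_barcodes(
    counts: CountsTriplet,
    min_umi: int = 10,
    min_reads: int = 10,
) -> tuple[CountsTriplet, pd.DataFrame]:
    """Floor-filter and Hamming-correct the organoid-BC features.

    BCs whose total UMI or total read count falls below the floors are
    removed.  Each surviving BC lying within Hamming distance 1 of exactly
    one strictly more abundant BC (by total UMI) is merged into it, counts
    summed; a BC with several such parents is ambiguous and left as-is.

    Returns the corrected counts (other feature classes untouched) and a
    log DataFrame with columns ``barcode``, ``action`` (``removed`` /
    ``merged`` / ``ambiguous``) and ``parent``.
    """
    is_bc = counts.feature_mask("organoid_bc")
    bc_ids = counts.features.loc[is_bc, "feature_id"].to_list()
    if not bc_ids:
        return counts, pd.DataFrame(columns=["barcode", "action", "parent"])
    lengths = {len(b) for b in bc_ids}
    if len(lengths) != 1:
        raise ValueError(f"organoid BCs have unequal lengths: {sorted(lengths)}")

    bc_cols = np.flatnonzero(is_bc)
    umi_tot = np.asarray(counts.umi[:, bc_cols].sum(axis=0)).ravel()
    read_tot = (
        np.asarray(counts.reads[:, bc_cols].sum(axis=0)).ravel()
        if counts.reads is not None
        else umi_tot
    )
    survive = (umi_tot >= min_umi) & (read_tot >= min_reads)
    log_rows = [(bc_ids[i], "removed", "") for i in np.flatnonzero(~survive)]

    kept = [i for i in range(len(bc_ids)) if survive[i]]
    kept_ids = [bc_ids[i] for i in kept]
    merge_into: dict[int, int] = {}
    if len(kept) > 1:
        dist = _hamming_matrix(kept_ids)
        kept_umi = umi_tot[kept]
        for a in range(len(kept)):
            parents = [
                b
                for b in range(len(kept))
                if b != a and dist[a, b] <= 1 and kept_umi[b] > kept_umi[a]
            ]
            if len(parents) == 1:
                merge_into[a] = parents[0]
                log_rows.append((kept_ids[a], "merged", kept_ids[parents[0]]))
            elif len(parents) > 1:
                log_rows.append((kept_ids[a], "ambiguous", ""))

    def root(a: int) -> int:
        while a in merge_into:
            a = merge_into[a]
        return a

    # build new feature set: non-BC features + surviving root BCs
    n_feat = counts.n_features
    roots = sorted({root(a) for a in range(len(kept))})
    root_of = {a: roots.index(root(a)) for a in range(len(kept))}

    other_cols = np.flatnonzero(~is_bc)
    n_new = len(other_cols) + len(roots)
    # column-mapping matrix: old features x new features
    rows_map, cols_map = [], []
    for j, c in enumerate(other_cols):
        rows_map.append(c)
        cols_map.append(j)
    for a in range(len(kept)):
        rows_map.append(bc_cols[kept[a]])
        cols_map.append(len(other_cols) + root_of[a])
    mapper = sp.coo_matrix(
        (np.ones(len(rows_map)), (rows_map, cols_map)), shape=(n_feat, n_new)
    ).tocsr()

    new_features = pd.concat(
        [
            counts.features.loc[~is_bc],
            pd.DataFrame(
                {
                    "feature_id": [kept_ids[r] for r in roots],
                    "feature_class": "organoid_bc",
                }
            ),
        ],
        ignore_index=True,
    )
    corrected = CountsTriplet(
        cell_ids=counts.cell_ids,
        features=new_features,
        umi=(counts.umi @ mapper).tocsr(),
        reads=None if counts.reads is None else (counts.reads @ mapper).tocsr(),
    )
    return corrected, pd.DataFrame(log_rows, columns=["barcode", "action", "parent"])


# ---------------------------------------------------------------------------
# per-cell BC assignment
# ---------------------------------------------------------------------------

def assign_bcs_to_cells(
    counts: CountsTriplet,
    min_log2_reads: float = 15.0,
    min_umi: int = 10,
    min_prop: float = 0.30,
) -> pd.DataFrame:
    """Assign high-abundance organoid BCs to cells.

    The BC universe is restricted to BCs with log2(total reads) at or
    above ``min_log2_reads`` (the 10x preset; shallow combinatorial-
    indexing data uses 10).  Within that universe a BC is assigned to a
    cell iff its UMI count is >= ``min_umi`` and its share of the cell's
    restricted-universe BC UMIs is >= ``min_prop``.

    Returns a boolean DataFrame (cells x selected BCs).
    """
    bc_view = counts.class_view("organoid_bc")
    read_tot = np.asarray(
        (bc_view.reads if bc_view.reads is not None else bc_view.umi).sum(axis=0)
    ).ravel()
    selected = np.log2(np.maximum(read_tot, 1)) >= min_log2_reads
    sel_ids = bc_view.features.loc[selected, "feature_id"].to_list()
    umi = bc_view.umi[:, np.flatnonzero(selected)].toarray().astype(float)
    cell_tot = umi.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(cell_tot > 0, umi / cell_tot, 0.0)
    assigned = (umi >= min_umi) & (prop >= min_prop)
    return pd.DataFrame(assigned, index=pd.Index(counts.cell_ids, name="cell_id"),
                        columns=sel_ids)


# ---------------------------------------------------------------------------
# correlation merging
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


@dataclass
class MergeResult:
    groups: dict[str, str]          # BC -> group representative BC
    cell_groups: pd.Series          # cell -> group representative (or NaN)
    correlations: pd.DataFrame      # BC x BC Pearson r over assigned cells
    excluded_cells: list[str]       # multi-BC cells whose BCs did not merge
    degenerate_bcs: list[str]       # zero-variance columns (r undefined)


def merge_correlated_bcs(
    counts: CountsTriplet,
    assignments: pd.DataFrame,
    r_threshold: float = 0.1,
) -> MergeResult:
    """Merge organoid BCs that co-occur across cells.

    Cells without any assigned BC are excluded first.  Per-cell BC UMI
    vectors (over the selected universe) are normalised by the cell total,
    each BC column is then standardised to zero mean / unit variance, and
    pairwise product-moment correlations are computed across cells.  A
    cell with several assigned BCs is excluded unless every pair among its
    BCs correlates above ``r_threshold``; qualifying pairs are merged,
    with merging closed transitively so the result is a partition.  A BC
    column with zero variance has undefined correlations and never merges.
    """
    bc_ids = list(assignments.columns)
    has_bc = assignments.to_numpy().any(axis=1)
    cells_with = assignments.index[has_bc]

    bc_view = counts.class_view("organoid_bc")
    order = {f: i for i, f in enumerate(bc_view.features["feature_id"])}
    cols = [order[b] for b in bc_ids]
    umi = bc_view.umi[:, cols].toarray().astype(float)[has_bc]
    totals = umi.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = umi / totals
    mean = norm.mean(axis=0)
    sd = norm.std(axis=0)
    degenerate = [bc_ids[j] for j in np.flatnonzero(sd == 0)]
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (norm - mean) / sd_safe
    with np.errstate(invalid="ignore"):
        corr = (z.T @ z) / len(z)
    corr_df = pd.DataFrame(corr, index=bc_ids, columns=bc_ids)

    uf = _UnionFind(bc_ids)
    excluded: list[str] = []
    assigned_sets = {}
    amat = assignments.to_numpy()
    for row, cell in zip(amat[has_bc], cells_with):
        bcs = [bc_ids[j] for j in np.flatnonzero(row)]
        assigned_sets[cell] = bcs
        if len(bcs) <= 1:
            continue
        ok = all(
            corr_df.at[a, b] > r_threshold
            and a not in degenerate
            and b not in degenerate
            for a in bcs
            for b in bcs
            if a < b
        )
        if ok:
            for a, b in zip(bcs, bcs[1:]):
                uf.union(a, b)
        else:
            excluded.append(cell)

    groups = {b: uf.find(b) for b in bc_ids}
    cell_group = {}
    for cell, bcs in assigned_sets.items():
        if cell in excluded:
            continue
        roots = {groups[b] for b in bcs}
        if len(roots) == 1:
            cell_group[cell] = roots.pop()
        else:
            excluded.append(cell)
    cell_groups = pd.Series(cell_group, dtype=object)
    cell_groups.index.name = "cell_id"
    return MergeResult(
        groups=groups,
        cell_groups=cell_groups,
        correlations=corr_df,
        excluded_cells=excluded,
        degenerate_bcs=degenerate,
    )


# ---------------------------------------------------------------------------
# clonotype calling and guide assignment
# ---------------------------------------------------------------------------

@dataclass
class ClonotypeMap:
    """clonotype id -> merged BC set, member cells, and (later) guide call."""

    clonotypes: pd.DataFrame  # clonotype_id, bcs (tuple), n_cells
    cell_assignments: pd.Series  # cell_id -> clonotype_id (assigned cells only)
    guide_calls: pd.DataFrame | None = None

    def members(self, clonotype_id: str) -> pd.Index:
        return self.cell_assignments.index[self.cell_assignments == clonotype_id]

    def to_tsv(self, path: str) -> None:
        out = self.clonotypes.copy()
        out["bcs"] = [",".join(b) for b in out["bcs"]]
        if self.guide_calls is not None:
            out = out.merge(self.guide_calls, on="clonotype_id", how="left")
        out.to_csv(path, sep="\t", index=False)


def call_clonotypes(
    merge_result: MergeResult,
    min_cells: int = 50,
) -> ClonotypeMap:
    """Group cells by merged BC and keep groups with >= ``min_cells`` cells.

    Surviving groups are numbered by descending size, ties broken by the
    lexicographically smallest member BC, so ids are stable across reruns.
    """
    cg = merge_result.cell_groups
    sizes = cg.value_counts()
    kept = sizes[sizes >= min_cells]
    group_bcs: dict[str, list[str]] = {}
    for bc, root in merge_result.groups.items():
        group_bcs.setdefault(root, []).append(bc)

    entries = sorted(
        ((root, n) for root, n in kept.items()),
        key=lambda it: (-it[1], min(group_bcs.get(it[0], [it[0]]))),
    )
    rows = []
    rename = {}
    for i, (root, n) in enumerate(entries):
        cid = f"clonotype{i + 1:03d}"
        rename[root] = cid
        rows.append((cid, tuple(sorted(group_bcs.get(root, [root]))), int(n)))
    assigned = cg[cg.isin(kept.index)].map(rename)
    return ClonotypeMap(
        clonotypes=pd.DataFrame(rows, columns=["clonotype_id", "bcs", "n_cells"]),
        cell_assignments=assigned,
    )


def assign_guide_to_clonotype(
    cmap: ClonotypeMap,
    counts: CountsTriplet,
    min_eligible_cells: int = 10,
    cell_umi_floor: int = 10,
    unique_threshold: float = 0.70,
) -> ClonotypeMap:
    """Call each clonotype's gRNA from directly captured guide UMIs.

    Cells with total guide UMIs >= ``cell_umi_floor`` are eligible;
    clonotypes with fewer than ``min_eligible_cells`` eligible cells are
    discarded.  Per eligible cell the guide UMI proportions are computed
    and averaged within the clonotype: one guide above
    ``unique_threshold`` is a unique call, otherwise the top two guides
    form a double call.
    """
    gv = counts.class_view("guide")
    if gv.n_features == 0:
        cmap.guide_calls = pd.DataFrame(
            {
                "clonotype_id": cmap.clonotypes["clonotype_id"],
                "guide_call": [()] * len(cmap.clonotypes),
                "call_class": "discarded",
                "mean_props": [{}] * len(cmap.clonotypes),
            }
        )
        return cmap
    guide_ids = gv.features["feature_id"].to_numpy(object)
    umi = gv.umi.toarray().astype(float)
    cell_pos = {c: i for i, c in enumerate(counts.cell_ids)}

    rows = []
    for cid in cmap.clonotypes["clonotype_id"]:
        members = [cell_pos[c] for c in cmap.members(cid)]
        sub = umi[members]
        totals = sub.sum(axis=1)
        eligible = totals >= cell_umi_floor
        if eligible.sum() < min_eligible_cells:
            rows.append((cid, (), "discarded", {}))
            continue
        props = sub[eligible] / totals[eligible, None]
        mean_props = props.mean(axis=0)
        order = np.lexsort((guide_ids, -mean_props))
        top = order[0]
        if mean_props[top] > unique_threshold:
            call, cls = (guide_ids[top],), "unique"
        else:
            call, cls = tuple(guide_ids[order[:2]]), "double"
        props_out = {
            guide_ids[j]: round(float(mean_props[j]), 6)
            for j in order[:5]
            if mean_props[j] > 0
        }
        rows.append((cid, call, cls, props_out))
    cmap.guide_calls = pd.DataFrame(
        rows, columns=["clonotype_id", "guide_call", "call_class", "mean_props"]
    )
    return cmap


def bc_guide_lookup_call(
    cmap: ClonotypeMap, lookup: LookupTable, prefix_length: int = 8
) -> pd.Series:
    """Guide call per clonotype from its BCs' fixed prefixes via the lookup.

    Returns a Series clonotype_id -> tuple of guide ids (one per member BC
    whose prefix resolves; unknown prefixes are skipped).
    """
    out = {}
    for cid, bcs, _ in cmap.clonotypes.itertuples(index=False):
        hits = []
        for bc in bcs:
            g = lookup.get(bc[:prefix_length]) or lookup.get(bc)
            if g is not None:
                hits.append(g)
        out[cid] = tuple(sorted(set(hits)))
    return pd.Series(out, name="bc_guide_call")


def deconvolve_clonotypes(
    counts: CountsTriplet,
    *,
    min_bc_umi: int = 10,
    min_bc_reads: int = 10,
    min_log2_reads: float = 15.0,
    min_umi: int = 10,
    min_prop: float = 0.30,
    r_threshold: float = 0.1,
    min_cells: int = 50,
    min_eligible_cells: int = 10,
    cell_umi_floor: int = 10,
    unique_threshold: float = 0.70,
) -> ClonotypeMap:
    """Run the full organoid-BC deconvolution pipeline on one experiment."""
    corrected, _ = correct_barcodes(counts, min_umi=min_bc_umi, min_reads=min_bc_reads)
    assignments = assign_bcs_to_cells(
        corrected, min_log2_reads=min_log2_reads, min_umi=min_umi, min_prop=min_prop
    )
    merged = merge_correlated_bcs(corrected, assignments, r_threshold=r_threshold)
    cmap = call_clonotypes(merged, min_cells=min_cells)
    return assign_guide_to_clonotype(
        cmap,
        corrected,
        min_eligible_cells=min_eligible_cells,
        cell_umi_floor=cell_umi_floor,
        unique_threshold=unique_threshold,
    )
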