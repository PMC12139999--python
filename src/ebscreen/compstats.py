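"""Composition and enrichment statistics for perturbation screens.

The central procedure is an empirical-null chi-square screen: for every
perturbation target (its three guides pooled) the distribution of assigned
cells over annotated cell types is compared to the pooled composition of
all non-targeting-control (NTC) cells.  Because single chi-square p-values
are badly miscalibrated for clustered single-cell data, significance is
never read off the chi-square distribution alone: NTC guides are randomly
bundled into groups of three to mimic targets, run through the identical
test, and a target is flagged only if its p-value falls below the
``q``-quantile of the NTC-group p-values (an empirical FDR cutoff).

For monoclonal, organoid-barcoded screens a clonotype-aware variant builds
the null from resampled groups of NTC clonotypes whose group sizes match
the targets' clonotype counts, so the null carries the same per-EB
clustering as the tested units.

Also here: per-cell-type odds ratios, k-nearest-neighbour enrichment in an
embedding, per-clonotype cell-fraction rank-sum tests, and the
pseudobulk-versus-single-cell differential-expression discordance check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenTestResult",
    "screen_composition",
    "screen_composition_clonal",
    "celltype_odds_ratios",
    "knn_enrichment",
    "clonotype_fraction_test",
    "pseudobulk_de_compare",
    "pca_embedding",
]


# ---------------------------------------------------------------------------
# chi-square against the pooled-NTC background
# ---------------------------------------------------------------------------

def _chisq_gof(observed: np.ndarray, expected_props: np.ndarray) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of observed counts against fixed proportions."""
    n = observed.sum()
    expected = n * expected_props
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


@dataclass
class ScreenTestResult:
    """Outcome of an empirical-null composition screen."""

    targets: pd.DataFrame       # target, n_cells, statistic, df, p, flagged
    ntc_groups: pd.DataFrame    # group, n_cells, statistic, df, p, flagged
    cutoff: float
    q: float
    categories: list[str]
    seed: int | None = None

    @property
    def flagged_fraction(self) -> float:
        if len(self.targets) == 0:
            return float("nan")
        return float(self.targets["flagged"].mean())

    @property
    def flagged_targets(self) -> set[str]:
        return set(self.targets.loc[self.targets["flagged"], "target"])


def _background(cells: pd.DataFrame, categories: list[str]) -> np.ndarray:
    bg = cells["cell_type"].value_counts().reindex(categories).fillna(0).to_numpy(float)
    return bg / bg.sum()


def _downsample(rng, idx: np.ndarray, n: int) -> np.ndarray:
    if len(idx) <= n:
        return idx
    return rng.choice(idx, size=n, replace=False)


def _unit_test(
    rng,
    cells: pd.DataFrame,
    idx: np.ndarray,
    bg_props: np.ndarray,
    categories: list[str],
    downsample: int,
) -> tuple[int, float, int, float]:
    sub = cells.loc[_downsample(rng, idx, downsample)]
    observed = (
        sub["cell_type"].value_counts().reindex(categories).fillna(0).to_numpy(float)
    )
    stat, df, p = _chisq_gof(observed, bg_props)
    return len(sub), stat, df, p


def screen_composition(
    cells: pd.DataFrame,
    *,
    min_target_cells: int = 50,
    min_ntc_cells: int = 20,
    ntc_group_size: int = 3,
    downsample: int = 100,
    q: float = 0.05,
    seed: int | None = None,
    include_self_in_background: bool = True,
) -> ScreenTestResult:
    """Empirical-null chi-square screen over cell-type composition.

    Parameters
    ----------
    cells : DataFrame with one row per assigned cell and columns
        ``target`` (target id, guides pooled), ``guide`` (guide id),
        ``is_ntc`` (bool) and ``cell_type``.
    min_target_cells, min_ntc_cells : units below these cell counts are not
        tested (targets as a whole; NTC guides individually).
    ntc_group_size : NTC guides are randomly partitioned (seeded) into
        groups of this size to mimic a target's pooled guides; leftover
        guides that do not fill a group are not tested.
    downsample : every tested unit is downsampled without replacement to
        this many cells; smaller units pass through unchanged.
    q : quantile of the NTC-group p-values used as the significance cutoff.
    include_self_in_background : the background is the pool of *all* NTC
        cells; set False to exclude a tested NTC group's own cells from its
        background (the default mirrors the standard procedure).

    Returns a :class:`ScreenTestResult`; a unit is flagged iff its p-value
    is strictly below the cutoff.
    """
    rng = np.random.default_rng(seed)
    required = {"target", "guide", "is_ntc", "cell_type"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table is missing columns {sorted(missing)}")
    cells = cells.reset_index(drop=True)

    ntc_cells = cells[cells["is_ntc"]]
    categories = sorted(ntc_cells["cell_type"].unique())
    dropped = set(cells["cell_type"].unique()) - set(categories)
    if dropped:
        warnings.warn(
            f"cell types absent from the NTC background dropped: {sorted(dropped)}"
        )
        cells = cells[cells["cell_type"].isin(categories)].reset_index(drop=True)
        ntc_cells = cells[cells["is_ntc"]]
    bg_props_all = _background(ntc_cells, categories)

    # NTC guides with enough cells, randomly partitioned into mimic groups
    ntc_sizes = ntc_cells.groupby("guide").size()
    eligible = sorted(ntc_sizes.index[ntc_sizes >= min_ntc_cells])
    perm = rng.permutation(len(eligible))
    groups = [
        [eligible[j] for j in perm[i : i + ntc_group_size]]
        for i in range(0, len(eligible) - ntc_group_size + 1, ntc_group_size)
    ]
    if len(groups) < 2:
        raise ValueError(
            f"only {len(groups)} NTC group(s) of size {ntc_group_size}; "
            "the empirical null is not estimable"
        )

    ntc_records = []
    for gi, guides in enumerate(groups):
        idx = ntc_cells.index[ntc_cells["guide"].isin(guides)].to_numpy()
        if include_self_in_background:
            bg = bg_props_all
        else:
            bg = _background(ntc_cells.loc[~ntc_cells.index.isin(idx)], categories)
        n, stat, df, p = _unit_test(rng, cells, idx, bg, categories, downsample)
        ntc_records.append(("+".join(guides), n, stat, df, p))
    ntc_df = pd.DataFrame(
        ntc_records, columns=["group", "n_cells", "statistic", "df", "p"]
    )

    target_records = []
    tgt_cells = cells[~cells["is_ntc"]]
    for target, sub in tgt_cells.groupby("target", sort=True):
        if len(sub) < min_target_cells:
            continue
        n, stat, df, p = _unit_test(
            rng, cells, sub.index.to_numpy(), bg_props_all, categories, downsample
        )
        target_records.append((target, n, stat, df, p))
    tgt_df = pd.DataFrame(
        target_records, columns=["target", "n_cells", "statistic", "df", "p"]
    )

    cutoff = float(np.quantile(ntc_df["p"].to_numpy(), q))  # type-7 interpolation
    tgt_df["flagged"] = tgt_df["p"] < cutoff
    ntc_df["flagged"] = ntc_df["p"] < cutoff
    return ScreenTestResult(
        targets=tgt_df,
        ntc_groups=ntc_df,
        cutoff=cutoff,
        q=q,
        categories=categories,
        seed=seed,
    )


def screen_composition_clonal(
    cells: pd.DataFrame,
    *,
    min_target_cells: int = 50,
    downsample: int = 100,
    n_null_groups: int = 200,
    q: float = 0.05,
    seed: int | None = None,
) -> ScreenTestResult:
    """Clonotype-aware empirical-null composition screen for monoclonal EBs.

    ``cells`` needs columns ``target``, ``is_ntc``, ``cell_type`` and
    ``clonotype``.  Each target unit pools the cells of all clonotypes
    assigned to it.  Null units are built by resampling: for each of
    ``n_null_groups`` groups, a clonotype count is drawn from the tested
    targets' empirical clonotype-count distribution and that many NTC
    clonotypes are sampled without replacement from the NTC pool.  Null
    units therefore carry the same between-EB clustering as targets, which
    is what makes the empirical cutoff calibrated for clustered data.
    """
    rng = np.random.default_rng(seed)
    required = {"target", "is_ntc", "cell_type", "clonotype"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table is missing columns {sorted(missing)}")
    cells = cells.reset_index(drop=True)

    ntc_cells = cells[cells["is_ntc"]]
    categories = sorted(ntc_cells["cell_type"].unique())
    cells = cells[cells["cell_type"].isin(categories)].reset_index(drop=True)
    ntc_cells = cells[cells["is_ntc"]]
    bg_props = _background(ntc_cells, categories)
    ntc_clonotypes = np.asarray(sorted(ntc_cells["clonotype"].unique()))
    if len(ntc_clonotypes) < 2:
        raise ValueError("need at least two NTC clonotypes for the resampled null")

    tgt_cells = cells[~cells["is_ntc"]]
    target_records = []
    k_profile = []
    for target, sub in tgt_cells.groupby("target", sort=True):
        if len(sub) < min_target_cells:
            continue
        k_profile.append(sub["clonotype"].nunique())
        n, stat, df, p = _unit_test(
            rng, cells, sub.index.to_numpy(), bg_props, categories, downsample
        )
        target_records.append((target, n, stat, df, p))
    tgt_df = pd.DataFrame(
        target_records, columns=["target", "n_cells", "statistic", "df", "p"]
    )
    if len(tgt_df) == 0:
        raise ValueError("no target passed the cell-count floor")

    by_clono = ntc_cells.groupby("clonotype").indices
    null_records = []
    for gi in range(n_null_groups):
        k = int(rng.choice(k_profile))
        k = min(k, len(ntc_clonotypes))
        chosen = rng.choice(ntc_clonotypes, size=k, replace=False)
        idx = np.concatenate([ntc_cells.index.to_numpy()[by_clono[c]] for c in chosen])
        n, stat, df, p = _unit_test(rng, cells, idx, bg_props, categories, downsample)
        null_records.append((f"null{gi + 1}", n, stat, df, p))
    null_df = pd.DataFrame(
        null_records, columns=["group", "n_cells", "statistic", "df", "p"]
    )

    cutoff = float(np.quantile(null_df["p"].to_numpy(), q))
    tgt_df["flagged"] = tgt_df["p"] < cutoff
    null_df["flagged"] = null_df["p"] < cutoff
    return ScreenTestResult(
        targets=tgt_df,
        ntc_groups=null_df,
        cutoff=cutoff,
        q=q,
        categories=categories,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------

def celltype_odds_ratios(
    target_types: pd.Series, ntc_types: pd.Series, haldane: float = 0.5
) -> pd.DataFrame:
    """Per-cell-type odds ratio of target vs NTC membership.

    For each cell type the 2x2 table (in/out of the type x target/NTC) is
    formed; tables containing a zero receive the Haldane-Anscombe
    correction (``haldane`` added to all four counts of that table only).
    """
    if len(target_types) == 0 or len(ntc_types) == 0:
        raise ValueError("both groups must be non-empty")
    types = sorted(set(target_types) | set(ntc_types))
    rows = []
    for ct in types:
        a = int((target_types == ct).sum())
        b = len(target_types) - a
        c = int((ntc_types == ct).sum())
        d = len(ntc_types) - c
        corrected = 0 in (a, b, c, d)
        if corrected:
            a, b, c, d = (x + haldane for x in (a, b, c, d))
        rows.append((ct, (a * d) / (b * c), corrected))
    return pd.DataFrame(rows, columns=["cell_type", "odds_ratio", "corrected"]).set_index(
        "cell_type"
    )


# ---------------------------------------------------------------------------
# kNN enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentScore:
    scores: pd.DataFrame  # target, score, expected, n_cells
    k: int
    n_dims: int


def knn_enrichment(
    embedding: np.ndarray,
    labels: pd.Series | np.ndarray,
    *,
    k: int = 20,
    per_target_downsample: int = 200,
    min_target_cells: int = 50,
    seed: int | None = None,
) -> EnrichmentScore:
    """Mean same-target fraction among each cell's k nearest neighbours.

    Targets below ``min_target_cells`` are excluded; the rest are
    downsampled (without replacement, seeded) to ``per_target_downsample``
    cells.  Neighbours are exact Euclidean neighbours within the retained
    set, self excluded.  Alongside each score the random-label expectation
    (the target's share of retained cells) is reported.
    """
    rng = np.random.default_rng(seed)
    embedding = np.asarray(embedding, float)
    labels = pd.Series(np.asarray(labels, object))
    if embedding.ndim != 2 or embedding.shape[1] < 1:
        raise ValueError("embedding must be 2-D with at least one dimension")

    keep_idx = []
    for target in sorted(labels.unique()):
        idx = np.flatnonzero((labels == target).to_numpy())
        if len(idx) < min_target_cells:
            continue
        keep_idx.append(_downsample(rng, idx, per_target_downsample))
    if not keep_idx:
        raise ValueError("no target passed the cell-count floor")
    keep = np.sort(np.concatenate(keep_idx))
    emb = embedding[keep]
    lab = labels.to_numpy(object)[keep]
    n = len(keep)
    if k >= n:
        raise ValueError(f"k={k} must be below the retained cell count {n}")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, nbr = nn.kneighbors(emb)
    nbr = nbr[:, 1:]  # drop self (nearest neighbour of a point is itself)
    same = (lab[nbr] == lab[:, None]).mean(axis=1)

    rows = []
    for target in sorted(pd.unique(lab)):
        mask = lab == target
        rows.append((target, float(same[mask].mean()), float(mask.mean()), int(mask.sum())))
    scores = pd.DataFrame(rows, columns=["target", "score", "expected", "n_cells"])
    return EnrichmentScore(scores=scores, k=k, n_dims=embedding.shape[1])


# ---------------------------------------------------------------------------
# per-clonotype fraction tests
# ---------------------------------------------------------------------------

def clonotype_fraction_test(
    cells: pd.DataFrame,
    target_id: str,
    ntc_id: str,
    cell_type: str,
) -> tuple[float, pd.Series, pd.Series]:
    """Two-sided rank-sum test of per-clonotype cell-type fractions.

    ``cells`` needs columns ``clonotype``, ``group`` (perturbation label)
    and ``cell_type``.  Each clonotype contributes one observation: the
    fraction of its cells annotated as ``cell_type``.  The Wilcoxon
    rank-sum (Mann-Whitney) test is exact for small tie-free samples and
    uses the tie-corrected normal approximation otherwise.

    Returns ``(p, target_fractions, ntc_fractions)``.
    """
    frac = (
        cells.assign(hit=cells["cell_type"] == cell_type)
        .groupby(["group", "clonotype"])["hit"]
        .mean()
    )
    for gid in (target_id, ntc_id):
        if gid not in frac.index.get_level_values("group"):
            raise ValueError(f"group {gid!r} has no clonotypes")
    x = frac.loc[target_id]
    y = frac.loc[ntc_id]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two clonotypes per group")
    p = rank_sum_p(x.to_numpy(float), y.to_numpy(float))
    return p, x, y


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact when tie-free and small, else normal.

    The normal approximation applies the tie correction without continuity
    correction, so identical samples return exactly 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not has_ties and max(len(x), len(y)) <= 25:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# pseudobulk vs single-cell differential expression
# ---------------------------------------------------------------------------

@dataclass
class DECompareResult:
    single_cell_calls: list[str]
    clonotype_calls: list[str]
    unsupported_fraction: float | None
    table: pd.DataFrame  # gene, p_sc, q_sc, p_clono, q_clono


def _cpm_log1p(mat: np.ndarray, scale: float = 1e6) -> np.ndarray:
    totals = mat.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(mat / totals * scale)


def pseudobulk_de_compare(
    gene_counts: np.ndarray | sp.spmatrix,
    gene_ids: "Sequence[str] | None" = None,
    *,
    clonotypes: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    target_id: str,
    ntc_id: str,
    alpha: float = 0.05,
) -> DECompareResult:
    """Quantify how many single-cell DE calls survive clonotype replication.

    Two differential-expression tracks between ``target_id`` and
    ``ntc_id`` cells:

    - single-cell: per-gene two-sided rank-sum across cells on
      log1p-counts-per-10k, Benjamini-Hochberg at ``alpha``;
    - clonotype: counts summed per clonotype (pseudobulk), normalised to
      counts-per-million, log1p, per-gene two-sided rank-sum across
      clonotypes, Benjamini-Hochberg at ``alpha``.

    The unsupported fraction is the share of single-cell calls absent from
    the clonotype calls — cells are pseudoreplicates, so calls driven by a
    single EB's idiosyncrasy evaporate when clonotypes are the replicates.
    Returns ``unsupported_fraction`` as None when there are no single-cell
    calls.
    """
    mat = np.asarray(
        gene_counts.toarray() if sp.issparse(gene_counts) else gene_counts, float
    )
    n_cells, n_genes = mat.shape
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    clonotypes = np.asarray(clonotypes, object)
    groups = np.asarray(groups, object)

    sel = np.isin(groups, [target_id, ntc_id])
    mat, clonotypes, groups = mat[sel], clonotypes[sel], groups[sel]
    is_target = groups == target_id
    clono_of = pd.Series(groups).groupby(pd.Series(clonotypes)).first()
    if (clono_of == target_id).sum() < 2 or (clono_of == ntc_id).sum() < 2:
        raise ValueError("need at least two clonotypes per group")

    # single-cell track
    norm = _cpm_log1p(mat, scale=1e4)
    p_sc = stats.mannwhitneyu(
        norm[is_target], norm[~is_target], alternative="two-sided",
        method="asymptotic", axis=0,
    ).pvalue
    q_sc = multipletests(p_sc, alpha=alpha, method="fdr_bh")[1]

    # clonotype (pseudobulk) track
    pb = pd.DataFrame(mat).groupby(pd.Series(clonotypes)).sum()
    pb_groups = clono_of.loc[pb.index].to_numpy(object)
    pb_norm = _cpm_log1p(pb.to_numpy(float), scale=1e6)
    p_cl = stats.mannwhitneyu(
        pb_norm[pb_groups == target_id], pb_norm[pb_groups == ntc_id],
        alternative="two-sided", method="asymptotic", axis=0,
    ).pvalue
    q_cl = multipletests(p_cl, alpha=alpha, method="fdr_bh")[1]

    table = pd.DataFrame(
        {"gene": gene_ids, "p_sc": p_sc, "q_sc": q_sc, "p_clono": p_cl, "q_clono": q_cl}
    )
    sc_calls = [g for g, q in zip(gene_ids, q_sc) if q < alpha]
    cl_calls = [g for g, q in zip(gene_ids, q_cl) if q < alpha]
    if sc_calls:
        unsupported = len(set(sc_calls) - set(cl_calls)) / len(sc_calls)
    else:
        unsupported = None
    return DECompareResult(
        single_cell_calls=sc_calls,
        clonotype_calls=cl_calls,
        unsupported_fraction=unsupported,
        table=table,
    )


# ---------------------------------------------------------------------------
# embedding helper
# ---------------------------------------------------------------------------

def pca_embedding(
    gene_umi: np.ndarray | sp.spmatrix,
    n_top_genes: int = 2500,
    n_components: int = 30,
) -> np.ndarray:
    """log1p counts-per-10k -> top-variance genes -> centred truncated SVD.

    Mirrors the conventional "top 30 PCs" preprocessing at small scale.
    """
    mat = np.asarray(
        gene_umi.toarray() if sp.issparse(gene_umi) else gene_umi, float
    )
    norm = _cpm_log1p(mat, scale=1e4)
    var = norm.var(axis=0)
    top = np.argsort(-var, kind="stable")[: min(n_top_genes, norm.shape[1])]
    sub = norm[:, top] - norm[:, top].mean(axis=0)
    n_comp = min(n_components, sub.shape[0] - 1, sub.shape[1])
    u, s, _ = np.linalg.svd(sub, full_matrices=False)
    return u[:, :n_comp] * s[:n_comp]
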