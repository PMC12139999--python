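import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ebscreen.compstats import (
    celltype_odds_ratios,
    clonotype_fraction_test,
    knn_enrichment,
    pca_embedding,
    pseudobulk_de_compare,
    rank_sum_p,
    screen_composition,
    screen_composition_clonal,
)


def cells_table(unit_counts, ntc_units, background_props, seed=0, n_types=None):
    """Build a cells DataFrame with per-unit cell-type counts drawn iid."""
    rng = np.random.default_rng(seed)
    props = np.asarray(background_props, float)
    types = [f"ct{k}" for k in range(len(props))]
    rows = []
    for unit, n in unit_counts.items():
        is_ntc = unit in ntc_units
        draws = rng.choice(len(props), size=n, p=props)
        for d in draws:
            rows.append((unit if not is_ntc else "NTC", unit, is_ntc, types[d]))
    return pd.DataFrame(rows, columns=["target", "guide", "is_ntc", "cell_type"])


class TestChiSquareOracle:
    def test_matches_direct_formula_on_random_tables(self):
        from ebscreen.compstats import _chisq_gof

        rng = np.random.default_rng(1)
        for _ in range(50):
            k = rng.integers(2, 10)
            props = rng.dirichlet(np.ones(k))
            obs = rng.integers(0, 50, size=k).astype(float)
            if obs.sum() == 0:
                continue
            stat, df, p = _chisq_gof(obs, props)
            expected = obs.sum() * props
            oracle = float(np.sum((obs - expected) ** 2 / expected))
            assert stat == pytest.approx(oracle, abs=1e-9)
            assert df == k - 1
            assert p == pytest.approx(float(stats.chi2.sf(oracle, k - 1)), abs=1e-12)

    def test_two_category_worked_example(self):
        from ebscreen.compstats import _chisq_gof

        stat, df, p = _chisq_gof(np.array([50.0, 50.0]), np.array([0.9, 0.1]))
        assert stat == pytest.approx(177.7777777, abs=1e-6)

    def test_background_composition_gives_zero_statistic(self):
        from ebscreen.compstats import _chisq_gof

        stat, _, p = _chisq_gof(np.array([90.0, 10.0]), np.array([0.9, 0.1]))
        assert stat == 0.0 and p == 1.0


class TestScreenComposition:
    def test_ntc_group_flag_rate_matches_quantile_by_construction(self):
        counts = {f"N{i}": 100 for i in range(120)}
        cells = cells_table(counts, set(counts), [0.3, 0.3, 0.2, 0.1, 0.1], seed=2)
        # no targets: only the NTC null is exercised
        cells_t = cells_table({"T0_g0": 100, "T0_g1": 100, "T0_g2": 100}, set(),
                              [0.3, 0.3, 0.2, 0.1, 0.1], seed=3)
        cells_t["target"] = "T0"
        res = screen_composition(pd.concat([cells, cells_t]), seed=4)
        m = len(res.ntc_groups)
        flagged = res.ntc_groups.flagged.sum()
        assert abs(flagged - 0.05 * m) <= 1  # quantile discreteness

    def test_min_cell_floors_exclude_units(self):
        counts = {"T0_g0": 20, "T0_g1": 20, "T0_g2": 9}  # 49 target cells
        counts |= {f"N{i}": c for i, c in enumerate([100] * 6 + [19])}
        cells = cells_table(counts, {f"N{i}" for i in range(7)}, [0.5, 0.5], seed=5)
        cells.loc[~cells.is_ntc, "target"] = "T0"
        res = screen_composition(cells, seed=6)
        assert len(res.targets) == 0  # 49 < 50
        # the 19-cell NTC guide cannot enter a group: 6 eligible -> 2 groups
        assert len(res.ntc_groups) == 2

    def test_too_few_ntc_groups_raise(self):
        counts = {"T0_g0": 60, "N0": 50, "N1": 50, "N2": 50}
        cells = cells_table(counts, {"N0", "N1", "N2"}, [0.5, 0.5], seed=7)
        cells.loc[~cells.is_ntc, "target"] = "T0"
        with pytest.raises(ValueError, match="NTC group"):
            screen_composition(cells, seed=8)

    def test_downsampling_is_seeded_and_deterministic(self):
        counts = {f"T{t}_g{g}": 80 for t in range(3) for g in range(3)}
        counts |= {f"N{i}": 80 for i in range(9)}
        cells = cells_table(counts, {f"N{i}" for i in range(9)},
                            [0.4, 0.3, 0.2, 0.1], seed=9)
        cells.loc[~cells.is_ntc, "target"] = cells.loc[~cells.is_ntc, "guide"].str[:2]
        a = screen_composition(cells, seed=10)
        b = screen_composition(cells, seed=10)
        pd.testing.assert_frame_equal(a.targets, b.targets)
        assert a.cutoff == b.cutoff

    def test_flag_definition(self):
        counts = {f"T{t}_g{g}": 100 for t in range(4) for g in range(3)}
        counts |= {f"N{i}": 100 for i in range(30)}
        cells = cells_table(counts, {f"N{i}" for i in range(30)},
                            [0.4, 0.3, 0.2, 0.1], seed=11)
        cells.loc[~cells.is_ntc, "target"] = cells.loc[~cells.is_ntc, "guide"].str[:2]
        res = screen_composition(cells, seed=12)
        assert (res.targets.flagged == (res.targets.p < res.cutoff)).all()


class TestClonalScreen:
    def test_calibrated_on_iid_clonotypes(self):
        rng = np.random.default_rng(13)
        props = np.array([0.4, 0.3, 0.2, 0.1])
        rows = []
        for t in range(10):
            for c in range(6):
                for d in rng.choice(4, size=40, p=props):
                    rows.append((f"T{t}", False, f"T{t}.c{c}", f"ct{d}"))
        for c in range(60):
            for d in rng.choice(4, size=40, p=props):
                rows.append(("NTC", True, f"N.c{c}", f"ct{d}"))
        cells = pd.DataFrame(rows, columns=["target", "is_ntc", "clonotype", "cell_type"])
        res = screen_composition_clonal(cells, n_null_groups=300, seed=14)
        assert res.targets.flagged.mean() <= 0.3  # no systematic flagging
        assert len(res.ntc_groups) == 300


class TestOddsRatios:
    def test_equal_rates_give_unit_odds(self):
        t = pd.Series(["a"] * 10 + ["b"] * 90)
        n = pd.Series(["a"] * 10 + ["b"] * 90)
        out = celltype_odds_ratios(t, n)
        assert out.loc["a", "odds_ratio"] == pytest.approx(1.0)

    def test_worked_example(self):
        t = pd.Series(["a"] * 20 + ["b"] * 80)
        n = pd.Series(["a"] * 10 + ["b"] * 90)
        out = celltype_odds_ratios(t, n)
        assert out.loc["a", "odds_ratio"] == pytest.approx(2.25)

    def test_zero_cell_correction_finite_and_below_one(self):
        t = pd.Series(["b"] * 100)
        n = pd.Series(["a"] * 10 + ["b"] * 90)
        out = celltype_odds_ratios(t, n)
        assert 0 < out.loc["a", "odds_ratio"] < 1
        assert out.loc["a", "corrected"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            celltype_odds_ratios(pd.Series([], dtype=object), pd.Series(["a"]))


class TestKnnEnrichment:
    def test_single_target_scores_one(self):
        rng = np.random.default_rng(15)
        emb = rng.normal(size=(100, 5))
        res = knn_enrichment(emb, ["T"] * 100, k=10, seed=0)
        assert res.scores.score.iloc[0] == 1.0

    def test_random_labels_match_expected_fraction(self):
        rng = np.random.default_rng(16)
        n = 2000
        emb = rng.normal(size=(n, 8))
        labels = np.where(rng.random(n) < 0.1, "T", "other")
        res = knn_enrichment(
            emb, labels, k=20, per_target_downsample=10_000, seed=1
        )
        row = res.scores.set_index("target").loc["T"]
        se = np.sqrt(0.1 * 0.9 / (row.n_cells * 20))
        assert abs(row.score - row.expected) < 3 * se + 0.01

    def test_separated_blobs_score_high(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, size=(300, 6))
        b = rng.normal(0, 1, size=(300, 6)) + 12.0
        emb = np.vstack([a, b])
        labels = ["A"] * 300 + ["B"] * 300
        res = knn_enrichment(emb, labels, k=20, seed=2)
        assert (res.scores.score > 0.95).all()

    def test_rotation_invariance(self):
        rng = np.random.default_rng(18)
        emb = rng.normal(size=(400, 6))
        labels = rng.choice(["A", "B", "C"], size=400)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        a = knn_enrichment(emb, labels, k=15, seed=3)
        b = knn_enrichment(emb @ q, labels, k=15, seed=3)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_matches_bruteforce_neighbours(self):
        rng = np.random.default_rng(19)
        emb = rng.normal(size=(150, 4))
        labels = rng.choice(["A", "B"], size=150)
        res = knn_enrichment(emb, labels, k=7, min_target_cells=10,
                             per_target_downsample=10_000, seed=4)
        d = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        nbr = np.argsort(d, axis=1, kind="stable")[:, :7]
        same = (labels[nbr] == labels[:, None]).mean(1)
        for target in ("A", "B"):
            mask = labels == target
            expected = same[mask].mean()
            got = res.scores.set_index("target").loc[target, "score"]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_k_must_be_below_cell_count(self):
        with pytest.raises(ValueError):
            knn_enrichment(np.zeros((30, 2)), ["T"] * 30, k=30, min_target_cells=1)


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        x = np.array([0.1, 0.2, 0.3])
        assert rank_sum_p(x, x.copy()) == pytest.approx(1.0)

    def test_exact_p_matches_exhaustive_enumeration(self):
        x = [0.1, 0.2, 0.3]
        y = [0.7, 0.8, 0.9]
        assert rank_sum_p(np.array(x), np.array(y)) == pytest.approx(0.1)

        rng = np.random.default_rng(20)
        for _ in range(10):
            n1, n2 = rng.integers(2, 5, size=2)
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            x, y = vals[:n1], vals[n1:]

            def u_stat(a, b):
                return sum(ai > bj for ai in a for bj in b)

            observed = u_stat(x, y)
            pooled = np.concatenate([x, y])
            us = [
                u_stat(pooled[list(c)], np.delete(pooled, list(c)))
                for c in itertools.combinations(range(n1 + n2), n1)
            ]
            mean_u = n1 * n2 / 2
            extreme = sum(abs(u - mean_u) >= abs(observed - mean_u) for u in us)
            oracle = extreme / len(us)
            assert rank_sum_p(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_clonotype_fraction_test_detects_depletion(self):
        rng = np.random.default_rng(21)
        rows = []
        for c in range(10):
            frac = 0.02 if c < 5 else 0.15
            group = "HAND1" if c < 5 else "NTC"
            hits = rng.binomial(200, frac)
            rows += [(f"c{c}", group, "lpm")] * hits
            rows += [(f"c{c}", group, "other")] * (200 - hits)
        cells = pd.DataFrame(rows, columns=["clonotype", "group", "cell_type"])
        p, x, y = clonotype_fraction_test(cells, "HAND1", "NTC", "lpm")
        assert p < 0.05
        assert len(x) == 5 and len(y) == 5

    def test_fraction_test_requires_two_clonotypes(self):
        cells = pd.DataFrame(
            {"clonotype": ["c1", "c2", "c3"], "group": ["T", "N", "N"],
             "cell_type": ["a", "a", "b"]}
        )
        with pytest.raises(ValueError):
            clonotype_fraction_test(cells, "T", "N", "a")


class TestPseudobulkDECompare:
    def _dataset(self, shift_clonotypes, seed=22, n_genes=60, cells_per_clono=60):
        """8 target + 8 NTC clonotypes; gene 0 shifted in given clonotypes.

        With 8v8 clonotypes the exact rank-sum floor (2/12870) survives a
        Benjamini-Hochberg correction over 60 genes; fewer replicates
        cannot reach significance at all, which is the method's point.
        """
        rng = np.random.default_rng(seed)
        clono, group, mats = [], [], []
        for c in range(16):
            g = "T" if c < 8 else "N"
            base = rng.poisson(5.0, size=(cells_per_clono, n_genes))
            if f"c{c}" in shift_clonotypes:
                base[:, 0] += rng.poisson(25.0, size=cells_per_clono)
            mats.append(base)
            clono += [f"c{c}"] * cells_per_clono
            group += [g] * cells_per_clono
        return np.vstack(mats), np.array(clono), np.array(group)

    def test_consistent_shift_called_in_both_tracks(self):
        mat, clono, group = self._dataset({f"c{i}" for i in range(8)})
        res = pseudobulk_de_compare(
            mat, clonotypes=clono, groups=group, target_id="T", ntc_id="N"
        )
        assert "gene0" in res.single_cell_calls
        assert "gene0" in res.clonotype_calls
        assert res.unsupported_fraction is not None
        assert "gene0" not in set(res.single_cell_calls) - set(res.clonotype_calls)

    def test_minority_clonotype_shift_is_unsupported(self):
        # a "jackpot" signal carried by 2 of 8 target EBs: plenty of cells,
        # too few biological replicates
        mat, clono, group = self._dataset({"c0", "c1"})
        res = pseudobulk_de_compare(
            mat, clonotypes=clono, groups=group, target_id="T", ntc_id="N"
        )
        assert "gene0" in res.single_cell_calls
        assert "gene0" not in res.clonotype_calls
        assert res.unsupported_fraction > 0

    def test_null_data_produces_no_calls(self):
        mat, clono, group = self._dataset(set())
        res = pseudobulk_de_compare(
            mat, clonotypes=clono, groups=group, target_id="T", ntc_id="N"
        )
        assert len(res.single_cell_calls) <= 1
        assert res.unsupported_fraction is None or len(res.single_cell_calls) > 0


class TestPcaEmbedding:
    def test_separates_two_expression_programs(self):
        rng = np.random.default_rng(23)
        a = rng.poisson(2.0, size=(80, 100))
        b = rng.poisson(2.0, size=(80, 100))
        b[:, :10] += rng.poisson(20.0, size=(80, 10))
        emb = pca_embedding(np.vstack([a, b]), n_components=5)
        assert emb.shape == (160, 5)
        labels = np.array(["A"] * 80 + ["B"] * 80)
        res = knn_enrichment(emb, labels, k=10, min_target_cells=10, seed=0)
        assert (res.scores.score > 0.9).all()
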