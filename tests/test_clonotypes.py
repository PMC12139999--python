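import numpy as np
import pandas as pd
import pytest

from ebscreen.clonotypes import (
    assign_bcs_to_cells,
    assign_guide_to_clonotype,
    call_clonotypes,
    correct_barcodes,
    deconvolve_clonotypes,
    merge_correlated_bcs,
)
from ebscreen.io_qc import CountsTriplet

from conftest import make_counts


def bc_counts(umi, reads=None, bc_ids=None):
    umi = np.asarray(umi)
    ct = make_counts(umi, reads if reads is not None else umi * 40,
                     classes=["organoid_bc"] * umi.shape[1])
    if bc_ids is not None:
        ct.features["feature_id"] = bc_ids
    return ct


class TestCorrectBarcodes:
    def test_shadow_merges_into_abundant_neighbour(self):
        # AACCGGTTA (low) is Hamming-1 from AACCGGTTT (high)
        umi = np.zeros((100, 2), dtype=int)
        umi[:, 1] = 5
        umi[:5, 0] = 1
        ct = bc_counts(umi, bc_ids=["AACCGGTTA", "AACCGGTTT"])
        out, log = correct_barcodes(ct, min_umi=2, min_reads=2)
        assert list(out.features.feature_id) == ["AACCGGTTT"]
        assert out.umi.sum() == umi.sum()
        assert log.query("action == 'merged'").barcode.tolist() == ["AACCGGTTA"]

    def test_distance_two_pair_unchanged(self):
        umi = np.zeros((100, 2), dtype=int)
        umi[:, 1] = 5
        umi[:50, 0] = 1
        ct = bc_counts(umi, bc_ids=["AACCGGTAA", "AACCGGTTT"])
        out, log = correct_barcodes(ct, min_umi=2, min_reads=2)
        assert out.feature_mask("organoid_bc").sum() == 2
        assert log.empty

    def test_equidistant_parents_left_unmerged(self):
        umi = np.zeros((100, 3), dtype=int)
        umi[:, 0] = 5   # AAAA abundant
        umi[:, 1] = 5   # AATT abundant
        umi[:3, 2] = 1  # AAAT: distance 1 from both
        ct = bc_counts(umi, bc_ids=["AAAA", "AATT", "AAAT"])
        out, log = correct_barcodes(ct, min_umi=2, min_reads=2)
        assert out.feature_mask("organoid_bc").sum() == 3
        assert log.query("action == 'ambiguous'").barcode.tolist() == ["AAAT"]

    def test_floor_filter_is_an_or_rule(self):
        # removed when either UMI or reads fall below their floor
        umi = np.array([[9, 12, 12]])
        reads = np.array([[400, 20, 500]])
        ct = bc_counts(umi, reads, bc_ids=["AAAA", "CCCC", "GGGG"])
        out, log = correct_barcodes(ct, min_umi=10, min_reads=50)
        assert list(out.features.feature_id) == ["GGGG"]
        assert sorted(log.query("action == 'removed'").barcode) == ["AAAA", "CCCC"]

    def test_unequal_lengths_rejected(self):
        ct = bc_counts(np.ones((5, 2), dtype=int) * 20, bc_ids=["AAAA", "AAAAA"])
        with pytest.raises(ValueError):
            correct_barcodes(ct)


class TestAssignBcsToCells:
    def test_read_total_selection_boundary(self):
        umi = np.full((2, 2), 20)
        reads = np.zeros((2, 2), dtype=int)
        reads[:, 0] = 2**14  # total 2**15 -> selected
        reads[:, 1] = 2**14 - 1  # total 2**15 - 2 -> not selected
        reads = np.maximum(reads, umi)
        ct = bc_counts(umi, reads, bc_ids=["AAAA", "CCCC"])
        out = assign_bcs_to_cells(ct)
        assert list(out.columns) == ["AAAA"]

    def test_proportion_and_umi_floors(self):
        # b0: 10 of 30 UMIs -> prop 1/3 >= 0.30, UMI >= 10 -> assigned
        # second cell: 9 + 9 -> below the UMI floor, nothing assigned
        umi = np.array([[10, 20], [9, 9]])
        ct = bc_counts(umi, umi * 2000, bc_ids=["AAAA", "CCCC"])
        out = assign_bcs_to_cells(ct, min_log2_reads=1)
        assert out.loc["c0"].tolist() == [True, True]
        assert out.loc["c1"].tolist() == [False, False]


class TestMergeCorrelatedBcs:
    def test_cooccurring_bcs_merge(self):
        umi = np.zeros((60, 3), dtype=int)
        umi[:30, 0] = 20
        umi[:30, 1] = 40  # proportional to column 0 -> r = 1
        umi[30:, 2] = 25
        ct = bc_counts(umi, umi * 2000, bc_ids=["AAAA", "CCCC", "GGGG"])
        assignments = assign_bcs_to_cells(ct, min_log2_reads=1)
        res = merge_correlated_bcs(ct, assignments)
        assert res.groups["AAAA"] == res.groups["CCCC"]
        assert res.groups["GGGG"] != res.groups["AAAA"]
        assert not res.excluded_cells

    def test_disjoint_bcs_do_not_merge_and_conflicted_cells_drop(self):
        umi = np.zeros((61, 2), dtype=int)
        umi[:30, 0] = 20
        umi[30:60, 1] = 20
        umi[60] = [20, 20]  # one cell carrying both anticorrelated BCs
        ct = bc_counts(umi, umi * 2000, bc_ids=["AAAA", "CCCC"])
        assignments = assign_bcs_to_cells(ct, min_log2_reads=1)
        res = merge_correlated_bcs(ct, assignments)
        assert res.groups["AAAA"] != res.groups["CCCC"]
        assert res.excluded_cells == ["c60"]

    def test_zero_variance_column_logged_not_merged(self):
        umi = np.full((40, 2), 20)  # both BCs in every cell, equal props
        ct = bc_counts(umi, umi * 2000, bc_ids=["AAAA", "CCCC"])
        assignments = assign_bcs_to_cells(ct, min_log2_reads=1)
        res = merge_correlated_bcs(ct, assignments)
        assert set(res.degenerate_bcs) == {"AAAA", "CCCC"}
        assert res.groups["AAAA"] != res.groups["CCCC"]


class TestCallClonotypes:
    def _merge_result(self, sizes):
        from ebscreen.clonotypes import MergeResult

        cells = {}
        groups = {}
        for j, (bc, n) in enumerate(sizes.items()):
            groups[bc] = bc
            for i in range(n):
                cells[f"{bc}_cell{i}"] = bc
        return MergeResult(
            groups=groups,
            cell_groups=pd.Series(cells, dtype=object),
            correlations=pd.DataFrame(),
            excluded_cells=[],
            degenerate_bcs=[],
        )

    def test_min_cells_boundary(self):
        res = self._merge_result({"AAAA": 49, "CCCC": 50})
        cmap = call_clonotypes(res)
        assert len(cmap.clonotypes) == 1
        assert cmap.clonotypes.bcs[0] == ("CCCC",)

    def test_ids_ordered_by_size_then_bc(self):
        res = self._merge_result({"TTTT": 80, "AAAA": 80, "CCCC": 90})
        cmap = call_clonotypes(res)
        assert [b[0] for b in cmap.clonotypes.bcs] == ["CCCC", "AAAA", "TTTT"]

    def test_partition_of_assigned_cells(self):
        res = self._merge_result({"AAAA": 60, "CCCC": 70})
        cmap = call_clonotypes(res)
        counts = cmap.cell_assignments.value_counts()
        assert counts.sum() == 130 and counts.nunique() == 2


class TestGuideAssignment:
    def _clonotype_with_props(self, guide_umis):
        """One clonotype of len(guide_umis) cells over 3 guide features."""
        from ebscreen.clonotypes import ClonotypeMap

        umi = np.array(guide_umis)
        ct = make_counts(umi, umi * 10, classes=["guide"] * umi.shape[1])
        cmap = ClonotypeMap(
            clonotypes=pd.DataFrame(
                {"clonotype_id": ["clonotype001"], "bcs": [("AAAA",)],
                 "n_cells": [umi.shape[0]]}
            ),
            cell_assignments=pd.Series(
                {f"c{i}": "clonotype001" for i in range(umi.shape[0])}, dtype=object
            ),
        )
        return cmap, ct

    def test_unique_assignment_above_threshold(self):
        cmap, ct = self._clonotype_with_props([[75, 25, 0]] * 12)
        out = assign_guide_to_clonotype(cmap, ct)
        call = out.guide_calls.iloc[0]
        assert call.call_class == "unique" and call.guide_call == ("f0",)

    def test_double_assignment_keeps_top_two(self):
        cmap, ct = self._clonotype_with_props([[50, 40, 10]] * 12)
        out = assign_guide_to_clonotype(cmap, ct)
        call = out.guide_calls.iloc[0]
        assert call.call_class == "double" and call.guide_call == ("f0", "f1")

    def test_too_few_eligible_cells_discards(self):
        cmap, ct = self._clonotype_with_props([[75, 25, 0]] * 9)
        out = assign_guide_to_clonotype(cmap, ct)
        assert out.guide_calls.iloc[0].call_class == "discarded"

    def test_umi_floor_defines_eligibility(self):
        rows = [[75, 25, 0]] * 10 + [[3, 1, 0]] * 5  # 5 cells below the floor
        cmap, ct = self._clonotype_with_props(rows)
        out = assign_guide_to_clonotype(cmap, ct)
        assert out.guide_calls.iloc[0].call_class == "unique"


class TestPipelineOnSimulation:
    def test_determinism_and_stable_ids(self, mono_sim):
        _, _, counts, _ = mono_sim
        a = deconvolve_clonotypes(counts, min_cells=30)
        b = deconvolve_clonotypes(counts, min_cells=30)
        pd.testing.assert_frame_equal(a.clonotypes, b.clonotypes)
        pd.testing.assert_series_equal(a.cell_assignments, b.cell_assignments)

    def test_clonotypes_partition_assigned_cells(self, mono_sim):
        _, _, counts, _ = mono_sim
        cmap = deconvolve_clonotypes(counts, min_cells=30)
        assert cmap.cell_assignments.index.is_unique
        sizes = cmap.cell_assignments.value_counts()
        expected = cmap.clonotypes.set_index("clonotype_id").n_cells
        pd.testing.assert_series_equal(
            sizes.sort_index(), expected.sort_index(), check_names=False
        )


class TestPrintedWorkedExample:
    def test_26_barcodes_with_4_merges_and_2_small_groups_yield_20(self):
        """26 selected BCs; pairs (1,21),(3,24),(5,22),(20,26) co-occur in
        double-integrant EBs and merge; BCs 23 and 25 fall below the 50-cell
        floor; everything else forms its own clonotype -> 20 clonotypes."""
        rng = np.random.default_rng(42)
        pairs = [(1, 21), (3, 24), (5, 22), (20, 26)]
        paired = {a for p in pairs for a in p}
        small = {23, 25}
        alphabet = np.array(list("ACGT"))
        bc_ids = ["".join(rng.choice(alphabet, size=10)) for _ in range(26)]

        blocks = []
        owners = []  # list of BC column indices per cell
        for bc in range(1, 27):
            if bc in {b for _, b in pairs}:
                continue  # generated together with its partner
            n_cells = 30 if bc in small else 60
            partner = dict(pairs).get(bc)
            for _ in range(n_cells):
                owners.append((bc - 1, None if partner is None else partner - 1))
        umi = np.zeros((len(owners), 26), dtype=int)
        for i, (a, b) in enumerate(owners):
            umi[i, a] = rng.integers(25, 45)
            if b is not None:
                umi[i, b] = rng.integers(25, 45)
        ct = make_counts(umi, umi * 60, classes=["organoid_bc"] * 26)
        ct.features["feature_id"] = bc_ids

        cmap = deconvolve_clonotypes(
            ct, min_log2_reads=np.log2(umi.sum(0).min() * 60) - 1
        )
        assert len(cmap.clonotypes) == 20
        merged_sets = {frozenset(b) for b in cmap.clonotypes.bcs if len(b) > 1}
        expected = {
            frozenset({bc_ids[a - 1], bc_ids[b - 1]}) for a, b in pairs
        }
        assert merged_sets == expected
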