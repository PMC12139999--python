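"""End-to-end study designs: confounding, rescue, calibration, recovery, power.

Each function here wires the simulator to the analysis pipeline under a
fixed study design and returns summary metrics.  They are the package's
reference experiments — the tests and the reproduction script both run
them — and their parameters are the study conditions, not tuning knobs:

- ``mosaic_confounding``: an effect-free 125-target mosaic screen in the
  jackpot regime, run twice.  Demonstrates the central confounder: naive
  chi-square significance is massively inflated and the screen's flagged
  sets are irreproducible between replicates, even though aggregate guide
  frequencies correlate tightly.
- ``monoclonal_rescue``: the effect-free monoclonal counterpart with
  organoid-BC clonotype deconvolution and the clonotype-resampled
  empirical null, whose flagged fraction is calibrated at q.
- ``null_calibration``: the screen test on label-permuted (iid) data with
  a deep NTC-group null; flagged fraction matches q within binomial error.
- ``clonotype_recovery``: a default-noise monoclonal simulation with
  multi-integrant founders, checking that deconvolution recovers EB
  identity, merges multi-integrant barcodes, and that barcode-prefix
  guide calls agree with directly captured guides.
- ``fraction_test_power``: a Hand1-like lateral-plate-mesoderm depletion
  (0.25x) tested per clonotype with the rank-sum test across many seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bottleneck import clonal_complexity
from .clonotypes import bc_guide_lookup_call, deconvolve_clonotypes
from .compstats import (
    clonotype_fraction_test,
    screen_composition,
    screen_composition_clonal,
)
from .guides import assign_guides, resolve_multi_guides
from .io_qc import LookupTable
from .simdata import (
    DEFAULT_BASELINE,
    LibraryDesign,
    ScreenConfig,
    simulate_monoclonal_screen,
    simulate_mosaic_screen,
)

__all__ = [
    "mosaic_confounding",
    "monoclonal_rescue",
    "null_calibration",
    "clonotype_recovery",
    "fraction_test_power",
    "binomial_acceptance_interval",
]


def _subseed(seed: int, k: int) -> int:
    """Derive independent child seeds below 2**31 from one master seed."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def binomial_acceptance_interval(n: int, q: float = 0.05) -> tuple[float, float]:
    """Central 95% interval of Binomial(n, q), as fractions."""
    lo = stats.binom.ppf(0.025, n, q) / n
    hi = stats.binom.ppf(0.975, n, q) / n
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# mosaic confounding
# ---------------------------------------------------------------------------

def _assigned_cells_table(lib: LibraryDesign, counts, truth) -> pd.DataFrame:
    """Guide-call the simulated counts and join the true cell types."""
    ntc = set(lib.ntc_guides)
    calls = resolve_multi_guides(
        assign_guides(counts, "alltf", ntc), "alltf_keep", ntc
    )
    t2g = dict(zip(lib.guides["guide_id"], lib.guides["target_id"]))
    truth_types = dict(zip(truth.cells["cell_id"], truth.cells["cell_type"]))
    rows = [
        (t2g[g], g, g in ntc, truth_types[cell])
        for cell, gset, status in calls.table.itertuples(index=False)
        if status != "unassigned"
        for g in gset
    ]
    return pd.DataFrame(rows, columns=["target", "guide", "is_ntc", "cell_type"])


def _mosaic_library(seed: int) -> LibraryDesign:
    return LibraryDesign.build(125, frequency_sigma=1.6, seed=_subseed(seed, 101))


def _mosaic_config(seed: int) -> ScreenConfig:
    return ScreenConfig(
        n_ebs=400,
        design="mosaic",
        founders_per_eb=500,
        clone_concentration=0.005,
        capture_cells_per_eb=220,
        detection_prob=0.75,
        eb_heterogeneity=30.0,
        seed=seed,
    )


@dataclass
class MosaicConfoundingResult:
    naive_flag_fractions: tuple[float, float]
    empirical_flag_fractions: tuple[float, float]
    flag_jaccard: float
    guide_frequency_r: float
    median_dominance: float
    median_distinct_guides: float
    founders_per_eb: int
    n_targets_tested: int
    dominant_guide_agreement: float  # share of EB ranks whose top guide matches


def mosaic_confounding(seed: int = 0) -> MosaicConfoundingResult:
    """Run the effect-free jackpot-regime mosaic screen twice and compare."""
    lib = _mosaic_library(seed)
    results, aggregates, top_guides = [], [], []
    doms, dists = [], []
    for k in (1, 2):
        cfg = _mosaic_config(_subseed(seed, k))
        counts, truth = simulate_mosaic_screen(lib, cfg)
        cells = _assigned_cells_table(lib, counts, truth)
        results.append(screen_composition(cells, seed=_subseed(seed, 10 + k)))
        eb_guides = truth.eb_guide_abundance()
        aggregates.append(eb_guides.groupby("guide_id")["n_cells"].sum())
        tops = []
        for _, sub in eb_guides.groupby("eb_id"):
            per_guide = sub.set_index("guide_id")["n_cells"]
            rep = clonal_complexity(per_guide)
            doms.append(rep.dominance)
            dists.append(rep.n_distinct)
            tops.append(per_guide.sort_index().sort_values(ascending=False, kind="stable").index[0])
        top_guides.append(tops)

    naive = tuple(float((r.targets["p"] < r.q).mean()) for r in results)
    empirical = tuple(r.flagged_fraction for r in results)
    f1, f2 = results[0].flagged_targets, results[1].flagged_targets
    jaccard = len(f1 & f2) / max(1, len(f1 | f2))
    both = pd.concat(aggregates, axis=1).fillna(0.0)
    r = float(np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1])
    n_pairs = min(len(top_guides[0]), len(top_guides[1]))
    agreement = float(
        np.mean([top_guides[0][i] == top_guides[1][i] for i in range(n_pairs)])
    )
    return MosaicConfoundingResult(
        naive_flag_fractions=naive,
        empirical_flag_fractions=empirical,
        flag_jaccard=float(jaccard),
        guide_frequency_r=r,
        median_dominance=float(np.median(doms)),
        median_distinct_guides=float(np.median(dists)),
        founders_per_eb=500,
        n_targets_tested=len(results[0].targets),
        dominant_guide_agreement=agreement,
    )


# ---------------------------------------------------------------------------
# monoclonal rescue
# ---------------------------------------------------------------------------

def _rescue_library(seed: int) -> LibraryDesign:
    return LibraryDesign.build(40, frequency_sigma=0.3, seed=_subseed(seed, 201))


@dataclass
class MonoclonalRescueResult:
    flagged: int
    n_tested: int
    flagged_fraction: float
    acceptance_interval: tuple[float, float]
    per_replicate: list[float]


def monoclonal_rescue(seed: int = 0, n_replicates: int = 4) -> MonoclonalRescueResult:
    """Effect-free monoclonal screens tested with the clonotype-aware null."""
    lib = _rescue_library(seed)
    lookup = LookupTable(mapping=lib.prefix_lookup(), provenance="predefined")
    t2g = dict(zip(lib.guides["guide_id"], lib.guides["target_id"]))

    flagged = tested = 0
    per_rep = []
    for k in range(n_replicates):
        cfg = ScreenConfig(
            n_ebs=350,
            design="monoclonal",
            capture_cells_per_eb=150,
            detection_prob=0.9,
            multi_integrant_prob=0.02,
            eb_heterogeneity=30.0,
            seed=_subseed(seed, 300 + k),
        )
        counts, truth = simulate_monoclonal_screen(lib, cfg)
        cmap = deconvolve_clonotypes(counts)
        bc_calls = bc_guide_lookup_call(cmap, lookup)
        clono_target = {}
        for cid, guides in bc_calls.items():
            targets = {t2g[g] for g in guides}
            if len(targets) == 1:
                clono_target[cid] = targets.pop()
        truth_types = dict(zip(truth.cells["cell_id"], truth.cells["cell_type"]))
        rows = [
            (clono_target[cid], clono_target[cid] == "NTC", cid, truth_types[cell])
            for cell, cid in cmap.cell_assignments.items()
            if cid in clono_target
        ]
        cells = pd.DataFrame(rows, columns=["target", "is_ntc", "clonotype", "cell_type"])
        res = screen_composition_clonal(
            cells, n_null_groups=500, seed=_subseed(seed, 400 + k)
        )
        flagged += int(res.targets["flagged"].sum())
        tested += len(res.targets)
        per_rep.append(res.flagged_fraction)

    return MonoclonalRescueResult(
        flagged=flagged,
        n_tested=tested,
        flagged_fraction=flagged / tested,
        acceptance_interval=binomial_acceptance_interval(tested),
        per_replicate=per_rep,
    )


# ---------------------------------------------------------------------------
# iid null calibration
# ---------------------------------------------------------------------------

@dataclass
class NullCalibrationResult:
    flagged: int
    n_tested: int
    flagged_fraction: float
    acceptance_interval: tuple[float, float]


def null_calibration(
    seed: int = 0,
    n_replicates: int = 20,
    n_targets: int = 40,
    n_ntc_guides: int = 1200,
    cells_per_guide: int = 100,
) -> NullCalibrationResult:
    """Screen test on label-permuted data: cell types iid of the labels.

    Each replicate draws every unit's cells from the same multinomial over
    cell types (equivalent to permuting labels), then runs the full
    empirical-null screen with a deep NTC null (n_ntc_guides / 3 groups).
    """
    base = np.asarray(DEFAULT_BASELINE)
    types = np.asarray([f"ct{i}" for i in range(len(base))], object)
    flagged = tested = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(_subseed(seed, 500 + rep))
        frames = []
        for t in range(n_targets):
            for g in range(3):
                ct = types[rng.choice(len(base), size=cells_per_guide, p=base)]
                frames.append(
                    pd.DataFrame(
                        {"target": f"T{t}", "guide": f"T{t}_g{g}",
                         "is_ntc": False, "cell_type": ct}
                    )
                )
        for g in range(n_ntc_guides):
            ct = types[rng.choice(len(base), size=cells_per_guide, p=base)]
            frames.append(
                pd.DataFrame(
                    {"target": "NTC", "guide": f"N{g}", "is_ntc": True, "cell_type": ct}
                )
            )
        res = screen_composition(
            pd.concat(frames, ignore_index=True), seed=_subseed(seed, 600 + rep)
        )
        flagged += int(res.targets["flagged"].sum())
        tested += len(res.targets)
    return NullCalibrationResult(
        flagged=flagged,
        n_tested=tested,
        flagged_fraction=flagged / tested,
        acceptance_interval=binomial_acceptance_interval(tested),
    )


# ---------------------------------------------------------------------------
# clonotype recovery
# ---------------------------------------------------------------------------

@dataclass
class ClonotypeRecoveryResult:
    n_ebs: int
    n_clonotypes: int
    cell_eb_accuracy: float
    guide_concordance: float
    n_multi_integrant_ebs: int
    n_multi_integrant_merged: int


def clonotype_recovery(seed: int = 0, n_ebs: int = 150) -> ClonotypeRecoveryResult:
    """Default-noise monoclonal simulation -> deconvolution -> fidelity."""
    lib = LibraryDesign.build(9, frequency_sigma=0.3, seed=_subseed(seed, 701))
    cfg = ScreenConfig(
        n_ebs=n_ebs,
        design="monoclonal",
        capture_cells_per_eb=120,
        detection_prob=0.9,
        multi_integrant_prob=0.04,
        seed=_subseed(seed, 702),
    )
    counts, truth = simulate_monoclonal_screen(lib, cfg)
    cmap = deconvolve_clonotypes(counts)

    truth_eb = dict(zip(truth.cells["cell_id"], truth.cells["eb_id"]))
    assigned = cmap.cell_assignments
    df = pd.DataFrame({"clono": assigned.values}, index=assigned.index)
    df["true_eb"] = [truth_eb[c] for c in df.index]
    majority = df.groupby("clono")["true_eb"].agg(lambda s: s.mode().iloc[0])
    accuracy = float((df["true_eb"] == df["clono"].map(majority)).mean())

    lookup = LookupTable(mapping=lib.prefix_lookup(), provenance="predefined")
    bc_calls = bc_guide_lookup_call(cmap, lookup)
    gc = cmap.guide_calls.set_index("clonotype_id")
    concordant = total = 0
    for cid, bcg in bc_calls.items():
        if gc.loc[cid, "call_class"] == "discarded" or not bcg:
            continue
        total += 1
        concordant += bool(set(gc.loc[cid, "guide_call"]) & set(bcg))

    multi = truth.cells.loc[
        truth.cells["organoid_bc"].str.contains(","), ["eb_id", "organoid_bc"]
    ].drop_duplicates()
    merged = 0
    clono_bc_sets = [set(b) for b in cmap.clonotypes["bcs"]]
    for _, row in multi.iterrows():
        pair = set(row["organoid_bc"].split(","))
        merged += any(pair <= s for s in clono_bc_sets)

    return ClonotypeRecoveryResult(
        n_ebs=n_ebs,
        n_clonotypes=len(cmap.clonotypes),
        cell_eb_accuracy=accuracy,
        guide_concordance=concordant / max(1, total),
        n_multi_integrant_ebs=len(multi),
        n_multi_integrant_merged=merged,
    )


# ---------------------------------------------------------------------------
# fraction-test power
# ---------------------------------------------------------------------------

@dataclass
class FractionTestPowerResult:
    power: float
    n_seeds: int
    min_target_clonotypes: int
    min_ntc_clonotypes: int


def fraction_test_power(
    seed: int = 0,
    n_seeds: int = 50,
    n_ebs: int = 28,
    multiplier: float = 0.25,
) -> FractionTestPowerResult:
    """Detection rate of a Hand1-like lateral-plate-mesoderm depletion.

    One target (three guides) against NTCs at 50:50, ~14 monoclonal EBs
    per arm, per-clonotype fraction of lateral plate mesoderm compared by
    the two-sided rank-sum test at alpha=0.05.
    """
    lib = LibraryDesign.build(1, target_ntc_ratio=(0.5, 0.5), seed=_subseed(seed, 801))
    hits = 0
    min_t, min_n = n_ebs, n_ebs
    for k in range(n_seeds):
        cfg = ScreenConfig(
            n_ebs=n_ebs,
            design="monoclonal",
            capture_cells_per_eb=150,
            detection_prob=0.9,
            eb_heterogeneity=30.0,
            effects={"TF0001": {"lateral_plate_mesoderm": multiplier}},
            seed=_subseed(seed, 900 + k),
        )
        _, truth = simulate_monoclonal_screen(lib, cfg)
        cells = truth.cells.copy()
        cells["group"] = np.where(
            cells["guide_id"].str.startswith("TF"), "TF0001", "NTC"
        )
        cells["clonotype"] = cells["eb_id"]
        n_t = cells.loc[cells["group"] == "TF0001", "eb_id"].nunique()
        n_n = cells.loc[cells["group"] == "NTC", "eb_id"].nunique()
        min_t, min_n = min(min_t, n_t), min(min_n, n_n)
        try:
            p, _, _ = clonotype_fraction_test(
                cells, "TF0001", "NTC", "lateral_plate_mesoderm"
            )
        except ValueError:
            continue
        hits += p < 0.05
    return FractionTestPowerResult(
        power=hits / n_seeds,
        n_seeds=n_seeds,
        min_target_clonotypes=min_t,
        min_ntc_clonotypes=min_n,
    )
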