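"""Synthetic embryoid-body (EB) screen generator.

This module emulates the data-generating process of pooled CRISPR screens
in EBs under the two designs the analysis pipeline has to distinguish:

``mosaic``
    Each EB is founded by a few hundred guide-bearing mouse ES cells and
    grows to 10,000-30,000 cells.  Founder clones do not contribute
    uniformly: clone sizes are drawn from a symmetric Dirichlet whose
    concentration is far below one, reproducing the stochastic clonal
    "jackpotting" seen in hand-picked EBs, where a handful of clones sit
    two to three orders of magnitude above the rest and fewer than a
    hundred distinct guides are detectable per EB.

``monoclonal``
    Each EB derives from a single founder cell carrying one guide and one
    expressed organoid barcode (an 8-symbol guide-identifying prefix plus
    a random 9-symbol EB-identifying suffix), so every cell of the EB
    shares the same perturbation and barcode.  A small fraction of
    founders may carry two integrants (two guide/barcode pairs present in
    every descendant).

On top of clonal structure the generator models per-EB heterogeneity of
cell-type composition (Dirichlet around a baseline), perturbation effects
as per-cell-type multiplicative tilts of that composition,
cell-type-dependent all-or-none silencing of the construct, overdispersed
guide/barcode UMI counts with amplification reads per UMI, and ambient
(floating-cell) contamination that deposits single foreign-feature UMIs.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_qc import CountsTriplet

__all__ = [
    "LibraryDesign",
    "ScreenConfig",
    "SimTruth",
    "poisson_single_integration",
    "simulate_mosaic_screen",
    "simulate_monoclonal_screen",
    "embed_cells",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_BASELINE",
]

_ALPHABET = np.array(list("ACGT"))

# A 12-type caricature of day-21 EB lineages spanning the three germ layers.
DEFAULT_CELL_TYPES = (
    "epiblast",
    "primitive_streak",
    "naive_pluripotent",
    "neuroectoderm",
    "neural_crest",
    "definitive_endoderm",
    "parietal_endoderm",
    "visceral_endoderm",
    "lateral_plate_mesoderm",
    "paraxial_mesoderm",
    "cardiomyocyte",
    "blood_progenitor",
)

DEFAULT_BASELINE = (
    0.14, 0.10, 0.06, 0.12, 0.05, 0.08, 0.09, 0.06, 0.10, 0.09, 0.06, 0.05,
)

# Lentiviral constructs silence preferentially in differentiated lineages;
# detection probabilities mimic the GFP+ gradient across cell states.
DEFAULT_DETECTION_MOSAIC = {
    "epiblast": 0.90,
    "primitive_streak": 0.85,
    "naive_pluripotent": 0.90,
    "neuroectoderm": 0.65,
    "neural_crest": 0.60,
    "definitive_endoderm": 0.60,
    "parietal_endoderm": 0.55,
    "visceral_endoderm": 0.55,
    "lateral_plate_mesoderm": 0.60,
    "paraxial_mesoderm": 0.60,
    "cardiomyocyte": 0.50,
    "blood_progenitor": 0.55,
}


# ---------------------------------------------------------------------------
# Transduction model
# ---------------------------------------------------------------------------

def poisson_single_integration(p: float) -> float:
    """Fraction of construct-positive cells carrying exactly one integration.

    Under an idealised Poisson model of lentiviral integrations, titrating
    the virus so that a fraction ``p`` of cells is positive (at least one
    integration) implies a rate ``lam = -ln(1 - p)``.  Among positive
    cells, the single-integration fraction is ``lam e^-lam / (1 - e^-lam)``,
    which simplifies to ``lam (1 - p) / p``.  At ``p = 0.10`` this is
    ~0.95, the usual justification for low-MOI transduction.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"positive fraction must lie in (0, 1), got {p}")
    lam = -np.log1p(-p)
    return float(lam * (1.0 - p) / p)


# ---------------------------------------------------------------------------
# Library and configuration
# ---------------------------------------------------------------------------

@dataclass
class LibraryDesign:
    """A guide library: targeting guides plus non-targeting controls (NTCs).

    ``guides`` has one row per guide with columns ``guide_id``,
    ``target_id``, ``is_ntc``, ``prefix`` (the fixed 8-symbol barcode
    prefix unequivocally identifying the guide) and ``frequency`` (the
    guide's relative abundance in the plasmid/cell pool; sums to 1).
    """

    guides: pd.DataFrame
    guides_per_target: int = 3
    target_ntc_ratio: tuple[float, float] = (0.8, 0.2)

    def __post_init__(self) -> None:
        g = self.guides
        if g["guide_id"].duplicated().any():
            raise ValueError("duplicate guide ids")
        if g["prefix"].duplicated().any():
            raise ValueError("fixed barcode prefixes must be distinct across guides")
        per_target = g.loc[~g["is_ntc"]].groupby("target_id").size()
        if len(per_target) and not (per_target == self.guides_per_target).all():
            raise ValueError(
                f"every target must carry exactly {self.guides_per_target} guides"
            )
        freq = g["frequency"].to_numpy(float)
        if not np.isclose(freq.sum(), 1.0):
            raise ValueError("guide frequencies must sum to 1")

    @property
    def n_guides(self) -> int:
        return len(self.guides)

    @property
    def targets(self) -> list[str]:
        return sorted(self.guides.loc[~self.guides["is_ntc"], "target_id"].unique())

    @property
    def ntc_guides(self) -> list[str]:
        return list(self.guides.loc[self.guides["is_ntc"], "guide_id"])

    def prefix_lookup(self) -> dict[str, str]:
        """Fixed-prefix -> guide map (the 'predefined' lookup table)."""
        return dict(zip(self.guides["prefix"], self.guides["guide_id"]))

    @classmethod
    def build(
        cls,
        n_targets: int,
        guides_per_target: int = 3,
        target_ntc_ratio: tuple[float, float] = (0.8, 0.2),
        frequency_sigma: float = 0.0,
        seed: int = 0,
        prefix_length: int = 8,
    ) -> "LibraryDesign":
        """Construct a library with an 80:20 targeting:NTC guide mix.

        ``frequency_sigma`` is the log-normal spread of guide representation
        (0 means perfectly even).  Real cloned libraries span two to three
        orders of magnitude between their most and least represented
        guides; a sigma around 1.5 reproduces that span.
        """
        rng = np.random.default_rng(seed)
        n_targeting = n_targets * guides_per_target
        share_t, share_n = target_ntc_ratio
        n_ntc = int(round(n_targeting * share_n / share_t))
        records = []
        for t in range(n_targets):
            target = f"TF{t + 1:04d}"
            for k in range(guides_per_target):
                records.append((f"{target}_g{k + 1}", target, False))
        for k in range(n_ntc):
            records.append((f"NTC_g{k + 1:04d}", "NTC", True))
        guides = pd.DataFrame(records, columns=["guide_id", "target_id", "is_ntc"])

        prefixes: set[str] = set()
        out_prefixes = []
        while len(out_prefixes) < len(guides):
            cand = "".join(rng.choice(_ALPHABET, size=prefix_length))
            if cand not in prefixes:
                prefixes.add(cand)
                out_prefixes.append(cand)
        guides["prefix"] = out_prefixes

        if frequency_sigma > 0:
            w = np.exp(rng.normal(0.0, frequency_sigma, size=len(guides)))
        else:
            w = np.ones(len(guides))
        guides["frequency"] = w / w.sum()
        return cls(
            guides=guides,
            guides_per_target=guides_per_target,
            target_ntc_ratio=target_ntc_ratio,
        )


@dataclass
class CountModel:
    """Noise model for guide / organoid-BC capture.

    UMI counts per expressed construct are negative binomial
    (``mean``, ``dispersion`` = NB size; smaller means noisier).  Each UMI
    is amplified into a geometric number of reads with the given mean
    (enrichment PCR sequencing is deep, so the default is 20 reads/UMI).
    With probability ``ambient_rate`` a cell additionally picks up a single
    UMI of one random foreign feature, the floating-cell artifact the 1%
    prevalence filter is aimed at.
    """

    guide_umi_mean: float = 15.0
    bc_umi_mean: float = 30.0
    dispersion: float = 2.0
    reads_per_umi: float = 20.0
    ambient_rate: float = 0.02


@dataclass
class ScreenConfig:
    """All knobs of one simulated screen.  See module docstring for context."""

    n_ebs: int = 150
    design: str = "mosaic"  # or "monoclonal"
    founders_per_eb: int = 300
    cells_per_eb: tuple[int, int] = (10_000, 30_000)
    # Symmetric Dirichlet concentration over founder clones.  The product
    # founders_per_eb * clone_concentration sets the effective number of
    # surviving clones; 300 * 0.005 = 1.5 lands in the reported regime of
    # 2-10 clones covering 90% of an EB.
    clone_concentration: float = 0.005
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    baseline_composition: tuple[float, ...] = DEFAULT_BASELINE
    # Per-EB compositions are Dirichlet(eb_heterogeneity * baseline): 30
    # gives the visibly unequal composition bars seen across individual EBs.
    eb_heterogeneity: float = 30.0
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    detection_prob: Mapping[str, float] | float = 0.9
    capture_cells_per_eb: int = 150
    count_model: CountModel = field(default_factory=CountModel)
    multi_integrant_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("mosaic", "monoclonal"):
            raise ValueError(f"unknown design {self.design!r}")
        base = np.asarray(self.baseline_composition, float)
        if len(base) != len(self.cell_types):
            raise ValueError("baseline_composition and cell_types length mismatch")
        if not np.isclose(base.sum(), 1.0):
            raise ValueError("baseline_composition must sum to 1")
        if self.clone_concentration <= 0 or self.eb_heterogeneity <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        for target, mult in self.effects.items():
            for ct, m in mult.items():
                if m <= 0:
                    raise ValueError(f"effect multiplier for {target}/{ct} must be > 0")
                if ct not in self.cell_types:
                    raise ValueError(f"effect refers to unknown cell type {ct!r}")
        probs = self._detection_vector()
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("detection probabilities must lie in [0, 1]")

    def _detection_vector(self) -> np.ndarray:
        if isinstance(self.detection_prob, Mapping):
            return np.array(
                [self.detection_prob.get(ct, 1.0) for ct in self.cell_types], float
            )
        return np.full(len(self.cell_types), float(self.detection_prob))

    def to_yaml(self, path: str) -> None:
        payload = {
            "n_ebs": self.n_ebs,
            "design": self.design,
            "founders_per_eb": self.founders_per_eb,
            "cells_per_eb": list(self.cells_per_eb),
            "clone_concentration": self.clone_concentration,
            "cell_types": list(self.cell_types),
            "baseline_composition": [float(x) for x in self.baseline_composition],
            "eb_heterogeneity": self.eb_heterogeneity,
            "effects": self.effects,
            "detection_prob": (
                dict(self.detection_prob)
                if isinstance(self.detection_prob, Mapping)
                else self.detection_prob
            ),
            "capture_cells_per_eb": self.capture_cells_per_eb,
            "count_model": vars(self.count_model),
            "multi_integrant_prob": self.multi_integrant_prob,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ScreenConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["cells_per_eb"] = tuple(payload["cells_per_eb"])
        payload["cell_types"] = tuple(payload["cell_types"])
        payload["baseline_composition"] = tuple(payload["baseline_composition"])
        payload["count_model"] = CountModel(**payload["count_model"])
        return cls(**payload)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated counts.

    ``cells``: one row per captured cell (cell_id, eb_id, clone_id,
    guide_id, organoid_bc, cell_type, silenced).  For multi-integrant
    monoclonal founders, guide_id/organoid_bc are comma-joined pairs.

    ``founders``: one row per founder clone per EB with its true final
    cell count (the whole EB, not just captured cells) — the basis for
    clonal-complexity ground truth.
    """

    cells: pd.DataFrame
    founders: pd.DataFrame

    def eb_guide_abundance(self) -> pd.DataFrame:
        """Per-EB per-guide true cell counts (long format)."""
        out = (
            self.founders.groupby(["eb_id", "guide_id"], sort=True)["n_cells"]
            .sum()
            .reset_index()
        )
        return out[out["n_cells"] > 0]

    def to_tsv(self, path: str) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Internal draws
# ---------------------------------------------------------------------------

def _nb_counts(rng, mean: float, size_param: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n).astype(np.int64)


def _reads_from_umis(rng, umis: np.ndarray, reads_per_umi: float) -> np.ndarray:
    """Total reads = sum over UMIs of a geometric (support >= 1) read count."""
    reads = np.zeros_like(umis)
    pos = umis > 0
    if pos.any():
        # sum of u geometric(mean m) variables = u + NB(u, 1/m) failures
        reads[pos] = umis[pos] + rng.negative_binomial(
            umis[pos], 1.0 / reads_per_umi
        )
    return reads


def _tilt(theta: np.ndarray, multipliers: np.ndarray) -> np.ndarray:
    tilted = theta * multipliers
    return tilted / tilted.sum()


def _effect_multipliers(config: ScreenConfig, target_id: str) -> np.ndarray:
    mult = np.ones(len(config.cell_types))
    eff = config.effects.get(target_id)
    if eff:
        for k, ct in enumerate(config.cell_types):
            mult[k] = eff.get(ct, 1.0)
    return mult


def _random_suffixes(rng, n: int, length: int, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(_ALPHABET, size=length))
        if cand not in taken:
            taken.add(cand)
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Mosaic screens
# ---------------------------------------------------------------------------

def simulate_mosaic_screen(
    library: LibraryDesign, config: ScreenConfig
) -> tuple[CountsTriplet, SimTruth]:
    """Simulate a mosaic EB screen; returns guide counts plus ground truth.

    Per EB: founder guides are drawn from the library pool at its
    frequencies, clone proportions from a symmetric
    Dirichlet(clone_concentration), final clone sizes by a multinomial
    over the EB's total cell count, and the captured cells by sampling
    without replacement from the grown EB.  Captured cells get a cell type
    from the EB's tilted composition and guide UMI/read counts from the
    count model, zeroed for silenced cells; ambient contamination then
    deposits single foreign-guide UMIs.
    """
    if config.design != "mosaic":
        raise ValueError("config.design must be 'mosaic'")
    if config.founders_per_eb < 1:
        raise ValueError("founders_per_eb must be >= 1")
    lo, hi = config.cells_per_eb
    if lo < config.founders_per_eb:
        raise ValueError("cells_per_eb must be >= founders_per_eb")

    rng = np.random.default_rng(config.seed)
    guide_ids = library.guides["guide_id"].to_numpy()
    guide_target = library.guides["target_id"].to_numpy()
    freq = library.guides["frequency"].to_numpy(float)
    base = np.asarray(config.baseline_composition, float)
    detect = config._detection_vector()
    cm = config.count_model
    mult_by_guide = np.stack(
        [_effect_multipliers(config, t) for t in guide_target]
    )

    cell_rows: list[pd.DataFrame] = []
    founder_rows: list[pd.DataFrame] = []
    umi_cols: list[np.ndarray] = []
    umi_vals: list[np.ndarray] = []
    read_vals: list[np.ndarray] = []
    cell_offsets: list[int] = []
    n_cells_total = 0

    for eb in range(config.n_ebs):
        eb_id = f"EB{eb + 1:04d}"
        n_cells_eb = int(rng.integers(lo, hi + 1))
        founders = rng.choice(len(guide_ids), size=config.founders_per_eb, p=freq)
        props = rng.dirichlet(
            np.full(config.founders_per_eb, config.clone_concentration)
        )
        # numerical floor: degenerate gamma underflow can zero the simplex
        if not np.isfinite(props).all() or props.sum() <= 0:
            props = np.full(config.founders_per_eb, 1.0 / config.founders_per_eb)
        clone_sizes = rng.multinomial(n_cells_eb, props)
        founder_rows.append(
            pd.DataFrame(
                {
                    "eb_id": eb_id,
                    "clone_id": [
                        f"{eb_id}.c{i + 1}" for i in range(config.founders_per_eb)
                    ],
                    "guide_id": guide_ids[founders],
                    "n_cells": clone_sizes,
                }
            )
        )

        n_capture = min(config.capture_cells_per_eb, n_cells_eb)
        captured = rng.multivariate_hypergeometric(clone_sizes, n_capture)
        clone_idx = np.repeat(np.arange(config.founders_per_eb), captured)
        n_cap = len(clone_idx)
        theta = rng.dirichlet(config.eb_heterogeneity * base)

        cell_guides = founders[clone_idx]
        types = np.empty(n_cap, dtype=np.int64)
        for g in np.unique(cell_guides):
            mask = cell_guides == g
            probs = _tilt(theta, mult_by_guide[g])
            types[mask] = rng.choice(len(base), size=int(mask.sum()), p=probs)

        silenced = rng.random(n_cap) >= detect[types]
        umis = _nb_counts(rng, cm.guide_umi_mean, cm.dispersion, n_cap)
        umis[silenced] = 0
        reads = _reads_from_umis(rng, umis, cm.reads_per_umi)

        cell_rows.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{eb_id}_{i + 1:05d}" for i in range(n_cap)],
                    "eb_id": eb_id,
                    "clone_id": [f"{eb_id}.c{i + 1}" for i in clone_idx],
                    "guide_id": guide_ids[cell_guides],
                    "organoid_bc": "",
                    "cell_type": np.asarray(config.cell_types, object)[types],
                    "silenced": silenced,
                }
            )
        )
        umi_cols.append(cell_guides)
        umi_vals.append(umis)
        read_vals.append(reads)
        cell_offsets.append(n_cells_total)
        n_cells_total += n_cap

    cells = pd.concat(cell_rows, ignore_index=True)
    founders_df = pd.concat(founder_rows, ignore_index=True)

    rows = np.arange(n_cells_total)
    cols = np.concatenate(umi_cols)
    u = np.concatenate(umi_vals)
    r = np.concatenate(read_vals)

    # ambient contamination: one foreign-guide UMI for a random subset of cells
    amb_mask = rng.random(n_cells_total) < cm.ambient_rate
    amb_rows = rows[amb_mask]
    amb_cols = rng.choice(len(guide_ids), size=len(amb_rows), p=freq)
    amb_umi = np.ones(len(amb_rows), dtype=np.int64)
    amb_reads = _reads_from_umis(rng, amb_umi, cm.reads_per_umi)

    shape = (n_cells_total, len(guide_ids))
    umi_mat = sp.coo_matrix(
        (np.concatenate([u, amb_umi]), (np.concatenate([rows, amb_rows]),
                                        np.concatenate([cols, amb_cols]))),
        shape=shape,
    ).tocsr()
    read_mat = sp.coo_matrix(
        (np.concatenate([r, amb_reads]), (np.concatenate([rows, amb_rows]),
                                          np.concatenate([cols, amb_cols]))),
        shape=shape,
    ).tocsr()
    umi_mat.sum_duplicates()
    read_mat.sum_duplicates()

    features = pd.DataFrame(
        {"feature_id": guide_ids, "feature_class": "guide"}
    )
    counts = CountsTriplet(
        cell_ids=cells["cell_id"].to_numpy(object),
        features=features,
        umi=umi_mat,
        reads=read_mat,
    )
    return counts, SimTruth(cells=cells, founders=founders_df)


# ---------------------------------------------------------------------------
# Monoclonal screens
# ---------------------------------------------------------------------------

def simulate_monoclonal_screen(
    library: LibraryDesign, config: ScreenConfig
) -> tuple[CountsTriplet, SimTruth]:
    """Simulate a pooled monoclonal, organoid-barcoded EB screen.

    Every EB descends from one founder carrying one guide and one organoid
    barcode (fixed per-guide 8-mer prefix + random 9-mer suffix); with
    probability ``multi_integrant_prob`` the founder carries two distinct
    guide/barcode pairs, both present in every cell.  Captured cells get
    guide UMI/read counts (direct capture) and organoid-BC UMI/read counts
    (enrichment PCR), both silenced all-or-none per cell, plus ambient
    single-UMI contamination of foreign barcodes and guides.
    """
    if config.design != "monoclonal":
        raise ValueError("config.design must be 'monoclonal'")

    rng = np.random.default_rng(config.seed)
    guide_ids = library.guides["guide_id"].to_numpy()
    guide_target = library.guides["target_id"].to_numpy()
    prefixes = library.guides["prefix"].to_numpy()
    freq = library.guides["frequency"].to_numpy(float)
    base = np.asarray(config.baseline_composition, float)
    detect = config._detection_vector()
    cm = config.count_model
    lo, hi = config.cells_per_eb

    # founders and barcodes for all EBs up front
    taken: set[str] = set()
    eb_guides: list[np.ndarray] = []
    eb_bcs: list[list[str]] = []
    for eb in range(config.n_ebs):
        n_int = 2 if rng.random() < config.multi_integrant_prob else 1
        gs = rng.choice(len(guide_ids), size=n_int, replace=False, p=freq)
        suffixes = _random_suffixes(rng, n_int, 9, taken)
        eb_guides.append(gs)
        eb_bcs.append([prefixes[g] + s for g, s in zip(gs, suffixes)])

    all_bcs = [bc for bcs in eb_bcs for bc in bcs]
    bc_index = {bc: i for i, bc in enumerate(all_bcs)}
    n_bc = len(all_bcs)
    n_guides = len(guide_ids)

    cell_rows: list[pd.DataFrame] = []
    founder_rows: list[dict] = []
    tri_rows: list[int] = []
    tri_cols: list[int] = []
    tri_umi: list[int] = []
    tri_reads: list[int] = []
    n_cells_total = 0

    for eb in range(config.n_ebs):
        eb_id = f"EB{eb + 1:04d}"
        n_cells_eb = int(rng.integers(lo, hi + 1))
        n_cap = min(config.capture_cells_per_eb, n_cells_eb)
        gs = eb_guides[eb]
        bcs = eb_bcs[eb]
        for j, g in enumerate(gs):
            founder_rows.append(
                {
                    "eb_id": eb_id,
                    "clone_id": f"{eb_id}.c1",
                    "guide_id": guide_ids[g],
                    "organoid_bc": bcs[j],
                    "n_cells": n_cells_eb,
                }
            )

        mult = np.ones(len(base))
        for g in gs:
            mult = mult * _effect_multipliers(config, guide_target[g])
        theta = rng.dirichlet(config.eb_heterogeneity * base)
        probs = _tilt(theta, mult)
        types = rng.choice(len(base), size=n_cap, p=probs)
        silenced = rng.random(n_cap) >= detect[types]

        rows = n_cells_total + np.arange(n_cap)
        for j, g in enumerate(gs):
            gu = _nb_counts(rng, cm.guide_umi_mean, cm.dispersion, n_cap)
            gu[silenced] = 0
            gr = _reads_from_umis(rng, gu, cm.reads_per_umi)
            keep = gu > 0
            tri_rows.extend(rows[keep])
            tri_cols.extend([int(g)] * int(keep.sum()))
            tri_umi.extend(gu[keep])
            tri_reads.extend(gr[keep])

            bu = _nb_counts(rng, cm.bc_umi_mean, cm.dispersion, n_cap)
            bu[silenced] = 0
            br = _reads_from_umis(rng, bu, cm.reads_per_umi)
            keep = bu > 0
            col = n_guides + bc_index[bcs[j]]
            tri_rows.extend(rows[keep])
            tri_cols.extend([col] * int(keep.sum()))
            tri_umi.extend(bu[keep])
            tri_reads.extend(br[keep])

        cell_rows.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{eb_id}_{i + 1:05d}" for i in range(n_cap)],
                    "eb_id": eb_id,
                    "clone_id": f"{eb_id}.c1",
                    "guide_id": ",".join(guide_ids[g] for g in gs),
                    "organoid_bc": ",".join(bcs),
                    "cell_type": np.asarray(config.cell_types, object)[types],
                    "silenced": silenced,
                }
            )
        )
        n_cells_total += n_cap

    cells = pd.concat(cell_rows, ignore_index=True)
    founders_df = pd.DataFrame(founder_rows)

    # ambient contamination: foreign guide UMIs and foreign BC UMIs
    for pool, offset, p in (
        (n_guides, 0, freq),
        (n_bc, n_guides, None),
    ):
        amb_mask = np.flatnonzero(rng.random(n_cells_total) < cm.ambient_rate)
        amb_cols = offset + rng.choice(pool, size=len(amb_mask), p=p)
        amb_umi = np.ones(len(amb_mask), dtype=np.int64)
        amb_reads = _reads_from_umis(rng, amb_umi, cm.reads_per_umi)
        tri_rows.extend(amb_mask)
        tri_cols.extend(amb_cols)
        tri_umi.extend(amb_umi)
        tri_reads.extend(amb_reads)

    shape = (n_cells_total, n_guides + n_bc)
    umi_mat = sp.coo_matrix(
        (np.asarray(tri_umi), (np.asarray(tri_rows), np.asarray(tri_cols))),
        shape=shape,
    ).tocsr()
    read_mat = sp.coo_matrix(
        (np.asarray(tri_reads), (np.asarray(tri_rows), np.asarray(tri_cols))),
        shape=shape,
    ).tocsr()
    umi_mat.sum_duplicates()
    read_mat.sum_duplicates()

    features = pd.DataFrame(
        {
            "feature_id": np.concatenate([guide_ids, np.asarray(all_bcs, object)]),
            "feature_class": ["guide"] * n_guides + ["organoid_bc"] * n_bc,
        }
    )
    counts = CountsTriplet(
        cell_ids=cells["cell_id"].to_numpy(object),
        features=features,
        umi=umi_mat,
        reads=read_mat,
    )
    return counts, SimTruth(cells=cells, founders=founders_df)


# ---------------------------------------------------------------------------
# Optional embedding for neighbourhood-enrichment tests
# ---------------------------------------------------------------------------

def embed_cells(
    truth: SimTruth,
    n_dims: int = 10,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian-blob embedding: one isotropic blob per cell type.

    A stand-in for a PCA embedding of the transcriptome, sufficient for
    k-nearest-neighbour enrichment analyses: cells of the same type are
    close, cells of different types are ``separation`` apart (in units of
    the within-type standard deviation).
    """
    rng = np.random.default_rng(seed)
    types = sorted(truth.cells["cell_type"].unique())
    centers = rng.normal(0.0, separation / np.sqrt(2), size=(len(types), n_dims))
    idx = truth.cells["cell_type"].map({t: i for i, t in enumerate(types)}).to_numpy()
    return centers[idx] + rng.normal(0.0, noise_sd, size=(len(idx), n_dims))
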