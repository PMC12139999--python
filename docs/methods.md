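# Methods

This note documents the models and procedural choices behind `ebscreen`:
what the synthetic screens emulate, how the statistics are defined, which
numerical conventions are fixed, and where the design was genuinely open.

## 1. The generative model of an EB screen

### Clonal structure

A mosaic EB is founded by `founders_per_eb` cells whose guides are drawn
from the library at its configured frequencies, and grows to a final size
drawn uniformly from `cells_per_eb` (default 10,000–30,000). Final clone
proportions follow a symmetric Dirichlet with concentration
`clone_concentration` (α) per founder; clone cell counts are a multinomial
over the EB size, and the `capture_cells_per_eb` profiled cells are a
multivariate-hypergeometric subsample of the grown EB.

The single product θ = `founders_per_eb · α` controls the effective number
of surviving clones (stick-breaking heuristic: the minimal number of top
clones covering a fraction *f* of cells is ≈ ln(1−f)/ln(θ/(θ+1))). The
defaults, 500 founders with α = 0.005 (θ = 2.5), put the median number of
clones covering 90% of an EB at ~5 and the distinct detectable guides per
EB in the tens — the jackpot regime in which a few clones sit orders of
magnitude above the rest. A symmetric Dirichlet was chosen over an explicit
birth–death simulation because only the end-state skew matters to the
analysis; whether jackpotting arises from growth-rate variance or cell
death is deliberately left outside the model (a single-knob agnostic
parameterisation).

Monoclonal EBs have one founder carrying one guide and one organoid
barcode (the guide's fixed 8-mer prefix plus a random 9-mer suffix); with
probability `multi_integrant_prob` a founder carries two independent
guide/barcode pairs, both present in every descendant.

### Cell types and perturbation effects

Each EB draws its composition θ_e from Dirichlet(κ·baseline) over a
12-type caricature of day-21 EB lineages. κ (`eb_heterogeneity`, default
30) sets inter-individual heterogeneity: at κ = 30 a type with baseline
10% has a per-EB standard deviation of ~5 percentage points — visibly
unequal composition bars across EBs, while keeping every lineage present
in most EBs. Perturbation effects are per-type multiplicative factors
applied to θ_e and renormalised; this single mechanism produces both
enrichments and depletions. Cell types are drawn independently per cell
given the tilted θ_e.

### Counts and noise

Guide and barcode UMI counts per expressing cell are negative binomial
(defaults: guide mean 15, barcode mean 30, dispersion 2); each UMI is
amplified into a geometric number of reads (mean 20, reflecting deep
enrichment-PCR/direct-capture sequencing — the `alltf` assignment rule is
only satisfiable when reads comfortably exceed UMIs). Construct silencing
is all-or-none per cell with a cell-type-dependent detection probability
(defaults: 0.9 uniform for transposon-delivered monoclonal screens; a
0.5–0.9 gradient across differentiation states for lentiviral mosaic
screens). Ambient contamination adds a single UMI of one random foreign
feature per affected cell (rate 0.02), mimicking floating-cell material;
these single-UMI events never pass the assignment thresholds and are the
artifact the 1%-prevalence guide filter removes. Everything is driven by
one integer seed through `numpy.random.default_rng`; identical inputs give
byte-identical outputs.

### What the generator does not model

No transcriptome is simulated beyond cell-type labels (an optional
Gaussian-blob embedding stands in for PCA space in neighbourhood tests,
and tests build ad-hoc gene-count matrices where differential expression
is needed); no spatial structure, growth kinetics, doublets, sequencing
errors in barcodes (Hamming correction is exercised on constructed
fixtures), or guide-specific efficacy differences. Passing tests therefore
say nothing about, e.g., transcriptional effect sizes in real data; they
validate the *compositional* statistics and the deconvolution logic under
realistic clonal and count noise.

## 2. Guide assignment and QC

The two threshold rules are applied exactly as stated, with inclusive
"≥" and strict "<" comparisons: `pilot` assigns a guide iff
log2(UMI+1) ≥ 2 and log2(reads+1) ≥ 5; `alltf` iff log2(UMI+1) ≥ 2 and
log2(UMI+1) < 1.25·log2(reads+1) − 5. The read matrix is used as given
(no internal deduplication); the `alltf` rule intentionally leaves
high-UMI/low-read cells unassignable. Cells with no guide UMIs are
unassigned, never an error. Multi-guide resolution: `pilot_strict` keeps
only single-guide cells; `alltf_keep` drops NTC guides from mixed cells
and retains multiple TF guides.

QC thresholds are floors/caps with the boundary conventions "fewer than"
(strict below) and "over" (strict above). The top-UMI rule removes cells
strictly above the empirical (1−q) quantile computed with "lower"
interpolation, so exactly the top q fraction of a distinct-valued sample
is removed (5 cells of 1000 at q = 0.005). Because an order-statistic rule
is not literally idempotent, the filter resolves the quantile to an
absolute cutoff on first application and reports it; re-runs with resolved
thresholds are idempotent. Doublet scores and MT/Ribo percentages are
consumed as inputs, never computed here.

## 3. Clonotype deconvolution

Pipeline order and conventions:

1. **Floor filter** — barcodes with total UMI < 10 *or* total reads < 10
   are removed (either floor suffices for removal).
2. **Hamming correction** — a surviving barcode merges into a neighbour at
   Hamming distance ≤ 1 only if that neighbour is strictly more abundant
   (by total UMI) and unique; equidistant candidates leave the barcode
   unmerged, logged as ambiguous.
3. **Selection and per-cell assignment** — barcodes with
   log2(total reads) ≥ 15 form the universe (a preset; shallow
   combinatorial-indexing data uses 10); a barcode is assigned to a cell
   iff its UMI ≥ 10 and its share of the cell's universe UMIs ≥ 30%.
4. **Correlation merging** — per-cell barcode vectors are normalised by
   cell total, columns standardised to zero mean/unit variance, and
   product-moment correlations computed across all barcode-assigned cells
   ("scaling" is read as column standardisation). A multi-barcode cell
   survives only if every pair among its barcodes has r > 0.1; qualifying
   pairs merge, with transitive closure so the result is a partition.
   Zero-variance columns have undefined correlations and never merge.
5. **Clonotype calling** — groups with ≥ 50 cells, numbered by descending
   size then lexicographically smallest barcode (stable ids across reruns).
6. **gRNA assignment** — cells with ≥ 10 guide UMIs are eligible;
   clonotypes with < 10 eligible cells are discarded; mean per-cell guide
   UMI proportions above 70% give a unique call, otherwise the top two
   guides form a double call. Discarded/unassigned entities keep explicit
   status; nothing is silently dropped.

On default-noise simulations (150 EBs, 120 captured cells each, 4%
multi-integrant founders) the pipeline recovers every EB as a clonotype,
assigns > 99% of cells to their true EB, merges every multi-integrant
barcode pair through the correlation rule, and the barcode-prefix lookup
agrees with the direct-capture majority call for ≥ 95% of clonotypes.

## 4. The composition screen and its calibration

Targets pool their three guides; targets with < 50 cells and NTC guides
with < 20 cells are excluded; surviving NTC guides are randomly
partitioned (seeded, fixed per run) into groups of three; every unit is
downsampled without replacement to 100 cells (smaller units pass through);
each unit's cell-type counts are tested by the goodness-of-fit chi-square
against the pooled all-NTC composition (the tested NTC group's own cells
included in the background — a knob allows excluding them); the
significance cutoff is the empirical 0.05 quantile (type-7 interpolation)
of the NTC-group p-values, and a unit is flagged iff p < cutoff. The full
category set is kept when a type is missing from a downsampled unit
(zeros in observed); categories absent from the background are dropped
with a warning.

Two calibration facts shape how results should be read:

- **Quantile bias.** The type-7 q-quantile of m null p-values admits a new
  exchangeable p with probability ≈ (1 + (m−1)q)/(m+1), which is well
  above q for small m (0.13 at m = 10, 0.07 at m = 40, 0.052 at m = 400).
  Reliable empirical-FDR screens need a deep null; the reference
  calibration experiment uses 400 NTC groups and lands within the exact
  binomial interval of q over 20 replicates.
- **Exchangeability.** When targets and NTC groups are built by the same
  recipe from the same cell population, the *empirically flagged* fraction
  of an effect-free screen has expectation ≈ q regardless of clustering —
  but with clustered cells its variance is enormous and the flags are
  noise. What clonal jackpotting inflates robustly is the **naive**
  chi-square significance fraction: in the reference mosaic experiment
  (125 targets, 80:20 targeting:NTC mix with lognormal σ = 1.6 library
  skew, 400 EBs per replicate, 500 founders/EB, θ = 2.5, 220 captured
  cells/EB) roughly a quarter to a third of effect-free targets reach
  p < 0.05, the flagged sets of two replicates overlap with Jaccard
  < 0.2, the per-EB dominant guides almost never agree — yet aggregate
  guide frequencies across replicates correlate at r > 0.9, exonerating
  library-level dropout as the explanation and isolating per-EB
  jackpotting as the confounder.

For monoclonal screens, `screen_composition_clonal` replaces the NTC-guide
triplet null with groups of NTC *clonotypes* resampled to match the
targets' clonotype-count distribution (500 groups by default). Null units
then carry the same per-EB clustering as targets, and the flagged fraction
of effect-free monoclonal screens returns to q (verified over pooled
replicates against the exact binomial interval). This, not any change in
the test statistic, is the statistical content of the monoclonal rescue:
the barcoded design manufactures many exchangeable null units at the
correct (EB) level of replication.

### Other statistics

- **Odds ratios** per cell type come from the 2×2 in/out × target/NTC
  table, with a Haldane–Anscombe 0.5 correction applied only to tables
  containing a zero.
- **kNN enrichment**: targets under 50 cells are excluded, the rest
  downsampled to 200; scores are each cell's same-target fraction among
  its 20 exact Euclidean nearest neighbours (self excluded) within the
  retained set, averaged per target and reported with the random-label
  expectation. Neighbour search is exact (brute force or tree — identical
  results).
- **Fraction tests** compare per-clonotype cell-type fractions between
  perturbation and NTC clonotypes with the two-sided Mann–Whitney test:
  exact for tie-free samples up to n = 25, otherwise the tie-corrected
  normal approximation without continuity correction (so identical
  samples give p = 1 exactly).
- **Pseudobulk DE discordance**: the single-cell track rank-sum-tests each
  gene across cells on log1p counts-per-10k; the clonotype track sums
  counts per clonotype, normalises to counts-per-million, log1p-transforms
  and rank-sum-tests across clonotypes; both tracks are BH-corrected at
  α = 0.05, and the unsupported fraction is |single-cell calls \
  clonotype calls| / |single-cell calls| (undefined when the single-cell
  track calls nothing). Rank-sum tests stand in for a negative-binomial
  GLM deliberately: the discordance being measured is about the unit of
  replication, not the likelihood family. Note the replication floor: with
  n clonotypes per arm the smallest achievable exact p is 2/C(2n, n), so
  fewer than ~8 clonotypes per arm cannot clear BH correction at all.

## 5. Cross-dataset correspondence

Pseudobulk profiles (mean log-normalised expression per type) are
intersected on genes; for each target type the design is restricted to the
union of its 1,500 most expressed and 1,500 most specific genes —
specificity is expression minus the mean of the other types (a documented
choice; a ratio would weight low-expression genes more). The NNLS fit
keeps the intercept unconstrained by splitting it into +/− columns inside
the non-negative solver. The combined score 2(β_ab+0.01)(β_ba+0.01) is
symmetric under swapping the datasets and floors at 2·10⁻⁴ for
orthogonal profiles. Scaling a target profile scales its forward
coefficients proportionally, leaving argmax matches unchanged.

## 6. Clonal-complexity diagnostics

Amplicon reads deduplicate to distinct (UMI, guide) pairs — no
birthday-collision correction is applied, a documented limitation that
undercounts only when the UMI space is nearly saturated. Complexity
reports sort guides by descending count with lexicographic tie-break, and
the dominance count is the smallest m whose top-m cumulative share reaches
the coverage fraction (default 0.9). Log2 fold changes versus a reference
library add a 0.5 pseudocount to raw counts before renormalising (the
exact pseudocount is configurable), keeping dropouts finite and the
transform antisymmetric. Per-sample count vectors are never pooled
implicitly.

## 7. Reference experiment sizes and runtimes

Problem sizes were chosen so the whole suite runs in minutes on one CPU:
mosaic confounding uses two replicates of 400 EBs × 220 captured cells
(~90,000 assigned cells each); the rescue, four replicates of 350
monoclonal EBs × 150 cells with full deconvolution; calibration, twenty
replicates of 124,000 iid cells; power, fifty 28-EB screens. These are
scaled-down but regime-faithful versions of screens one or two orders of
magnitude larger; every qualitative conclusion above was checked to be
stable across independent seed pairs before the defaults were frozen.

## 8. Known limitations

- The Dirichlet clone-size law matches the end-state skew, not the
  dynamics; time-resolved questions are out of scope.
- Silencing is all-or-none per cell; partial expression is not modelled.
- The naive-inflation magnitude depends on κ and θ jointly; the package
  makes no claim about its value in any real dataset, only about its sign
  and irreproducibility.
- `screen_composition` assumes NTC cells are numerous enough that the
  background is effectively fixed; with very few NTC cells the self-
  inclusion knob matters and the cutoff becomes unstable.
- The per-lane adjustment of QC thresholds seen in real data is exposed as
  configuration, not automated.
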