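# Methods

This note documents the statistical procedures, the numerical choices, the
synthetic-data generator and the limitations of `sorcna`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and the genome model

All intervals are 1-based and fully closed; the length of `[start, end]`
is `end − start + 1` and region sizes in Mb are rounded **half-up** to one
decimal (`region_size_mb`). Half-up matches the convention of the printed
sizes of cytogenetically named regions and is additionally robust, for all
regions handled here, to one-base-pair convention shifts — a property the
test suite asserts explicitly. UCSC-style inputs (0-based half-open) are
converted on load and round-trip losslessly.

The bundled hg18/NCBI36 build carries the true chromosome lengths. Its
banding table is deliberately minimal and **synthetic**: one p and one q
band per chromosome, split at an approximate centromere position
(`data/cytoband_hg18_arms.synthetic.txt`). This resolves arm labels
("1q", "20p") exactly as needed for arm-scale summaries but does not
resolve sub-band names; users with a real cytoBand file can load it via
`load_genome(chrom_sizes, cytobands)`. Positions exactly on a band
boundary belong to the band that contains them; which cytoband release is
used can shift arm labels by at most a band at region edges.

## SOR segmentation

`build_sors` is a sweep-line over all call breakpoints of one direction:
between consecutive breakpoints the supporting case set is constant;
zero-support gaps are discarded and adjacent contiguous segments with
identical support are merged, so segments are maximal by construction.
Gains and losses are segmented independently (a combined track is
derivable but not primary). Correctness is checked against a brute-force
per-base counting oracle on hundreds of random cohorts, plus the
conservation identity Σ_segments length×|support| = Σ_cases covered bases
and idempotence on SOR-shaped input.

The RF denominator is the number of **all** analysed cases, including
CNA-free ones — these are retained from the clinical table even when they
contribute no call.

Per-case burden statistics:

- *Percent genome altered*: 100 × altered bases / genome size, where the
  genome size is the sum of the loaded build's chromosome lengths
  (X and Y included) and altered bases are merged per direction first, so
  the value is invariant to call fragmentation.
- *Regional burden*: the fraction of a region's bases covered by a case's
  calls of one direction. This continuous statistic is the default input
  to regional group tests; a binary overlap indicator is available
  (`binary=True`) since either reading of "changes of CNAs in a region"
  is defensible.

Profile-matrix membership uses the segment **midpoint** (a case scores
±1 if its call covers the midpoint), which is robust to single-base-pair
boundary ambiguity; `membership="overlap"` switches to any-overlap. For
segments produced by `build_sors` on the same case set, midpoint coverage
coincides with membership in the supporting set (calls cover maximal
segments entirely), which the tests verify.

## Group statistics

- **Wilcoxon rank-sum** (`wilcoxon_rank_sum`): exact enumeration when the
  combined sample size is ≤ 10 and tie-free; with ties at small n the
  permutation distribution of the observed data is enumerated instead
  (ties make the tabulated null data-dependent); otherwise the normal
  approximation with mid-rank tie correction and continuity correction.
  Fully constant data return p = 1. Grade III vs II burden comparisons
  use `alternative="greater"` with explicit group order; genome-wide scans
  default to two-sided.
- **Genome-wide scan** (`differential_scan`): the regional comparison
  applied to every SOR segment; raw p-values by default, matching the
  convention of reporting unadjusted regional p-values, with
  Benjamini–Hochberg available behind `adjust=True`.
- **Fisher's exact test**: two-sided hypergeometric-tail p for 2×2 tables
  (scipy); degenerate margins are rejected.
- **ROC/AUC** (`roc_auc`): AUC is the Mann–Whitney concordance
  probability with ties counting ½. The CI is a stratified percentile
  bootstrap (default 2000 replicates, fixed seed): positives and
  negatives are resampled independently so every replicate keeps both
  classes. The reported interval is additionally clipped to bracket the
  point estimate. No analytic CI is attempted because the bootstrap makes
  no distributional assumption at these sample sizes.

## Clustering

`weighted_kmeans` is Lloyd's algorithm with per-feature weights (SOR
segment sizes in bp), k-means++ seeding, best of `restarts` (default 100)
runs, convergence when assignments stabilise or after 300 iterations, and
empty-cluster repair by reseeding the empty centroid to the point
farthest from its current centroid. The objective is asserted
non-increasing at every half-step. Determinism: the master seed spawns
one child seed per restart, so identical inputs and seed give
bit-identical output. Two mathematical identities are used as independent
cross-checks in the tests rather than as the implementation: with equal
weights the result coincides with ordinary k-means, and weighting by w_j
equals unweighted k-means on columns scaled by √w_j (compared against
scikit-learn on both counts).

The feature encoding is the signed {−1, 0, +1} matrix — chosen because
cluster phenotypes are naturally described as loss-dominated versus
gain-dominated, which an unsigned encoding cannot express. k = 3 is the
pipeline default; sex chromosomes are excluded before clustering to avoid
clustering mixed-sex cohorts by sex. After fitting, clusters are
relabelled by the size-weighted mean signed burden of their centroids
(cluster 1 most loss-dominated … cluster k most gain-dominated), making
cluster identities stable across seeds and runs.

## Survival

Times are months from surgery. Kaplan–Meier estimation and the k-sample
log-rank test are delegated to lifelines; subjects censored at an event
time remain at risk for that time's deaths, and the reported median is the
first time the curve reaches ≤ 0.5 (None if it never does).

`cox_fit_binary` maximises the Breslow-ties partial likelihood for a
single binary covariate by Newton iteration with step-halving (≤ 50
iterations, score tolerance 1e−9). With a binary covariate the risk-set
sums reduce to group counts, so each evaluation is exact and cheap. The
fit exposes the score test at β = 0, which on tie-free data equals the
two-group log-rank chi-square — checked numerically against lifelines —
and reports monotone partial likelihood (|β| diverging, as under complete
separation of event times) as `converged=False` rather than returning a
spuriously huge estimate. lifelines' `CoxPHFitter` serves as the
independent oracle for coefficient and standard error in the tests.

`power_logrank_sim` draws exponential survival — reference group at unit
rate, comparison group at rate equal to the hazard ratio; the log-rank
test is invariant to the common scale — applies an optional pluggable
censoring rule (default none, since power statements of this kind rarely
specify one), and counts rejections of the two-sided test at level α.
The inner statistic is an authored two-group log-rank with the
hypergeometric variance, tested for equality against lifelines, keeping
5000-replicate runs to seconds. A Wilson binomial CI accompanies the
power estimate. Note the asymptotic log-rank test is slightly
anti-conservative at very small n (its true size at 16+16 exceeds 0.05
by about a percentage point), so the simulator's own null calibration is
checked at n = 100.

## Synthetic cohorts

`simulate_case_set` draws, per case and arm, at most one event — gain and
loss are mutually exclusive on an arm, which guarantees the generated
call set satisfies the single-valued per-case profile invariant. Event
spans are the arm span shrunk by uniform breakpoint jitter (default 5 Mb
per side, minimum call length 1 Mb): the signal of interest is arm/band
scale, so probe-level noise is deliberately not modelled. Defaults follow
the recurrent HCC landscape — 1q+/8q+ gains and 16q− loss at 0.50,
4q−/17p− losses and 5p+ gain at 0.40, 8p−/13q− losses at 0.30 — with a
0.05 background on every other arm split evenly between directions.
Within-arm breakpoint placement is uniform, a modelling choice in the
absence of a stated distribution.

Clinical labels are drawn from configurable marginal proportions
(defaults: grade II/III ≈ 35/44, stage A/B/C ≈ 32/12/35, recurrence
29/50 — the cohort marginals of the motivating study population); factors
named in `balanced_factors` are allocated exactly by largest remainder
and permuted, which is how the recovery experiments obtain exact 40/40
group splits. Survival is exponential under proportional hazards,
hazard = baseline × exp(Σ β·x) with indicator coding of grade III,
stage B/C and recurrence; defaults (β = −0.3, +0.5, +1.0, +1.2 on a
0.015/month baseline, administrative censoring at 54 months ≈ the
follow-up horizon of a 2014–2016 accrual window closed mid-2018) give
stage and recurrence strong adverse effects and grade a mild protective
modification, qualitatively mirroring the motivating cohort. Labels are
drawn independently across factors; real cohorts show factor dependence
(e.g. grade–recurrence association within stage), which this generator
does not emulate — tests passing on synthetic data therefore do not
certify behaviour under correlated clinical structure.

Planted structure: a `PlantedRegion` raises the event probability of one
region by `delta` for cases with a chosen clinical label.
`planted_differential_config` places a grade-associated loss on
chr10:78–124 Mb — a background-rate arm, mirroring where grade-differential
losses are observed in practice — because planting on an arm that already
carries a high grade-independent event rate would mask the uplift.
`archetype_pair_config` defines two four-region signatures (all-gain vs
all-loss): with background arm events arriving at ≈ 2.4 per case and each
being arm-sized, a one- or two-region archetype is dominated by background
for the (1 − baseline − delta) of cases missing an event, whereas a
four-region carrier holds ≈ 3.4 signature events and a fully
signature-free case has probability (1 − baseline − delta)³·⁺ ≈ 0.05%.

All generators are pure functions of (config, seed); the case-set seed
also derives the survival seed, so one integer reproduces a whole cohort.

## Problem sizes used in the checks

The recovery and calibration experiments run at the sizes their claims
state: 100 cohorts of 80 cases (40/40) for differential-region recovery,
100 cohorts of 60 cases for archetype recovery (ARI ≥ 0.9), 100
replicates of 200 + 200 subjects for Cox recovery of log HR = log 0.17,
1000 label permutations (n = 100) for regional-test calibration, and 5000
replicates for power estimates. The SOR oracle comparison uses 200
direction-instances of ≤ 10 cases on 1 kb chromosomes, where per-base
enumeration is exact and fast.

## Known limitations

- No liftover: coordinates are interpreted in the loaded build (hg18 by
  default); printed region sizes are convention-robust but arm labels
  depend on the banding table supplied.
- The bundled banding is arm-level; sub-band annotation requires a real
  cytoBand file.
- The Cox module fits a single binary covariate only — multivariable
  models are out of scope.
- GISTIC-style amplitude-weighted recurrence scoring is deliberately not
  implemented; recurrence here is plain case frequency.
- The SEG reader's ±0.25 log₂ thresholds are a pragmatic default, not a
  calling method; calls should normally come from a dedicated caller.
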