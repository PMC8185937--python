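# sorcna

Smallest-overlap-region (SOR) profiling of somatic copy-number alterations
(CNAs), with clinicopathologic group comparison, size-weighted clustering
and survival analysis.

## What problem this solves

Array-CGH and segmentation pipelines yield per-case CNA calls: intervals of
gain or loss on a reference genome. To describe a tumor cohort — here the
motivating setting is hepatocellular carcinoma (HCC), whose recurrent
landscape features arm-level gains of 1q, 5p and 8q and losses of 4q, 8p,
13q, 16q and 17p — one needs cohort-level summaries and tests:

- **SOR partition.** Sweeping over all call breakpoints of one direction
  partitions the altered genome into maximal segments over which the set of
  supporting cases is constant (the shared overlapped regions of the calls).
  For each SOR the *relative frequency* is

  RF = |cases with an overlapping CNA| / n,

  where n counts **all** analysed cases, CNA-free ones included.
- **Per-case burden.** Percent genome altered, PGA = 100 · (total CNA
  length) / (genome size), and per-region covered fractions, compared
  between clinicopathologic groups (histologic grade, tumor stage,
  recurrence) with the Wilcoxon rank-sum test, Fisher's exact test and
  ROC/AUC.
- **Size-weighted k-means.** Cases are clustered on a signed {−1, 0, +1}
  profile over the SOR segments, each segment weighted by its genomic size
  w_j (bp), minimising Σᵢ Σⱼ w_j (x_ij − c_{a(i)j})², with sex chromosomes
  excluded so mixed-sex cohorts do not cluster by sex. Cluster labels are
  canonicalised loss-dominated → gain-dominated.
- **Survival.** Kaplan–Meier curves, the k-sample log-rank test, a
  two-group Cox proportional-hazards fit, and a simulation-based power
  estimate for the log-rank test under a given hazard ratio.
- **Synthetic cohorts.** A generator draws arm-level events at configured
  per-arm rates (defaults emulate the recurrent HCC landscape above),
  plants group-associated regions, and simulates proportional-hazards
  survival — so the whole pipeline is testable without any data download.

Coordinates are 1-based and fully closed throughout (hg18/NCBI36 for the
bundled build); region sizes are (end − start + 1)/10⁶ Mb, rounded half-up
to one decimal.

## Worked example

```python
import sorcna
from sorcna.genome import load_hg18
from sorcna.cluster import exclude_sex_chromosomes, weighted_kmeans
from sorcna.survival import logrank_test, power_logrank_sim

build = load_hg18()
config = sorcna.default_hcc_config(75)          # HCC landscape defaults
cases = sorcna.simulate_case_set(config, seed=1)

profile = sorcna.build_sors(cases, "gain")
print(profile.to_frame().nlargest(3, "rf").to_string(index=False))

pga = sorcna.pga_per_case(cases, build)
print(f"median percent genome altered: {pga.median():.1f}%")

region = ("chr10", 78_314_145, 124_106_670)     # a 45.8 Mb 10q region
cmp = sorcna.compare_region(cases, region, "loss", cases.grouping("grade"),
                            alternative="greater", group_order=("III", "II"))
print(f"10q loss burden, grade III vs II: U={cmp.statistic:.0f} p={cmp.p_value:.3f}")

segments = exclude_sex_chromosomes(sorcna.build_sor_profile(cases).segments)
matrix = sorcna.profile_matrix(cases, segments)
model = weighted_kmeans(matrix, [s.length for s in segments], k=3, seed=1)
print("cluster sizes:", model.sizes().to_dict())

clin = cases.clinical_frame()
lr = logrank_test(clin["time"], clin["event"], clin["stage"])
print(f"survival by BCLC stage: chi2={lr.chi_square:.2f} df={lr.df} p={lr.p_value:.4f}")

power = power_logrank_sim(hazard_ratio=0.17, n_total=32, reps=5000, seed=1)
print(f"log-rank power at HR=0.17, n=32: {power.power:.3f}")
```

Output:

```
chromosome     start       end direction  n_cases       rf
      chr1 129108839 242288003      gain       36 0.480000
      chr1 129054332 129108838      gain       35 0.466667
      chr1 242288004 242430933      gain       35 0.466667
median percent genome altered: 11.4%
10q loss burden, grade III vs II: U=672 p=0.228
cluster sizes: {1: 36, 2: 19, 3: 20}
survival by BCLC stage: chi2=5.42 df=2 p=0.0666
log-rank power at HR=0.17, n=32: 0.995
```

Reading this: the most recurrent gain SOR sits on 1q at RF 0.48 (36 of 75
simulated cases), matching the configured 0.50 arm rate; the 10q loss
region shows no grade association here because this cohort was simulated
without planted group structure (p = 0.23); cluster 1 (loss-dominated)
versus cluster 3 (gain-dominated) follow the canonical ordering; stage
trends toward separating survival at n = 75; and a two-group log-rank test
at hazard ratio 0.17 with 16 + 16 subjects has essentially full power.

## Command line

`sorcna` wires the same operations into subcommands: `simulate`, `sor`,
`pga`, `compare`, `scan`, `cluster`, `survive`, `power` and `run` (the
all-in-one pipeline, which writes SOR tracks, scan tables, ROC results,
cluster assignments and crosstabs, survival tables and a parameter
manifest). Exit codes: 0 success, 2 validation error, 3 runtime failure.

```sh
sorcna simulate --n-cases 75 --seed 1 --out-dir demo/
sorcna run --calls demo/calls.tsv --clinical demo/clinical.tsv --out-dir demo/out/
```

## Input formats

- **Calls** (canonical TSV, headered): `case_id  chromosome  start  end
  direction` with 1-based inclusive coordinates and direction `gain`/`loss`.
  A SEG dialect (`sample  chrom  loc.start  loc.end  seg.mean`, thresholded
  at ±0.25 log₂ by default) and BED export are also provided. Within a
  case, overlapping same-direction calls are merged on load; overlapping
  opposite-direction calls are rejected.
- **Clinical** (TSV, headered): `case_id  grade  stage  recurrence  time
  event` with grade II/III (Edmondson–Steiner), stage A/B/C
  (Barcelona-Clinic Liver Cancer), recurrence yes/no, time in months,
  event `dead`/`censored`. Cases without calls are kept as CNA-free.
- **Genome**: `chrom.sizes` plus UCSC-style cytoBand text; a bundled hg18
  build (true chromosome lengths, arm-level banding) is the default.
- Optional benign-variant **blacklist** (TSV: chromosome, start, end) is
  subtracted from every call before analysis.

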