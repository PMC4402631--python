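# Methods

This note documents the models and procedures `pbla` implements, the
parameter choices behind them, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## The mapping model

A population-based linkage analysis treats pairwise IBD segments —
haplotype stretches two individuals co-inherited from a common ancestor —
as the unit of evidence. If a rare risk variant segregates in the
cohort, case–case pairs should share segments spanning its location more
often than background. For marker *m*, with `n_cc(m)` the number of
case–case segments whose physical span covers the marker and `N_cc` the
number of case–case pairs, the statistic is

    s(m) = (n_cc(m) / N_cc) / gw_avg,   gw_avg = mean over markers of n_cc(m)/N_cc.

Normalising by the genome-wide average corrects for cohort-level
relatedness: a cohort whose cases are globally more related everywhere
produces s ≈ 1 at null markers rather than a uniformly inflated signal.

**Assumptions.** Segments are taken as given (detection is upstream, in
our case simulated); spanning is the closed interval `start_bp <= bp(m)
<= end_bp` on the same chromosome; each per-haplotype-pair record counts
once even when the same sample pair shares both haplotypes (a
collapse-to-pair option is deliberately not the default, matching the
record granularity of the input format).

**Segment filtering.** Segments with LOD < 3 or genetic length < 1 cM
are excluded before computing the genome-wide average or any statistic.
Short/low-LOD calls are dominated by false detections. We read the
exclusion rule as two independent criteria (keep iff LOD ≥ 3 AND length
≥ 1 cM), the conventional thresholds for refined-IBD output; the
literal union reading (exclude only segments failing both) is available
as `SegmentFilterParams(literal_conjunction=True)`.

**Permutation significance.** Case/control labels are shuffled
preserving class sizes; each permutation's statistic is renormalised by
its own genome-wide average so the correction is part of the null
distribution. Pointwise p-values use the add-one estimator
`(1 + #{s_perm >= s_obs}) / (P + 1)`, which is valid (stochastically
conservative) at any P. Genome-wide significance is family-wise error
control by the max-statistic method: marker *m* is significant iff
`s_obs(m)` reaches the (1 − α) linear-interpolation quantile of the
per-permutation maxima, α = 0.05. We interpret the "0.05 percentile of
the permutation p-value distribution" threshold convention as this
family-wise 5% level (the 5% quantile of per-permutation minimum
p-values is the same object on the p scale); the literal 0.0005-quantile
reading is selectable via `MappingParams(literal_pvalue_quantile=True)`.
The default permutation count is 10,000 — production analyses of this
kind use millions, which is reachable by config but pointless at
simulation scale.

**Low-coverage filter.** IBD detection is systematically weaker near
chromosome ends, which inflates the normalised statistic there (small
expected counts, large relative noise) and produces spurious telomeric
peaks. The filter computes the total spanning count per marker over all
pairs (cases and controls — the detection artifact is label-free),
takes the 10% linear-interpolation quantile of those counts over all
accepted markers before any other masking, and masks markers strictly
below it; an all-equal count profile masks nothing. Reported hits are
markers that are genome-wide significant AND unmasked; the raw
permutation call is kept on the result (`exceeds_threshold`) because
calibration of the permutation procedure is a property of that flag
alone.

## Quality control

Filters and defaults: per-individual missingness ≤ 0.07 (a downstream
phasing requirement), then — recomputed on the survivors — per-marker
missingness ≤ 0.1, folded MAF ≥ 0.05, and Hardy–Weinberg exact-test
p ≥ 1e-6. Individuals are filtered before markers, matching standard
GWAS-QC tool behaviour; the order matters because a few bad samples can
push many markers over the missingness threshold. QC is idempotent on
the panels the generator produces (margins guarantee the second pass is
a no-op); pathological panels where removing high-missingness markers
re-exposes borderline individuals are possible in principle.

The HWE test is the conditional exact test: conditioning on the
observed allele counts, sum the probabilities of all heterozygote
configurations no more probable than the observed one. It is computed
with the stable mode-anchored ratio recurrence in doubles (tolerance
`p_config <= p_obs * (1 + 1e-9)` absorbs rounding in tie detection) and
is verified against an exact rational enumeration over every
configuration with n ≤ 50 to 1e-12. Whether the test should use cases,
controls or both is genuinely ambiguous in practice; the default uses
all samples, `QCThresholds(hwe_controls_only=True)` restricts to
controls.

## PCA and outlier removal

`compute_pcs` centres each marker at 2p̂ and scales by sqrt(p̂(1−p̂))
(EIGENSTRAT normalisation), mean-imputes missing calls, and returns the
top components as **unit-norm eigenvectors** of the sample covariance —
the smartPCA output convention. This matters because the 0.15 density
cutoff is scale-dependent: unit-norm coordinates shrink as 1/sqrt(n),
so the default cutoff presumes cohort-scale sample counts (thousands).
On small simulated panels the cutoff must be raised accordingly (the
pipeline exposes it; examples use 0.6 at n ≈ 100). Signs are fixed by
making each component's largest-magnitude marker loading positive.

The two-stage filter runs exactly once (no iteration): stage 1 keeps
samples with mean 10-NN distance ≤ cutoff ("the main cluster" is defined
by the density criterion itself — no connected-components step, since
none is warranted by the procedure's description); stage 2 keeps a
stage-1 sample iff ≥ 9 of its 10 nearest neighbours *in the full sample
set* are stage-1 members. Computing stage-2 neighbours among stage-1
survivors instead would make the interior rule vacuous (every neighbour
would be a member by construction) — which is why the full-set reading
is the default; the alternative is still exposed as
`OutlierParams(neighbors_within_stage1=True)` and documented as
reducing stage 2 to stage 1. Nearest-neighbour ties break by sample
order (stable sort), so results are deterministic.

## The synthetic cohort generator

The generator produces data with the statistical structure the analysis
assumes, at desk scale. Defaults (all configurable on `SimSpec`):

| parameter | default | rationale |
|---|---|---|
| cohort | 50 cases + 50 controls | smallest size at which per-marker counts are comfortably away from 0 |
| genome | 2 chromosomes × 100 Mb, 1 cM/Mb | 2 Morgans; enough markers for a genome-wide maximum to be meaningful |
| markers | 250/chromosome, evenly spaced | ~0.4 cM spacing, finer than the minimum segment length |
| segment lengths | Pareto(α = 2.5, x_m = 0.65 cM) | mean α·x_m/(α−1) ≈ 1.083 cM — "slightly above 1 cM", the empirically observed shape; no fitted parameters are published, so these are calibration choices |
| sharing rate | 3.0 segments/pair/Morgan | gives ≈ 20 case–case segments spanning a typical marker *after* the LOD/length filter (1225 pairs × 3 × E[L; L ≥ 1 cM]/100 ≈ 21), the regime where count discreteness no longer distorts the permutation quantile |
| telomere depletion | width 5 cM, retention 0.5 | reproduces the reduced IBD detection near chromosome ends that motivates the coverage filter |
| LOD scores | 3 + Exponential(mean 2) | detected segments mostly pass the LOD ≥ 3 filter; `lod_below3_frac` forces a fraction below for filter tests |
| MAF | Uniform(0.15, 0.45) | comfortably inside the QC threshold so only planted markers fail |

Segment placement is midpoint-uniform in *genetic* distance with
lengths drawn in cM, so the length distribution is exactly Pareto
before truncation at chromosome ends; physical coordinates follow from
the uniform cM/Mb rate. A planted locus multiplies the expected number
of case–case segments overlapping it by `enrichment`, implemented by
replication of covering segments (expected multiplicity = enrichment),
which leaves the marginal length distribution unchanged. At
enrichment = 1 nothing depends on the labels, so case–case and other
pair classes are exchangeable by construction — the property the
family-wise error calibration rests on.

Planted QC failures are constructed, not sampled: low-MAF markers get
an exact minor-allele count at MAF ≈ 0.025, HWE failures are
all-heterozygote columns (infeasibly small cohorts raise an error
because the exact-test p cannot reach 1e-6), missingness plants use 15%
(markers) and 12% (individuals) against the 0.1/0.07 thresholds. All
non-planted markers are rejection-sampled to pass with margin (observed
MAF ≥ 0.10, HWE p ≥ 1e-3, missingness ≤ 0.05), so QC recovery of the
planted truth is exact, not probabilistic.

**What the generator does not emulate:** linkage disequilibrium
(markers are independent given MAF), coalescent or pedigree structure
behind the segments (counts are Poisson per pair, not correlated
through genealogy), phasing error, and the dependence of detection
power on local marker density. Passing tests therefore demonstrate that
the *procedures* are correct and calibrated under their stated
assumptions — not that a real cohort satisfies those assumptions.

## Numerical conventions

- Coordinates: bp are 1-based inclusive throughout; fastIBD-style
  records use 0-based marker indices per chromosome (stated in the file
  header). Genetic-map interpolation is linear between anchors, linear
  at the terminal interval's rate beyond them, floored at 0 cM.
- Spanning counts use a sorted endpoint sweep (searchsorted + difference
  array), verified exactly against the brute-force double loop.
- The permutation loop computes all counts through one sparse
  marker×segment incidence matrix in float64; permutation label matrices
  are processed in chunks of ≤ 256 to bound memory.
- Quantiles everywhere use numpy's linear interpolation between order
  statistics.
- One master seed drives each generator/procedure via
  `numpy.random.default_rng`; identical seeds give bit-identical
  outputs, including byte-identical pipeline result files.
- Degenerate inputs: a zero-variance panel yields an all-zero embedding
  with a flag; a profile with no case–case sharing yields a flagged
  degenerate mapping result (all p = 1) rather than an exception; an
  empty post-QC panel is flagged on the report.

## Problem sizes used in the checks

The statistical acceptance checks run at the generator's default scale:
200 null cohorts × 200 permutations for family-wise error calibration
(the binomial 99% check interval around 0.05 at 200 datasets is
3–19 hits), 50 replicates × 1000 permutations for planted-locus power,
100,000 draws for the length-distribution mean, and exhaustive
enumeration to n = 50 for the HWE oracle. These sizes make the full
suite complete in a few minutes on one CPU while keeping Monte-Carlo
error well inside the asserted bounds.

## Known limitations

- The 0.15 outlier cutoff is meaningful only under the smartPCA
  coordinate convention and cohort-scale n; the package documents but
  cannot remove this scale dependence.
- The mapping statistic uses case–case sharing only; designs
  contrasting case–case against control–control sharing directly are
  out of scope.
- No plotting; results are tab-separated tables intended for downstream
  tooling.
- The refined-IBD and fastIBD dialects implemented are the documented
  column contracts in `pbla.segio`; private converter formats vary.
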