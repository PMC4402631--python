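# pbla — population-based linkage analysis from IBD segments

`pbla` implements case–control mapping of chromosomal segments shared
identical-by-descent (IBD). In a population-based linkage analysis
(PBLA), segments detected among nominally unrelated individuals (for
example by BEAGLE's refined-IBD algorithm) are tested for being shared
more often between case–case pairs than expected — a design aimed at
chromosomal regions carrying rare risk variants that genome-wide
association tests of common alleles miss.

The package is a library first (everything importable from `pbla`),
with a thin `pbla` command-line interface over the same functions and
short narrative scripts in `examples/`. It covers the full analysis:

- **Cohort QC** — marker/individual filters: MAF ≥ 0.05, Hardy–Weinberg
  exact-test p ≥ 1e-6, per-individual missingness ≤ 0.07, per-marker
  missingness ≤ 0.1 (`pbla.qc`).
- **Outlier removal** — genotype PCA (EIGENSTRAT normalisation) followed
  by a two-stage nearest-neighbour filter on the first six PCs: keep
  samples whose mean distance to their 10 nearest neighbours is ≤ 0.15,
  then require 9 of those 10 neighbours to be kept too (`pbla.pca`).
- **Segment I/O** — refined-IBD text parsing, fastIBD-style marker-index
  conversion, genetic-map (cM) interpolation (`pbla.segio`).
- **IBD mapping** — segment filtering (LOD ≥ 3, length ≥ 1 cM),
  per-marker sharing profiles, and permutation-based genome-wide
  significance (`pbla.mapping`). The statistic at marker *m* is

  ```
  s(m) = (n_cc(m) / N_cc) / gw_avg,     gw_avg = mean_m n_cc(m) / N_cc
  ```

  where `n_cc(m)` counts case–case segments spanning *m* and `N_cc` is
  the number of case–case pairs — i.e. the local case–case sharing rate
  corrected for the average genome-wide sharing. Case/control labels are
  permuted preserving class sizes, each permutation renormalised by its
  own genome-wide average, and family-wise error is controlled through
  the permutation distribution of max<sub>m</sub> s(m). Markers in the
  lowest 10% of total IBD detection are masked, removing the inflated
  telomeric signals this method is prone to.
- **Synthetic cohorts** — `pbla.sim` generates genotype panels with
  plantable QC failures, PC embeddings with planted outliers, and IBD
  segment sets with Pareto-distributed cM lengths (mean slightly above
  1 cM), reduced detection near chromosome ends, and an optional planted
  risk locus where case–case sharing is enriched.

## Worked example

`examples/04_ibd_mapping.py` simulates a 100+100 cohort with a risk
locus at marker chr1:50199203 where case–case pairs share segments five
times more often, then maps it with 1000 permutations:

```
segments: 113943 detected, 38992 pass the LOD/length filter
genome-wide average case-case sharing rate: 0.01663
significance threshold on s: 2.70 (permutation p ~ 0.0509)
top marker: chr1_m00126 at chr1:50199203 with s = 5.59 (planted locus at chr1:50199203)
significant markers (genome-wide, low-coverage regions masked):
chrom       bp          id  statistic        p     p_gw  low_coverage  significant
 chr1 49402390 chr1_m00124   2.976552 0.000999 0.007992         False         True
 chr1 49800797 chr1_m00125   4.349411 0.000999 0.000999         False         True
 chr1 50199203 chr1_m00126   5.588628 0.000999 0.000999         False         True
 chr1 50597610 chr1_m00127   4.531649 0.000999 0.000999         False         True
 chr1 50996016 chr1_m00128   3.122342 0.000999 0.001998         False         True
```

The planted marker attains the genome-wide maximum (s = 5.59, about 5.6
times the background sharing rate); flanking markers are dragged along
because the same shared segments span them. The add-one pointwise
p-value floor with 1000 permutations is 1/1001 ≈ 0.000999.

The command-line route over the same data:

```sh
pbla simulate --out cohort/ --seed 1
pbla qc --ped cohort/cohort --out qc/
pbla map --segments cohort/segments.ibd.txt --map cohort/cohort.map \
         --genetic-map cohort/genetic_map.tsv --phenotypes cohort/phenotypes.tsv \
         --permutations 10000 --out mapping/
```

## Layout

```
src/pbla/        core.py  sim.py  qc.py  pca.py  segio.py  panelio.py
                 mapping.py  pipeline.py  cli.py
examples/        one narrative script per capability
docs/methods.md  models, assumptions, parameter choices, limitations
tests/           unit, property and acceptance suites
```
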