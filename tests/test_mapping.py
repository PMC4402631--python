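"""Segment filtering, sharing profiles, the mapping statistic and the
permutation significance procedure."""

import numpy as np
import pandas as pd
import pytest

from pbla.core import CASE, CONTROL, SEGMENT_COLUMNS
from pbla.mapping import (
    MappingParams,
    SegmentFilterParams,
    SharingProfile,
    coverage_filter,
    filter_segments,
    genomewide_average,
    mapping_statistic,
    permutation_mapping,
    significant_markers,
    spanning_counts,
)
from pbla.segio import GeneticMap, annotate_segments
from pbla.sim import Chromosome, SimSpec, default_cohort, simulate_ibd_segments, uniform_marker_table

from conftest import random_segments, spanning_counts_bruteforce


def make_segments(rows):
    """rows: (sample1, sample2, chrom, start, end, lod[, length_cm])"""
    recs = []
    for r in rows:
        rec = {"sample1": r[0], "hap1": 1, "sample2": r[1], "hap2": 1,
               "chrom": r[2], "start_bp": r[3], "end_bp": r[4], "lod": r[5]}
        if len(r) > 6:
            rec["length_cm"] = r[6]
        recs.append(rec)
    return pd.DataFrame(recs, columns=SEGMENT_COLUMNS if not recs else None)


FIVE_MARKERS = pd.DataFrame(
    {"id": [f"m{i}" for i in range(5)], "chrom": "chr1", "bp": [100, 200, 300, 400, 500]}
)


class TestFilterSegments:
    @pytest.mark.parametrize(
        "lod, length_cm, kept",
        [(3.5, 2.0, True), (2.9, 2.0, False), (5.0, 0.8, False), (3.0, 1.0, True)],
    )
    def test_exclusion_rule(self, lod, length_cm, kept):
        segs = make_segments([("a", "b", "chr1", 10, 20, lod, length_cm)])
        out, report = filter_segments(segs)
        assert (len(out) == 1) is kept
        assert report["n_input"] == 1

    def test_literal_conjunction_reading(self):
        segs = make_segments(
            [("a", "b", "chr1", 10, 20, 2.0, 2.0), ("a", "b", "chr1", 10, 20, 2.0, 0.5)]
        )
        out, _ = filter_segments(segs, SegmentFilterParams(literal_conjunction=True))
        # excluded only when both criteria fail
        assert len(out) == 1

    def test_requires_annotation(self):
        segs = make_segments([("a", "b", "chr1", 10, 20, 5.0)])
        with pytest.raises(ValueError, match="length_cm"):
            filter_segments(segs)

    def test_report_reasons_partition(self):
        segs = make_segments(
            [
                ("a", "b", "chr1", 10, 20, 2.0, 2.0),
                ("a", "b", "chr1", 10, 20, 5.0, 0.5),
                ("a", "b", "chr1", 10, 20, 2.0, 0.5),
                ("a", "b", "chr1", 10, 20, 5.0, 5.0),
            ]
        )
        _, report = filter_segments(segs)
        assert report["n_excluded_lod"] == 1
        assert report["n_excluded_length"] == 1
        assert report["n_excluded_both"] == 1
        assert report["n_kept"] == 1


class TestSpanningCounts:
    LABELS = pd.Series(
        {"a": CASE, "b": CASE, "c": CONTROL, "d": CONTROL}
    )

    def test_no_segments(self):
        prof = spanning_counts(make_segments([]), FIVE_MARKERS, self.LABELS)
        assert prof.count_cc.sum() == prof.count_cn.sum() == prof.count_nn.sum() == 0
        assert prof.n_cc == 1 and prof.n_cn == 4 and prof.n_nn == 1

    def test_single_case_case_segment(self):
        segs = make_segments([("a", "b", "chr1", 150, 420, 5.0)])
        prof = spanning_counts(segs, FIVE_MARKERS, self.LABELS)
        assert prof.count_cc.tolist() == [0, 1, 1, 1, 0]
        assert prof.count_cn.tolist() == [0] * 5

    def test_pair_classes_routed(self):
        segs = make_segments(
            [("a", "c", "chr1", 1, 600, 5.0), ("c", "d", "chr1", 1, 600, 5.0)]
        )
        prof = spanning_counts(segs, FIVE_MARKERS, self.LABELS)
        assert prof.count_cn.tolist() == [1] * 5
        assert prof.count_nn.tolist() == [1] * 5

    def test_missing_label_raises(self):
        segs = make_segments([("a", "zz", "chr1", 1, 600, 5.0)])
        with pytest.raises(ValueError, match="zz"):
            spanning_counts(segs, FIVE_MARKERS, self.LABELS)

    def test_sweep_equals_bruteforce_random(self):
        rng = np.random.default_rng(42)
        chroms = [Chromosome("chr1", 10_000), Chromosome("chr2", 8_000)]
        ids = [f"s{i}" for i in range(8)]
        labels = pd.Series(rng.integers(0, 2, size=8).astype(np.int8), index=ids)
        markers = pd.DataFrame(
            {"id": [f"m{i}" for i in range(30)],
             "chrom": ["chr1"] * 15 + ["chr2"] * 15,
             "bp": sorted(rng.choice(np.arange(1, 10_000), 15, replace=False).tolist())
             + sorted(rng.choice(np.arange(1, 8_000), 15, replace=False).tolist())}
        )
        for _ in range(20):
            segs = random_segments(rng, ids, chroms, 60)
            prof = spanning_counts(segs, markers, labels)
            brute = spanning_counts_bruteforce(segs, markers, labels)
            assert np.array_equal(prof.count_cc, brute["cc"])
            assert np.array_equal(prof.count_cn, brute["cn"])
            assert np.array_equal(prof.count_nn, brute["nn"])

    def test_segment_removal_monotone(self):
        rng = np.random.default_rng(7)
        chroms = [Chromosome("chr1", 10_000)]
        ids = [f"s{i}" for i in range(6)]
        labels = pd.Series([CASE] * 3 + [CONTROL] * 3, index=ids)
        markers = FIVE_MARKERS
        segs = random_segments(rng, ids, chroms, 40)
        full = spanning_counts(segs, markers, labels)
        sub = spanning_counts(segs.iloc[:30], markers, labels)
        assert (sub.count_all <= full.count_all).all()


class TestStatistic:
    def profile(self, count_cc, n_cc=10):
        m = len(count_cc)
        markers = pd.DataFrame({"id": [f"m{i}" for i in range(m)], "chrom": "chr1",
                                "bp": np.arange(1, m + 1)})
        z = np.zeros(m, dtype=int)
        return SharingProfile(markers, np.asarray(count_cc), z, z, n_cc, 5, 5)

    def test_uniform_profile_average(self):
        prof = self.profile([4, 4, 4, 4], n_cc=8)
        assert genomewide_average(prof) == pytest.approx(0.5)

    def test_zero_profile_average_is_zero(self):
        assert genomewide_average(self.profile([0, 0, 0])) == 0.0

    def test_no_case_pairs_raises(self):
        with pytest.raises(ValueError, match="case-case"):
            genomewide_average(self.profile([1, 2], n_cc=0))

    def test_statistic_normalisation(self):
        prof = self.profile([2, 4, 0, 2], n_cc=10)
        gw = genomewide_average(prof)
        s = mapping_statistic(prof, gw)
        assert s[0] == pytest.approx(1.0)  # marker at the genome-wide average
        assert s[2] == 0.0
        assert s[1] == pytest.approx(2.0)

    def test_scale_invariance(self):
        prof1 = self.profile([2, 4, 0, 2], n_cc=10)
        prof2 = self.profile([4, 8, 0, 4], n_cc=10)
        s1 = mapping_statistic(prof1, genomewide_average(prof1))
        s2 = mapping_statistic(prof2, genomewide_average(prof2))
        assert np.allclose(s1, s2)

    def test_zero_average_raises(self):
        with pytest.raises(ValueError):
            mapping_statistic(self.profile([1, 2]), 0.0)


class TestCoverageFilter:
    MARKERS10 = pd.DataFrame(
        {"id": [f"m{i}" for i in range(10)], "chrom": "chr1",
         "bp": np.arange(100, 1100, 100)}
    )

    def counts_mask(self, counts, fraction):
        from pbla.mapping import _mask_low_coverage

        return _mask_low_coverage(np.asarray(counts), fraction)

    def test_all_equal_none_masked(self):
        assert not self.counts_mask([5] * 10, 0.10).any()

    def test_single_zero_count_masked(self):
        # counts [0, 5 x 9], q10 = 4.5 by linear interpolation
        mask = self.counts_mask([0] + [5] * 9, 0.10)
        assert mask.tolist() == [True] + [False] * 9

    def test_increasing_counts_mask_fraction(self):
        mask = self.counts_mask(np.arange(1, 101), 0.10)
        assert mask.sum() == 10  # q = 10.9 -> counts 1..10 masked

    def test_from_segments(self):
        segs = make_segments([("a", "b", "chr1", 150, 1050, 5.0)] * 3)
        mask = coverage_filter(segs, self.MARKERS10, 0.10)
        # marker m0 at bp 100 uncovered (count 0), all others covered (count 3)
        assert mask.tolist() == [True] + [False] * 9

    def test_continuous_counts_converge_to_fraction(self):
        rng = np.random.default_rng(0)
        counts = rng.random(10_000)
        assert abs(self.counts_mask(counts, 0.25).mean() - 0.25) < 0.01

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError):
            self.counts_mask([1, 2, 3], 1.5)


class TestPermutationMapping:
    def small_instance(self, seed=0, enrichment=1.0, n=20):
        spec = SimSpec(
            n_cases=n, n_controls=n,
            chromosomes=[Chromosome("chr1", 50_000_000, 1.0)],
            n_markers_per_chrom=50,
            planted_locus=("chr1", 25_000_000) if enrichment > 1 else None,
            enrichment=enrichment, seed=seed,
        )
        segs, _ = simulate_ibd_segments(spec)
        gmap = GeneticMap.uniform(spec.chromosomes)
        kept, _ = filter_segments(annotate_segments(segs, gmap))
        ids, pheno = default_cohort(spec)
        labels = pd.Series(pheno, index=ids)
        markers = uniform_marker_table(spec.chromosomes, spec.n_markers_per_chrom)
        return kept, labels, markers

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            MappingParams(n_permutations=0)

    def test_single_class_labels_rejected(self):
        kept, labels, markers = self.small_instance()
        labels[:] = CASE
        with pytest.raises(ValueError, match="two cases and two controls"):
            permutation_mapping(kept, labels, markers, MappingParams(n_permutations=10))

    def test_deterministic_given_seed(self):
        kept, labels, markers = self.small_instance(seed=3)
        params = MappingParams(n_permutations=100, seed=11)
        r1 = permutation_mapping(kept, labels, markers, params)
        r2 = permutation_mapping(kept, labels, markers, params)
        assert np.array_equal(r1.p_pointwise, r2.p_pointwise)
        assert r1.threshold_statistic == r2.threshold_statistic

    def test_pvalues_valid_range(self):
        kept, labels, markers = self.small_instance(seed=5)
        res = permutation_mapping(kept, labels, markers, MappingParams(n_permutations=99, seed=1))
        assert np.all(res.p_pointwise > 0) and np.all(res.p_pointwise <= 1)
        assert res.p_pointwise.min() >= 1 / 100  # add-one estimator floor

    def test_null_pvalues_stochastically_uniform_or_larger(self):
        """Conservative add-one p-values: mean over markers >= ~0.5 under the null."""
        means = []
        for seed in range(5):
            kept, labels, markers = self.small_instance(seed=seed)
            res = permutation_mapping(
                kept, labels, markers, MappingParams(n_permutations=100, seed=seed + 50)
            )
            means.append(res.p_pointwise.mean())
        assert np.mean(means) > 0.45

    def test_relabelling_invariance(self):
        """Renaming samples consistently leaves every statistic unchanged."""
        kept, labels, markers = self.small_instance(seed=7)
        res1 = permutation_mapping(kept, labels, markers, MappingParams(n_permutations=50, seed=2))
        rename = {sid: f"x_{sid}" for sid in labels.index}
        kept2 = kept.copy()
        kept2["sample1"] = kept2["sample1"].map(rename)
        kept2["sample2"] = kept2["sample2"].map(rename)
        labels2 = pd.Series(labels.to_numpy(), index=[rename[s] for s in labels.index])
        res2 = permutation_mapping(kept2, labels2, markers, MappingParams(n_permutations=50, seed=2))
        assert np.array_equal(res1.statistic, res2.statistic)
        assert np.array_equal(res1.p_pointwise, res2.p_pointwise)

    def test_planted_locus_is_top_marker(self):
        kept, labels, markers = self.small_instance(seed=9, enrichment=8.0, n=50)
        res = permutation_mapping(kept, labels, markers, MappingParams(n_permutations=200, seed=4))
        top = int(np.argmax(res.statistic))
        planted = int(np.argmin(np.abs(markers["bp"] - 25_000_000)))
        assert abs(top - planted) <= 1  # enrichment splits between flanking markers

    def test_significant_requires_unmasked(self):
        kept, labels, markers = self.small_instance(seed=13)
        res = permutation_mapping(kept, labels, markers, MappingParams(n_permutations=50, seed=3))
        assert not np.any(res.significant & res.low_coverage)

    def test_gw_pvalue_at_least_pointwise(self):
        kept, labels, markers = self.small_instance(seed=15)
        res = permutation_mapping(kept, labels, markers, MappingParams(n_permutations=100, seed=5))
        assert np.all(res.p_genomewide >= res.p_pointwise - 1e-12)


class TestSignificantMarkers:
    def result(self, significant, low_coverage):
        from pbla.mapping import MappingResult

        m = len(significant)
        markers = pd.DataFrame({"id": [f"m{i}" for i in range(m)], "chrom": "chr1",
                                "bp": np.arange(1, m + 1)})
        sig = np.asarray(significant) & ~np.asarray(low_coverage)
        return MappingResult(
            markers=markers, statistic=np.ones(m), p_pointwise=np.full(m, 0.5),
            p_genomewide=np.full(m, 0.5), low_coverage=np.asarray(low_coverage),
            exceeds_threshold=np.asarray(significant), significant=sig,
            threshold_statistic=1.0, threshold_p=0.05, gw_avg=0.1,
            n_permutations=10, seed=0,
        )

    def test_masked_hit_excluded(self):
        res = self.result([True, True, False], [True, False, False])
        out = significant_markers(res)
        assert out["id"].tolist() == ["m1"]

    def test_empty_result_valid(self):
        res = self.result([False] * 3, [False] * 3)
        assert len(significant_markers(res)) == 0
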