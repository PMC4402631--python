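"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pbla.core import CASE, CONTROL
from pbla.sim import SimSpec, default_cohort, uniform_marker_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Exact-rational HWE test by brute enumeration of heterozygote counts.

    Conditions on the observed allele counts; sums multinomial weights
    n!/(a! h! b!) * 2^h of all configurations as or less probable than the
    observed one. Fully independent of the package implementation.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    rare = min(n_A, n_a)
    if rare == 0:
        return Fraction(1)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (rare - h) // 2
        b = (2 * n - rare - h) // 2
        weights[h] = comb(n, a) * comb(n - a, h) * 2**h
    obs = weights[n_Aa]
    return Fraction(sum(w for w in weights.values() if w <= obs), sum(weights.values()))


def spanning_counts_bruteforce(segments: pd.DataFrame, markers: pd.DataFrame, labels: pd.Series):
    """Double loop over (segment, marker): the independent spanning oracle."""
    m = len(markers)
    counts = {"cc": np.zeros(m, dtype=int), "cn": np.zeros(m, dtype=int), "nn": np.zeros(m, dtype=int)}
    chrom = markers["chrom"].to_numpy()
    bp = markers["bp"].to_numpy()
    for seg in segments.itertuples(index=False):
        l1, l2 = labels[seg.sample1], labels[seg.sample2]
        if l1 == CASE and l2 == CASE:
            cls = "cc"
        elif l1 == CONTROL and l2 == CONTROL:
            cls = "nn"
        else:
            cls = "cn"
        for j in range(m):
            if chrom[j] == seg.chrom and seg.start_bp <= bp[j] <= seg.end_bp:
                counts[cls][j] += 1
    return counts


def random_segments(rng, sample_ids, chroms, n):
    """Random canonical segment table on the given chromosomes."""
    names = [c.name for c in chroms]
    lengths = {c.name: c.length_bp for c in chroms}
    rows = []
    for _ in range(n):
        i, j = sorted(rng.choice(len(sample_ids), size=2, replace=False))
        chrom = names[rng.integers(len(names))]
        a, b = sorted(rng.integers(1, lengths[chrom], size=2) + np.array([0, 1]))
        rows.append((sample_ids[i], rng.integers(1, 3), sample_ids[j], rng.integers(1, 3),
                     chrom, int(a), int(b), float(rng.uniform(3, 10))))
    from pbla.core import SEGMENT_COLUMNS

    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


@pytest.fixture
def small_spec():
    """A quick 20+20 cohort on one short chromosome."""
    from pbla.sim import Chromosome

    return SimSpec(
        n_cases=20,
        n_controls=20,
        chromosomes=[Chromosome("chr1", 50_000_000, 1.0)],
        n_markers_per_chrom=50,
        seed=123,
    )


@pytest.fixture
def cohort_labels():
    def make(spec: SimSpec) -> pd.Series:
        ids, pheno = default_cohort(spec)
        return pd.Series(pheno, index=ids)

    return make
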