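"""Synthetic cohorts for population-based linkage analysis.

Three generators emulate the statistical structure the pipeline assumes,
so every downstream stage is testable without access-controlled data:

* :func:`simulate_panel` — diploid biallelic genotype panels with optional
  planted QC failures (low MAF, Hardy-Weinberg violation, missingness).
* :func:`simulate_embedding` — a dense main cluster in PC space plus
  planted outliers, for the two-stage outlier-removal algorithm.
* :func:`simulate_ibd_segments` — pairwise IBD segments with
  Pareto-distributed centiMorgan lengths, reduced detection near
  chromosome ends, and an optional planted risk locus at which case-case
  pairs share in excess.

All generators are deterministic given :attr:`SimSpec.seed`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CASE, CONTROL, MISSING, GenotypePanel, PCEmbedding

__all__ = [
    "Chromosome",
    "SimSpec",
    "default_chromosomes",
    "default_cohort",
    "uniform_marker_table",
    "pareto_lengths",
    "simulate_panel",
    "simulate_embedding",
    "simulate_ibd_segments",
]


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with a uniform genetic-map rate."""

    name: str
    length_bp: int
    cm_per_mb: float = 1.0

    @property
    def length_cm(self) -> float:
        return self.length_bp / 1e6 * self.cm_per_mb

    def bp_to_cm(self, bp) -> np.ndarray:
        return np.asarray(bp, dtype=float) / 1e6 * self.cm_per_mb

    def cm_to_bp(self, cm) -> np.ndarray:
        return np.asarray(cm, dtype=float) / self.cm_per_mb * 1e6


def default_chromosomes() -> list[Chromosome]:
    """Two 100-Mb chromosomes at 1 cM/Mb (a 2-Morgan desk-scale genome)."""
    return [Chromosome("chr1", 100_000_000, 1.0), Chromosome("chr2", 100_000_000, 1.0)]


@dataclass
class SimSpec:
    """Parameters of the synthetic cohort.

    Defaults describe the desk-scale study conditions used throughout the
    test-suite: a 50+50 cohort on a 2-Morgan genome whose segment-sharing
    rate yields roughly 20 case-case segments spanning a typical marker
    after the standard LOD >= 3 / length >= 1 cM filter.

    Attributes
    ----------
    base_share_rate
        Expected IBD segments per sample pair per Morgan of genome,
        before any filtering.
    pareto_shape, pareto_scale
        Shape alpha > 1 and scale x_m (cM) of the segment-length
        distribution; the mean alpha*x_m/(alpha-1) is ~1.08 cM at the
        defaults, matching the empirically observed "slightly above 1 cM".
    planted_locus
        ``(chrom_name, bp)`` of a risk locus, or ``None``.
    enrichment
        Multiplicative factor >= 1 on the expected number of case-case
        segments overlapping the planted locus (1 = null).
    telomere_width_cm, telomere_retention
        Segments whose midpoint lies within ``telomere_width_cm`` of a
        chromosome end are kept with probability ``telomere_retention``,
        emulating reduced IBD detection near telomeres.
    lod_exp_mean, lod_below3_frac
        LOD scores are 3 + Exponential(mean ``lod_exp_mean``); a fraction
        ``lod_below3_frac`` is instead drawn Uniform(0, 3) to exercise the
        LOD filter.
    """

    n_cases: int = 50
    n_controls: int = 50
    chromosomes: list[Chromosome] = field(default_factory=default_chromosomes)
    n_markers_per_chrom: int = 250
    maf_range: tuple[float, float] = (0.15, 0.45)
    missing_rate: float = 0.0
    base_share_rate: float = 3.0
    pareto_shape: float = 2.5
    pareto_scale: float = 0.65
    planted_locus: tuple[str, int] | None = None
    enrichment: float = 1.0
    telomere_width_cm: float = 5.0
    telomere_retention: float = 0.5
    lod_exp_mean: float = 2.0
    lod_below3_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pareto_shape <= 1:
            raise ValueError("pareto_shape must exceed 1 for a finite mean length")
        if self.pareto_scale <= 0:
            raise ValueError("pareto_scale must be positive")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if not 0 <= self.telomere_retention <= 1:
            raise ValueError("telomere_retention must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 0.5:
            raise ValueError("maf_range must be within (0, 0.5)")
        if self.planted_locus is not None:
            chrom, bp = self.planted_locus
            match = [c for c in self.chromosomes if c.name == chrom]
            if not match or not 1 <= bp <= match[0].length_bp:
                raise ValueError(f"planted locus {self.planted_locus} outside the genome")

    @property
    def mean_segment_length_cm(self) -> float:
        """Closed-form Pareto mean alpha*x_m/(alpha-1)."""
        return self.pareto_shape * self.pareto_scale / (self.pareto_shape - 1)

    @property
    def genome_morgans(self) -> float:
        return sum(c.length_cm for c in self.chromosomes) / 100.0


def default_cohort(spec: SimSpec) -> tuple[list[str], np.ndarray]:
    """Sample ids and phenotype codes for the spec's cohort (cases first)."""
    ids = [f"case{i:04d}" for i in range(1, spec.n_cases + 1)]
    ids += [f"ctrl{i:04d}" for i in range(1, spec.n_controls + 1)]
    pheno = np.array([CASE] * spec.n_cases + [CONTROL] * spec.n_controls, dtype=np.int8)
    return ids, pheno


def uniform_marker_table(chromosomes: list[Chromosome], n_per_chrom: int) -> pd.DataFrame:
    """Evenly spaced markers along each chromosome, with cM positions."""
    frames = []
    for c in chromosomes:
        bp = np.round(np.linspace(0, c.length_bp, n_per_chrom + 2)[1:-1]).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{c.name}_m{i:05d}" for i in range(1, n_per_chrom + 1)],
                    "chrom": c.name,
                    "bp": bp,
                    "cm": c.bp_to_cm(bp),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def pareto_lengths(n: int, shape: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` segment lengths (cM) from Pareto(shape, scale)."""
    return scale * (1.0 + rng.pareto(shape, size=n))


# ---------------------------------------------------------------------------
# genotype panel


def _draw_hwe_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    return rng.choice(3, size=n, p=p).astype(np.int8)


def _marker_passes(calls: np.ndarray, maf_min: float, hwe_p_min: float) -> bool:
    """Margin check on the observed (non-missing) genotypes."""
    from .qc import hwe_exact_p

    obs = calls[calls != MISSING]
    if len(obs) == 0:
        return False
    freq = obs.sum() / (2 * len(obs))
    maf = min(freq, 1 - freq)
    if maf < maf_min:
        return False
    counts = np.bincount(obs, minlength=3)
    return hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2])) >= hwe_p_min


def simulate_panel(
    spec: SimSpec,
    n_maf_fail: int = 0,
    n_hwe_fail: int = 0,
    n_marker_missing_fail: int = 0,
    n_ind_missing_fail: int = 0,
) -> tuple[GenotypePanel, dict]:
    """Simulate a genotype panel with exactly the requested QC failures planted.

    Non-planted markers are drawn at HWE proportions with MAF in
    ``spec.maf_range`` and rejection-resampled until they pass the standard
    QC thresholds with margin (observed MAF >= 0.10, HWE p >= 1e-3,
    missingness <= 0.05), so the planted failures are exactly the removals
    a QC run reports.

    Returns
    -------
    panel, truth
        The panel and a truth record with keys ``maf_fail``, ``hwe_fail``,
        ``marker_missing_fail`` (marker ids) and ``ind_missing_fail``
        (sample ids).

    Raises
    ------
    ValueError
        If a planted failure is infeasible at the cohort size (for example
        an all-heterozygote marker whose exact-test p cannot reach 1e-6).
    """
    from .qc import hwe_exact_p

    rng = np.random.default_rng(spec.seed)
    sample_ids, pheno = default_cohort(spec)
    n = len(sample_ids)
    markers = uniform_marker_table(spec.chromosomes, spec.n_markers_per_chrom)
    m = len(markers)

    n_marker_plants = n_maf_fail + n_hwe_fail + n_marker_missing_fail
    if n_marker_plants > m:
        raise ValueError("more planted marker failures than markers")
    if n_ind_missing_fail > n:
        raise ValueError("more planted individual failures than samples")

    bad_ind = rng.choice(n, size=n_ind_missing_fail, replace=False)
    good_ind = np.setdiff1d(np.arange(n), bad_ind)
    g = len(good_ind)
    if g < 2:
        raise ValueError("too few unplanted individuals")

    plant_idx = rng.choice(m, size=n_marker_plants, replace=False)
    maf_idx = plant_idx[:n_maf_fail]
    hwe_idx = plant_idx[n_maf_fail : n_maf_fail + n_hwe_fail]
    mmiss_idx = plant_idx[n_maf_fail + n_hwe_fail :]
    planted = set(plant_idx.tolist())

    if n_hwe_fail and hwe_exact_p(0, g, 0) >= 1e-6:
        raise ValueError(f"HWE-failure plant infeasible with {g} unplanted individuals")
    minor_count = max(1, round(0.025 * 2 * g))
    if n_maf_fail and minor_count / (2 * g) >= 0.05:
        raise ValueError(f"MAF-failure plant infeasible with {g} unplanted individuals")

    calls = np.full((n, m), MISSING, dtype=np.int8)
    n_miss_marker = math.ceil(0.15 * g)  # > 0.1 threshold with margin

    for j in range(m):
        miss_mask = np.zeros(n, dtype=bool)
        if spec.missing_rate > 0 and j not in planted:
            miss_mask[good_ind] = rng.random(g) < spec.missing_rate
            # keep per-marker missingness safely below the 0.1 threshold
            while miss_mask[good_ind].sum() / g > 0.05:
                on = np.flatnonzero(miss_mask)
                miss_mask[rng.choice(on)] = False
        col = np.empty(n, dtype=np.int8)
        if j in set(hwe_idx.tolist()):
            col[:] = 1  # all-heterozygote excess: exact-test p << 1e-6
        elif j in set(maf_idx.tolist()):
            col[:] = 0
            het = rng.choice(good_ind, size=minor_count, replace=False)
            col[het] = 1
        else:
            for _attempt in range(1000):
                maf = rng.uniform(*spec.maf_range)
                col = _draw_hwe_genotypes(n, maf, rng)
                obs = col[good_ind][~miss_mask[good_ind]]
                if len(obs) and _marker_passes(obs, maf_min=0.10, hwe_p_min=1e-3):
                    break
            else:  # pragma: no cover - margins make this unreachable in practice
                raise RuntimeError(f"could not draw a passing marker {j}")
            if j in set(mmiss_idx.tolist()):
                extra = rng.choice(good_ind, size=n_miss_marker, replace=False)
                miss_mask[extra] = True
        col = col.copy()
        col[miss_mask] = MISSING
        calls[:, j] = col

    # planted high-missingness individuals: 12% of markers missing (> 0.07)
    n_miss_ind = math.ceil(0.12 * m)
    for i in bad_ind:
        cols = rng.choice(m, size=n_miss_ind, replace=False)
        calls[i, cols] = MISSING

    truth = {
        "maf_fail": sorted(markers["id"].iloc[sorted(maf_idx)]),
        "hwe_fail": sorted(markers["id"].iloc[sorted(hwe_idx)]),
        "marker_missing_fail": sorted(markers["id"].iloc[sorted(mmiss_idx)]),
        "ind_missing_fail": sorted(sample_ids[i] for i in bad_ind),
    }
    panel = GenotypePanel(sample_ids=sample_ids, phenotype=pheno, calls=calls, markers=markers)
    return panel, truth


# ---------------------------------------------------------------------------
# PC embedding


def simulate_embedding(
    n_core: int,
    n_outliers: int,
    dims: int = 6,
    core_scale: float = 0.03,
    outlier_offset: float = 0.3,
    seed: int = 0,
) -> tuple[PCEmbedding, np.ndarray]:
    """A spherical Gaussian core cluster plus planted outliers.

    Core samples are drawn from N(0, core_scale^2 I) in ``dims`` dimensions;
    outliers sit at distance ``outlier_offset`` from the origin in random
    directions. Returns the embedding and a truth label array of
    ``"core"`` / ``"outlier"`` strings.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if outlier_offset <= 0:
        raise ValueError("outlier_offset must be positive")
    if n_core < 11:
        raise ValueError("need at least 11 core samples for 10-NN statistics")
    rng = np.random.default_rng(seed)
    core = rng.normal(scale=core_scale, size=(n_core, dims))
    directions = rng.normal(size=(n_outliers, dims))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    outliers = directions * outlier_offset
    coords = np.vstack([core, outliers])
    ids = [f"E{i:05d}" for i in range(1, n_core + n_outliers + 1)]
    labels = np.array(["core"] * n_core + ["outlier"] * n_outliers)
    return PCEmbedding(sample_ids=ids, coords=coords), labels


# ---------------------------------------------------------------------------
# IBD segments


def simulate_ibd_segments(
    spec: SimSpec,
    sample_ids: list[str] | None = None,
    phenotype: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate pairwise IBD segments for a labelled cohort.

    For every unordered sample pair the segment count is
    Poisson(base_share_rate x genome Morgans); midpoints are uniform in
    genetic distance, lengths i.i.d. Pareto(shape, scale) cM truncated at
    chromosome ends. Segments whose midpoint falls within
    ``telomere_width_cm`` of an end survive with probability
    ``telomere_retention``. With a planted locus, case-case segments
    overlapping it are replicated so their expected multiplicity equals
    ``enrichment`` (marginal length distribution unchanged). Each segment
    receives a LOD score draw.

    Returns the canonical segment table (bp coordinates, 1-based inclusive)
    and a truth record.
    """
    rng = np.random.default_rng(spec.seed)
    if sample_ids is None:
        sample_ids, phenotype = default_cohort(spec)
    if phenotype is None:
        raise ValueError("phenotype labels required with explicit sample_ids")
    phenotype = np.asarray(phenotype)
    if len(sample_ids) != len(phenotype):
        raise ValueError("sample_ids and phenotype length mismatch")

    order = np.argsort(np.asarray(sample_ids, dtype=object))
    ids_sorted = [sample_ids[i] for i in order]
    case = phenotype[order] == CASE
    n = len(ids_sorted)
    ii, jj = np.triu_indices(n, k=1)

    chroms = spec.chromosomes
    lens_cm = np.array([c.length_cm for c in chroms])
    lam = spec.base_share_rate * spec.genome_morgans
    per_pair = rng.poisson(lam, size=len(ii))
    pair_of_seg = np.repeat(np.arange(len(ii)), per_pair)
    k = len(pair_of_seg)

    chrom_idx = rng.choice(len(chroms), size=k, p=lens_cm / lens_cm.sum())
    mid = rng.uniform(0, lens_cm[chrom_idx])
    length = pareto_lengths(k, spec.pareto_shape, spec.pareto_scale, rng)
    start_cm = np.clip(mid - length / 2, 0, lens_cm[chrom_idx])
    end_cm = np.clip(mid + length / 2, 0, lens_cm[chrom_idx])

    n_telomere_dropped = 0
    if spec.telomere_retention < 1:
        near = (mid < spec.telomere_width_cm) | (mid > lens_cm[chrom_idx] - spec.telomere_width_cm)
        drop = near & (rng.random(k) >= spec.telomere_retention)
        n_telomere_dropped = int(drop.sum())
        keep = ~drop
        pair_of_seg, chrom_idx = pair_of_seg[keep], chrom_idx[keep]
        start_cm, end_cm = start_cm[keep], end_cm[keep]
        k = len(pair_of_seg)

    s1_idx, s2_idx = ii[pair_of_seg], jj[pair_of_seg]
    is_cc = case[s1_idx] & case[s2_idx]

    if spec.planted_locus is not None and spec.enrichment > 1:
        locus_chrom, locus_bp = spec.planted_locus
        ci = next(i for i, c in enumerate(chroms) if c.name == locus_chrom)
        locus_cm = chroms[ci].bp_to_cm(locus_bp)
        covers = (chrom_idx == ci) & (start_cm <= locus_cm) & (locus_cm <= end_cm) & is_cc
        extra = math.floor(spec.enrichment - 1)
        frac = spec.enrichment - 1 - extra
        copies = np.ones(k, dtype=np.int64)
        copies[covers] += extra
        if frac > 0:
            copies[covers] += rng.random(covers.sum()) < frac
        rep = np.repeat(np.arange(k), copies)
        s1_idx, s2_idx = s1_idx[rep], s2_idx[rep]
        chrom_idx, start_cm, end_cm = chrom_idx[rep], start_cm[rep], end_cm[rep]
        k = len(rep)

    lod = 3.0 + rng.exponential(spec.lod_exp_mean, size=k)
    if spec.lod_below3_frac > 0:
        low = rng.random(k) < spec.lod_below3_frac
        lod[low] = rng.uniform(0, 3, size=low.sum())

    rates = np.array([c.cm_per_mb for c in chroms])[chrom_idx]
    length_bp = np.array([c.length_bp for c in chroms])[chrom_idx]
    start_bp = np.floor(start_cm / rates * 1e6).astype(np.int64) + 1
    end_bp = np.ceil(end_cm / rates * 1e6).astype(np.int64)
    start_bp = np.clip(start_bp, 1, length_bp - 1)
    end_bp = np.clip(np.maximum(end_bp, start_bp + 1), 2, length_bp)

    names = np.array([c.name for c in chroms], dtype=object)
    id_arr = np.array(ids_sorted, dtype=object)
    segments = pd.DataFrame(
        {
            "sample1": id_arr[s1_idx],
            "hap1": rng.integers(1, 3, size=k).astype(np.int8),
            "sample2": id_arr[s2_idx],
            "hap2": rng.integers(1, 3, size=k).astype(np.int8),
            "chrom": names[chrom_idx],
            "start_bp": start_bp,
            "end_bp": end_bp,
            "lod": lod,
        }
    )
    truth = {
        "planted_locus": spec.planted_locus,
        "enrichment": spec.enrichment,
        "n_segments": k,
        "n_telomere_dropped": n_telomere_dropped,
        "n_case_case": int(is_cc.sum()) if spec.enrichment == 1 else int((case[s1_idx] & case[s2_idx]).sum()),
    }
    return segments, truth
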