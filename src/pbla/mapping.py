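"""IBD case-control mapping: segment filtering, per-marker sharing
profiles, the normalised case-case sharing statistic, permutation-based
genome-wide significance, and the low-IBD-coverage marker filter.

The per-marker statistic is the case-case sharing rate normalised by the
genome-wide average case-case rate,

    s(m) = (count_cc(m) / N_cc) / gw_avg,
    gw_avg = mean_m count_cc(m) / N_cc,

so the permutation test is corrected for average genome-wide sharing:
each label permutation is normalised by its own genome-wide average.
Genome-wide significance uses the per-permutation maximum of s, giving
family-wise error control at the nominal level; markers falling in the
lowest-coverage decile of total IBD detection are masked as likely
telomeric artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .core import CASE, CONTROL, phenotype_codes, validate_segments

__all__ = [
    "SegmentFilterParams",
    "MappingParams",
    "SharingProfile",
    "MappingResult",
    "filter_segments",
    "spanning_counts",
    "genomewide_average",
    "mapping_statistic",
    "permutation_mapping",
    "coverage_filter",
    "significant_markers",
]


@dataclass(frozen=True)
class SegmentFilterParams:
    """Segment exclusion thresholds: LOD >= lod_min and length >= length_min_cm.

    With ``literal_conjunction=True`` a segment is excluded only when it
    fails *both* criteria (the alternative reading of the exclusion rule).
    """

    lod_min: float = 3.0
    length_min_cm: float = 1.0
    literal_conjunction: bool = False

    def __post_init__(self) -> None:
        if self.lod_min < 0 or self.length_min_cm < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class MappingParams:
    """Permutation-analysis parameters.

    ``n_permutations`` defaults to a desk-scale 10,000 (the full-scale
    analysis used millions); ``fwer_level`` is the genome-wide
    family-wise error level; ``coverage_fraction`` the low-IBD-detection
    quantile masked. ``literal_pvalue_quantile=True`` selects the literal
    reading of the genome-wide threshold as the 0.0005 quantile of
    pointwise permutation p-values instead of FWER control at 0.05.
    """

    n_permutations: int = 10_000
    fwer_level: float = 0.05
    coverage_fraction: float = 0.10
    seed: int = 0
    literal_pvalue_quantile: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.fwer_level < 1:
            raise ValueError("fwer_level must lie in (0, 1)")
        if not 0 < self.coverage_fraction < 1:
            raise ValueError("coverage_fraction must lie in (0, 1)")


@dataclass
class SharingProfile:
    """Per-marker counts of spanning segments by pair class."""

    markers: pd.DataFrame
    count_cc: np.ndarray
    count_cn: np.ndarray
    count_nn: np.ndarray
    n_cc: int
    n_cn: int
    n_nn: int

    @property
    def count_all(self) -> np.ndarray:
        return self.count_cc + self.count_cn + self.count_nn


@dataclass
class MappingResult:
    """Per-marker mapping output.

    ``exceeds_threshold`` is the raw permutation genome-wide call;
    ``significant`` additionally requires the marker not be low-coverage
    masked (the reportable hits).
    """

    markers: pd.DataFrame
    statistic: np.ndarray
    p_pointwise: np.ndarray
    p_genomewide: np.ndarray
    low_coverage: np.ndarray
    exceeds_threshold: np.ndarray
    significant: np.ndarray
    threshold_statistic: float
    threshold_p: float
    gw_avg: float
    n_permutations: int
    seed: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = self.markers[["chrom", "bp", "id"]].copy()
        df["statistic"] = self.statistic
        df["p"] = self.p_pointwise
        df["p_gw"] = self.p_genomewide
        df["low_coverage"] = self.low_coverage
        df["significant"] = self.significant
        return df


def filter_segments(
    segments: pd.DataFrame, params: SegmentFilterParams = SegmentFilterParams()
) -> tuple[pd.DataFrame, dict]:
    """Apply LOD/length exclusion; return kept segments and an exclusion report.

    Requires ``length_cm`` annotation (see :func:`pbla.segio.annotate_segments`).
    """
    validate_segments(segments)
    if "length_cm" not in segments.columns:
        raise ValueError("segments lack length_cm; annotate with a genetic map first")
    lod_ok = segments["lod"] >= params.lod_min
    len_ok = segments["length_cm"] >= params.length_min_cm
    if params.literal_conjunction:
        keep = lod_ok | len_ok
    else:
        keep = lod_ok & len_ok
    report = {
        "n_input": len(segments),
        "n_kept": int(keep.sum()),
        "n_excluded_lod": int((~lod_ok & len_ok).sum()),
        "n_excluded_length": int((lod_ok & ~len_ok).sum()),
        "n_excluded_both": int((~lod_ok & ~len_ok).sum()),
    }
    return segments[keep].reset_index(drop=True), report


def _marker_arrays(markers: pd.DataFrame) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Per-chromosome marker bp arrays and global index offsets."""
    by_chrom, offsets = {}, {}
    off = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = grp["bp"].to_numpy()
        offsets[str(chrom)] = off
        off += len(grp)
    return by_chrom, offsets


def _segment_spans(segments: pd.DataFrame, markers: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Global first/last spanned marker index per segment (-1,-2 when none).

    A segment spans marker m iff start_bp <= bp(m) <= end_bp on the same
    chromosome.
    """
    by_chrom, offsets = _marker_arrays(markers)
    first = np.zeros(len(segments), dtype=np.int64)
    last = np.full(len(segments), -1, dtype=np.int64)
    seg = segments.reset_index(drop=True)
    for chrom, grp in seg.groupby("chrom", sort=False):
        if str(chrom) not in by_chrom:
            raise ValueError(f"segment chromosome {chrom!r} not in marker table")
        bp = by_chrom[str(chrom)]
        off = offsets[str(chrom)]
        loc = grp.index.to_numpy()
        first[loc] = off + np.searchsorted(bp, grp["start_bp"].to_numpy(), side="left")
        last[loc] = off + np.searchsorted(bp, grp["end_bp"].to_numpy(), side="right") - 1
    return first, last


def _pair_class_indices(
    segments: pd.DataFrame, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment sample indices into the label vector; errors on unlabelled."""
    sample_ids = labels.index.to_numpy(dtype=object)
    lookup = {sid: i for i, sid in enumerate(sample_ids)}
    try:
        i1 = np.array([lookup[s] for s in segments["sample1"]], dtype=np.int64)
        i2 = np.array([lookup[s] for s in segments["sample2"]], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"segment sample {exc.args[0]!r} has no phenotype label") from None
    return i1, i2


def _diff_counts(first: np.ndarray, last: np.ndarray, n_markers: int, which: np.ndarray) -> np.ndarray:
    """Spanning counts via an endpoint difference array (the sorted sweep)."""
    diff = np.zeros(n_markers + 1, dtype=np.int64)
    f, l = first[which], last[which]
    ok = f <= l
    np.add.at(diff, f[ok], 1)
    np.add.at(diff, l[ok] + 1, -1)
    return np.cumsum(diff[:-1])


def spanning_counts(
    segments: pd.DataFrame, markers: pd.DataFrame, labels
) -> SharingProfile:
    """Count segments spanning each marker, stratified by pair class.

    ``labels`` is a Series/dict of case/control per sample id (strings or
    integer codes). Pair totals N_cc, N_cn, N_nn are computed from the
    label vector.
    """
    validate_segments(segments)
    labels = phenotype_codes(labels)
    first, last = _segment_spans(segments, markers)
    i1, i2 = _pair_class_indices(segments, labels)
    lab = labels.to_numpy()
    known = np.isin(lab[i1], (CASE, CONTROL)) & np.isin(lab[i2], (CASE, CONTROL))
    if not known.all():
        bad = segments["sample1"].to_numpy()[~known][0]
        raise ValueError(f"segment sample {bad!r} has an unknown phenotype")
    case1, case2 = lab[i1] == CASE, lab[i2] == CASE
    cc = case1 & case2
    nn = ~case1 & ~case2
    cn = ~(cc | nn)

    m = len(markers)
    n_case = int((lab == CASE).sum())
    n_ctrl = int((lab == CONTROL).sum())
    return SharingProfile(
        markers=markers,
        count_cc=_diff_counts(first, last, m, cc),
        count_cn=_diff_counts(first, last, m, cn),
        count_nn=_diff_counts(first, last, m, nn),
        n_cc=n_case * (n_case - 1) // 2,
        n_cn=n_case * n_ctrl,
        n_nn=n_ctrl * (n_ctrl - 1) // 2,
    )


def genomewide_average(profile: SharingProfile) -> float:
    """Mean over markers of the case-case sharing rate count_cc(m)/N_cc."""
    if len(profile.markers) == 0:
        raise ValueError("profile has no markers")
    if profile.n_cc == 0:
        raise ValueError("no case-case pairs; genome-wide average undefined")
    return float(profile.count_cc.mean() / profile.n_cc)


def mapping_statistic(profile: SharingProfile, gw_avg: float) -> np.ndarray:
    """Per-marker normalised case-case sharing s(m) = (count_cc/N_cc)/gw_avg."""
    if gw_avg <= 0:
        raise ValueError("genome-wide average sharing must be positive")
    return profile.count_cc / profile.n_cc / gw_avg


def _span_matrix(first: np.ndarray, last: np.ndarray, n_markers: int) -> sparse.csr_matrix:
    """Sparse (n_markers x n_segments) indicator of segment-spans-marker."""
    ok = first <= last
    lengths = np.where(ok, last - first + 1, 0)
    cols = np.repeat(np.arange(len(first)), lengths)
    # concatenated ranges first[j]..last[j] without a Python loop
    starts = np.repeat(first, lengths)
    within = np.arange(lengths.sum()) - np.repeat(np.cumsum(lengths) - lengths, lengths)
    rows = starts + within
    data = np.ones(len(rows), dtype=np.float64)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_markers, len(first)))


def permutation_mapping(
    segments: pd.DataFrame,
    labels,
    markers: pd.DataFrame,
    params: MappingParams = MappingParams(),
) -> MappingResult:
    """Permutation analysis of the case-case sharing statistic.

    Case/control labels are shuffled preserving class sizes; for every
    permutation the statistic is recomputed with its own genome-wide
    average. Pointwise p-values use the add-one estimator
    ``(1 + #{s_perm(m) >= s_obs(m)}) / (P + 1)``. Genome-wide
    significance: s_obs(m) at or above the (1 - fwer_level) quantile of
    the per-permutation maxima of s (max-statistic FWER control); a
    genome-wide p-value per marker is reported from the maxima
    distribution. Markers in the lowest ``coverage_fraction`` of total
    spanning counts are masked; ``significant`` requires both.
    """
    validate_segments(segments)
    labels = phenotype_codes(labels)
    lab = labels.to_numpy()
    n_case = int((lab == CASE).sum())
    n_ctrl = int((lab == CONTROL).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least two cases and two controls")
    m = len(markers)
    if m == 0:
        raise ValueError("no markers")

    profile = spanning_counts(segments, markers, labels)
    first, last = _segment_spans(segments, markers)
    i1, i2 = _pair_class_indices(segments, labels)
    S = _span_matrix(first, last, m)

    count_obs = profile.count_cc.astype(np.float64)
    obs_mean = count_obs.mean()
    degenerate = obs_mean <= 0
    if degenerate:
        zeros = np.zeros(m)
        return MappingResult(
            markers=markers, statistic=zeros, p_pointwise=np.ones(m),
            p_genomewide=np.ones(m), low_coverage=coverage_filter(segments, markers, params.coverage_fraction),
            exceeds_threshold=np.zeros(m, dtype=bool), significant=np.zeros(m, dtype=bool),
            threshold_statistic=np.inf, threshold_p=0.0, gw_avg=0.0,
            n_permutations=params.n_permutations, seed=params.seed, degenerate=True,
        )
    s_obs = count_obs / obs_mean  # N_cc cancels in the normalised statistic

    rng = np.random.default_rng(params.seed)
    P = params.n_permutations
    exceed = np.zeros(m, dtype=np.int64)
    maxima = np.empty(P)
    base = (lab == CASE).astype(np.int8)
    done = 0
    chunk = max(1, min(256, P))
    while done < P:
        b = min(chunk, P - done)
        perm_lab = rng.permuted(np.tile(base, (b, 1)), axis=1)  # (b, n_samples)
        cc = (perm_lab[:, i1] & perm_lab[:, i2]).T.astype(np.float64)  # (n_seg, b)
        counts = S @ cc  # (m, b)
        col_mean = counts.mean(axis=0)
        col_mean[col_mean <= 0] = np.inf  # degenerate permutation: statistic 0
        s_perm = counts / col_mean
        exceed += (s_perm >= s_obs[:, None]).sum(axis=1)
        maxima[done : done + b] = s_perm.max(axis=0)
        done += b

    p_point = (1 + exceed) / (P + 1)
    # genome-wide p per marker from the distribution of permutation maxima
    p_gw = (1 + np.searchsorted(np.sort(-maxima), -s_obs, side="right")) / (P + 1)

    if params.literal_pvalue_quantile:
        # literal reading: threshold = 0.0005 quantile of pointwise p-values
        threshold_p = float(np.quantile(p_point, 0.0005))
        exceeds = p_point <= threshold_p
        threshold_stat = float(s_obs[exceeds].min()) if exceeds.any() else np.inf
    else:
        threshold_stat = float(np.quantile(maxima, 1 - params.fwer_level))
        exceeds = s_obs >= threshold_stat
        threshold_p = float((1 + (maxima >= threshold_stat).sum()) / (P + 1))

    low_cov = _mask_low_coverage(profile.count_all, params.coverage_fraction)
    return MappingResult(
        markers=markers,
        statistic=s_obs,
        p_pointwise=p_point,
        p_genomewide=p_gw,
        low_coverage=low_cov,
        exceeds_threshold=exceeds,
        significant=exceeds & ~low_cov,
        threshold_statistic=threshold_stat,
        threshold_p=threshold_p,
        gw_avg=float(obs_mean / profile.n_cc),
        n_permutations=P,
        seed=params.seed,
    )


def _mask_low_coverage(counts: np.ndarray, fraction: float) -> np.ndarray:
    if len(counts) == 0:
        raise ValueError("no markers")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    q = np.quantile(counts, fraction)  # linear interpolation between order stats
    return counts < q


def coverage_filter(
    segments: pd.DataFrame, markers: pd.DataFrame, fraction: float = 0.10
) -> np.ndarray:
    """Mask markers in the lowest ``fraction`` of total IBD detection.

    The total spanning-segment count over all pairs is computed per
    marker; the quantile at ``fraction`` uses linear interpolation and
    masking is strict (an all-equal count profile masks nothing).
    """
    validate_segments(segments)
    first, last = _segment_spans(segments, markers)
    counts = _diff_counts(first, last, len(markers), np.ones(len(segments), dtype=bool))
    return _mask_low_coverage(counts, fraction)


def significant_markers(result: MappingResult) -> pd.DataFrame:
    """Markers that are genome-wide significant and not low-coverage masked."""
    df = result.to_frame()
    return df[result.significant].reset_index(drop=True)
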