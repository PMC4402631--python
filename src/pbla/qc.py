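"""Genotype-panel quality control.

Standard GWAS-style marker and sample filters: minor allele frequency,
Hardy-Weinberg exact test, per-individual and per-marker missingness.
Individuals are filtered first and marker statistics recomputed on the
survivors, matching common QC-tool convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypePanel

__all__ = ["QCThresholds", "QCReport", "marker_stats", "hwe_exact_p", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds.

    Defaults are the conventional values for IBD-mapping cohort QC:
    MAF >= 0.05, HWE exact p >= 1e-6, per-individual missingness <= 0.07
    (required by downstream phasing), per-marker missingness <= 0.1.
    ``hwe_controls_only`` restricts the HWE test to control samples.
    """

    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    ind_missing_max: float = 0.07
    marker_missing_max: float = 0.1
    hwe_controls_only: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "ind_missing_max", "marker_missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Exhaustive record of removals, one reason string per removal.

    ``removed_markers`` maps marker id -> comma-joined failing criteria
    among ``{"missing", "maf", "hwe"}``; ``removed_individuals`` maps
    sample id -> ``"ind_missing"``.
    """

    removed_individuals: dict[str, str] = field(default_factory=dict)
    removed_markers: dict[str, str] = field(default_factory=dict)
    empty_output: bool = False

    @property
    def n_removed(self) -> int:
        return len(self.removed_individuals) + len(self.removed_markers)

    def to_frame(self) -> pd.DataFrame:
        rows = [("individual", sid, r) for sid, r in self.removed_individuals.items()]
        rows += [("marker", mid, r) for mid, r in self.removed_markers.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def marker_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-marker genotype counts, folded MAF and call rate.

    MAF is minor-allele count over twice the non-missing sample count,
    folded to min(f, 1-f). Markers with call rate 0 get ``maf = NaN``
    and ``maf_defined = False``.
    """
    if panel.n_samples == 0 or panel.n_markers == 0:
        raise ValueError("empty panel")
    calls = panel.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    n0 = ((calls == 0) & obs).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n2 = (calls == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (n1 + 2 * n2) / (2 * n_obs)
    maf = np.minimum(freq, 1 - freq)
    maf[n_obs == 0] = np.nan
    return pd.DataFrame(
        {
            "id": panel.markers["id"].to_numpy(),
            "n_hom_ref": n0,
            "n_het": n1,
            "n_hom_alt": n2,
            "n_obs": n_obs,
            "maf": maf,
            "maf_defined": n_obs > 0,
            "call_rate": n_obs / panel.n_samples,
        }
    )


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations as or less probable than the observed
    one (the standard GWAS-QC exact test). Uses the stable ratio
    recurrence from the distribution's mode; exact enumeration on small
    tables agrees to ~1e-15 relative.

    Returns a p-value in (0, 1]. Monomorphic markers return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # rarer allele by convention below
    n_A = 2 * n_AA + n_Aa
    n_rare = min(n_a, n_A)
    if n_rare == 0:
        return 1.0

    h_min = n_rare % 2
    h_max = n_rare
    n_h = (h_max - h_min) // 2 + 1
    probs = np.zeros(n_h)

    # P(h+2)/P(h) = h_a*h_b / ((h/2+1)*(h_ab+1)) with hom counts at h;
    # start at an interior het count and sweep both ways.
    def homs(h: int) -> tuple[int, int]:
        return (n_rare - h) // 2, (2 * n - n_rare - h) // 2

    # start at the conditional mode so unnormalised probs never overflow
    h_mode = n_rare * (2 * n - n_rare) / (2 * n)
    h_mid_idx = int(np.clip(round((h_mode - h_min) / 2), 0, n_h - 1))
    probs[h_mid_idx] = 1.0
    for i in range(h_mid_idx, n_h - 1):
        h = h_min + 2 * i
        ha, hb = homs(h)
        probs[i + 1] = probs[i] * 4 * ha * hb / ((h + 2) * (h + 1))
    for i in range(h_mid_idx, 0, -1):
        h = h_min + 2 * i
        ha, hb = homs(h)
        probs[i - 1] = probs[i] * h * (h - 1) / (4 * (ha + 1) * (hb + 1))

    probs /= probs.sum()
    obs_idx = (n_Aa - h_min) // 2
    p_obs = probs[obs_idx]
    p = probs[probs <= p_obs * (1 + 1e-9)].sum()
    return float(min(p, 1.0))


def _individual_missingness(panel: GenotypePanel) -> np.ndarray:
    return (panel.calls == MISSING).mean(axis=1)


def apply_qc(
    panel: GenotypePanel, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypePanel, QCReport]:
    """Filter a panel: individuals by missingness, then markers.

    Individuals with missingness above ``ind_missing_max`` are removed
    first; marker statistics are recomputed on the survivors; markers
    then fail on missingness above ``marker_missing_max``, folded MAF
    below ``maf_min``, or HWE exact p below ``hwe_p_min`` (all failing
    reasons recorded). An empty output panel is flagged on the report,
    not raised.
    """
    report = QCReport()
    ind_miss = _individual_missingness(panel)
    drop_ind = ind_miss > thresholds.ind_missing_max
    for i in np.flatnonzero(drop_ind):
        report.removed_individuals[panel.sample_ids[i]] = "ind_missing"
    kept = panel.subset(sample_idx=np.flatnonzero(~drop_ind))

    if kept.n_samples == 0:
        report.empty_output = True
        return kept.subset(marker_idx=np.array([], dtype=int)), report

    if thresholds.hwe_controls_only:
        from .core import CONTROL

        hwe_panel = kept.subset(sample_idx=np.flatnonzero(kept.phenotype == CONTROL))
    else:
        hwe_panel = kept
    stats = marker_stats(kept)
    hwe_stats = stats if hwe_panel is kept else marker_stats(hwe_panel)

    keep_marker = np.ones(kept.n_markers, dtype=bool)
    for j in range(kept.n_markers):
        reasons = []
        if 1 - stats["call_rate"].iloc[j] > thresholds.marker_missing_max:
            reasons.append("missing")
        maf = stats["maf"].iloc[j]
        if not stats["maf_defined"].iloc[j] or maf < thresholds.maf_min:
            reasons.append("maf")
        if hwe_stats["n_obs"].iloc[j] > 0:
            p = hwe_exact_p(
                int(hwe_stats["n_hom_ref"].iloc[j]),
                int(hwe_stats["n_het"].iloc[j]),
                int(hwe_stats["n_hom_alt"].iloc[j]),
            )
            if p < thresholds.hwe_p_min:
                reasons.append("hwe")
        if reasons:
            keep_marker[j] = False
            report.removed_markers[stats["id"].iloc[j]] = ",".join(reasons)

    out = kept.subset(marker_idx=np.flatnonzero(keep_marker))
    if out.n_markers == 0 or out.n_samples == 0:
        report.empty_output = True
    return out, report
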