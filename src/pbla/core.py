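"""Core containers shared across the pipeline.

Genotype calls are coded as minor-allele dose ``0/1/2`` with ``-1`` for
missing. Phenotypes use integer codes (:data:`CASE`, :data:`CONTROL`,
:data:`UNKNOWN`). IBD segments travel as a :class:`pandas.DataFrame` with
the column contract in :data:`SEGMENT_COLUMNS`; pair order is canonical
(``sample1 <= sample2`` lexicographically, haplotype ids swapped along).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE: int = 1
CONTROL: int = 0
UNKNOWN: int = -1

MISSING: int = -1

#: Required columns of a segment table, in canonical order.
SEGMENT_COLUMNS = ["sample1", "hap1", "sample2", "hap2", "chrom", "start_bp", "end_bp", "lod"]

#: Added by :func:`pbla.segio.annotate_segments`.
SEGMENT_CM_COLUMNS = ["start_cm", "end_cm", "length_cm"]


@dataclass
class GenotypePanel:
    """Samples x biallelic markers with case/control labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``calls``.
    phenotype
        Integer codes per sample (:data:`CASE`, :data:`CONTROL`, :data:`UNKNOWN`).
    calls
        ``(n_samples, n_markers)`` int8 array of minor-allele doses,
        ``-1`` marking missing calls.
    markers
        Marker table with columns ``id, chrom, bp`` (1-based) and optional ``cm``;
        ``bp`` strictly increasing within each chromosome.
    """

    sample_ids: list[str]
    phenotype: np.ndarray
    calls: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} call rows")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match sample count")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} markers for {m} call columns")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"marker bp not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypePanel":
        """Return a panel restricted to the given sample/marker indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in si],
            phenotype=self.phenotype[si],
            calls=self.calls[np.ix_(si, mi)],
            markers=self.markers.iloc[mi].reset_index(drop=True),
        )

    def phenotype_series(self) -> pd.Series:
        return pd.Series(self.phenotype, index=self.sample_ids, name="phenotype")


@dataclass
class PCEmbedding:
    """Per-sample coordinates in principal-component space."""

    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, n_pcs)
    degenerate: bool = False  # True when the panel had zero variance

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a 2-d array")
        if len(self.sample_ids) != self.coords.shape[0]:
            raise ValueError("sample count does not match coordinate rows")

    @property
    def n_pcs(self) -> int:
        return self.coords.shape[1]


def canonical_pairs(s1, s2, h1=None, h2=None):
    """Order each sample pair lexicographically, carrying haplotype ids along."""
    s1 = np.asarray(s1, dtype=object)
    s2 = np.asarray(s2, dtype=object)
    swap = s2 < s1
    out1, out2 = s1.copy(), s2.copy()
    out1[swap], out2[swap] = s2[swap], s1[swap]
    if h1 is None:
        return out1, out2
    h1 = np.asarray(h1).copy()
    h2 = np.asarray(h2).copy()
    h1[swap], h2[swap] = h2[swap], h1[swap].copy()
    return out1, out2, h1, h2


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Check the segment column contract and invariants; return ``df``."""
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing columns {missing}")
    if len(df) and not (df["start_bp"] < df["end_bp"]).all():
        raise ValueError("segments must satisfy start_bp < end_bp")
    if len(df) and (df["sample2"] < df["sample1"]).any():
        raise ValueError("segment sample pairs must be in canonical sorted order")
    return df


def phenotype_codes(labels, sample_ids=None) -> pd.Series:
    """Coerce case/control labels to an integer-coded Series indexed by sample id.

    Accepts a Series/dict of ``'case'``/``'control'`` strings or of
    :data:`CASE`/:data:`CONTROL` codes.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    if isinstance(labels, pd.Series):
        ser = labels
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required for array-like labels")
        ser = pd.Series(np.asarray(labels), index=list(sample_ids))
    if ser.dtype == object:
        mapping = {"case": CASE, "control": CONTROL, "unknown": UNKNOWN}
        bad = set(ser.unique()) - set(mapping)
        if bad:
            raise ValueError(f"unrecognised phenotype labels: {sorted(map(str, bad))}")
        ser = ser.map(mapping)
    return ser.astype(np.int8)
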