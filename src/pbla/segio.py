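"""IBD segment I/O, format conversion and genetic-map interpolation.

Segments arrive as refined-IBD tab-separated text — one line per detected
shared haplotype segment with columns

    sample1  hap1  sample2  hap2  chrom  start_bp  end_bp  LOD

(bp coordinates 1-based inclusive). They can be converted to
fastIBD-style records whose coordinates are 0-based marker indices per
chromosome, and annotated with centiMorgan positions linearly
interpolated from a genetic-map anchor file (chrom, bp, cM).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SEGMENT_COLUMNS, canonical_pairs, validate_segments

__all__ = [
    "GeneticMap",
    "read_refined_ibd",
    "write_refined_ibd",
    "convert_to_fastibd",
    "write_fastibd",
    "interpolate_cm",
    "annotate_segments",
    "read_genetic_map",
]

FASTIBD_COLUMNS = ["sample1", "sample2", "start_marker", "end_marker", "score"]


class SegmentParseError(ValueError):
    """A malformed refined-IBD line, reported with its line number."""


@dataclass
class GeneticMap:
    """Per-chromosome anchor lists of (bp, cM), bp strictly increasing."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        gmap = cls()
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("bp")
            bp = grp["bp"].to_numpy(dtype=np.int64)
            cm = grp["cm"].to_numpy(dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"duplicate bp anchors on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM anchors decrease on {chrom}")
            gmap.anchors[str(chrom)] = (bp, cm)
        return gmap

    @classmethod
    def uniform(cls, chromosomes) -> "GeneticMap":
        """Two-anchor map per chromosome from uniform cM/Mb rates."""
        rows = []
        for c in chromosomes:
            rows.append({"chrom": c.name, "bp": 1, "cm": c.bp_to_cm(1)})
            rows.append({"chrom": c.name, "bp": c.length_bp, "cm": c.length_cm})
        return cls.from_frame(pd.DataFrame(rows))

    def chromosomes(self) -> list[str]:
        return list(self.anchors)


def read_genetic_map(path) -> GeneticMap:
    """Read a tab-separated (chrom, bp, cM) anchor file."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "bp", "cm"], header=None)
    if len(df) and df.iloc[0]["chrom"] == "chrom":  # tolerate a header line
        df = df.iloc[1:].astype({"bp": np.int64, "cm": float})
    return GeneticMap.from_frame(df)


def read_refined_ibd(source) -> pd.DataFrame:
    """Parse refined-IBD segment text into the canonical segment table.

    ``source`` is a path or text stream. Pairs are canonicalised
    (``sample1 <= sample2``); malformed lines raise
    :class:`SegmentParseError` naming the 1-based line number.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            return read_refined_ibd(fh)
    rows = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 8:
            raise SegmentParseError(f"line {lineno}: expected 8 columns, got {len(parts)}")
        s1, h1, s2, h2, chrom, start, end, lod = parts
        try:
            h1, h2 = int(h1), int(h2)
            start, end = int(start), int(end)
            lod = float(lod)
        except ValueError as exc:
            raise SegmentParseError(f"line {lineno}: non-numeric field ({exc})") from None
        if h1 not in (1, 2) or h2 not in (1, 2):
            raise SegmentParseError(f"line {lineno}: haplotype ids must be 1 or 2")
        if start >= end:
            raise SegmentParseError(f"line {lineno}: start_bp {start} >= end_bp {end}")
        rows.append((s1, h1, s2, h2, chrom, start, end, lod))
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    if len(df):
        s1, s2, h1, h2 = canonical_pairs(df["sample1"], df["sample2"], df["hap1"], df["hap2"])
        df["sample1"], df["sample2"] = s1, s2
        df["hap1"], df["hap2"] = h1, h2
        df = df.astype({"start_bp": np.int64, "end_bp": np.int64, "lod": float})
    return validate_segments(df)


def write_refined_ibd(segments: pd.DataFrame, path) -> None:
    """Write the canonical segment table as refined-IBD text (no header)."""
    validate_segments(segments)
    segments.to_csv(path, sep="\t", header=False, index=False, columns=SEGMENT_COLUMNS)


def _marker_span(
    segments: pd.DataFrame, markers: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment first/last spanned marker index (per chromosome, 0-based).

    Returns (first_idx, last_idx, valid) where ``valid`` marks segments
    spanning at least one marker. Raises on chromosomes absent from the
    marker table.
    """
    first = np.zeros(len(segments), dtype=np.int64)
    last = np.full(len(segments), -1, dtype=np.int64)
    by_chrom = {str(c): grp["bp"].to_numpy() for c, grp in markers.groupby("chrom", sort=False)}
    for chrom, grp in segments.groupby("chrom", sort=False):
        if str(chrom) not in by_chrom:
            raise ValueError(f"segment chromosome {chrom!r} not in marker table")
        bp = by_chrom[str(chrom)]
        idx = grp.index.to_numpy()
        pos = segments.loc[idx]
        first[segments.index.get_indexer(idx)] = np.searchsorted(bp, pos["start_bp"], side="left")
        last[segments.index.get_indexer(idx)] = (
            np.searchsorted(bp, pos["end_bp"], side="right") - 1
        )
    valid = first <= last
    return first, last, valid


def convert_to_fastibd(
    segments: pd.DataFrame, markers: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Convert segments to fastIBD-style marker-index records.

    Each segment becomes ``(sample1, sample2, index of first marker >=
    start_bp, index of last marker <= end_bp, score=LOD)`` with marker
    indices 0-based within the chromosome. Segments spanning no marker
    are dropped; the drop count is returned alongside the records.
    """
    validate_segments(segments)
    seg = segments.reset_index(drop=True)
    first, last, valid = _marker_span(seg, markers)
    records = pd.DataFrame(
        {
            "sample1": seg["sample1"][valid].to_numpy(),
            "sample2": seg["sample2"][valid].to_numpy(),
            "chrom": seg["chrom"][valid].to_numpy(),
            "start_marker": first[valid],
            "end_marker": last[valid],
            "score": seg["lod"][valid].to_numpy(),
        }
    )
    return records, int((~valid).sum())


def write_fastibd(records: pd.DataFrame, path) -> None:
    """Write fastIBD-style records with a header documenting the columns."""
    with open(path, "w") as fh:
        fh.write("# fastIBD-style records: marker indices 0-based per chromosome\n")
        fh.write("#" + "\t".join(["sample1", "sample2", "chrom", "start_marker", "end_marker", "score"]) + "\n")
        records.to_csv(fh, sep="\t", header=False, index=False)


def interpolate_cm(bp, gmap: GeneticMap, chrom: str) -> np.ndarray | float:
    """Genetic-map position(s) for physical position(s) on one chromosome.

    Linear interpolation between bracketing anchors; beyond the terminal
    anchors, linear extrapolation at the terminal interval's rate, floored
    at 0 cM.
    """
    if chrom not in gmap.anchors:
        raise ValueError(f"chromosome {chrom!r} absent from genetic map")
    abp, acm = gmap.anchors[chrom]
    if len(abp) < 2:
        raise ValueError(f"need >= 2 anchors on {chrom} to interpolate")
    scalar = np.isscalar(bp)
    bp = np.atleast_1d(np.asarray(bp, dtype=float))
    cm = np.interp(bp, abp, acm)
    lo_rate = (acm[1] - acm[0]) / (abp[1] - abp[0])
    hi_rate = (acm[-1] - acm[-2]) / (abp[-1] - abp[-2])
    below = bp < abp[0]
    above = bp > abp[-1]
    cm[below] = acm[0] + (bp[below] - abp[0]) * lo_rate
    cm[above] = acm[-1] + (bp[above] - abp[-1]) * hi_rate
    cm = np.maximum(cm, 0.0)
    return float(cm[0]) if scalar else cm


def annotate_segments(segments: pd.DataFrame, gmap: GeneticMap) -> pd.DataFrame:
    """Return a copy with ``start_cm``, ``end_cm`` and ``length_cm`` filled."""
    validate_segments(segments)
    out = segments.copy()
    start_cm = np.empty(len(out))
    end_cm = np.empty(len(out))
    for chrom, grp in out.groupby("chrom", sort=False):
        loc = out.index.get_indexer(grp.index)
        start_cm[loc] = interpolate_cm(grp["start_bp"].to_numpy(), gmap, str(chrom))
        end_cm[loc] = interpolate_cm(grp["end_bp"].to_numpy(), gmap, str(chrom))
    out["start_cm"] = start_cm
    out["end_cm"] = end_cm
    out["length_cm"] = end_cm - start_cm
    if len(out) and (out["length_cm"] < 0).any():
        raise ValueError("genetic map produced negative segment lengths")
    return out
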