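"""Genotype PCA and two-stage nearest-neighbour outlier removal.

The outlier procedure operates on the first few principal components of
the genotype matrix (EIGENSTRAT normalisation). Stage 1 keeps samples
whose mean Euclidean distance to their 10 nearest neighbours is at most a
density cutoff (0.15 by default) — this defines the main cluster. Stage 2
keeps a stage-1 sample only if at least 9 of its 10 nearest neighbours
are themselves stage-1 members, trimming the cluster boundary so only
interior samples remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import MISSING, GenotypePanel, PCEmbedding

__all__ = [
    "OutlierParams",
    "compute_pcs",
    "mean_knn_distance",
    "two_stage_outlier_removal",
]


@dataclass(frozen=True)
class OutlierParams:
    """Parameters of the two-stage procedure.

    The density cutoff is scale-dependent: it presumes coordinates
    normalised as by :func:`compute_pcs` (EIGENSTRAT convention).
    ``neighbors_within_stage1`` recomputes stage-2 neighbours among
    stage-1 survivors instead of the full sample set.
    """

    n_neighbors: int = 10
    density_cutoff: float = 0.15
    interior_min: int = 9
    n_pcs: int = 6
    neighbors_within_stage1: bool = False

    def __post_init__(self) -> None:
        if self.interior_min > self.n_neighbors:
            raise ValueError("interior_min cannot exceed n_neighbors")
        if self.n_neighbors < 1 or self.n_pcs < 1:
            raise ValueError("n_neighbors and n_pcs must be positive")


def compute_pcs(panel: GenotypePanel, n_components: int = 6) -> PCEmbedding:
    """Principal components of a genotype panel, EIGENSTRAT-normalised.

    Each marker column is centred at 2*p_hat and scaled by
    sqrt(p_hat*(1-p_hat)) with p_hat the observed allele frequency;
    missing calls are mean-imputed (zero after centring). Returns the top
    ``n_components`` sample coordinates as unit-norm eigenvectors of the
    sample covariance (the smartPCA output convention, which the 0.15
    density cutoff presumes; note the coordinate scale therefore shrinks
    as 1/sqrt(n_samples)). Sign convention: the largest-magnitude marker
    loading of each component is positive.

    A zero-variance panel yields all-zero coordinates with
    ``degenerate=True``.
    """
    if n_components > min(panel.n_samples, panel.n_markers):
        raise ValueError("n_components exceeds min(samples, markers)")
    calls = panel.calls.astype(float)
    obs = panel.calls != MISSING
    calls[~obs] = np.nan
    with np.errstate(invalid="ignore"):
        p_hat = np.nanmean(calls, axis=0) / 2.0
    p_hat = np.where(np.isnan(p_hat), 0.0, p_hat)
    X = calls - 2.0 * p_hat
    X[~obs] = 0.0
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    nonzero = scale > 0
    X[:, nonzero] /= scale[nonzero]
    X[:, ~nonzero] = 0.0

    if not np.any(np.abs(X) > 1e-12):
        coords = np.zeros((panel.n_samples, n_components))
        return PCEmbedding(panel.sample_ids, coords, degenerate=True)

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    flip = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    coords = U * flip
    return PCEmbedding(panel.sample_ids, coords)


def _knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of each sample's k nearest other samples.

    Ties in distance are broken by sample order (stable sort), so results
    are deterministic.
    """
    n = len(coords)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k}-NN, got {n}")
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    idx = np.argsort(d, axis=1, kind="stable")[:, :k]
    return idx, np.take_along_axis(d, idx, axis=1)


def mean_knn_distance(embedding: PCEmbedding, k: int = 10) -> np.ndarray:
    """Mean Euclidean distance of each sample to its k nearest neighbours."""
    _, dists = _knn(embedding.coords, k)
    return dists.mean(axis=1)


def two_stage_outlier_removal(
    embedding: PCEmbedding, params: OutlierParams = OutlierParams()
) -> tuple[list[str], pd.DataFrame]:
    """Run both stages; return kept sample ids and per-sample diagnostics.

    Stage 1: mean distance to the ``n_neighbors`` nearest neighbours at
    most ``density_cutoff``. Stage 2: at least ``interior_min`` of those
    neighbours (computed in the full sample set by default) are stage-1
    members. Exactly one pass is run.

    The diagnostics frame has columns ``sample_id, mean_knn_dist,
    stage1, n_interior, kept``.
    """
    if embedding.n_pcs != params.n_pcs:
        raise ValueError(
            f"embedding has {embedding.n_pcs} PCs but params expect {params.n_pcs}"
        )
    nn_idx, nn_dist = _knn(embedding.coords, params.n_neighbors)
    mean_dist = nn_dist.mean(axis=1)
    stage1 = mean_dist <= params.density_cutoff

    if params.neighbors_within_stage1 and stage1.sum() > params.n_neighbors:
        # neighbours drawn from stage-1 survivors are inside by construction,
        # so this reading reduces stage 2 to stage 1
        neighbor_interior = np.where(stage1, params.n_neighbors, 0)
    else:
        neighbor_interior = stage1[nn_idx].sum(axis=1)

    kept_mask = stage1 & (neighbor_interior >= params.interior_min)
    diagnostics = pd.DataFrame(
        {
            "sample_id": embedding.sample_ids,
            "mean_knn_dist": mean_dist,
            "stage1": stage1,
            "n_interior": neighbor_interior,
            "kept": kept_mask,
        }
    )
    kept = [sid for sid, m in zip(embedding.sample_ids, kept_mask) if m]
    return kept, diagnostics
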