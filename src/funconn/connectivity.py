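"""From ROI time series to sparsity-thresholded binary networks.

Each subject's regional time series are pairwise Pearson-correlated into an
N x N connectivity matrix (diagonal structurally zero).  Negative
correlations are excluded (set to zero) before network construction, owing
to their ambiguous interpretation in functional connectivity.  Binarization
uses a subject-specific threshold chosen so that every network has exactly
the same number of edges: at sparsity S the K = round_half_up(S * N(N-1)/2)
strongest positive correlations become edges.  Analyses are repeated over a
sparsity grid (default 0.05 to 0.39 in steps of 0.02) because no single
density is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "pearson_matrix",
    "rectify_negatives",
    "sparsity_threshold",
    "edge_count_for_sparsity",
    "default_grid",
    "group_mean_matrix",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with structurally zero diagonal."""

    values: np.ndarray
    subject_id: str = "sub"
    rectified: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if np.abs(v).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.rectified and v.min(initial=0.0) < 0:
            raise ValueError("rectified matrix contains negative entries")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    subject_id: str = "sub"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.dtype != bool:
            if not np.isin(a, (0, 1)).all():
                raise ValueError("adjacency must be 0/1")
            a = a.astype(bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise ValueError("adjacency must have an empty diagonal")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edges(self) -> np.ndarray:
        """(K, 2) array of upper-triangle edge endpoints."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


def pearson_matrix(panel) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of a subject's regional time series.

    Raises if any region's series is constant (correlation undefined), naming
    the offending region index.
    """
    x = np.asarray(panel.data, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("at least 3 time points are required")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(
            f"region {bad} of subject {panel.subject_id!r} has a constant "
            "time series; correlation undefined"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, subject_id=panel.subject_id)


def rectify_negatives(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Exclude negative correlations (set them to zero).  Idempotent."""
    return ConnectivityMatrix(
        values=np.maximum(m.values, 0.0), subject_id=m.subject_id, rectified=True
    )


def edge_count_for_sparsity(n_rois: int, sparsity: float) -> int:
    """K = round_half_up(S * N(N-1)/2).

    The rounding convention is a pinned implementation constant (half-up);
    a tiny epsilon guards against binary-float products such as
    0.1 * 4005 = 400.49999... landing just below the half-way mark.
    """
    m = n_rois * (n_rois - 1) // 2
    return int(np.floor(sparsity * m + 0.5 + 1e-9))


def sparsity_threshold(m: ConnectivityMatrix, sparsity: float) -> BinaryNetwork:
    """Binarize a rectified matrix by keeping its K strongest correlations.

    Ties at the cutoff value are broken by ascending (row, column) index so
    that results are reproducible across platforms.  Because the edge
    ordering does not depend on S, edge sets are nested across increasing
    sparsity.
    """
    if not m.rectified:
        raise ValueError("matrix must be rectified (negatives set to 0) first")
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie in (0, 1)")
    n = m.n_rois
    k = edge_count_for_sparsity(n, sparsity)
    if k == 0:
        raise ValueError(f"sparsity {sparsity} yields zero edges for N={n}")
    iu, ju = np.triu_indices(n, 1)
    vals = m.values[iu, ju]
    n_pos = int((vals > 0).sum())
    if n_pos < k:
        raise ValueError(
            f"only {n_pos} positive correlations available; requested K={k} "
            f"(achievable sparsity {n_pos / len(vals):.4f})"
        )
    # primary key: descending value; then ascending row, ascending column
    order = np.lexsort((ju, iu, -vals))[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[order], ju[order]] = True
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=sparsity, subject_id=m.subject_id)


def default_grid() -> np.ndarray:
    """The default sparsity grid: 0.05, 0.07, ..., 0.39 (18 values)."""
    return np.round(0.05 + 0.02 * np.arange(18), 2)


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean connectivity across subjects."""
    if not matrices:
        raise ValueError("need at least one matrix")
    n = matrices[0].n_rois
    if any(m.n_rois != n for m in matrices):
        raise ValueError("matrices have mixed sizes")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(
        values=mean,
        subject_id="group_mean",
        rectified=all(m.rectified for m in matrices),
    )
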