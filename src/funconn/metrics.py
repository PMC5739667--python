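"""Small-world efficiency metrics on binary graphs.

Three measures characterize a binary network G with N nodes and shortest
path lengths d_ij (minimum edge counts):

* global efficiency   Eglob(G) = 1/(N(N-1)) * sum_{i != j} 1/d_ij
* local efficiency    Eloc(G)  = 1/N * sum_i Eglob(G_i), with G_i the
  subgraph induced by the neighbours of node i
* nodal efficiency    e_i      = 1/(N-1) * sum_{j != i} 1/d_ij

Unreachable pairs contribute 0 (1/inf), which is what makes efficiency
well defined on disconnected graphs; neighbour subgraphs with fewer than two
nodes contribute 0 to Eloc.  The mean of nodal efficiency over nodes equals
global efficiency by construction — an identity the test-suite pins to 1e-12.

Metrics are evaluated across a sparsity grid and summarized per subject by
the area under the curve (trapezoidal rule), giving a threshold-free scalar
per metric for group inference.

Shortest paths use a breadth-first expansion implemented as repeated boolean
matrix products, which is fast for the dense batches of small graphs this
analysis produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._fast import local_efficiency_sum, nodal_inverse_distance_sums
from .connectivity import BinaryNetwork, ConnectivityMatrix, sparsity_threshold

__all__ = [
    "shortest_paths",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "metric_curve",
    "MetricCurve",
    "auc",
    "AUCSummary",
    "identify_hubs",
    "HubTable",
    "METRICS",
]


def _as_adjacency(g) -> np.ndarray:
    if isinstance(g, BinaryNetwork):
        return g.adjacency
    return np.asarray(g, dtype=bool)


def _apsp(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths of a binary graph (inf = unreachable)."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    if n <= 1 or not adj.any():
        return d
    reach = adj | np.eye(n, dtype=bool)
    a = adj.astype(np.uint8)
    dist = 1
    frontier = adj.copy()
    while frontier.any():
        dist += 1
        grown = (frontier.astype(np.uint8) @ a) > 0
        new = grown & ~reach
        if not new.any():
            break
        d[new] = dist
        reach |= new
        frontier = new
    return d


def shortest_paths(g) -> np.ndarray:
    """Breadth-first shortest path length matrix; np.inf marks unreachable pairs."""
    return _apsp(_as_adjacency(g))


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g) -> float:
    """Mean inverse shortest path length over ordered node pairs; in [0, 1]."""
    adj = _as_adjacency(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    return float(nodal_inverse_distance_sums(adj).sum() / (n * (n - 1)))


def local_efficiency(g) -> float:
    """Mean over nodes of the global efficiency of the neighbour subgraph."""
    adj = _as_adjacency(g)
    if adj.shape[0] < 2:
        raise ValueError("local efficiency requires at least 2 nodes")
    return float(local_efficiency_sum(adj))


def nodal_efficiency(g) -> np.ndarray:
    """Per-node mean inverse distance to all other nodes, e_i in [0, 1]."""
    adj = _as_adjacency(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    return nodal_inverse_distance_sums(adj) / (n - 1)


METRICS: dict[str, Callable] = {
    "global_efficiency": global_efficiency,
    "local_efficiency": local_efficiency,
    "nodal_efficiency": nodal_efficiency,
}


@dataclass
class MetricCurve:
    """One metric evaluated across the sparsity grid for one subject."""

    metric_name: str
    grid: np.ndarray
    values: np.ndarray  # shape (len(grid),) or (len(grid), n_rois) for nodal
    subject_id: str = "sub"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.grid):
            raise ValueError("curve length must match the sparsity grid")


@dataclass
class AUCSummary:
    metric_name: str
    auc: float
    subject_id: str = "sub"


def metric_curve(
    m: ConnectivityMatrix,
    grid: np.ndarray,
    metric: str | Callable = "global_efficiency",
) -> MetricCurve:
    """Threshold a rectified matrix at every grid sparsity and apply a metric."""
    fn = METRICS[metric] if isinstance(metric, str) else metric
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    values = [fn(sparsity_threshold(m, s)) for s in np.asarray(grid, dtype=float)]
    return MetricCurve(
        metric_name=name, grid=np.asarray(grid, float),
        values=np.asarray(values), subject_id=m.subject_id,
    )


def auc(curve: MetricCurve, grid: np.ndarray | None = None) -> AUCSummary:
    """Trapezoidal integral of a metric curve over the sparsity range.

    NaN values (e.g. normalized efficiencies with an undefined ensemble mean)
    are dropped pairwise with their grid points before integration.
    """
    g = curve.grid if grid is None else np.asarray(grid, dtype=float)
    v = curve.values
    if len(v) != len(g):
        raise ValueError("curve and grid lengths differ")
    if v.ndim == 1:
        ok = np.isfinite(v)
        if ok.sum() < 2:
            raise ValueError("fewer than two finite curve values; AUC undefined")
        area = float(np.trapezoid(v[ok], g[ok]))
    else:
        area = np.trapezoid(v, g, axis=0)
    return AUCSummary(metric_name=curve.metric_name, auc=area, subject_id=curve.subject_id)


@dataclass
class HubTable:
    """Hubs of one group: regions whose mean nodal-efficiency AUC is at least
    one standard deviation above the group mean, where mean and SD pool all
    node-by-participant values."""

    group: str
    regional_mean: np.ndarray  # (n_rois,)
    threshold: float
    is_hub: np.ndarray  # bool (n_rois,)

    def hub_indices(self) -> np.ndarray:
        """0-based indices of hub regions."""
        return np.nonzero(self.is_hub)[0]


def identify_hubs(nodal_auc: np.ndarray, group: str = "group") -> HubTable:
    """Flag hub regions from a subjects x regions nodal-efficiency AUC array.

    The threshold is mean + 1 SD computed over the full node-by-participant
    value pool (sample SD, ddof=1); a region is a hub when its across-subject
    mean meets or exceeds the threshold.
    """
    x = np.asarray(nodal_auc, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("nodal_auc must be a subjects x regions array")
    pooled_mean = float(x.mean())
    pooled_sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    threshold = pooled_mean + pooled_sd
    regional = x.mean(axis=0)
    return HubTable(
        group=group,
        regional_mean=regional,
        threshold=threshold,
        is_hub=regional >= threshold,
    )
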