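"""Degree-preserving random surrogates and normalized small-world efficiency.

Random networks are produced by double-edge swaps: two edges (a, b), (c, d)
are replaced by (a, d), (c, b) whenever that creates no self-loop or
duplicate edge.  Every swap preserves each node's degree exactly, so the
surrogate ensemble shares the real network's node count, edge count and
degree sequence while higher-order structure is destroyed.  The swap budget
is ``swap_factor * |E|`` attempted swaps (default 10), enough to decorrelate
the edge set from the original for the densities this analysis uses.

Normalized efficiencies divide the real network's global and local
efficiency at each sparsity by the ensemble mean (default 100 surrogates) of
the same quantity:

    lambda(S) = Eglob(G) / <Eglob(G_rand)>,  gamma(S) = Eloc(G) / <Eloc(G_rand)>

A network with lambda ~ 1 and gamma > 1 relative to matched random networks
is small-world.  The lambda tolerance band for the boolean flag (default
[0.8, 1.2]) is a reporting device only and plays no role in inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectivity import BinaryNetwork, ConnectivityMatrix, sparsity_threshold
from .metrics import AUCSummary, MetricCurve, auc, global_efficiency, local_efficiency

__all__ = [
    "degree_preserving_rewire",
    "NormalizedCurves",
    "normalize_curves",
    "smallworld_flag",
]

DEFAULT_SWAP_FACTOR = 10
DEFAULT_ENSEMBLE_SIZE = 100
LAMBDA_BAND = (0.8, 1.2)


@njit(cache=False)
def _swap_kernel(adj, edges, n_attempts, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    m = edges.shape[0]
    done = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.random() < 0.5:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        done += 1
    return done


def degree_preserving_rewire(
    g: BinaryNetwork,
    seed: int | np.random.Generator,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
) -> BinaryNetwork:
    """Randomize a network by double-edge swaps, preserving every degree.

    Graphs that admit no legal swap (complete graphs, stars) come back
    unchanged with a RuntimeWarning.
    """
    k = g.edge_count
    if k < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    adj = g.adjacency.copy()
    edges = g.edges().astype(np.int64)
    done = _swap_kernel(adj, edges, int(swap_factor) * k, kernel_seed)
    if done == 0:
        warnings.warn(
            "no legal double-edge swap was found; returning the network "
            "unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
    return BinaryNetwork(adjacency=adj, sparsity=g.sparsity, subject_id=g.subject_id)


@dataclass
class NormalizedCurves:
    """lambda/gamma curves of one subject across the sparsity grid."""

    grid: np.ndarray
    lambda_curve: np.ndarray
    gamma_curve: np.ndarray
    subject_id: str = "sub"
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE

    def lambda_auc(self) -> AUCSummary:
        c = MetricCurve("normalized_global_efficiency", self.grid,
                        self.lambda_curve, self.subject_id)
        return auc(c)

    def gamma_auc(self) -> AUCSummary:
        c = MetricCurve("normalized_local_efficiency", self.grid,
                        self.gamma_curve, self.subject_id)
        return auc(c)


def _ensemble_means(
    net: BinaryNetwork,
    ensemble_size: int,
    rng: np.random.Generator,
    swap_factor: int,
    rewire=degree_preserving_rewire,
) -> tuple[float, float]:
    eg = np.empty(ensemble_size)
    el = np.empty(ensemble_size)
    for r in range(ensemble_size):
        surrogate = rewire(net, rng, swap_factor=swap_factor)
        eg[r] = global_efficiency(surrogate)
        el[r] = local_efficiency(surrogate)
    return float(eg.mean()), float(el.mean())


def normalize_curves(
    m: ConnectivityMatrix,
    grid: np.ndarray,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int | np.random.Generator = 0,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    rewire=degree_preserving_rewire,
) -> NormalizedCurves:
    """Normalized global/local efficiency of one subject across the grid.

    At each sparsity the real network's efficiencies are divided by the mean
    over ``ensemble_size`` degree-preserving surrogates.  A zero ensemble
    mean (possible for local efficiency on star-like graphs) yields NaN with
    a warning; AUC summaries drop such points.
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be at least 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    lam = np.empty(len(grid))
    gam = np.empty(len(grid))
    for idx, s in enumerate(grid):
        net = sparsity_threshold(m, s)
        real_g = global_efficiency(net)
        real_l = local_efficiency(net)
        mean_g, mean_l = _ensemble_means(net, ensemble_size, rng, swap_factor, rewire)
        lam[idx] = real_g / mean_g if mean_g > 0 else np.nan
        if mean_l > 0:
            gam[idx] = real_l / mean_l
        else:
            warnings.warn(
                f"ensemble mean local efficiency is 0 at sparsity {s}; "
                "normalized value undefined (NaN)",
                RuntimeWarning,
                stacklevel=2,
            )
            gam[idx] = np.nan
    return NormalizedCurves(
        grid=grid, lambda_curve=lam, gamma_curve=gam,
        subject_id=m.subject_id, ensemble_size=ensemble_size,
    )


def smallworld_flag(
    nc: NormalizedCurves,
    lambda_band: tuple[float, float] = LAMBDA_BAND,
) -> np.ndarray:
    """True at each sparsity where gamma > 1 and lambda lies in the band."""
    lo, hi = lambda_band
    return (
        (nc.gamma_curve > 1.0)
        & (nc.lambda_curve >= lo)
        & (nc.lambda_curve <= hi)
    )
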