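"""Between-group inference for network measures.

All group comparisons are non-parametric: the observed difference in group
means is referred to an empirical null built by randomly reallocating
subjects to groups.  Reported p-values use add-one smoothing,
p = (#{null as extreme} + 1) / (n_perm + 1), so that p > 0 always; an exact
mode enumerates every group split when that is feasible.

Edge-wise inference uses the network-based statistic (NBS): an edge-by-edge
two-sample t-test is thresholded at a primary p-value, connected components
of the suprathreshold graph are extracted, and each component's size (edge
count) is referred to the permutation null distribution of the *maximal*
component size, which controls the family-wise error rate.  Only edges whose
correlation is positive in more than 80% of all subjects enter the
analysis.

Nodal tests are Bonferroni-corrected across regions; brain-behaviour
correlations are Benjamini-Hochberg FDR-corrected across tested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

__all__ = [
    "PermutationResult",
    "mean_diff_permutation_test",
    "edge_inclusion_mask",
    "NBSComponent",
    "NBSResult",
    "nbs",
    "NodalComparison",
    "nodal_comparison",
    "SubsampleReport",
    "balanced_subsample_analysis",
    "BehaviorCorrelation",
    "behavior_correlation",
]

TAILS = ("one_sided_upper", "one_sided_lower", "two_sided")


def _tail_count(null: np.ndarray, observed: float, tail: str) -> np.ndarray:
    if tail == "one_sided_upper":
        return null >= observed
    if tail == "one_sided_lower":
        return null <= observed
    if tail == "two_sided":
        return np.abs(null) >= abs(observed)
    raise ValueError(f"unknown tail {tail!r}; expected one of {TAILS}")


@dataclass
class PermutationResult:
    metric_name: str
    observed_diff: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    tail: str
    exact: bool = False


def _perm_mean_diffs(
    values: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """Null mean differences from random group reallocations.

    ``values`` is (n_subjects,) or (n_subjects, n_vars); returns (n_perm,)
    or (n_perm, n_vars).  The same label shuffles are shared across columns.
    """
    x = np.asarray(values, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n, n_vars = x.shape
    n_b = n - n_a
    out = np.empty((n_perm, n_vars))
    total = x.sum(axis=0)
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        keys = rng.random((stop - start, n))
        idx = np.argsort(keys, axis=1)[:, :n_a]
        sum_a = x[idx].sum(axis=1)
        out[start:stop] = sum_a / n_a - (total - sum_a) / n_b
    return out[:, 0] if squeeze else out


def mean_diff_permutation_test(
    a,
    b,
    n_perm: int = 10000,
    tail: str = "one_sided_upper",
    seed: int | np.random.Generator = 0,
    metric_name: str = "metric",
    exact: bool = False,
) -> PermutationResult:
    """Permutation test of mean(a) - mean(b) under group-label exchange.

    With ``exact=True`` all C(n, len(a)) splits are enumerated and the
    p-value is the proportion of splits at least as extreme as the observed
    labelling (which is itself one of the splits, so p > 0); otherwise
    ``n_perm`` random reallocations are drawn and the smoothed estimate
    p = (count + 1) / (n_perm + 1) is reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    if exact:
        n_splits = comb(n, n_a)
        if n_splits > 500_000:
            raise ValueError(
                f"exact enumeration over {n_splits} splits is infeasible; "
                "use the random-permutation mode"
            )
        null = np.empty(n_splits)
        grand = pooled.sum()
        for k, idx in enumerate(combinations(range(n), n_a)):
            sa = pooled[list(idx)].sum()
            null[k] = sa / n_a - (grand - sa) / (n - n_a)
        # the first split is the observed labelling itself; compare against
        # the identically computed value so it is always counted (p > 0)
        p = float(_tail_count(null, null[0], tail).mean())
        return PermutationResult(metric_name, observed, null, p, n_splits, tail, True)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    null = _perm_mean_diffs(pooled, n_a, n_perm, rng)
    count = int(_tail_count(null, observed, tail).sum())
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(metric_name, observed, null, p, n_perm, tail, False)


# ---------------------------------------------------------------------------
# Network-based statistic


def edge_inclusion_mask(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Edges whose correlation is positive in more than 80% of subjects.

    The proportion is strict (> 0.8): an edge positive in exactly 80% of
    subjects is excluded.  Returns an N x N boolean matrix with an empty
    diagonal.
    """
    if not matrices:
        raise ValueError("need at least one subject")
    stacked = np.stack([m.values for m in matrices])
    frac_positive = (stacked > 0).mean(axis=0)
    mask = frac_positive > 0.8
    np.fill_diagonal(mask, False)
    return mask & mask.T


def _edge_t(x: np.ndarray, in_a: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Pooled-variance two-sample t per column of x given a boolean A-mask."""
    a = x[in_a]
    b = x[~in_a]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    t = np.zeros_like(ma)
    ok = denom > 0
    t[ok] = (ma - mb)[ok] / denom[ok]
    return t


@dataclass
class NBSComponent:
    nodes: list[int]  # 0-based region indices
    edges: list[tuple[int, int]]  # 0-based, i < j
    size: int  # number of edges, the component statistic M
    corrected_p: float


@dataclass
class NBSResult:
    direction: str
    primary_p: float
    components: list[NBSComponent]
    null_max_sizes: np.ndarray
    n_perm: int
    t_matrix: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)

    def significant_components(self, alpha: float = 0.05) -> list[NBSComponent]:
        return [c for c in self.components if c.corrected_p <= alpha]


def _components_from_edges(
    n: int, iu: np.ndarray, ju: np.ndarray, supra: np.ndarray
):
    """Connected components of the suprathreshold edge set.

    Returns (list of (nodes, edges, size)) sorted by decreasing size.
    """
    ei, ej = iu[supra], ju[supra]
    if ei.size == 0:
        return []
    g = sparse.coo_matrix(
        (np.ones(ei.size), (ei, ej)), shape=(n, n)
    )
    n_comp, labels = sparse.csgraph.connected_components(g, directed=False)
    comp_of_edge = labels[ei]
    out = []
    for c in np.unique(comp_of_edge):
        sel = comp_of_edge == c
        edges = sorted(zip(ei[sel].tolist(), ej[sel].tolist()))
        nodes = sorted(set(ei[sel].tolist()) | set(ej[sel].tolist()))
        out.append((nodes, edges, int(sel.sum())))
    out.sort(key=lambda t: -t[2])
    return out


def _max_component_size(n: int, iu, ju, supra) -> int:
    comps = _components_from_edges(n, iu, ju, supra)
    return comps[0][2] if comps else 0


def nbs(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    primary_p: float = 0.01,
    n_perm: int = 10000,
    direction: str = "A_gt_B",
    seed: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
) -> NBSResult:
    """Network-based statistic for an edge-wise group comparison.

    ``direction`` selects the one-sided contrast ("A_gt_B" or "B_gt_A") or
    "two_sided".  ``mask`` defaults to the >80%-positive inclusion mask
    computed over all subjects of both groups.  Family-wise-corrected
    component p-values are (#{null max sizes >= M} + 1) / (n_perm + 1).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if direction not in ("A_gt_B", "B_gt_A", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    all_mats = list(group_a) + list(group_b)
    n = all_mats[0].n_rois
    if mask is None:
        mask = edge_inclusion_mask(all_mats)
    iu, ju = np.nonzero(np.triu(mask, 1))
    n_a, n_b = len(group_a), len(group_b)
    n_subj = n_a + n_b
    x = np.stack([m.values[iu, ju] for m in all_mats])  # (n_subj, n_edges)
    df = n_a + n_b - 2
    if direction == "two_sided":
        t_crit = stats.t.ppf(1.0 - primary_p / 2.0, df)
    else:
        t_crit = stats.t.ppf(1.0 - primary_p, df)

    in_a = np.zeros(n_subj, dtype=bool)
    in_a[:n_a] = True
    t_obs = _edge_t(x, in_a, n_a, n_b)
    if x.shape[1] and (x.std(axis=0) == 0).any():
        warnings.warn(
            "edges with degenerate variance detected; their t statistic is 0",
            RuntimeWarning,
            stacklevel=2,
        )

    def supra(t: np.ndarray) -> np.ndarray:
        if direction == "A_gt_B":
            return t > t_crit
        if direction == "B_gt_A":
            return -t > t_crit
        return np.abs(t) > t_crit

    observed = _components_from_edges(n, iu, ju, supra(t_obs))

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for p_idx in range(n_perm):
        perm = rng.permutation(n_subj)
        perm_in_a = np.zeros(n_subj, dtype=bool)
        perm_in_a[perm[:n_a]] = True
        t_perm = _edge_t(x, perm_in_a, n_a, n_b)
        null_max[p_idx] = _max_component_size(n, iu, ju, supra(t_perm))

    components = [
        NBSComponent(
            nodes=nodes,
            edges=edges,
            size=size,
            corrected_p=(int((null_max >= size).sum()) + 1) / (n_perm + 1),
        )
        for nodes, edges, size in observed
    ]
    t_full = np.zeros((n, n))
    t_full[iu, ju] = t_obs
    t_full += t_full.T
    return NBSResult(
        direction=direction,
        primary_p=primary_p,
        components=components,
        null_max_sizes=null_max,
        n_perm=n_perm,
        t_matrix=t_full,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Nodal comparison with Bonferroni correction


@dataclass
class NodalComparison:
    observed_diff: np.ndarray  # (n_regions,), group A mean - group B mean
    p_values: np.ndarray
    significant: np.ndarray  # bool, p < alpha / n_regions
    alpha: float
    tail: str
    n_perm: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.p_values.size


def nodal_comparison(
    nodal_a: np.ndarray,
    nodal_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    tail: str = "two_sided",
    alpha: float = 0.05,
) -> NodalComparison:
    """Per-region permutation tests with Bonferroni correction across regions.

    ``nodal_a``/``nodal_b`` are subjects x regions arrays (e.g. nodal
    efficiency AUCs).  All regions share the same label reallocations.
    """
    a = np.atleast_2d(np.asarray(nodal_a, dtype=float))
    b = np.atleast_2d(np.asarray(nodal_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("region counts differ between groups")
    observed = a.mean(axis=0) - b.mean(axis=0)
    pooled = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    null = _perm_mean_diffs(pooled, a.shape[0], n_perm, rng)  # (n_perm, n_regions)
    if tail == "one_sided_upper":
        count = (null >= observed).sum(axis=0)
    elif tail == "one_sided_lower":
        count = (null <= observed).sum(axis=0)
    elif tail == "two_sided":
        count = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = (count + 1) / (n_perm + 1)
    return NodalComparison(
        observed_diff=observed,
        p_values=p,
        significant=p < alpha / a.shape[1],
        alpha=alpha,
        tail=tail,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Balanced-subsample robustness check


@dataclass
class SubsampleReport:
    metric_name: str
    full_sample_diff: float
    diffs: np.ndarray  # balanced-sample mean differences, length n_iter
    ci_low: float
    ci_high: float
    inside_ci: bool
    n_iter: int
    n_significant: int | None = None  # populated when per-iteration tests run


def balanced_subsample_analysis(
    patient_values,
    control_values,
    subsample_size: int | None = None,
    n_iter: int = 10000,
    seed: int | np.random.Generator = 0,
    metric_name: str = "metric",
    run_tests: bool = False,
    n_perm: int = 1000,
    tail: str = "two_sided",
    alpha: float = 0.05,
) -> SubsampleReport:
    """Robustness of a group difference to the imbalance in group sizes.

    Repeatedly draws a random control subset of ``subsample_size`` (default:
    the patient count), records the balanced mean difference, and checks that
    the full-sample difference lies inside the 2.5-97.5 percentile interval
    of the balanced distribution.  With ``run_tests=True`` each balanced
    draw additionally gets its own permutation test and the count of
    significant iterations is reported.
    """
    pat = np.asarray(patient_values, dtype=float)
    con = np.asarray(control_values, dtype=float)
    if subsample_size is None:
        subsample_size = pat.size
    if subsample_size > con.size:
        raise ValueError("subsample_size exceeds the control group size")
    rng = np.random.default_rng(seed)
    full_diff = float(pat.mean() - con.mean())
    diffs = np.empty(n_iter)
    n_sig = 0
    for it in range(n_iter):
        subset = con[rng.choice(con.size, size=subsample_size, replace=False)]
        diffs[it] = pat.mean() - subset.mean()
        if run_tests:
            res = mean_diff_permutation_test(
                pat, subset, n_perm=n_perm, tail=tail, seed=rng,
                metric_name=metric_name,
            )
            n_sig += res.p_value < alpha
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    return SubsampleReport(
        metric_name=metric_name,
        full_sample_diff=full_diff,
        diffs=diffs,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        inside_ci=bool(ci_low <= full_diff <= ci_high),
        n_iter=n_iter,
        n_significant=n_sig if run_tests else None,
    )


# ---------------------------------------------------------------------------
# Brain-behaviour correlations


@dataclass
class BehaviorCorrelation:
    metric_name: str
    score_name: str
    r: float
    p: float
    p_fdr: float


def behavior_correlation(
    metric_values: dict[str, np.ndarray],
    scores: dict[str, np.ndarray],
) -> list[BehaviorCorrelation]:
    """Pearson correlations between network metrics and behavioural scores.

    Every (metric, score) pair is tested (two-sided) and the p-values are
    jointly Benjamini-Hochberg corrected across all pairs.
    """
    pairs = []
    for m_name, m_vals in metric_values.items():
        mv = np.asarray(m_vals, dtype=float)
        for s_name, s_vals in scores.items():
            sv = np.asarray(s_vals, dtype=float)
            if mv.size != sv.size:
                raise ValueError(
                    f"size mismatch between {m_name!r} and {s_name!r}"
                )
            if mv.size < 3:
                raise ValueError("at least 3 paired observations are required")
            if mv.std() == 0 or sv.std() == 0:
                raise ValueError(
                    f"zero variance in {m_name!r} or {s_name!r}"
                )
            r, p = stats.pearsonr(mv, sv)
            pairs.append((m_name, s_name, float(r), float(p)))
    if not pairs:
        return []
    _, p_fdr, _, _ = multipletests([p for *_, p in pairs], method="fdr_bh")
    return [
        BehaviorCorrelation(m, s, r, p, float(q))
        for (m, s, r, p), q in zip(pairs, p_fdr)
    ]
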