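"""Synthetic two-group cohorts of ROI time series with known ground truth.

The generator emulates a resting-state fMRI case-control study: 28 patients
versus 40 matched controls, 90 regional mean time series per subject, 235
time points each (a 480 s scan at TR = 2 s with the first five volumes
discarded).  Region covariance is block-modular — a target correlation
``within_r`` inside modules and ``between_r`` elsewhere — and a group effect
is planted by adding ``group_delta`` to a chosen edge set in the patient
group's model correlation matrix.  Every cohort carries a truth record
(planted edges, deltas, expected direction of group differences) so that
downstream detection can be scored against known ground truth.

Time series are white Gaussian draws from the model covariance; band-pass
filtering and nuisance regression are upstream preprocessing concerns and are
not simulated.  An optional AR(1) coefficient adds temporal autocorrelation
for robustness experiments (default off: the analysis consumes only
correlations, which a shared AR(1) leaves asymptotically unchanged).

All region indices in this module are 0-based Python indices; 1-based atlas
indices appear only in exported tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

Edge = tuple[int, int]

#: score name -> ((patient mean, patient sd), (control mean, control sd))
#: Gaussian score models shaped like the emulated study's cognitive battery:
#: a 0-30 global cognition score and a source-memory accuracy in [0, 1].
SCORE_MODELS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "mmse": ((25.89, 2.41), (28.35, 1.46)),
    "source_memory": ((0.53, 0.04), (0.75, 0.04)),
}

_MIN_EIG = 1e-6


def default_modules(n_rois: int, n_modules: int = 6) -> list[list[int]]:
    """Partition ``range(n_rois)`` into ``n_modules`` contiguous blocks."""
    return [list(b) for b in np.array_split(np.arange(n_rois), n_modules)]


@dataclass
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    ``modules`` must partition ``range(n_rois)``; ``group_delta`` is added to
    the model correlation of every edge in ``planted_edges`` for the patient
    group only.
    """

    n_patients: int = 28
    n_controls: int = 40
    n_rois: int = 90
    n_timepoints: int = 235
    modules: list[list[int]] | None = None
    within_r: float = 0.5
    between_r: float = 0.1
    #: patient-group within-module correlation; None = same as controls.
    #: Setting it below within_r randomizes the patients' module structure.
    patient_within_r: float | None = None
    group_delta: float = 0.0
    planted_edges: tuple[Edge, ...] = ()
    ar1: float = 0.0
    seed: int = 0
    expected_directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modules is None:
            self.modules = default_modules(self.n_rois)
        flat = sorted(i for m in self.modules for i in m)
        if flat != list(range(self.n_rois)):
            raise ValueError("modules must partition range(n_rois)")
        if not (0 <= self.within_r < 1 and 0 <= self.between_r < 1):
            raise ValueError("within_r and between_r must lie in [0, 1)")
        if self.patient_within_r is not None and not 0 <= self.patient_within_r < 1:
            raise ValueError("patient_within_r must lie in [0, 1)")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be at least 3")
        self.planted_edges = tuple(
            (min(i, j), max(i, j)) for i, j in self.planted_edges
        )
        for i, j in self.planted_edges:
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"invalid planted edge ({i}, {j})")


@dataclass
class TimeSeriesPanel:
    """One subject's ROI time series, time points in rows, regions in columns."""

    subject_id: str
    group: str  # "patient" | "control"
    data: np.ndarray  # shape (n_timepoints, n_rois)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be 2-D (time x region)")
        if not np.isfinite(self.data).all():
            raise ValueError(f"panel {self.subject_id}: non-finite values")
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class BehaviorTable:
    """Per-subject behavioural scores (one row per subject)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["subject_id"].duplicated().any():
            raise ValueError("behavior table: duplicated subject_id")
        if "source_memory" in t.columns:
            acc = t["source_memory"].to_numpy(float)
            if ((acc < 0) | (acc > 1)).any():
                raise ValueError("accuracy scores must lie in [0, 1]")

    @property
    def score_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("subject_id", "group")]


@dataclass
class Cohort:
    panels: list[TimeSeriesPanel]
    behavior: BehaviorTable
    truth: dict


def block_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Model correlation matrix for one group.

    Within-module entries equal ``within_r``, between-module entries
    ``between_r``; for the patient group ``group_delta`` is added on the
    planted edges.  If the result is not positive definite its eigenvalues
    are clipped at 1e-6 and the matrix rescaled to unit diagonal (with a
    RuntimeWarning), so aggressive deltas degrade gracefully instead of
    aborting the simulation.
    """
    n = spec.n_rois
    within = spec.within_r
    if group == "patient" and spec.patient_within_r is not None:
        within = spec.patient_within_r
    r = np.full((n, n), spec.between_r, dtype=float)
    for block in spec.modules:
        bb = np.ix_(block, block)
        r[bb] = within
    np.fill_diagonal(r, 1.0)
    if group == "patient" and spec.group_delta != 0.0:
        for i, j in spec.planted_edges:
            r[i, j] += spec.group_delta
            r[j, i] = r[i, j]
        off = r[~np.eye(n, dtype=bool)]
        if off.size and (np.abs(off) >= 1.0).any():
            bad = float(np.max(np.abs(off)))
            raise ValueError(
                f"group_delta pushes a model correlation to {bad:.3f}, "
                "outside (-1, 1)"
            )
    w = np.linalg.eigvalsh(r)
    if w[0] < _MIN_EIG:
        warnings.warn(
            f"model correlation matrix not positive definite "
            f"(min eigenvalue {w[0]:.3e}); clipping eigenvalues at {_MIN_EIG:g} "
            "and rescaling to unit diagonal",
            RuntimeWarning,
            stacklevel=2,
        )
        w, v = np.linalg.eigh(r)
        r = (v * np.clip(w, _MIN_EIG, None)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    return r


def sample_panel(
    cov: np.ndarray,
    n_timepoints: int,
    seed: int | np.random.Generator,
    subject_id: str = "sub",
    group: str = "control",
    ar1: float = 0.0,
) -> TimeSeriesPanel:
    """Draw a zero-mean Gaussian panel from a positive-definite covariance."""
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be at least 3 (correlation degenerate)")
    cov = np.asarray(cov, dtype=float)
    ev_min = np.linalg.eigvalsh(cov)[0]
    if ev_min <= 0:
        raise ValueError(f"covariance not positive definite (min eigenvalue {ev_min:.3e})")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((n_timepoints, cov.shape[0])) @ chol.T
    if ar1:
        if not -1.0 < ar1 < 1.0:
            raise ValueError("ar1 coefficient must lie in (-1, 1)")
        x = lfilter([1.0], [1.0, -ar1], x, axis=0)
    return TimeSeriesPanel(subject_id=subject_id, group=group, data=x)


def make_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a full two-group cohort with behaviour scores and truth record."""
    rng = np.random.default_rng(spec.seed)
    cov = {g: block_covariance(spec, g) for g in ("patient", "control")}
    panels: list[TimeSeriesPanel] = []
    rows = []
    for group, count in (("patient", spec.n_patients), ("control", spec.n_controls)):
        for k in range(count):
            sid = f"{'pat' if group == 'patient' else 'con'}{k + 1:03d}"
            panels.append(
                sample_panel(
                    cov[group], spec.n_timepoints, rng,
                    subject_id=sid, group=group, ar1=spec.ar1,
                )
            )
            scores = {}
            for name, (pat, con) in SCORE_MODELS.items():
                mean, sd = pat if group == "patient" else con
                val = rng.normal(mean, sd)
                if name == "source_memory":
                    val = float(np.clip(val, 0.0, 1.0))
                scores[name] = val
            rows.append({"subject_id": sid, "group": group, **scores})
    behavior = BehaviorTable(pd.DataFrame(rows))
    null = spec.group_delta == 0.0 or not spec.planted_edges
    truth = {
        "null_cohort": null and spec.patient_within_r is None,
        "patient_within_r": spec.patient_within_r,
        "group_delta": 0.0 if null else spec.group_delta,
        "planted_edges": [] if null else [list(e) for e in spec.planted_edges],
        "n_patients": spec.n_patients,
        "n_controls": spec.n_controls,
        "expected_directions": {} if null else dict(spec.expected_directions),
        "seed": spec.seed,
    }
    return Cohort(panels=panels, behavior=behavior, truth=truth)


def ring_lattice_weights(
    n_rois: int = 90,
    n_shortcuts: int = 45,
    seed: int = 0,
    shortcut_weight: float = 0.45,
) -> np.ndarray:
    """Weighted ring lattice with random long-range shortcuts.

    Edge weight decays with ring distance (1/(1+d)), so sparsity
    thresholding recovers a ring lattice of growing reach; ``n_shortcuts``
    random pairs at ring distance > 5 get a weight between the distance-1
    and distance-2 weights and therefore enter the network at every grid
    sparsity.  This is the canonical small-world construction: high
    clustering from the lattice, short paths from the shortcuts, hence
    gamma > 1 with lambda ~ 1 across the default sparsity grid.
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(n_rois)
    dist = np.abs(idx[:, None] - idx[None, :])
    dist = np.minimum(dist, n_rois - dist)
    w = np.where(dist > 0, 1.0 / (1.0 + dist), 0.0)
    placed = 0
    while placed < n_shortcuts:
        i, j = rng.integers(0, n_rois, 2)
        if i == j:
            continue
        d = min(abs(i - j), n_rois - abs(i - j))
        if d <= 5 or w[i, j] >= shortcut_weight:
            continue
        w[i, j] = w[j, i] = shortcut_weight
        placed += 1
    return w


# ---------------------------------------------------------------------------
# Preset cohort constructions


def hub_incident_edges(n_rois: int, hubs: Sequence[int]) -> tuple[Edge, ...]:
    """All edges incident to the given hub regions (deduplicated)."""
    hubset = set(hubs)
    edges = set()
    for h in hubset:
        for j in range(n_rois):
            if j != h:
                edges.add((min(h, j), max(h, j)))
    return tuple(sorted(edges))


def hub_enhanced_spec(
    delta: float = 0.2,
    n_hubs: int = 8,
    patient_within_r: float | None = 0.35,
    seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """Cohort in which patients gain hub-concentrated hyperconnectivity
    while their module structure is simultaneously randomized.

    Every edge incident to ``n_hubs`` evenly spaced regions is raised by
    ``delta`` in the patient group (the resulting model correlation matrix
    is strongly non-PD and is eigenvalue-repaired, which spreads the
    hyperconnectivity over the hub neighbourhoods), and the patients'
    within-module correlation is lowered to ``patient_within_r`` (default
    0.35 against the control 0.5), weakening modular clustering.  At fixed
    sparsity the hub edges shorten paths and star-dominate neighbourhoods —
    absolute global and local efficiency rise — while the heavy-tailed
    binary degree sequence inflates the local efficiency of
    degree-preserving random surrogates faster than the de-modularized real
    networks can match, so normalized local efficiency (gamma) falls: the
    qualitative dissociation hyperconnectivity studies report.  Normalized
    global efficiency (lambda) is reported but carries no planted
    direction: at matched density the random-network global efficiency is
    nearly degree-invariant outside the fragmented low-sparsity regime, so
    lambda tracks absolute global efficiency for any edge-level planting.
    """
    spec = CohortSpec(seed=seed, **kwargs)
    hubs = [int(i * spec.n_rois / n_hubs) for i in range(n_hubs)]
    return CohortSpec(
        **{
            **_spec_kwargs(spec),
            "patient_within_r": patient_within_r,
            "group_delta": delta,
            "planted_edges": hub_incident_edges(spec.n_rois, hubs),
            "expected_directions": {
                "global_efficiency_auc": "patient>control",
                "local_efficiency_auc": "patient>control",
                "normalized_local_efficiency_auc": "patient<control",
            },
            "seed": seed,
        }
    )


def planted_component_spec(
    n_component_nodes: int = 12,
    n_component_edges: int = 40,
    delta: float = 0.3,
    seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """Cohort with one connected suprathreshold component planted for NBS.

    A connected subgraph with ``n_component_edges`` edges over
    ``n_component_nodes`` evenly spaced regions is raised by ``delta`` in the
    patient group; its edge list is recorded in the truth record so recovery
    sensitivity can be measured.
    """
    spec = CohortSpec(seed=seed, **kwargs)
    max_edges = n_component_nodes * (n_component_nodes - 1) // 2
    if n_component_edges > max_edges:
        raise ValueError("requested component has more edges than node pairs")
    nodes = [int(i * spec.n_rois / n_component_nodes) for i in range(n_component_nodes)]
    rng = np.random.default_rng(seed + 1)
    # random spanning tree first (guarantees connectedness), then extra pairs
    order = list(rng.permutation(nodes))
    edges = set()
    for k in range(1, len(order)):
        a = order[k]
        b = order[int(rng.integers(0, k))]
        edges.add((min(a, b), max(a, b)))
    pool = [
        (min(a, b), max(a, b))
        for i, a in enumerate(nodes)
        for b in nodes[i + 1:]
    ]
    rng.shuffle(pool)
    for e in pool:
        if len(edges) >= n_component_edges:
            break
        edges.add(e)
    return CohortSpec(
        **{
            **_spec_kwargs(spec),
            "group_delta": delta,
            "planted_edges": tuple(sorted(edges)),
            "expected_directions": {"planted_component": "patient>control"},
            "seed": seed,
        }
    )


def _spec_kwargs(spec: CohortSpec) -> dict:
    return {
        "n_patients": spec.n_patients,
        "n_controls": spec.n_controls,
        "n_rois": spec.n_rois,
        "n_timepoints": spec.n_timepoints,
        "modules": spec.modules,
        "within_r": spec.within_r,
        "between_r": spec.between_r,
        "patient_within_r": spec.patient_within_r,
        "ar1": spec.ar1,
    }
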