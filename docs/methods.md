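# Methods

`funconn` implements a graph-theoretic analysis of resting-state functional
connectivity: per-subject Pearson correlation matrices over a 90-region
parcellation are converted to binary networks across a sparsity grid,
characterized by small-world efficiency metrics with degree-preserving
random-network normalization, and compared between groups with permutation
tests, including the network-based statistic (NBS).  A synthetic cohort
generator with planted effects makes every stage testable without imaging
data.

## Network construction

Each subject contributes an N x N Pearson correlation matrix of regional
mean time series (N = 90 by default; diagonal structurally zero).  Negative
correlations are excluded — set to zero — before any network analysis,
because their interpretation in functional connectivity is ambiguous.
Binarization is by **sparsity** S: the K = round_half_up(S · N(N−1)/2)
strongest positive correlations become edges, so every subject's network has
exactly the same edge count and the comparison is not confounded by overall
connectivity strength.  The rounding convention (half-up) and the tie rule
(ties at the cutoff broken by ascending row, then column index) are pinned
implementation constants; the analyses this emulates do not state either,
and the tie rule trades fidelity to an unknown toolbox internal for
cross-platform reproducibility.  Because the edge ordering is independent of
S, edge sets are nested across the grid.  The default grid is
S = 0.05, 0.07, …, 0.39 (18 values): the stated open range 0.05 < S < 0.4 at
step 0.02 is only consistent with a grid that starts at 0.05, so the closed
grid is used.

## Efficiency metrics

With d_ij the minimum edge count between nodes i and j:

- global efficiency  E_glob = 1/(N(N−1)) Σ_{i≠j} 1/d_ij
- local efficiency   E_loc = 1/N Σ_i E_glob(G_i), G_i the subgraph induced
  by the neighbours of node i
- nodal efficiency   e_i = 1/(N−1) Σ_{j≠i} 1/d_ij

Unreachable pairs contribute 0 (the standard convention that makes
efficiency well defined on disconnected graphs); neighbour subgraphs with
fewer than two nodes contribute 0 to E_loc, avoiding 0/0.  The mean of e_i
over nodes equals E_glob algebraically; the test-suite pins this identity at
1e-12 and checks distances against a Floyd–Warshall oracle and the
efficiency values against networkx.  Distances are computed by per-source
breadth-first search (numba kernels; a pure-numpy boolean-matrix BFS backs
the public `shortest_paths` and the cross-checks).

Metrics are evaluated at every grid sparsity and summarized per subject by
the area under the curve (trapezoidal rule — the quadrature is not stated in
the literature this follows; trapezoid is the pinned choice), giving one
threshold-free scalar per metric for inference.

## Null models and small-worldness

Each network is compared with degree-preserving random surrogates produced
by double-edge swaps: 10 · |E| attempted swaps (pinned, configurable), each
accepted only if it creates no self-loop or duplicate edge.  Degree
sequences are preserved exactly; connectedness is not enforced (efficiency
handles disconnection).  Normalized efficiencies divide the real values by
the surrogate-ensemble mean (library default 100 surrogates, matching the
emulated study's convention): λ(S) for global, γ(S) for local.  A network
with γ > 1 and λ ~ 1 is small-world; the λ tolerance band for the boolean
flag (default [0.8, 1.2]) is a reporting device only and never enters
inference.  A zero ensemble mean (star-like graphs) yields NaN, which AUC
summaries drop with a warning.

## Group inference

All group comparisons are non-parametric.  The mean-difference permutation
test reallocates subjects to groups (default 10,000 permutations) and
reports p = (#{null as extreme} + 1)/(n_perm + 1); the add-one smoothing
generalizes percentile critical values and guarantees p > 0.  An exact mode
enumerates all C(n, n_A) splits when feasible.  The tail is always an
explicit argument — the emulated study's one-tailed choice is not assumed.

The NBS thresholds an edge-wise pooled-variance two-sample t map at a
primary p (default 0.01, converted to a t cutoff at the pooled dof and
re-applied inside every permutation), extracts connected components of the
suprathreshold graph, and refers each component's edge count M to the
permutation null of the *maximal* component size, controlling family-wise
error: corrected p = (#{null max ≥ M} + 1)/(n_perm + 1).  Only edges
positive in strictly more than 80% of all subjects enter the analysis.
Each one-sided direction is run separately (a two-sided mode exists).
Edges with degenerate variance get t = 0 with a warning.

Nodal-efficiency AUCs are tested per region with shared permutations and
Bonferroni correction across the 90 regions; hubs are regions whose mean
nodal-efficiency AUC is at least one standard deviation above the group
mean, with mean and SD pooled over all node-by-participant values (sample
SD; the ≥ rule makes the degenerate zero-SD case flag every region).  Hubs
are defined on AUC values rather than a single sparsity — the source
analyses are ambiguous here, and AUC matches how every other nodal quantity
is summarized.  Brain–behaviour Pearson correlations are computed for
metrics with significant group differences, in the patient group, with
Benjamini–Hochberg FDR across tested (metric, score) pairs.  The
balanced-subsample robustness check repeatedly draws control subsets of the
patient-group size, records balanced mean differences, and verifies the
full-sample difference falls inside the 2.5–97.5 percentile interval (the
CI construction is a pinned choice); optionally each balanced draw gets its
own permutation test.

## Synthetic cohorts

The generator emulates the target study's design: 28 patients vs 40
controls, 90 regions, 235 time points (a 480 s scan at TR = 2 s minus five
discarded volumes).  Time series are zero-mean Gaussian draws from a
block-modular model correlation matrix — `within_r` (default 0.5) inside
modules (default: six contiguous blocks of 15 regions), `between_r`
(default 0.1) elsewhere — values typical of resting-state functional
connectivity within and between large-scale networks.  Group effects are
planted by adding `group_delta` to a chosen edge set for patients only; if
the shifted matrix is no longer positive definite its eigenvalues are
clipped at 1e-6 and the matrix rescaled to unit diagonal, with a loud
warning, so aggressive plantings degrade gracefully.  Behaviour scores are
Gaussian with group means/SDs shaped like the emulated study's cognitive
battery (a 0–30 global-cognition score and a source-memory accuracy in
[0, 1], lower in patients).  Time series are white (no autocorrelation) by
default because the analysis consumes only correlations and temporal
filtering is upstream preprocessing; an AR(1) knob exists for robustness
experiments.

Two preset plantings carry truth records for recovery tests:

- `planted_component_spec`: a connected 40-edge subgraph over 12 spread-out
  regions raised by +0.3 — ground truth for NBS recovery.  The delta is a
  calibration choice (no effect size is documented for the real data),
  giving an edge-level effect large enough that recovery is expected at the
  study's sample sizes.
- `hub_enhanced_spec`: every edge incident to 8 evenly spaced regions raised
  by +0.2, combined with a weakened patient within-module correlation
  (0.35 against the control 0.5) that randomizes the patients' module
  structure.  The hub planting is deliberately non-PD and relies on the
  repair, which diffuses hyperconnectivity over hub neighbourhoods.
  Together the two manipulations raise patients' absolute global and local
  efficiency while depressing normalized local efficiency (γ): hub stars
  keep the real networks locally efficient, but the heavy-tailed degree
  sequence inflates the surrogate ensemble's local efficiency faster than
  the de-modularized real networks can match.  Normalized
  global efficiency (λ) carries no planted direction: at matched edge count
  the surrogate ensemble's global efficiency is nearly degree-invariant
  outside the fragmented low-sparsity regime, so λ tracks absolute E_glob
  for any edge-level planting of this kind — a structural limit of the
  generator, not of the inference machinery.

What the generator does **not** emulate: hemodynamics, head motion, scanner
noise spectra, spatial autocorrelation of the parcellation, and
non-Gaussian tails of real BOLD correlations.  Passing tests therefore
demonstrate the correctness and calibration of the graph/statistical
machinery under a known ground truth, not the reproduction of any clinical
finding.

## Numerical choices and problem sizes

- K rounding half-up with a 1e-9 epsilon against binary-float products.
- PD repair threshold 1e-6 on eigenvalues.
- Permutation p-values smoothed (+1/+1); NBS component statistic is the
  edge count; corrected p uses ≥ with the same smoothing.
- All randomness flows from explicit seeds (numpy Generators); the full
  pipeline is byte-deterministic given a seed.
- The acceptance run and test-suite scale Monte-Carlo sizes that trade only
  precision for time: surrogate ensembles of 20–25 (library default 100),
  2,000 permutations for group tests (default 10,000), 500 balanced
  subsample iterations (default 10,000), 500 null cohorts at 30 regions for
  the NBS family-wise-error simulation.  These choices are recorded here as
  the package's own reduced-precision defaults for simulation studies.

## Known limitations

- Binary undirected graphs only; no weighted metrics, no Fisher z.
- No covariate adjustment in group tests (the emulated design matches
  groups on age and education instead).
- The double-edge-swap ensemble is not a uniform sample of the fixed-degree
  graph space (standard caveat for swap-based nulls).
- λ's direction cannot be planted independently of absolute E_glob in the
  generator (see above).
- The homogeneous control model (identical model correlations for every
  region of a module) produces little regional heterogeneity, so control
  groups typically show no hubs under the mean + 1 SD rule; hub counts are
  informative only for cohorts with planted hub structure.
- NBS power at 90 regions under the modular background is low for small
  components: correlation-estimation errors are correlated across edges
  that share nodes or modules, so pure-noise suprathreshold clusters reach
  ~80 edges at the 95th percentile of the max-component null.  Family-wise
  error control is unaffected (the max statistic calibrates to its own
  null); component-recovery simulations therefore run at 30 regions.
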