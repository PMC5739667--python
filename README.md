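# funconn

Graph-theoretic analysis of functional brain connectivity for case-control
studies: sparsity-thresholded binary networks, small-world efficiency
metrics with degree-preserving random-network normalization, and
permutation-based group inference including the network-based statistic
(NBS).  Written for researchers who analyse regional rs-fMRI time series
(or precomputed correlation matrices) with the GRETNA-style binary-graph
workflow and want a scriptable, fully seeded, plain-text-I/O
implementation — plus a synthetic cohort generator with planted ground
truth for validating every stage.

## The method

Each subject's N regional mean time series (N = 90 by default, following
the standard 90-region anatomical parcellation) are Pearson-correlated into
an N × N connectivity matrix; negative correlations are set to zero.  At a
sparsity S, the K = round_half_up(S·N(N−1)/2) strongest correlations become
the edges of a binary graph, so every subject's network has the same cost.
Over the grid S = 0.05, 0.07, …, 0.39 the package computes, with d_ij the
shortest path length:

- global efficiency E_glob = 1/(N(N−1)) Σ_{i≠j} 1/d_ij,
- local efficiency E_loc = 1/N Σ_i E_glob(G_i) over neighbour subgraphs G_i,
- nodal efficiency e_i = 1/(N−1) Σ_{j≠i} 1/d_ij,

plus normalized efficiencies λ(S) and γ(S) against the mean of
degree-preserving random surrogates (double-edge swaps); γ > 1 with λ ∼ 1
marks small-world organization.  Curves are summarized per subject by the
area under the curve (AUC) and compared between groups with permutation
tests; edge-level group differences use the NBS (primary t-threshold,
connected components, max-component permutation null for family-wise error
control); hubs are regions with nodal-efficiency AUC at least one SD above
the group mean.  See `docs/methods.md` for every convention and default.

## Worked example

```python
import numpy as np
from funconn import (default_grid, hub_enhanced_spec, make_cohort,
                     mean_diff_permutation_test, metric_curve, auc,
                     pearson_matrix, rectify_negatives)
from funconn.synthetic import default_modules

# simulated case-control cohort in which patients carry hub-concentrated
# hyperconnectivity (known ground truth in cohort.truth)
spec = hub_enhanced_spec(seed=1, n_rois=30, n_hubs=4,
                         modules=default_modules(30, 2),
                         n_patients=14, n_controls=20, n_timepoints=235)
cohort = make_cohort(spec)

grid = default_grid()
aucs, groups = [], []
for panel in cohort.panels:
    m = rectify_negatives(pearson_matrix(panel))
    aucs.append(auc(metric_curve(m, grid, "global_efficiency")).auc)
    groups.append(panel.group)
aucs, groups = np.array(aucs), np.array(groups)
pat, con = aucs[groups == "patient"], aucs[groups == "control"]
res = mean_diff_permutation_test(pat, con, n_perm=5000,
                                 tail="two_sided", seed=2)
print(f"global efficiency AUC: patients {pat.mean():.4f} +/- {pat.std(ddof=1):.4f}, "
      f"controls {con.mean():.4f} +/- {con.std(ddof=1):.4f}")
print(f"difference {res.observed_diff:+.4f}, permutation p = {res.p_value:.4f} "
      f"({res.n_perm} permutations)")
```

prints

```
global efficiency AUC: patients 0.1542 +/- 0.0139, controls 0.1054 +/- 0.0045
difference +0.0487, permutation p = 0.0002 (5000 permutations)
```

i.e. the patients' thresholded networks transfer information more
efficiently at matched network cost (higher mean inverse path length
integrated over the sparsity grid), and no random group reallocation among
the 5,000 drawn came close to the observed difference (smoothed p =
1/5001).

## Command line

The same pipeline runs end to end from a shell, producing tidy TSVs, JSON
reports, a markdown summary, and BrainNet-Viewer-style `.node`/`.edge`
exports in one output directory:

```
funconn run-all -o run1 --planting hub --seed 7 \
    --ensemble-size 25 --n-perm 2000
```

Stages (`simulate`, `connectivity`, `metrics`, `nulls`, `compare`, `nbs`,
`report`) can be re-run individually on the same directory, and real data
enter via `--mode timeseries_dir` (per-subject TSVs + a manifest) or
`--mode matrices_dir` (precomputed correlation matrices).

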