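"""Permutation tests, NBS, subsample robustness, behaviour correlations."""

from itertools import combinations

import numpy as np
import pytest

from funconn import (
    balanced_subsample_analysis,
    behavior_correlation,
    edge_inclusion_mask,
    mean_diff_permutation_test,
    nbs,
    nodal_comparison,
)
from funconn.connectivity import ConnectivityMatrix, rectify_negatives
from funconn.synthetic import (
    CohortSpec,
    block_covariance,
    make_cohort,
    planted_component_spec,
    sample_panel,
)
from funconn import pearson_matrix


def brute_force_p(a, b, tail):
    """Independent exhaustive-enumeration oracle for the mean-difference test."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    obs = a.mean() - b.mean()
    stats = []
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        stats.append(pooled[mask].mean() - pooled[~mask].mean())
    stats = np.asarray(stats)
    if tail == "one_sided_upper":
        extreme = stats >= obs
    elif tail == "one_sided_lower":
        extreme = stats <= obs
    else:
        extreme = np.abs(stats) >= abs(obs)
    return extreme.mean()


class TestMeanDiffPermutation:
    @pytest.mark.parametrize("tail", ["one_sided_upper", "one_sided_lower",
                                      "two_sided"])
    def test_exact_mode_matches_enumeration_oracle(self, tail):
        a = np.array([3.1, 4.2, 5.9])
        b = np.array([1.0, 2.5])
        res = mean_diff_permutation_test(a, b, tail=tail, exact=True)
        assert res.n_perm == 10  # C(5, 3) label splits
        assert res.p_value == pytest.approx(brute_force_p(a, b, tail))

    def test_identical_multisets_give_p_near_one(self):
        a = np.array([1.0, 2.0, 3.0])
        res = mean_diff_permutation_test(a, a.copy(), n_perm=500,
                                         tail="one_sided_upper", seed=0)
        assert res.observed_diff == 0.0
        assert res.p_value > 0.4

    def test_smoothed_p_bounds(self):
        rng = np.random.default_rng(1)
        res = mean_diff_permutation_test(rng.normal(2, 1, 10),
                                         rng.normal(0, 1, 10),
                                         n_perm=99, seed=2)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_strong_effect_hits_smoothing_floor(self):
        res = mean_diff_permutation_test(np.arange(10) + 100.0, np.arange(10),
                                         n_perm=200, tail="one_sided_upper",
                                         seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mean_diff_permutation_test([], [1.0])

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(size=9)
        r1 = mean_diff_permutation_test(a, b, n_perm=200, seed=11)
        r2 = mean_diff_permutation_test(a, b, n_perm=200, seed=11)
        assert r1.p_value == r2.p_value


class TestEdgeInclusionMask:
    def _mats(self, values):
        out = []
        for v in values:
            m = np.array(v, dtype=float)
            out.append(ConnectivityMatrix(m, rectified=False))
        return out

    def test_boundary_exactly_80_percent_excluded(self):
        # edge (0,1) positive in 4 of 5 subjects = exactly 0.8 -> excluded
        base = np.zeros((3, 3))
        mats = []
        for k in range(5):
            v = base.copy()
            v[0, 1] = v[1, 0] = 0.5 if k < 4 else -0.5
            v[0, 2] = v[2, 0] = 0.4  # positive in all -> included
            mats.append(ConnectivityMatrix(v))
        mask = edge_inclusion_mask(mats)
        assert not mask[0, 1]
        assert mask[0, 2]

    def test_matches_direct_recount_on_random_cohort(self, rng):
        mats = []
        for _ in range(9):
            v = rng.uniform(-1, 1, (6, 6))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats.append(ConnectivityMatrix(v))
        mask = edge_inclusion_mask(mats)
        stacked = np.stack([m.values for m in mats])
        for i in range(6):
            for j in range(6):
                expected = (i != j) and (stacked[:, i, j] > 0).sum() / 9 > 0.8
                assert mask[i, j] == expected


def _simulate_matrices(spec):
    cohort = make_cohort(spec)
    pats = [rectify_negatives(pearson_matrix(p)) for p in cohort.panels
            if p.group == "patient"]
    cons = [rectify_negatives(pearson_matrix(p)) for p in cohort.panels
            if p.group == "control"]
    return pats, cons, cohort.truth


@pytest.fixture(scope="module")
def planted():
    spec = planted_component_spec(
        n_component_nodes=8, n_component_edges=12, delta=0.4,
        n_patients=12, n_controls=14, n_rois=20, n_timepoints=120,
        modules=[list(range(10)), list(range(10, 20))], seed=31)
    return spec, _simulate_matrices(spec)


class TestNBS:

    def test_planted_component_recovered(self, planted):
        spec, (pats, cons, truth) = planted
        res = nbs(pats, cons, primary_p=0.01, n_perm=400, direction="A_gt_B",
                  seed=0)
        sig = res.significant_components(0.05)
        assert sig, "planted component not detected"
        found = {tuple(e) for c in sig for e in c.edges}
        planted_edges = {tuple(e) for e in truth["planted_edges"]}
        sensitivity = len(found & planted_edges) / len(planted_edges)
        assert sensitivity >= 0.8

    def test_corrected_p_floor_and_monotonicity(self, planted):
        spec, (pats, cons, _) = planted
        res = nbs(pats, cons, primary_p=0.01, n_perm=400, direction="A_gt_B",
                  seed=1)
        sizes = [c.size for c in res.components]
        ps = [c.corrected_p for c in res.components]
        assert res.components[0].corrected_p >= 1 / 401
        # monotone: larger component -> corrected p no larger
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            assert s1 >= s2 and p1 <= p2

    def test_null_direction_finds_nothing(self, planted):
        spec, (pats, cons, _) = planted
        res = nbs(pats, cons, primary_p=0.01, n_perm=200, direction="B_gt_A",
                  seed=2)
        assert not res.significant_components(0.05)

    def test_degenerate_variance_warns_and_zeroes(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.5
        mats_a = [ConnectivityMatrix(v.copy()) for _ in range(3)]
        mats_b = [ConnectivityMatrix(v.copy()) for _ in range(3)]
        mask = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(mask, False)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = nbs(mats_a, mats_b, n_perm=20, seed=0, mask=mask)
        assert not res.components

    def test_group_size_validation(self):
        m = ConnectivityMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            nbs([m], [m, m], n_perm=10)


class TestNodalComparison:
    def test_identical_groups_all_negative(self, rng):
        x = rng.normal(size=(8, 6))
        res = nodal_comparison(x, x.copy(), n_perm=200, seed=0)
        assert not res.significant.any()

    def test_inflated_region_detected_with_direction(self, rng):
        a = rng.normal(size=(15, 6))
        b = rng.normal(size=(15, 6))
        a[:, 2] += 8.0
        res = nodal_comparison(a, b, n_perm=2000, seed=1)
        assert list(np.nonzero(res.significant)[0]) == [2]
        assert res.observed_diff[2] > 0

    def test_bonferroni_threshold(self, rng):
        res = nodal_comparison(rng.normal(size=(4, 10)),
                               rng.normal(size=(4, 10)), n_perm=50, seed=0)
        assert res.bonferroni_threshold == pytest.approx(0.05 / 10)


class TestBalancedSubsample:
    def test_full_size_subsample_degenerate_ci(self, rng):
        pat = rng.normal(1, 1, 10)
        con = rng.normal(0, 1, 12)
        rep = balanced_subsample_analysis(pat, con, subsample_size=12,
                                          n_iter=50, seed=0)
        assert rep.ci_low == pytest.approx(rep.full_sample_diff)
        assert rep.ci_high == pytest.approx(rep.full_sample_diff)
        assert rep.inside_ci

    def test_oversized_subsample_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            balanced_subsample_analysis(rng.normal(size=5), rng.normal(size=6),
                                        subsample_size=7, n_iter=10)

    def test_strong_effect_all_iterations_significant(self, rng):
        pat = rng.normal(5, 1, 20)
        con = rng.normal(0, 1, 28)
        rep = balanced_subsample_analysis(pat, con, n_iter=100, seed=1,
                                          run_tests=True, n_perm=99,
                                          tail="one_sided_upper")
        assert rep.n_significant == 100
        assert rep.inside_ci


class TestBehaviorCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        out = behavior_correlation({"m": x}, {"s": x.copy()})
        assert out[0].r == pytest.approx(1.0)
        assert out[0].p < 1e-10

    def test_fdr_no_smaller_than_raw_p(self, rng):
        metrics = {f"m{k}": rng.normal(size=15) for k in range(3)}
        scores = {f"s{k}": rng.normal(size=15) for k in range(2)}
        for c in behavior_correlation(metrics, scores):
            assert c.p_fdr >= c.p - 1e-15

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            behavior_correlation({"m": np.ones(5)}, {"s": np.arange(5.0)})

    def test_recovers_true_correlation(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(40):
            x = rng.normal(size=28)
            y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=28)
            rs.append(behavior_correlation({"m": x}, {"s": y})[0].r)
        se = np.sqrt((1 - 0.5 ** 2) ** 2 / 28)  # approx sampling SE of r
        assert np.mean(rs) == pytest.approx(0.5, abs=3 * se / np.sqrt(40))
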