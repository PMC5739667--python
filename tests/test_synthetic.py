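"""Synthetic cohort generator: covariance construction, sampling, truth records."""

import numpy as np
import pytest

from funconn.synthetic import (
    BehaviorTable,
    CohortSpec,
    block_covariance,
    default_modules,
    hub_enhanced_spec,
    hub_incident_edges,
    make_cohort,
    planted_component_spec,
    ring_lattice_weights,
    sample_panel,
)


class TestBlockCovariance:
    def test_independence_case_is_identity(self):
        spec = CohortSpec(n_rois=6, within_r=0.0, between_r=0.0,
                          modules=[[0, 1, 2], [3, 4, 5]])
        for group in ("patient", "control"):
            np.testing.assert_array_equal(
                block_covariance(spec, group), np.eye(6))

    def test_block_structure_by_construction(self):
        spec = CohortSpec(n_rois=4, modules=[[0, 1], [2, 3]],
                          within_r=0.6, between_r=0.1)
        cov = block_covariance(spec, "control")
        assert cov[0, 1] == pytest.approx(0.6)
        assert cov[0, 2] == pytest.approx(0.1)
        assert np.diag(cov) == pytest.approx(1.0)
        np.testing.assert_allclose(cov, cov.T)

    def test_dense_equicorrelated_blocks_stay_pd(self):
        # compound-symmetric blocks are PSD by construction; min eigenvalue
        # 1 - within_r stays above the repair threshold (eigen oracle)
        spec = CohortSpec(n_rois=40, modules=[list(range(30)), list(range(30, 40))],
                          within_r=0.99, between_r=0.98)
        cov = block_covariance(spec, "control")
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_pd_repair_engages_on_aggressive_delta(self):
        # identity base + a strong open path 0-1-2 violates PD
        # (eigen oracle: min eig of the 3x3 block is 1 - 0.9*sqrt(2) < 0)
        spec = CohortSpec(n_rois=5, modules=[list(range(5))],
                          within_r=0.0, between_r=0.0, group_delta=0.9,
                          planted_edges=((0, 1), (1, 2)))
        with pytest.warns(RuntimeWarning, match="not positive definite"):
            cov = block_covariance(spec, "patient")
        # repaired matrix is PD with unit diagonal
        assert np.linalg.eigvalsh(cov)[0] > 0
        assert np.diag(cov) == pytest.approx(1.0)

    def test_delta_out_of_range_raises(self):
        spec = CohortSpec(n_rois=4, modules=[[0, 1], [2, 3]], within_r=0.9,
                          between_r=0.1, group_delta=0.2,
                          planted_edges=((0, 1),))
        with pytest.raises(ValueError, match="outside"):
            block_covariance(spec, "patient")

    def test_patient_only_shift(self):
        spec = CohortSpec(n_rois=4, modules=[[0, 1], [2, 3]], within_r=0.3,
                          between_r=0.1, group_delta=0.2,
                          planted_edges=((0, 2),))
        assert block_covariance(spec, "patient")[0, 2] == pytest.approx(0.3)
        assert block_covariance(spec, "control")[0, 2] == pytest.approx(0.1)


class TestSamplePanel:
    def test_identity_cov_has_near_zero_correlations(self):
        # Fisher-z bound: SE ~ 1/sqrt(n-3) ~ 0.003 at n = 1e5
        panel = sample_panel(np.eye(4), 100_000, seed=1)
        r = np.corrcoef(panel.data, rowvar=False)
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_sample_correlation_converges_to_model(self):
        cov = np.eye(3)
        cov[0, 1] = cov[1, 0] = 0.6
        panel = sample_panel(cov, 100_000, seed=2)
        r = np.corrcoef(panel.data, rowvar=False)
        assert r[0, 1] == pytest.approx(0.6, abs=0.01)

    def test_seeded_determinism_is_bit_identical(self):
        cov = block_covariance(CohortSpec(n_rois=10, modules=[list(range(10))]),
                               "control")
        p1 = sample_panel(cov, 50, seed=42)
        p2 = sample_panel(cov, 50, seed=42)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sample_panel(np.eye(3), 2, seed=0)

    def test_ar1_panel_keeps_cross_correlation(self):
        cov = np.eye(2)
        cov[0, 1] = cov[1, 0] = 0.5
        panel = sample_panel(cov, 50_000, seed=3, ar1=0.4)
        r = np.corrcoef(panel.data, rowvar=False)
        assert r[0, 1] == pytest.approx(0.5, abs=0.03)


class TestMakeCohort:
    def test_default_cohort_sizes(self):
        cohort = make_cohort(CohortSpec(n_timepoints=10, seed=1))
        assert len(cohort.panels) == 68
        assert sum(p.group == "patient" for p in cohort.panels) == 28
        assert sum(p.group == "control" for p in cohort.panels) == 40

    def test_null_cohort_declared_in_truth(self, small_cohort):
        assert small_cohort.truth["null_cohort"] is True
        assert small_cohort.truth["planted_edges"] == []

    def test_planted_edges_recorded_exactly(self):
        spec = planted_component_spec(
            n_component_nodes=12, n_component_edges=40, delta=0.3,
            n_patients=3, n_controls=3, n_timepoints=10, seed=5)
        assert len(spec.planted_edges) == 40
        cohort = make_cohort(spec)
        assert cohort.truth["planted_edges"] == [list(e) for e in spec.planted_edges]
        assert cohort.truth["group_delta"] == 0.3

    def test_seed_determinism_of_whole_cohort(self):
        spec = CohortSpec(n_patients=2, n_controls=2, n_rois=8,
                          modules=[list(range(8))], n_timepoints=20, seed=9)
        c1, c2 = make_cohort(spec), make_cohort(spec)
        for p1, p2 in zip(c1.panels, c2.panels):
            np.testing.assert_array_equal(p1.data, p2.data)
        assert c1.behavior.table.equals(c2.behavior.table)

    def test_behavior_scores_directional_and_bounded(self, small_cohort):
        t = small_cohort.behavior.table
        pat = t[t["group"] == "patient"]
        con = t[t["group"] == "control"]
        assert pat["source_memory"].mean() < con["source_memory"].mean()
        assert pat["mmse"].mean() < con["mmse"].mean()
        assert t["source_memory"].between(0, 1).all()


class TestSpecValidation:
    def test_modules_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            CohortSpec(n_rois=4, modules=[[0, 1], [1, 2, 3]])

    def test_invalid_planted_edge(self):
        with pytest.raises(ValueError, match="planted edge"):
            CohortSpec(n_rois=4, modules=[[0, 1, 2, 3]], planted_edges=((0, 7),))

    def test_default_modules_partition(self):
        mods = default_modules(90)
        assert sorted(i for m in mods for i in m) == list(range(90))

    def test_accuracy_bounds_enforced(self):
        import pandas as pd
        bad = pd.DataFrame({"subject_id": ["a"], "group": ["patient"],
                            "source_memory": [1.4]})
        with pytest.raises(ValueError, match="accuracy"):
            BehaviorTable(bad)


class TestPresets:
    def test_hub_edges_cover_all_hub_pairs(self):
        edges = hub_incident_edges(10, [0, 5])
        assert len(edges) == 9 + 9 - 1  # hub-hub edge deduplicated
        assert all(0 in e or 5 in e for e in edges)

    def test_hub_spec_expected_directions(self):
        spec = hub_enhanced_spec(n_timepoints=10)
        dirs = spec.expected_directions
        assert dirs["global_efficiency_auc"] == "patient>control"
        assert dirs["normalized_local_efficiency_auc"] == "patient<control"

    def test_planted_component_is_connected(self):
        import networkx as nx
        spec = planted_component_spec(seed=11)
        g = nx.Graph(list(spec.planted_edges))
        assert nx.is_connected(g)
        assert g.number_of_edges() == 40

    def test_ring_lattice_weights_shape(self):
        w = ring_lattice_weights(30, n_shortcuts=5, seed=0)
        np.testing.assert_allclose(w, w.T)
        assert np.diag(w) == pytest.approx(0.0)
        assert w[0, 1] == pytest.approx(0.5)  # ring distance 1
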