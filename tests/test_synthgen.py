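import numpy as np
import pandas as pd
import pytest

from csvdnet import metrics, netbuild, synthgen
from csvdnet.errors import ConfigError, ParameterError
from csvdnet.synthgen import COGNITIVE_TESTS, GROUPS, SyntheticCohortConfig


class TestBaseTopology:
    def test_pure_lattice_closed_form(self, rng):
        adj = synthgen.generate_base_topology(90, 10, 0.0, rng)
        assert (adj.sum(axis=1) == 10).all()
        # ring lattice binary clustering: 3(k-2)/(4(k-1)) = 2/3 for k=10
        ncv, cp = metrics.clustering(adj)
        np.testing.assert_allclose(ncv.c, 2 / 3, atol=1e-12)

    def test_edge_count_conserved_by_rewiring(self, rng):
        adj = synthgen.generate_base_topology(90, 10, 0.1, rng)
        assert adj.sum() / 2 == 450  # n * k0 / 2

    def test_deterministic_for_fixed_seed(self):
        a = synthgen.generate_base_topology(90, 10, 0.1, np.random.default_rng(5))
        b = synthgen.generate_base_topology(90, 10, 0.1, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_odd_neighbor_count_rejected(self, rng):
        with pytest.raises(ParameterError):
            synthgen.generate_base_topology(90, 9, 0.1, rng)


class TestAssignWeights:
    def test_zero_edge_adjacency_gives_zero_matrix(self, rng):
        cm = synthgen.assign_weights(np.zeros((5, 5)), -4, 0.7, rng)
        assert not cm.weights.any()

    def test_support_matches_adjacency(self, rng):
        adj = synthgen.generate_base_topology(30, 4, 0.2, rng)
        cm = synthgen.assign_weights(adj, -4, 0.7, rng)
        np.testing.assert_array_equal(cm.weights > 0, adj > 0)

    def test_weights_clipped_to_unit_interval(self, rng):
        adj = synthgen.generate_base_topology(50, 8, 0.1, rng)
        cm = synthgen.assign_weights(adj, 0.5, 1.0, rng)  # fat distribution: clipping bites
        vals = cm.weights[cm.weights > 0]
        assert vals.min() > 0 and vals.max() <= 1.0


class TestGroupEffect:
    def test_control_group_is_identity(self, ws_weighted, rng):
        out, damage = synthgen.apply_group_effect(
            ws_weighted, "HC", SyntheticCohortConfig(), rng
        )
        assert damage == 0.0
        np.testing.assert_array_equal(out.weights, ws_weighted.weights)

    def test_full_attenuation_limit(self, ws_weighted, rng):
        cfg = SyntheticCohortConfig(
            attenuation={"CSVD-s": 1e-9, "CSVD-m": 0.9, "HC": 1.0},
            attenuated_fraction=1.0, severity_jitter=0.0,
        )
        out, damage = synthgen.apply_group_effect(ws_weighted, "CSVD-s", cfg, rng)
        assert out.weights.max() <= 1e-9
        assert damage == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_preserved_and_damage_matches_count(self, ws_weighted, rng):
        cfg = SyntheticCohortConfig(severity_jitter=0.0)
        out, damage = synthgen.apply_group_effect(ws_weighted, "CSVD-s", cfg, rng)
        np.testing.assert_array_equal(out.weights, out.weights.T)
        n_att = int((out.weights[np.triu_indices(90, 1)]
                     < ws_weighted.weights[np.triu_indices(90, 1)]).sum())
        assert damage == pytest.approx(n_att * 0.5 / 450)

    def test_invalid_delta_rejected(self, ws_weighted, rng):
        cfg = SyntheticCohortConfig()
        cfg.attenuation["CSVD-s"] = 0.0
        with pytest.raises(ParameterError):
            synthgen.apply_group_effect(ws_weighted, "CSVD-s", cfg, rng)

    def test_lower_delta_lowers_cohort_local_efficiency(self):
        """Paired subjects (same backbone, same damage sites): Eloc at sparsity
        0.15 must decrease strictly as the attenuation deepens."""
        means = []
        for delta in (1.0, 0.8, 0.4):
            cfg = SyntheticCohortConfig(
                attenuation={"CSVD-s": delta, "CSVD-m": 0.9, "HC": 1.0})
            vals = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                adj = synthgen.generate_base_topology(90, 10, 0.1, rng)
                cm = synthgen.assign_weights(adj, -4, 0.7, rng)
                dmg_rng = np.random.default_rng(1000 + seed)  # same sites per delta
                out, _ = synthgen.apply_group_effect(cm, "CSVD-s", cfg, dmg_rng) \
                    if delta < 1 else (cm, 0.0)
                with pytest.warns(Warning):
                    tn = netbuild.threshold_sweep(out, 0.15, 0.15, 0.01)[0]
                vals.append(metrics.local_efficiency(tn))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestCognition:
    def test_zero_noise_at_mean_damage_recovers_calibration_means(self):
        cfg = SyntheticCohortConfig(noise_share=0.0)
        rng = np.random.default_rng(0)
        scores = synthgen.generate_cognition(
            synthgen.expected_damage("CSVD-s", cfg), "CSVD-s", cfg, rng
        )
        assert scores["MoCA"] == pytest.approx(24.03, abs=1e-9)
        assert scores["SDMT"] == pytest.approx(26.39, abs=1e-9)
        assert scores["TMT_BA"] == pytest.approx(172.86, abs=1e-9)

    def test_pure_noise_mode_reproduces_calibration_sd(self):
        # noise_share = 1 removes the damage slope entirely
        cfg = SyntheticCohortConfig(noise_share=1.0)
        rng = np.random.default_rng(1)
        draws = np.array([
            synthgen.generate_cognition(0.2, "CSVD-m", cfg, rng)["MoCA"]
            for _ in range(1000)
        ])
        assert draws.std(ddof=1) == pytest.approx(3.58, rel=0.1)

    def test_deterministic_for_fixed_seed(self):
        cfg = SyntheticCohortConfig()
        a = synthgen.generate_cognition(0.1, "CSVD-s", cfg, np.random.default_rng(3))
        b = synthgen.generate_cognition(0.1, "CSVD-s", cfg, np.random.default_rng(3))
        assert a == b

    def test_unknown_test_name_rejected(self):
        cfg = SyntheticCohortConfig()
        cfg.cognition_calibration["CSVD-s"]["NotATest"] = (0, 1)
        with pytest.raises(ConfigError):
            synthgen.generate_cognition(0.1, "CSVD-s", cfg, np.random.default_rng(0))


class TestGenerateCohort:
    def test_default_cohort_has_published_group_sizes(self):
        cfg = SyntheticCohortConfig()
        assert sum(cfg.group_sizes.values()) == 67 + 133 + 89

    def test_small_cohort_structure_and_reproducibility(self):
        cfg = SyntheticCohortConfig(
            group_sizes={"CSVD-s": 3, "CSVD-m": 3, "HC": 3}, seed=9)
        mats_a, table_a = synthgen.generate_cohort(cfg)
        mats_b, table_b = synthgen.generate_cohort(cfg)
        assert len(mats_a) == 9
        assert list(table_a["group"].value_counts()[list(GROUPS)]) == [3, 3, 3]
        assert set(COGNITIVE_TESTS) <= set(table_a.columns)
        pd.testing.assert_frame_equal(table_a, table_b)
        for a, b in zip(mats_a, mats_b):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_matrices_satisfy_connectivity_invariants(self):
        cfg = SyntheticCohortConfig(group_sizes={"CSVD-s": 2, "CSVD-m": 2, "HC": 2})
        mats, _ = synthgen.generate_cohort(cfg)
        for m in mats:
            w = m.weights
            assert w.shape == (90, 90)
            np.testing.assert_array_equal(w, w.T)
            assert np.diagonal(w).max() == 0
            assert w.min() >= 0 and w.max() <= 1
            assert np.isfinite(w).all()

    def test_sex_proportions_track_calibration(self):
        cfg = SyntheticCohortConfig(
            group_sizes={"CSVD-s": 150, "CSVD-m": 2, "HC": 2}, seed=17)
        _, table = synthgen.generate_cohort(cfg)
        male = (table.loc[table["group"] == "CSVD-s", "sex"] == "M").mean()
        assert male == pytest.approx(43 / 67, abs=0.1)

    def test_too_small_groups_rejected(self):
        cfg = SyntheticCohortConfig(group_sizes={"CSVD-s": 1, "CSVD-m": 3, "HC": 3})
        with pytest.raises(ParameterError):
            synthgen.generate_cohort(cfg)
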