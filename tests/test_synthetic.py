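"""Generators: VAR sampling, connectome nulls, spatial fields, surrogates."""

import numpy as np
import pytest

from phidyn import synthetic as syn
from phidyn.io import RegionalMap, RegionalTimeseries
from phidyn.synthetic import (ConditionSpec, VarSystem, add_hub_node,
                              distance_weights, generate_var, morans_i,
                              msr_surrogate_maps, rewire_connectome,
                              spatial_map, synthetic_connectome,
                              synthetic_study, time_shuffle_surrogate,
                              two_node_ar)


class TestGenerateVar:
    def test_white_noise_has_no_lagged_structure(self):
        ts = generate_var(VarSystem(np.zeros((3, 3)), np.eye(3)), 5000, seed=0)
        v = ts.values
        lag_cov = (v[:-1].T @ v[1:]) / (len(v) - 1)
        assert np.max(np.abs(lag_cov)) < 3 / np.sqrt(5000)

    def test_stationary_cov_matches_lyapunov_solution(self):
        a = np.array([[0.0, 0.4], [0.4, 0.0]])
        system = VarSystem(a, np.eye(2))
        ts = generate_var(system, 20000, seed=1)
        emp = np.cov(ts.values, rowvar=False)
        exact = system.stationary_cov()
        assert np.max(np.abs(emp - exact) / np.abs(exact).max()) < 0.05

    def test_determinism(self):
        system = VarSystem(np.array([[0.2, 0.3], [0.3, 0.2]]), np.eye(2))
        t1 = generate_var(system, 200, seed=7)
        t2 = generate_var(system, 200, seed=7)
        assert np.array_equal(t1.values, t2.values)

    def test_nonstationary_rejected_with_radius(self):
        with pytest.raises(ValueError, match="spectral radius"):
            VarSystem(np.eye(2) * 1.2, np.eye(2))

    def test_two_node_parameter_range_enforced(self):
        with pytest.raises(ValueError):
            two_node_ar(1.5, 0.0, 100, 0)
        with pytest.raises(ValueError):
            two_node_ar(0.3, 1.5, 100, 0)


class TestConnectomes:
    def test_lattice_is_regular(self):
        # ring lattice at density 4/(n-1): every node degree 4
        conn = synthetic_connectome(10, 4 / 9, "lattice", seed=0)
        assert np.all(conn.degrees() == 4)

    @pytest.mark.parametrize("kind", ["lattice", "random", "degree-preserving"])
    def test_rewired_nulls_preserve_weight_multiset(self, kind,
                                                    small_connectome):
        null = rewire_connectome(small_connectome, kind, seed=3)
        iu = np.triu_indices(small_connectome.n, 1)
        w0 = np.sort(small_connectome.weights[iu])
        w1 = np.sort(null.weights[iu])
        assert np.allclose(w0, w1)
        assert null.density == small_connectome.density

    def test_degree_preserving_keeps_degree_sequence(self, small_connectome):
        null = rewire_connectome(small_connectome, "degree-preserving", seed=4)
        assert np.array_equal(null.degrees(), small_connectome.degrees())
        # but the topology must actually change
        assert not np.array_equal(null.weights, small_connectome.weights)

    def test_strength_preserving_keeps_degrees_and_strengths(
            self, small_connectome):
        null = rewire_connectome(small_connectome, "strength-preserving",
                                 seed=4)
        assert np.array_equal(null.degrees(), small_connectome.degrees())
        rel = np.abs(null.strengths() - small_connectome.strengths()) \
            / small_connectome.strengths()
        assert np.max(rel) < 1e-6

    def test_incompatible_density_rejected(self):
        with pytest.raises(ValueError):
            synthetic_connectome(10, 1e-4, "modular", seed=0)

    def test_hub_augmentation_makes_top_strength_node(self, small_connectome):
        aug = add_hub_node(small_connectome, weight_scale=2.0)
        assert aug.n == small_connectome.n + 1
        assert np.argmax(aug.strengths()) == small_connectome.n


class TestSpatialMaps:
    def test_determinism(self, coords40):
        m1 = spatial_map(coords40, 0.3, seed=5)
        m2 = spatial_map(coords40, 0.3, seed=5)
        assert np.array_equal(m1.values, m2.values)

    def test_correlation_length_orders_morans_i(self, coords40, spatial_w):
        # longer correlation length -> more spatial autocorrelation
        i_long = np.mean([morans_i(spatial_map(coords40, 0.5, seed=s).values,
                                   spatial_w) for s in range(20)])
        i_short = np.mean([morans_i(spatial_map(coords40, 0.01, seed=s).values,
                                    spatial_w) for s in range(20)])
        assert i_long > i_short + 0.1

    def test_tiny_corr_length_decorrelates(self, coords40):
        vals = np.array([spatial_map(coords40, 1e-4, seed=s).values[:2]
                         for s in range(200)])
        r = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        assert abs(r) < 0.2

    def test_degenerate_coords_rejected(self):
        with pytest.raises(ValueError):
            spatial_map(np.zeros((10, 3)), 0.3, seed=0)


class TestMSRSurrogates:
    def test_mean_preserved_exactly(self, smooth_map, spatial_w):
        for s in msr_surrogate_maps(smooth_map, spatial_w, 20, seed=0):
            assert s.values.mean() == pytest.approx(smooth_map.values.mean(),
                                                    abs=1e-9)

    def test_morans_i_band_and_bracketing(self, smooth_map, spatial_w):
        i_emp = morans_i(smooth_map.values, spatial_w)
        i_surr = [morans_i(s.values, spatial_w)
                  for s in msr_surrogate_maps(smooth_map, spatial_w, 100,
                                              seed=1)]
        assert abs(np.mean(i_surr) - i_emp) <= 0.1
        assert min(i_surr) <= i_emp <= max(i_surr)

    def test_surrogates_differ_from_input_and_each_other(self, smooth_map,
                                                         spatial_w):
        surr = msr_surrogate_maps(smooth_map, spatial_w, 3, seed=2)
        assert not np.allclose(surr[0].values, smooth_map.values)
        assert not np.allclose(surr[0].values, surr[1].values)

    def test_distribution_matched_surrogates_keep_value_multiset(
            self, smooth_map, spatial_w):
        for s in msr_surrogate_maps(smooth_map, spatial_w, 5, seed=3,
                                    match_distribution=True):
            assert np.array_equal(np.sort(s.values),
                                  np.sort(smooth_map.values))
            assert not np.array_equal(s.values, smooth_map.values)

    def test_constant_map_maps_to_itself(self, spatial_w):
        m = RegionalMap(np.full(40, 3.14))
        for s in msr_surrogate_maps(m, spatial_w, 5, seed=0):
            assert np.allclose(s.values, 3.14, atol=1e-9)

    def test_zero_surrogates_rejected(self, smooth_map, spatial_w):
        with pytest.raises(ValueError):
            msr_surrogate_maps(smooth_map, spatial_w, 0)


class TestTimeShuffle:
    def test_zero_lag_cov_and_marginals_preserved_exactly(self, rng):
        ts = RegionalTimeseries(rng.standard_normal((500, 4)))
        surr = time_shuffle_surrogate(ts, seed=9)
        # mathematically identical; summation order shifts the last bit
        assert np.allclose(np.cov(ts.values, rowvar=False),
                           np.cov(surr.values, rowvar=False), atol=1e-12)
        assert np.array_equal(np.sort(ts.values, axis=0),
                              np.sort(surr.values, axis=0))

    def test_destroys_autocorrelation(self):
        ts = generate_var(VarSystem(np.eye(2) * 0.9, np.eye(2)), 5000, seed=0)
        surr = time_shuffle_surrogate(ts, seed=1)

        def lag1(v):
            return np.corrcoef(v[:-1, 0], v[1:, 0])[0, 1]

        assert lag1(ts.values) > 0.8
        assert abs(lag1(surr.values)) < 0.1


class TestSyntheticStudy:
    def test_determinism_and_schema(self):
        s1 = synthetic_study(n_subjects=3, n_regions=10, seed=5, n_time=120)
        s2 = synthetic_study(n_subjects=3, n_regions=10, seed=5, n_time=120)
        for cond in s1.conditions:
            for a, b in zip(s1.subjects[cond], s2.subjects[cond]):
                assert np.array_equal(a.values, b.values)
            assert s1.arousal[cond] == s2.arousal[cond]
            assert all(0 <= a <= 11 for a in s1.arousal[cond])
        assert s1.truth_map.normalized

    def test_arousal_tracks_coupling_scale(self):
        study = synthetic_study(n_subjects=6, n_regions=10, seed=2,
                                n_time=120)
        awake = np.mean(study.arousal["awake"])
        anaes = np.mean(study.arousal["anaesthesia"])
        assert awake > anaes

    def test_roundtrip_through_manifest(self, tmp_path):
        study = synthetic_study(n_subjects=2, n_regions=8, seed=3, n_time=100)
        manifest = syn.save_study(study, tmp_path)
        loaded = syn.load_study(manifest)
        assert loaded.conditions == study.conditions
        for cond in study.conditions:
            for a, b in zip(study.subjects[cond], loaded.subjects[cond]):
                assert np.allclose(a.values, b.values, atol=1e-12)
        assert loaded.arousal == study.arousal

    def test_bad_condition_spec_rejected(self):
        with pytest.raises(ValueError):
            synthetic_study(n_subjects=3,
                            condition_spec=[ConditionSpec("only_one")])
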