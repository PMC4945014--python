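import numpy as np
import pandas as pd
import pytest
from scipy import stats

import treeforage as tf
from treeforage.synthetic import (
    ConfigurationError,
    SimulationConfig,
    di_covariance,
    gaussian_random_field,
    redraw_use_states,
)


class TestConfigValidation:
    def test_zero_area_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(extent_m=(0.0, 100.0)).validate()

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(tree_density=0.0).validate()

    def test_species_probs_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(species_probs=(0.5, 0.2, 0.2, 0.2)).validate()

    def test_short_routes_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(route_length=5).validate()

    def test_bad_strategy_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(strategy="XX").validate()


class TestLandscape:
    def test_poisson_count_at_reference_scale(self):
        # 100 ha at 100 trees/ha -> around 10,000 trees
        cfg = SimulationConfig(extent_m=(1000.0, 1000.0), tree_density=100.0, seed=1)
        trees = tf.generate_landscape(cfg, grf_method="grid")
        assert abs(len(trees) - 10_000) < 4 * np.sqrt(10_000)

    def test_degenerate_field_sd_zero(self):
        cfg = SimulationConfig(extent_m=(200.0, 200.0), di_field=(50.0, 0.4, 0.0), seed=2)
        trees = tf.generate_landscape(cfg)
        assert np.allclose(trees["di"], 0.4)

    def test_columns_and_invariants(self):
        cfg = SimulationConfig(extent_m=(200.0, 200.0), seed=3)
        trees = tf.generate_landscape(cfg)
        assert np.isfinite(trees[["x", "y", "di"]].to_numpy()).all()
        assert (trees["di"] > 0).all()
        assert (trees["dbh"] > 0).all() and (trees["height"] > 0).all()
        assert set(trees["species"]) <= {"NPUM", "NANT", "NBET", "OTHER"}

    def test_field_covariance_matches_oracle(self):
        # oracle: direct evaluation of the covariance function on 200 fixed
        # points, against the empirical covariance over replicate fields
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 200, size=(200, 2))
        corr_length, sd = 50.0, 0.15
        reps = np.array([
            gaussian_random_field(pts, (200.0, 200.0), corr_length, 0.0, sd,
                                  np.random.default_rng(1000 + k), method="exact")
            for k in range(400)
        ])
        emp_cov = (reps[:, :, None] * reps[:, None, :]).mean(axis=0)
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
        oracle = di_covariance(d, corr_length, sd)
        iu = np.triu_indices(200, k=1)
        assert np.abs(emp_cov[iu] - oracle[iu]).mean() < 0.002
        # the covariance has flattened to ~0 well beyond the correlation length
        far = d[iu] > 3 * corr_length
        assert np.abs(emp_cov[iu][far]).mean() < 0.002

    def test_grid_method_matches_marginal_moments(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 500, size=(4000, 2))
        z = gaussian_random_field(pts, (500.0, 500.0), 30.0, 0.5, 0.2, rng, method="grid")
        assert abs(z.std() - 0.2) < 0.05
        assert abs(z.mean() - 0.5) < 0.08


class TestRoutes:
    def test_uniform_selection_when_beta1_zero(self, cluster_trees):
        # no selectivity: selection frequencies uniform over candidates
        cfg = SimulationConfig(extent_m=(6.0, 6.0), true_beta0=0.0, true_beta1=0.0,
                               n_routes=50, route_length=101, memory=1,
                               perceptual_radius_m=20.0, min_route_length=6)
        routes, _ = tf.simulate_routes(cluster_trees, cfg, seed=9)
        # drop each route's start tree: it is drawn uniformly, not selected
        sel = routes[routes["step"] > 1]["tree_id"].to_numpy()
        counts = np.bincount(sel, minlength=21)
        stat, p = stats.chisquare(counts)
        assert len(sel) == 50 * 100
        assert p > 0.01

    def test_lf_selects_above_average_trees(self):
        cfg = SimulationConfig(extent_m=(400.0, 400.0), strategy="LF",
                               true_beta0=-2.0, true_beta1=2.0, di_nugget_sd=0.15,
                               n_routes=30, route_length=12, seed=21)
        trees = tf.generate_landscape(cfg)
        _, truth = tf.simulate_routes(trees, cfg, seed=22)
        sel = np.concatenate([v for v in truth["selected_dirs"].values()])
        assert sel.mean() > 1.01

    def test_route_invariants_hold(self):
        cfg = SimulationConfig(extent_m=(400.0, 400.0), n_routes=100, route_length=8,
                               seed=31)
        trees = tf.generate_landscape(cfg)
        routes, _ = tf.simulate_routes(trees, cfg, seed=32)
        assert (routes["departure_min"] >= routes["arrival_min"]).all()
        for route_id, grp in routes.groupby("route_id"):
            g = grp.sort_values("step")
            steps = g["step"].to_numpy()
            assert np.array_equal(steps, np.arange(1, len(steps) + 1))
            ids = g["tree_id"].to_numpy()
            assert (ids[1:] != ids[:-1]).all()
            assert not g["censored"].iloc[:-1].any()
            assert bool(g["censored"].iloc[-1])

    def test_fixed_seed_reproducibility(self):
        cfg = SimulationConfig(extent_m=(300.0, 300.0), n_routes=6, route_length=8,
                               seed=41)
        trees = tf.generate_landscape(cfg, rng=np.random.default_rng(41))
        r1, _ = tf.simulate_routes(trees, cfg, seed=42)
        r2, _ = tf.simulate_routes(trees, cfg, seed=42)
        assert r1.to_csv(index=False) == r2.to_csv(index=False)

    def test_empty_landscape_raises(self):
        cfg = SimulationConfig()
        with pytest.raises(ConfigurationError):
            tf.simulate_routes(pd.DataFrame(columns=["tree_id", "x", "y", "di"]), cfg)

    def test_truncation_discards_short_routes(self, cluster_trees):
        # a 3 m perceptual radius strands most foragers immediately
        cfg = SimulationConfig(extent_m=(6.0, 6.0), perceptual_radius_m=0.5,
                               n_routes=10, route_length=10)
        routes, truth = tf.simulate_routes(cluster_trees, cfg, seed=51)
        assert truth["n_routes_discarded"] + truth["n_routes_kept"] == 10
        if len(routes):
            assert routes.groupby("route_id")["step"].size().min() >= 6


class TestResidenceLaw:
    def test_exponential_survival_closed_form(self):
        # at DIR = 1 with only the DIR effect active the times are
        # exponential with rate = baseline * exp(-2.5); DKW band check
        rate = 0.2 * np.exp(-2.5)
        rec = tf.simulate_residence_records(
            2000, (-2.5, 0.0, 0.0, 0.0), baseline_rate=0.2, dir_sd=0.0, seed=61)
        t = np.sort(rec["T"].to_numpy())
        ecdf = np.arange(1, len(t) + 1) / len(t)
        oracle = 1.0 - np.exp(-rate * t)
        eps = np.sqrt(np.log(2 / 0.001) / (2 * len(t)))  # DKW at alpha=0.001
        assert np.max(np.abs(ecdf - oracle)) < eps

    def test_censoring_flags(self):
        rec = tf.simulate_residence_records(500, (0, 0, 0, 0), baseline_rate=0.5,
                                            censor_time=1.0, seed=62)
        assert ((rec["event"] == 0) == (rec["T"] == 1.0)).all()


class TestRedrawnStates:
    def test_rf_states_have_larger_route_ratio_than_lf(self, small_world):
        from scipy.stats import mannwhitneyu
        from treeforage.selection import build_observations

        obs = build_observations(small_world["dir_table"], small_world["routes"])
        means = {}
        for scale, col in (("LF", "dir_local"), ("RF", "dir_route")):
            redrawn = redraw_use_states(obs, beta0=-7.0, beta1=5.0, scale_col=col,
                                        seed=71)
            used = redrawn[redrawn["y"] != "U"]
            means[scale] = used["dir_route"].to_numpy()
        _, p = mannwhitneyu(means["RF"], means["LF"], alternative="greater")
        assert p < 0.05

    def test_redraw_is_seeded(self, small_world):
        from treeforage.selection import build_observations

        obs = build_observations(small_world["dir_table"], small_world["routes"])
        a = redraw_use_states(obs, -4.0, 2.0, "dir_local", seed=3)
        b = redraw_use_states(obs, -4.0, 2.0, "dir_local", seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSelectionObservationGenerator:
    def test_states_and_rates(self):
        obs = tf.simulate_selection_observations(20, 10, beta0=-2.0, beta1=0.0,
                                                 v=0.8, seed=81)
        assert set(obs["y"]) == {"U", "F", "O"}
        used = obs[obs["y"] != "U"]
        # use rate ~ expit(-2) = 0.119
        assert abs(len(used) / len(obs) - 0.119) < 0.03
        assert abs((used["y"] == "F").mean() - 0.8) < 0.05
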