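import numpy as np
import pandas as pd
import pytest

import treeforage as tf


@pytest.fixture(scope="session")
def small_world():
    """A small landscape with simulated routes, disks and DIR table."""
    cfg = tf.SimulationConfig(extent_m=(300.0, 300.0), n_routes=8, route_length=12,
                              di_nugget_sd=0.1, seed=11)
    trees = tf.generate_landscape(cfg)
    routes, truth = tf.simulate_routes(trees, cfg, seed=12)
    disks, avail, sigma2_m = tf.build_availability(trees, routes)
    dir_table = tf.build_dir_table(trees, routes, disks, max_lag=4)
    return {
        "config": cfg,
        "trees": trees,
        "routes": routes,
        "truth": truth,
        "disks": disks,
        "availability": avail,
        "sigma2_m": sigma2_m,
        "dir_table": dir_table,
    }


@pytest.fixture(scope="session")
def cluster_trees():
    """21 trees packed inside a 6 m box: every tree sees every other."""
    rng = np.random.default_rng(5)
    n = 21
    return pd.DataFrame(
        {
            "tree_id": np.arange(n),
            "x": rng.uniform(0, 6, n),
            "y": rng.uniform(0, 6, n),
            "di": rng.uniform(0.3, 0.7, n),
            "species": ["NPUM"] * n,
            "dbh": np.full(n, 40.0),
            "height": np.full(n, 15.0),
            "decay_stage": np.ones(n, dtype=int),
        }
    )
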