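"""Synthetic landscapes and simulated foragers.

Generates georeferenced tree landscapes (homogeneous Poisson pattern with a
spatially autocorrelated decay index) and simulates foraging routes under
three informational strategies:

* ``LF`` — locally informed: candidates judged against the mean quality of
  the current candidate set;
* ``DF`` — delayed informed: judged against the candidate set seen ``lag``
  steps earlier;
* ``RF`` — route informed: judged against all candidates encountered so far.

Residence times on used trees follow an exponential proportional-hazards
law so that the downstream survival model has a known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import expit

logger = logging.getLogger(__name__)

SPECIES = ("NPUM", "NANT", "NBET", "OTHER")
STRATEGIES = ("LF", "DF", "RF")

TREE_COLUMNS = ["tree_id", "x", "y", "di", "species", "dbh", "height", "decay_stage"]
ROUTE_COLUMNS = [
    "route_id",
    "woodpecker_id",
    "step",
    "tree_id",
    "arrival_min",
    "departure_min",
    "behavior",
    "family_size",
    "censored",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Knobs for landscape generation and forager simulation.

    ``di_field`` is ``(correlation length m, marginal mean, marginal SD)``;
    ``residence_betas`` are the log-hazard coefficients for
    ``(DIR, distance, DBH, height)``; ``species_hazard`` adds per-species
    log-hazard offsets relative to the first species level.
    """

    extent_m: tuple[float, float] = (500.0, 500.0)
    tree_density: float = 100.0  # trees per hectare
    di_field: tuple[float, float, float] = (50.0, 0.5, 0.15)
    di_nugget_sd: float = 0.0  # white-noise (tree-to-tree) DI component
    species_probs: tuple[float, float, float, float] = (0.5, 0.2, 0.2, 0.1)
    strategy: str = "LF"
    lag: int = 1
    # selection logits are beta0 + beta1*DIR; with DIR centred near 1 an
    # intercept near -beta1 keeps the logistic in its discriminative range
    true_beta0: float = -1.2
    true_beta1: float = 1.2
    perceptual_radius_m: float = 20.0
    v_true: float = 0.94
    n_routes: int = 10
    route_length: int = 15
    residence_betas: tuple[float, float, float, float] = (-1.0, -0.02, -0.03, -0.01)
    species_hazard: tuple[float, float, float, float] = (0.0, 0.8, 0.3, -0.4)
    baseline_rate: float = 2.0  # departure events per minute before covariates
    travel_speed_m_min: float = 60.0
    memory: int | None = None  # None: never revisit any tree of the route
    dbh_median_cm: float = 40.0
    dbh_sigma: float = 0.3
    height_median_m: float = 15.0
    height_sigma: float = 0.25
    decay_stage_slope: float = 8.0
    n_decay_stages: int = 5
    min_route_length: int = 6
    seed: int = 0

    def validate(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ConfigurationError(f"extent must be positive, got {self.extent_m}")
        if self.tree_density <= 0:
            raise ConfigurationError("tree_density must be strictly positive")
        if self.perceptual_radius_m <= 0:
            raise ConfigurationError("perceptual_radius_m must be strictly positive")
        if not math.isclose(sum(self.species_probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError("species_probs must sum to 1")
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"strategy must be one of {STRATEGIES}")
        if not 1 <= self.lag <= 4:
            raise ConfigurationError("lag must be in 1..4")
        if self.route_length < 6:
            raise ConfigurationError("route_length must be at least 6")
        if self.di_field[0] <= 0 or self.di_field[2] < 0:
            raise ConfigurationError("di_field needs positive length and non-negative SD")
        if not 0.0 <= self.v_true <= 1.0:
            raise ConfigurationError("v_true must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def di_covariance(distances: np.ndarray, corr_length: float, sd: float) -> np.ndarray:
    """Gaussian (squared-exponential) covariance of the decay-index field.

    ``C(d) = sd^2 * exp(-d^2 / (2 * corr_length^2))`` — the independent
    oracle used by the variogram tests.
    """
    d = np.asarray(distances, dtype=float)
    return sd**2 * np.exp(-(d**2) / (2.0 * corr_length**2))


def _grf_exact(points: np.ndarray, corr_length: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    cov = sd**2 * np.exp(-d2 / (2.0 * corr_length**2))
    cov[np.diag_indices(n)] += 1e-10 * max(sd**2, 1.0)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def _grf_grid(points: np.ndarray, extent: tuple[float, float], corr_length: float,
              sd: float, rng: np.random.Generator) -> np.ndarray:
    # white noise smoothed by a Gaussian kernel of sd l/sqrt(2) pixels gives
    # correlation exp(-d^2 / (2 l^2)); wrap mode keeps the kernel norm exact
    h = corr_length / 4.0
    nx = int(np.ceil(extent[0] / h)) + 1
    ny = int(np.ceil(extent[1] / h)) + 1
    s_pix = corr_length / (math.sqrt(2.0) * h)
    white = rng.standard_normal((ny, nx))
    smooth = ndimage.gaussian_filter(white, sigma=s_pix, mode="wrap")
    impulse = np.zeros((ny, nx))
    impulse[ny // 2, nx // 2] = 1.0
    norm = math.sqrt((ndimage.gaussian_filter(impulse, sigma=s_pix, mode="wrap") ** 2).sum())
    unit = smooth / norm
    ix = np.clip(points[:, 0] / h, 0, nx - 1)
    iy = np.clip(points[:, 1] / h, 0, ny - 1)
    return sd * ndimage.map_coordinates(unit, [iy, ix], order=1, mode="nearest")


def gaussian_random_field(points: np.ndarray, extent: tuple[float, float],
                          corr_length: float, mean: float, sd: float,
                          rng: np.random.Generator,
                          method: str = "auto") -> np.ndarray:
    """Sample a stationary Gaussian random field at ``points``.

    ``method='exact'`` uses a dense Cholesky factor (quadratic memory,
    reserved for small n); ``'grid'`` smooths white noise on a lattice and
    interpolates, which is what large landscapes get under ``'auto'``.
    """
    points = np.asarray(points, dtype=float)
    if sd == 0.0:
        return np.full(len(points), mean)
    if method == "auto":
        method = "exact" if len(points) <= 1200 else "grid"
    if method == "exact":
        z = _grf_exact(points, corr_length, sd, rng)
    elif method == "grid":
        z = _grf_grid(points, extent, corr_length, sd, rng)
    else:
        raise ValueError(f"unknown GRF method {method!r}")
    return mean + z


def generate_landscape(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       grf_method: str = "auto") -> pd.DataFrame:
    """Generate a homogeneous-Poisson tree landscape.

    Decay indices come from a Gaussian random field with the configured
    correlation length, floored at 0.01 so ratios stay defined; DBH and
    height are lognormal; an ordinal decay stage is derived from the decay
    index through a logistic latent variable.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w, h = config.extent_m
    area_ha = w * h / 1e4
    n = rng.poisson(config.tree_density * area_ha)
    xy = rng.uniform([0.0, 0.0], [w, h], size=(n, 2))
    corr_length, di_mean, di_sd = config.di_field
    di = gaussian_random_field(xy, config.extent_m, corr_length, di_mean, di_sd,
                               rng, method=grf_method)
    if config.di_nugget_sd > 0:
        di = di + config.di_nugget_sd * rng.standard_normal(n)
    di = np.maximum(di, 0.01)
    species = rng.choice(SPECIES, size=n, p=config.species_probs)
    dbh = np.exp(np.log(config.dbh_median_cm) + config.dbh_sigma * rng.standard_normal(n))
    height = np.exp(np.log(config.height_median_m) + config.height_sigma * rng.standard_normal(n))

    # ordinal decay stage: latent logistic score on the centred decay index,
    # cut at evenly spaced thresholds
    latent = config.decay_stage_slope * (di - di_mean) + rng.logistic(size=n)
    edges = np.quantile(latent, np.linspace(0, 1, config.n_decay_stages + 1)[1:-1])
    decay_stage = np.searchsorted(edges, latent) + 1

    return pd.DataFrame(
        {
            "tree_id": np.arange(n, dtype=int),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "di": di,
            "species": species,
            "dbh": dbh,
            "height": height,
            "decay_stage": decay_stage,
        }
    )


def _species_offsets(config: SimulationConfig) -> dict[str, float]:
    return dict(zip(SPECIES, config.species_hazard))


def _residence_rate(config: SimulationConfig, dir_value: float, distance: float,
                    dbh: float, height: float, species: str) -> float:
    b_dir, b_dis, b_dbh, b_ht = config.residence_betas
    lp = (b_dir * dir_value + b_dis * distance + b_dbh * dbh + b_ht * height
          + _species_offsets(config)[species])
    return config.baseline_rate * math.exp(lp)


def _simulate_one_route(trees: pd.DataFrame, tree_xy: np.ndarray, kdtree: cKDTree,
                        config: SimulationConfig, rng: np.random.Generator,
                        route_id: int, woodpecker_id: int,
                        family_size: int) -> tuple[list[dict], list[float], list[float]]:
    di = trees["di"].to_numpy()
    n_trees = len(trees)
    current = int(rng.integers(n_trees))
    visited: list[int] = [current]
    cand_history: list[np.ndarray] = []  # candidate index sets per step
    seen: set[int] = set()
    rows: list[dict] = []
    dirs_selected: list[float] = []
    # route-informed quality ratio of each selected tree (DI over the mean
    # DI of all candidates encountered so far), recorded for any strategy
    dir_seen_selected: list[float] = []

    t_now = 0.0
    for step in range(1, config.route_length + 1):
        # residence on the current tree
        tr = trees.iloc[current]
        if step == 1:
            dist_in = 0.0
            dir_val = 1.0
        else:
            dist_in = float(np.linalg.norm(tree_xy[current] - tree_xy[visited[-2]]))
            dir_val = dirs_selected[-1]
        rate = _residence_rate(config, dir_val, dist_in, tr["dbh"], tr["height"], tr["species"])
        residence = rng.exponential(1.0 / rate)
        behavior = "F" if rng.random() < config.v_true else "O"
        rows.append(
            {
                "route_id": route_id,
                "woodpecker_id": woodpecker_id,
                "step": step,
                "tree_id": int(tr["tree_id"]),
                "arrival_min": t_now,
                "departure_min": t_now + residence,
                "behavior": behavior,
                "family_size": family_size,
                "censored": False,
            }
        )
        t_now += residence
        if step == config.route_length:
            break

        # enumerate candidates within the perceptual radius
        cand = np.array(kdtree.query_ball_point(tree_xy[current], config.perceptual_radius_m),
                        dtype=int)
        if config.memory is None:
            blocked = set(visited)
        else:
            blocked = set(visited[-config.memory:])
        cand_history.append(cand)
        seen.update(int(c) for c in cand)
        cand = np.array([c for c in cand if c not in blocked], dtype=int)
        if cand.size == 0:
            logger.warning("route %d truncated at step %d: no candidate in radius",
                           route_id, step)
            break

        # strategy-specific reference set for the quality ratio
        if config.strategy == "LF":
            ref = di[cand_history[-1]].mean()
        elif config.strategy == "DF":
            ref_step = max(0, len(cand_history) - 1 - config.lag)
            ref = di[cand_history[ref_step]].mean()
        else:  # RF
            ref = float(np.mean([di[j] for j in seen]))
        # sequential screening: inspect candidates in random order, accept
        # each with its selection probability; settle on a uniform pick if
        # every candidate is rejected
        dir_cand = di[cand] / ref
        w = expit(config.true_beta0 + config.true_beta1 * dir_cand)
        pick = -1
        for j in rng.permutation(len(cand)):
            if rng.random() < w[j]:
                pick = int(j)
                break
        if pick < 0:
            pick = int(rng.integers(len(cand)))
        current = int(cand[pick])
        visited.append(current)
        dirs_selected.append(float(dir_cand[pick]))
        seen_mean = float(np.mean([di[j] for j in seen]))
        dir_seen_selected.append(float(di[current] / seen_mean))

        travel = float(np.linalg.norm(tree_xy[current] - tree_xy[visited[-2]]))
        t_now += travel / config.travel_speed_m_min

    if rows:
        rows[-1]["censored"] = True
    return rows, dirs_selected, dir_seen_selected


def simulate_routes(trees: pd.DataFrame, config: SimulationConfig,
                    seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate foraging routes over a landscape.

    Returns the route table plus a ground-truth record (strategy, selection
    and residence coefficients, per-route selected quality ratios). Routes
    truncated below ``min_route_length`` are discarded and counted in the
    ground truth.
    """
    config.validate()
    if trees.empty:
        raise ConfigurationError("landscape is empty")
    if seed is None:
        seed = config.seed
    streams = np.random.SeedSequence(seed).spawn(config.n_routes)
    tree_xy = trees[["x", "y"]].to_numpy()
    kdtree = cKDTree(tree_xy)

    all_rows: list[dict] = []
    selected_dirs: dict[int, list[float]] = {}
    selected_dir_seen: dict[int, list[float]] = {}
    discarded = 0
    master = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_woodpeckers = max(1, config.n_routes // 3)
    wp_ids = master.integers(0, n_woodpeckers, size=config.n_routes)
    family_sizes = master.integers(3, 6, size=config.n_routes)

    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        rows, dirs, dirs_seen = _simulate_one_route(
            trees, tree_xy, kdtree, config, rng, route_id=r,
            woodpecker_id=int(wp_ids[r]), family_size=int(family_sizes[r]))
        if len(rows) < config.min_route_length:
            discarded += 1
            logger.info("route %d discarded: %d < %d steps", r, len(rows),
                        config.min_route_length)
            continue
        all_rows.extend(rows)
        selected_dirs[r] = dirs
        selected_dir_seen[r] = dirs_seen

    routes = pd.DataFrame(all_rows, columns=ROUTE_COLUMNS)
    truth = {
        "strategy": config.strategy,
        "lag": config.lag,
        "true_beta0": config.true_beta0,
        "true_beta1": config.true_beta1,
        "v_true": config.v_true,
        "residence_betas": list(config.residence_betas),
        "species_hazard": list(config.species_hazard),
        "baseline_rate": config.baseline_rate,
        "n_routes_kept": int(routes["route_id"].nunique()) if len(routes) else 0,
        "n_routes_discarded": discarded,
        "selected_dirs": {str(k): v for k, v in selected_dirs.items()},
        "selected_dir_seen": {str(k): v for k, v in selected_dir_seen.items()},
    }
    return routes, truth


# ---------------------------------------------------------------------------
# direct generators for parameter-recovery oracles


def simulate_selection_observations(
    n_routes: int,
    n_periods: int,
    beta0: float,
    beta1: float,
    *,
    v: float = 0.9,
    gamma_sd: float = 0.0,
    n_woodpeckers: int = 5,
    mean_avail: float = 10.0,
    dir_sd: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw tree-use observations directly from the three-state model.

    Every available tree gets an independent Bernoulli selection with
    probability ``expit(beta0 + beta1*dir + gamma)``; selected trees are
    foraging trees with probability ``v``. This is the model's own
    generative process, used to check posterior recovery of ``beta1``.
    """
    rng = np.random.default_rng(seed)
    gammas = gamma_sd * rng.standard_normal(n_woodpeckers)
    rows = []
    tree_counter = 0
    for r in range(n_routes):
        wp = int(rng.integers(n_woodpeckers))
        fam = int(rng.integers(3, 6))
        for t in range(1, n_periods + 1):
            n_avail = max(2, rng.poisson(mean_avail))
            dir_vals = np.maximum(1.0 + dir_sd * rng.standard_normal(n_avail), 0.05)
            w = expit(beta0 + beta1 * dir_vals + gammas[wp])
            used = rng.random(n_avail) < w
            forag = rng.random(n_avail) < v
            for j in range(n_avail):
                if used[j]:
                    y = "F" if forag[j] else "O"
                else:
                    y = "U"
                rows.append(
                    {
                        "route_id": r,
                        "period": t,
                        "tree_id": tree_counter,
                        "y": y,
                        "a": 1,
                        "f_prev": 0,
                        "dir": dir_vals[j],
                        "woodpecker_id": wp,
                        "family_size": fam,
                        "route_length": n_periods,
                    }
                )
                tree_counter += 1
    return pd.DataFrame(rows)


def simulate_brownian_triplets(n: int, sigma2_m: float, *, t_total: float = 10.0,
                               alpha: float = 0.5, delta: float = 0.0,
                               seed: int = 0) -> pd.DataFrame:
    """Triplets whose intermediate point follows the conditioned-bridge law.

    Endpoints are diffused over ``t_total`` minutes at rate ``sigma2_m``;
    the middle point is normal around the interpolated location with the
    bridge variance plus location error. Used to test rate recovery.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0, 1000, (n, 2))
    p2 = p0 + rng.standard_normal((n, 2)) * math.sqrt(t_total * sigma2_m)
    mu = (1 - alpha) * p0 + alpha * p2
    var = (t_total * alpha * (1 - alpha) * sigma2_m
           + ((1 - alpha) ** 2 + alpha**2) * delta**2)
    p1 = mu + rng.standard_normal((n, 2)) * math.sqrt(var)
    return pd.DataFrame(
        {"x0": p0[:, 0], "y0": p0[:, 1], "x1": p1[:, 0], "y1": p1[:, 1],
         "x2": p2[:, 0], "y2": p2[:, 1],
         "elapsed_min": t_total, "alpha": alpha}
    )


def redraw_use_states(observations: pd.DataFrame, beta0: float, beta1: float,
                      scale_col: str, v: float = 0.9, seed: int = 0) -> pd.DataFrame:
    """Replace observed use-states with draws from the three-state model.

    Each available tree independently becomes used with probability
    ``expit(beta0 + beta1 * dir)`` where ``dir`` is taken from
    ``scale_col`` — the covariate that defines the strategy being emulated
    (local disk for LF, route level for RF). Used trees are foraging trees
    with probability ``v``. Movement geometry, disks and covariates are
    kept; only the states are regenerated, which makes the strategy
    identifiable by construction.
    """
    rng = np.random.default_rng(seed)
    obs = observations.copy()
    w = expit(beta0 + beta1 * obs[scale_col].to_numpy(dtype=float))
    used = rng.random(len(obs)) < w
    forag = rng.random(len(obs)) < v
    obs["f_prev"] = 0
    obs["y"] = np.where(used, np.where(forag, "F", "O"), "U")
    obs["used"] = used.astype(int)
    return obs


def simulate_residence_records(
    n: int,
    betas: Sequence[float],
    *,
    baseline_rate: float = 0.2,
    species_hazard: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
    rho: float = 0.0,
    censor_time: float | None = None,
    dir_sd: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw residence records from an exponential proportional-hazards law.

    ``betas`` multiply ``(dir, dis, dbh, ht)``. ``T ~ Exp(rate)`` with
    ``rate = baseline_rate * exp(linear predictor)``; optional type-I
    censoring at ``censor_time``.
    """
    rng = np.random.default_rng(seed)
    b = np.asarray(betas, dtype=float)
    dir_vals = np.maximum(1.0 + dir_sd * rng.standard_normal(n), 0.05)
    dis = rng.exponential(25.0, size=n)
    dbh = np.exp(np.log(40.0) + 0.3 * rng.standard_normal(n))
    ht = np.exp(np.log(15.0) + 0.25 * rng.standard_normal(n))
    sp_idx = rng.integers(0, len(SPECIES), size=n)
    fam = rng.integers(3, 6, size=n)
    lp = (b[0] * dir_vals + b[1] * dis + b[2] * dbh + b[3] * ht
          + np.asarray(species_hazard)[sp_idx] + rho * fam)
    rate = baseline_rate * np.exp(lp)
    t = rng.exponential(1.0 / rate)
    event = np.ones(n, dtype=int)
    if censor_time is not None:
        event = (t <= censor_time).astype(int)
        t = np.minimum(t, censor_time)
    return pd.DataFrame(
        {
            "route_id": np.zeros(n, dtype=int),
            "tree_id": np.arange(n),
            "T": t,
            "event": event,
            "dir": dir_vals,
            "dis": dis,
            "dbh": dbh,
            "ht": ht,
            "species": np.asarray(SPECIES)[sp_idx],
            "family_size": fam,
        }
    )
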