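"""Movement-bridge availability disks.

For each triplet of sequentially used trees the intermediate location is
modelled as a conditioned Brownian bridge: a circular (isotropic bivariate)
normal centred on the linear interpolation of the two endpoint trees with
per-axis variance

    sigma2_t = T * alpha * (1 - alpha) * sigma2_m + ((1-alpha)^2 + alpha^2) * delta^2

where ``T`` is the total elapsed time, ``alpha`` the elapsed-time fraction
at the intermediate stop, ``sigma2_m`` the Brownian motion rate and
``delta`` the location-error SD.  Trees inside the 90% isopleth of that
circular normal — a disk of radius ``sigma * sqrt(2 ln 10)`` — are the
available trees for the period.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)

AVAILABILITY_COLUMNS = [
    "route_id", "period", "center_x", "center_y", "sigma2_t", "r90", "tree_id", "a",
]


@dataclass
class BBMMParams:
    sigma2_m: float  # m^2 per minute
    delta: float = 3.0  # location error SD, metres
    alpha_mode: str = "timestamps"  # or "midpoint"

    def __post_init__(self) -> None:
        if self.sigma2_m < 0:
            raise ValueError("sigma2_m must be non-negative")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.alpha_mode not in ("timestamps", "midpoint"):
            raise ValueError("alpha_mode must be 'timestamps' or 'midpoint'")


@dataclass
class AvailabilityDisk:
    """The 90%-isopleth availability disk for one foraging period."""

    route_id: int
    period: int
    center: tuple[float, float]
    sigma2_t: float
    r90: float
    available_tree_ids: frozenset = field(default_factory=frozenset)

    def a(self, tree_id: int) -> int:
        return 1 if tree_id in self.available_tree_ids else 0


def interpolate_expected_location(tr_t, tr_t2, alpha: float) -> np.ndarray:
    """Linear interpolation between the two endpoint trees."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    tr_t = np.asarray(tr_t, dtype=float)
    tr_t2 = np.asarray(tr_t2, dtype=float)
    return (1.0 - alpha) * tr_t + alpha * tr_t2


def bridge_variance(params: BBMMParams, elapsed_total: float, alpha) -> float | np.ndarray:
    """Per-axis variance of the bridge at elapsed fraction ``alpha``."""
    if elapsed_total <= 0:
        raise ValueError("elapsed_total must be positive")
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("alpha must lie in [0, 1]")
    out = (elapsed_total * alpha * (1.0 - alpha) * params.sigma2_m
           + ((1.0 - alpha) ** 2 + alpha**2) * params.delta**2)
    return float(out) if out.ndim == 0 else out


def r90_radius(sigma2_t: float) -> float:
    """Radius containing 90% of an isotropic bivariate normal's mass.

    The radial distance is Rayleigh(sigma), whose q-quantile is
    ``sigma * sqrt(-2 ln(1-q))``; at q = 0.9 that is ``sigma*sqrt(2 ln 10)``.
    """
    if sigma2_t < 0:
        raise ValueError("sigma2_t must be non-negative")
    return math.sqrt(2.0 * sigma2_t * _LN10)


def extract_triplets(routes: pd.DataFrame, trees: pd.DataFrame,
                     alpha_mode: str = "timestamps") -> pd.DataFrame:
    """One row per sequential triplet: endpoints, observed midpoint, T, alpha.

    The bridge for period ``t`` spans departure from the tree at ``t-1`` to
    arrival at the tree at ``t+1``; ``alpha`` is the elapsed-time fraction
    at arrival on the intermediate tree (0.5 under ``midpoint`` mode or
    degenerate timestamps).
    """
    xy = trees.set_index("tree_id")[["x", "y"]]
    rows = []
    for route_id, grp in routes.sort_values("step").groupby("route_id"):
        steps = grp.reset_index(drop=True)
        for i in range(1, len(steps) - 1):
            prev_s, cur_s, next_s = steps.iloc[i - 1], steps.iloc[i], steps.iloc[i + 1]
            p0 = xy.loc[prev_s["tree_id"]].to_numpy(dtype=float)
            p1 = xy.loc[cur_s["tree_id"]].to_numpy(dtype=float)
            p2 = xy.loc[next_s["tree_id"]].to_numpy(dtype=float)
            elapsed = float(next_s["arrival_min"] - prev_s["departure_min"])
            if alpha_mode == "timestamps" and elapsed > 0:
                alpha = float(cur_s["arrival_min"] - prev_s["departure_min"]) / elapsed
                alpha = min(max(alpha, 0.0), 1.0)
            else:
                alpha = 0.5
            if elapsed <= 0:
                elapsed = 1.0
            rows.append(
                {
                    "route_id": route_id,
                    "period": int(cur_s["step"]),
                    "x0": p0[0], "y0": p0[1],
                    "x1": p1[0], "y1": p1[1],
                    "x2": p2[0], "y2": p2[1],
                    "elapsed_min": elapsed,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)


def estimate_sigma2m(triplets: pd.DataFrame, delta: float = 3.0,
                     upper: float | None = None) -> float:
    """Maximum-likelihood Brownian rate pooled over all triplets.

    Maximizes the product over triplets of the bivariate-normal density of
    the observed intermediate tree given the interpolated mean and the
    bridge variance. One-dimensional bounded optimization.
    """
    if len(triplets) < 3:
        raise ValueError("need at least 3 triplets to estimate sigma2_m")
    mu_x = (1 - triplets["alpha"]) * triplets["x0"] + triplets["alpha"] * triplets["x2"]
    mu_y = (1 - triplets["alpha"]) * triplets["y0"] + triplets["alpha"] * triplets["y2"]
    d2 = ((triplets["x1"] - mu_x) ** 2 + (triplets["y1"] - mu_y) ** 2).to_numpy()
    t_a = (triplets["elapsed_min"] * triplets["alpha"] * (1 - triplets["alpha"])).to_numpy()
    err = (((1 - triplets["alpha"]) ** 2 + triplets["alpha"] ** 2) * delta**2).to_numpy()

    if np.allclose(d2, 0.0):
        logger.warning("all triplets have zero bridge dispersion; sigma2_m = 0")
        return 0.0

    def nll(s2m: float) -> float:
        var = t_a * s2m + err
        var = np.maximum(var, 1e-12)
        return float(np.sum(np.log(var) + d2 / (2.0 * var)))

    if upper is None:
        with np.errstate(divide="ignore"):
            upper = 10.0 * float(np.max(d2 / np.maximum(t_a, 1e-9))) + 1.0
    res = minimize_scalar(nll, bounds=(0.0, upper), method="bounded",
                          options={"xatol": 1e-8 * upper})
    return float(res.x)


def availability_disk(route_id: int, period: int, center: np.ndarray,
                      sigma2_t: float, trees: pd.DataFrame,
                      kdtree: cKDTree | None = None) -> AvailabilityDisk:
    """Build the closed 90%-isopleth disk and collect member trees."""
    r90 = r90_radius(sigma2_t)
    if kdtree is None:
        kdtree = cKDTree(trees[["x", "y"]].to_numpy())
    idx = kdtree.query_ball_point(np.asarray(center, dtype=float), r90)
    ids = frozenset(int(t) for t in trees["tree_id"].to_numpy()[idx])
    if not ids:
        logger.info("empty availability disk: route %s period %s", route_id, period)
    return AvailabilityDisk(route_id=route_id, period=period,
                            center=(float(center[0]), float(center[1])),
                            sigma2_t=float(sigma2_t), r90=float(r90),
                            available_tree_ids=ids)


def build_availability(trees: pd.DataFrame, routes: pd.DataFrame,
                       delta: float = 3.0, sigma2_m: float | None = None,
                       alpha_mode: str = "timestamps",
                       ) -> tuple[list[AvailabilityDisk], pd.DataFrame, float]:
    """Availability disks for every interior period of every route.

    When ``sigma2_m`` is None it is estimated by pooled maximum likelihood
    across all triplets. Returns the disks, a long-format table (one row
    per available tree) and the Brownian rate used.
    """
    triplets = extract_triplets(routes, trees, alpha_mode=alpha_mode)
    if triplets.empty:
        return [], pd.DataFrame(columns=AVAILABILITY_COLUMNS), float(sigma2_m or 0.0)
    if sigma2_m is None:
        sigma2_m = estimate_sigma2m(triplets, delta=delta)
    params = BBMMParams(sigma2_m=sigma2_m, delta=delta, alpha_mode=alpha_mode)
    kdtree = cKDTree(trees[["x", "y"]].to_numpy())

    disks: list[AvailabilityDisk] = []
    rows = []
    for rec in triplets.itertuples():
        center = interpolate_expected_location((rec.x0, rec.y0), (rec.x2, rec.y2), rec.alpha)
        s2t = bridge_variance(params, rec.elapsed_min, rec.alpha)
        disk = availability_disk(rec.route_id, rec.period, center, s2t, trees, kdtree)
        disks.append(disk)
        for tid in sorted(disk.available_tree_ids):
            rows.append(
                {
                    "route_id": rec.route_id,
                    "period": rec.period,
                    "center_x": disk.center[0],
                    "center_y": disk.center[1],
                    "sigma2_t": disk.sigma2_t,
                    "r90": disk.r90,
                    "tree_id": tid,
                    "a": 1,
                }
            )
    table = pd.DataFrame(rows, columns=AVAILABILITY_COLUMNS)
    return disks, table, float(sigma2_m)
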