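"""Decay-index ratios at several spatio-temporal scales.

A tree's Decay Index Ratio (DIR) is its decay index divided by the mean
decay index of a reference set of available trees: the current period's
disk (local, lag 0), the union of the disks at the previous ``lag``
periods, or the union of all the route's disks (route level). DIR >= 1
marks a tree whose quality is at or above expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from treeforage.bbmm import AvailabilityDisk

logger = logging.getLogger(__name__)


class UndefinedAvailabilityError(ValueError):
    """An expected decay index was requested over an empty reference set."""


def expected_di(di_values: Iterable[float]) -> float:
    """Arithmetic mean decay index of a reference set."""
    arr = np.asarray(list(di_values), dtype=float)
    if arr.size == 0:
        raise UndefinedAvailabilityError("empty reference set")
    return float(arr.mean())


def compute_dir(di_i: float, reference_di: Iterable[float]) -> float:
    """Ratio of a tree's decay index to the reference-set mean."""
    ref = expected_di(reference_di)
    if ref == 0.0:
        raise ZeroDivisionError("reference mean decay index is zero")
    return di_i / ref


def _reference_ids(disks_by_period: Mapping[int, AvailabilityDisk], period: int,
                   lag: int, pooling: str) -> set[int] | None:
    """Distinct tree ids in the lag-``lag`` reference set, or None if the
    history is too short."""
    wanted = range(period - lag, period) if pooling == "union" else [period - lag]
    ids: set[int] = set()
    for p in wanted:
        if p not in disks_by_period:
            return None
        ids |= set(disks_by_period[p].available_tree_ids)
    return ids


def build_dir_table(trees: pd.DataFrame, routes: pd.DataFrame,
                    disks: Sequence[AvailabilityDisk], max_lag: int = 4,
                    lag_pooling: str = "union") -> pd.DataFrame:
    """Per-(route, period, available tree) DIR values at every scale.

    ``lag_pooling='union'`` pools the disks at periods ``t-1 .. t-lag``
    (each distinct tree once); ``'single'`` uses only the disk at ``t-lag``.
    Lags without enough preceding disks yield NaN. Standardized residuals of
    each lagged DIR on the route-level DIR are appended per route
    (``resid_lag0..max_lag``).
    """
    if lag_pooling not in ("union", "single"):
        raise ValueError("lag_pooling must be 'union' or 'single'")
    di_of = trees.set_index("tree_id")["di"]
    used_at = {(r.route_id, int(r.step)): int(r.tree_id) for r in routes.itertuples()}
    behavior_at = {(r.route_id, int(r.step)): r.behavior for r in routes.itertuples()}

    by_route: dict[int, dict[int, AvailabilityDisk]] = {}
    for d in disks:
        by_route.setdefault(d.route_id, {})[d.period] = d

    rows = []
    for route_id, by_period in by_route.items():
        route_ids_all: set[int] = set()
        for d in by_period.values():
            route_ids_all |= set(d.available_tree_ids)
        if not route_ids_all:
            continue
        route_mean = float(di_of.loc[sorted(route_ids_all)].mean())
        for period in sorted(by_period):
            disk = by_period[period]
            if not disk.available_tree_ids:
                continue
            members = sorted(disk.available_tree_ids)
            local_mean = float(di_of.loc[members].mean())
            lag_means: dict[int, float] = {}
            for lag in range(1, max_lag + 1):
                ids = _reference_ids(by_period, period, lag, lag_pooling)
                if ids:
                    lag_means[lag] = float(di_of.loc[sorted(ids)].mean())
            for tid in members:
                di = float(di_of.loc[tid])
                row = {
                    "route_id": route_id,
                    "period": period,
                    "tree_id": tid,
                    "used": int(used_at.get((route_id, period)) == tid),
                    "behavior": behavior_at.get((route_id, period), "")
                    if used_at.get((route_id, period)) == tid else "",
                    "dir_local": di / local_mean,
                    "dir_route": di / route_mean,
                }
                for lag in range(1, max_lag + 1):
                    row[f"dir_lag{lag}"] = di / lag_means[lag] if lag in lag_means else np.nan
                rows.append(row)

    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.sort_values(["route_id", "period", "tree_id"]).reset_index(drop=True)

    # standardized residuals of each lagged DIR on the route-level DIR
    lag_cols = {0: "dir_local", **{k: f"dir_lag{k}" for k in range(1, max_lag + 1)}}
    for lag, col in lag_cols.items():
        resid = np.full(len(table), np.nan)
        ok = table[col].notna().to_numpy()
        if ok.sum() >= 3:
            resid[ok] = residualize_dir(table.loc[ok, col].to_numpy(),
                                        table.loc[ok, "dir_route"].to_numpy())
        table[f"resid_lag{lag}"] = resid
    return table


def residualize_dir(dir_lag_values: np.ndarray, dir_route_values: np.ndarray) -> np.ndarray:
    """Standardized OLS residuals of lagged DIR on route-level DIR.

    Returns residuals scaled to unit sample SD (mean 0 by construction).
    A constant regressor degrades to centring; an exact fit returns zeros.
    """
    y = np.asarray(dir_lag_values, dtype=float)
    x = np.asarray(dir_route_values, dtype=float)
    if y.shape != x.shape:
        raise ValueError("paired inputs must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 points to residualize")
    if np.ptp(x) == 0.0:
        logger.warning("constant route-level DIR: slope undefined, centring only")
        resid = y - y.mean()
    else:
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        return np.zeros_like(resid)  # exact fit up to rounding
    return resid / sd


@dataclass
class OrdinalFit:
    """Proportional-odds fit of an ordinal response on one predictor."""

    slope: float
    slope_se: float
    thresholds: np.ndarray  # K-1 ordered cutpoints
    zstat: float
    loglike: float


def fit_ordinal_psri(decay_stage: Sequence[int], psri: Sequence[float]) -> OrdinalFit:
    """Cumulative-logit model ``logit P(Y <= k) = theta_k - b * PSRI``.

    Fit by maximum likelihood via statsmodels' ordered model; a positive
    slope means higher senescence-index values shift trees into later decay
    stages.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = pd.Series(decay_stage).astype("category")
    if y.cat.categories.size < 2:
        raise ValueError("need at least 2 observed decay-stage categories")
    x = pd.DataFrame({"psri": np.asarray(psri, dtype=float)})
    model = OrderedModel(y, x, distr="logit")
    try:
        res = model.fit(method="bfgs", disp=False)
    except Exception:  # separation or ill-conditioning
        logger.warning("BFGS failed for ordinal fit; falling back to nm")
        res = model.fit(method="nm", disp=False, maxiter=5000)
    slope = float(res.params.iloc[0])
    se = float(res.bse.iloc[0])
    thresholds = model.transform_threshold_params(res.params.to_numpy())[1:-1]
    return OrdinalFit(slope=slope, slope_se=se, thresholds=np.asarray(thresholds),
                      zstat=slope / se if se > 0 else np.inf,
                      loglike=float(res.llf))
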