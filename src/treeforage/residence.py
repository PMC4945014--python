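"""Bayesian proportional-hazards model for tree residence time.

Counting-process construction: event times are grouped into intervals
(Breslow-style for ties), the baseline hazard receives an independent-
increments gamma prior ``dH_k ~ Gamma(c * lambda* * delta_k, c)`` centred
on the exponential guess ``H*(t) = lambda* t`` with confidence ``c``, and
each record contributes Poisson terms ``dH_k * exp(x'beta)`` while at risk.
Baseline increments then have exact conjugate Gibbs updates; regression
coefficients move by adaptive random-walk Metropolis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from treeforage.mcmc import AdaptiveScale, compute_dic, dic_weights, rank_models, summarize_draws

logger = logging.getLogger(__name__)

SPECIES_BASELINE = "NPUM"
SPECIES_LEVELS = ("NANT", "NBET", "OTHER")
ALL_SPECIES = (SPECIES_BASELINE,) + SPECIES_LEVELS


def cox_linear_predictor(record, betas, species_effects=None, rho: float = 0.0):
    """Log relative hazard for one record.

    ``record`` maps covariate names (``dir``, ``dis``, ``dbh``, ``ht``,
    ``species``, ``family_size``) to values; ``betas`` maps the numeric
    covariate names to coefficients; ``species_effects`` maps species
    levels to offsets (baseline level 0).
    """
    lp = 0.0
    for cov, b in betas.items():
        lp += b * float(record.get(cov, 0.0))
    if species_effects:
        sp = record.get("species", SPECIES_BASELINE)
        if sp not in ALL_SPECIES:
            raise KeyError(f"unknown species level {sp!r}")
        lp += species_effects.get(sp, 0.0)
    lp += rho * float(record.get("family_size", 0.0))
    return lp


def hazard_ratio(beta: float) -> tuple[float, str]:
    """``exp(beta)`` with its directional reading.

    HR > 1: a unit increase makes the forager leave earlier; HR < 1: it
    stays longer.
    """
    hr = float(np.exp(beta))
    if hr > 1.0:
        flag = "leaves earlier"
    elif hr < 1.0:
        flag = "stays longer"
    else:
        flag = "no effect"
    return hr, flag


@dataclass
class CoxGammaConfig:
    """Covariate set, gamma-process hyperparameters and MCMC settings."""

    covariates: tuple[str, ...] = ("dir", "dis", "dbh")
    include_species: bool = False
    include_rho: bool = True
    confidence: float = 0.001  # c: weight of the prior baseline guess
    lambda_star: float | None = None  # None: 1 / mean(T)
    standardize: bool = False
    chains: int = 3
    iterations: int = 20000
    burnin: int = 10000
    thin: int = 3
    prior_sd: float = 10.0

    def validate(self) -> None:
        if self.confidence <= 0:
            raise ValueError("confidence c must be positive")
        if self.lambda_star is not None and self.lambda_star <= 0:
            raise ValueError("lambda_star must be positive")
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burnin must be < iterations")


@dataclass
class CoxFit:
    name: str
    n_obs: int
    summary: pd.DataFrame
    dic: float
    p_d: float
    deviance_draws: np.ndarray
    event_times: np.ndarray  # interval right endpoints
    baseline_increments: np.ndarray  # posterior-mean dH_k
    draws: dict
    converged: bool
    max_psrf: float
    config: CoxGammaConfig
    covariate_names: list[str] = field(default_factory=list)

    def coef(self, parameter: str) -> float:
        return float(self.summary.set_index("parameter").loc[parameter, "mean"])

    def hazard_ratios(self) -> pd.DataFrame:
        tab = self.summary.copy()
        tab["hr"] = np.exp(tab["mean"])
        return tab


def build_residence_records(dir_table: pd.DataFrame, routes: pd.DataFrame,
                            trees: pd.DataFrame, dir_col: str = "dir_route",
                            foraging_only: bool = True,
                            censor_last: bool = False) -> pd.DataFrame:
    """Residence records for the used trees of each route.

    Residence time is departure minus arrival; travel distance is the
    Euclidean step from the previous tree (0 for route starts). Only
    foraging trees enter by default. ``censor_last`` flags each route's
    final tree as censored instead of an observed departure.
    """
    xy = trees.set_index("tree_id")[["x", "y"]]
    attrs = trees.set_index("tree_id")
    dir_used = dir_table.loc[dir_table["used"] == 1].set_index(["route_id", "period"])

    rows = []
    for route_id, grp in routes.sort_values("step").groupby("route_id"):
        steps = grp.reset_index(drop=True)
        for i, st in steps.iterrows():
            if foraging_only and st["behavior"] != "F":
                continue
            key = (route_id, int(st["step"]))
            if key not in dir_used.index:
                continue  # no availability disk for this period
            rec = dir_used.loc[key]
            if isinstance(rec, pd.DataFrame):
                rec = rec.iloc[0]
            tid = int(st["tree_id"])
            if i == 0:
                dis = 0.0
            else:
                prev = xy.loc[int(steps.iloc[i - 1]["tree_id"])]
                here = xy.loc[tid]
                dis = float(np.hypot(here["x"] - prev["x"], here["y"] - prev["y"]))
            t_res = float(st["departure_min"] - st["arrival_min"])
            if t_res <= 0:
                continue
            event = 1
            rows.append(
                {
                    "route_id": route_id,
                    "tree_id": tid,
                    "T": t_res,
                    "event": event,
                    "dir": float(rec[dir_col]),
                    "dis": dis,
                    "dbh": float(attrs.loc[tid, "dbh"]),
                    "ht": float(attrs.loc[tid, "height"]),
                    "species": str(attrs.loc[tid, "species"]),
                    "family_size": int(st["family_size"]),
                }
            )
    records = pd.DataFrame(rows)
    if censor_last and len(records):
        last_idx = records.groupby("route_id").tail(1).index
        records.loc[last_idx, "event"] = 0
    return records


def _design(records: pd.DataFrame, config: CoxGammaConfig) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for cov in config.covariates:
        x = records[cov].to_numpy(dtype=float)
        if config.standardize:
            sd = x.std(ddof=1)
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        cols.append(x)
        names.append(f"beta_{cov}")
    if config.include_species:
        sp = records["species"].astype(str)
        for lev in SPECIES_LEVELS:
            cols.append((sp == lev).to_numpy(dtype=float))
            names.append(f"sp_{lev}")
    if config.include_rho:
        cols.append(records["family_size"].to_numpy(dtype=float))
        names.append("rho")
    if not cols:
        return np.zeros((len(records), 0)), []
    return np.column_stack(cols), names


def fit_cox_gamma(records: pd.DataFrame, config: CoxGammaConfig | None = None,
                  seed: int = 0, name: str | None = None) -> CoxFit:
    """Fit the gamma-process Cox model by Metropolis-within-Gibbs."""
    config = config or CoxGammaConfig()
    config.validate()
    t_obs = records["T"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if event.sum() < 10:
        raise ValueError("need at least 10 observed departures")
    if np.any(t_obs <= 0):
        raise ValueError("residence times must be positive")

    x, names = _design(records, config)
    n, p = x.shape
    c_chains = config.chains
    rng = np.random.default_rng(seed)

    # Breslow grouping: one interval per unique event time
    ev_times = np.unique(t_obs[event == 1])
    n_k = len(ev_times)
    delta_k = np.diff(np.concatenate([[0.0], ev_times]))
    d_k = np.array([(event[t_obs == t] == 1).sum() for t in ev_times], dtype=float)
    # record i is at risk in interval k iff T_i >= ev_times[k]
    # n_int[i] = number of intervals record i fully survives into
    n_int = np.searchsorted(ev_times, t_obs, side="right")

    lam_star = config.lambda_star if config.lambda_star is not None else 1.0 / t_obs.mean()
    prior_shape = config.confidence * lam_star * delta_k

    order_t = np.argsort(t_obs)
    sorted_t = t_obs[order_t]
    # pos_k: first sorted index with T >= ev_times[k]
    pos_k = np.searchsorted(sorted_t, ev_times, side="left")
    is_event = event == 1
    ev_interval = np.searchsorted(ev_times, t_obs[is_event])  # interval of each event

    def risk_sums(elp: np.ndarray) -> np.ndarray:
        # sum of exp(lp) over records at risk in each interval, per chain
        suffix = np.cumsum(elp[:, order_t][:, ::-1], axis=1)[:, ::-1]
        padded = np.concatenate([suffix, np.zeros((elp.shape[0], 1))], axis=1)
        return padded[:, pos_k]

    beta = 0.01 * rng.standard_normal((c_chains, p))
    lp = beta @ x.T  # (chains, n)
    elp = np.exp(lp)

    scale = AdaptiveScale(c_chains, initial=0.05, target=0.25)
    prop_dir = np.full(p, 1.0 / np.sqrt(max(p, 1)))

    n_keep = (config.iterations - config.burnin) // config.thin
    keep_beta = np.empty((c_chains, n_keep, p))
    keep_dh = np.empty((c_chains, n_keep, n_k))
    keep_dev = np.empty((c_chains, n_keep))
    k_idx = 0

    # cumulative baseline at each record's T: sum of dH over intervals <= T
    def cum_h(dh: np.ndarray) -> np.ndarray:
        cs = np.concatenate([np.zeros((dh.shape[0], 1)), np.cumsum(dh, axis=1)], axis=1)
        return cs[:, n_int]

    dh = np.tile(lam_star * delta_k, (c_chains, 1))
    prior_var = config.prior_sd**2

    for it in range(config.iterations):
        # conjugate Gibbs for the baseline increments
        s_k = risk_sums(elp)
        dh = rng.gamma(prior_shape[None, :] + d_k[None, :],
                       1.0 / (config.confidence + s_k))
        h_at_t = cum_h(dh)
        log_dh = np.log(np.maximum(dh, 1e-300))

        if p:
            ev_lp_sum = lp[:, is_event].sum(axis=1)
            ll = ev_lp_sum - (h_at_t * elp).sum(axis=1)
            step = scale.scale[:, None] * prop_dir[None, :] * rng.standard_normal((c_chains, p))
            beta_prop = beta + step
            lp_prop = beta_prop @ x.T
            elp_prop = np.exp(np.clip(lp_prop, -700, 700))
            ll_prop = lp_prop[:, is_event].sum(axis=1) - (h_at_t * elp_prop).sum(axis=1)
            lpr = (beta**2 - beta_prop**2).sum(axis=1) / (2 * prior_var)
            acc = np.log(rng.random(c_chains)) < ll_prop - ll + lpr
            beta[acc] = beta_prop[acc]
            lp[acc] = lp_prop[acc]
            elp[acc] = elp_prop[acc]
            if it < config.burnin:
                scale.update(acc)

        if it >= config.burnin and (it - config.burnin) % config.thin == 0 and k_idx < n_keep:
            keep_beta[:, k_idx] = beta
            keep_dh[:, k_idx] = dh
            loglik = ((d_k[None, :] * log_dh).sum(axis=1)
                      + lp[:, is_event].sum(axis=1)
                      - (cum_h(dh) * elp).sum(axis=1))
            keep_dev[:, k_idx] = -2.0 * loglik
            k_idx += 1

    beta_hat = keep_beta.reshape(-1, p).mean(axis=0) if p else np.zeros(0)
    dh_hat = keep_dh.reshape(-1, n_k).mean(axis=0)
    lp_hat = x @ beta_hat if p else np.zeros(n)
    h_hat = np.concatenate([[0.0], np.cumsum(dh_hat)])[n_int]
    ll_hat = float((d_k * np.log(dh_hat)).sum() + lp_hat[is_event].sum()
                   - (h_hat * np.exp(lp_hat)).sum())
    dic, p_d = compute_dic(keep_dev, -2.0 * ll_hat)

    if p:
        summary = summarize_draws(keep_beta, names)
        max_psrf = float(np.nanmax(summary["psrf"])) if c_chains > 1 else 1.0
    else:
        summary = pd.DataFrame(columns=["parameter", "mean", "sd", "bci_2.5",
                                        "bci_97.5", "psrf"])
        max_psrf = 1.0
    converged = max_psrf <= 1.1
    if not converged:
        logger.warning("cox model %s: max PSRF %.3f > 1.1", name, max_psrf)

    return CoxFit(
        name=name or "+".join(config.covariates) or "baseline-only",
        n_obs=n,
        summary=summary,
        dic=float(dic),
        p_d=float(p_d),
        deviance_draws=keep_dev,
        event_times=ev_times,
        baseline_increments=dh_hat,
        draws={"beta": keep_beta, "dh": keep_dh, "names": names},
        converged=converged,
        max_psrf=max_psrf,
        config=config,
    )


def remaining_probability(fit: CoxFit, covariate_profile: dict,
                          times: np.ndarray) -> np.ndarray:
    """Survival curve ``S(t|x) = exp(-H0(t) exp(x'beta))``.

    Uses the posterior-mean cumulative baseline (a step function over the
    event-time grid) and the posterior-mean coefficients.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be non-negative and increasing")
    betas = dict(zip(fit.draws["names"], fit.summary["mean"]))
    lp = 0.0
    for nm, b in betas.items():
        if nm.startswith("sp_"):
            sp = covariate_profile.get("species", SPECIES_BASELINE)
            if sp not in ALL_SPECIES:
                raise KeyError(f"unknown species level {sp!r}")
            lp += b * (sp == nm.removeprefix("sp_"))
        elif nm == "rho":
            lp += b * float(covariate_profile.get("family_size", 0.0))
        else:
            lp += b * float(covariate_profile.get(nm.removeprefix("beta_"), 0.0))
    cum = np.concatenate([[0.0], np.cumsum(fit.baseline_increments)])
    idx = np.searchsorted(fit.event_times, times, side="right")
    h0 = cum[idx]
    return np.exp(-h0 * np.exp(lp))


def candidate_set_selection(records: pd.DataFrame, candidates: dict,
                            config: CoxGammaConfig | None = None,
                            seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Fit and DIC-rank a set of candidate covariate structures.

    ``candidates`` maps model name -> kwargs overriding the base config
    (e.g. ``{"covariates": ("dir", "dis"), "include_species": True}``).
    Returns the ranking table (with DIC weights) and the fits by name.
    """
    base = config or CoxGammaConfig()
    fits = {}
    for i, (nm, kw) in enumerate(candidates.items()):
        cfg = replace(base, **kw)
        fits[nm] = fit_cox_gamma(records, cfg, seed=seed + 7919 * i, name=nm)
    table = rank_models(list(fits.values()), weights=True)
    return table, fits
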