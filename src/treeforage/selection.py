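"""Three-state Bayesian hierarchical tree-use model.

Each available tree at a foraging period is unused (U), used for foraging
(F) or used for another behaviour (O). With availability indicator ``a``,
previous-use indicator ``f``, selection probability ``W`` and foraging-mode
probability ``v`` the state probabilities are

    Pr(U) = (1 - a) + [(1 - f)(1 - W) + f] a
    Pr(F) = v (1 - f) W a
    Pr(O) = (1 - v)(1 - f) W a

and ``logit(W)`` is a linear model in the tree's decay-index ratio, species,
a per-forager Gaussian random intercept and a family-size slope. Sampling
is adaptive random-walk Metropolis within Gibbs with conjugate updates for
``v``; optional Kuo-Mallick indicator variables give posterior inclusion
probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from treeforage.mcmc import AdaptiveScale, compute_dic, psrf, summarize_draws

logger = logging.getLogger(__name__)

STATES = ("U", "F", "O")
SPECIES_BASELINE = "NPUM"
SPECIES_LEVELS = ("NANT", "NBET", "OTHER")  # coefficients relative to N. pumilio


def state_probabilities(a_t, f_prev, w_t, v_t):
    """Probabilities of the three use-states; always sums to exactly 1.

    Accepts scalars or broadcastable arrays, all in [0, 1].
    """
    a_t, f_prev, w_t, v_t = (np.asarray(z, dtype=float) for z in (a_t, f_prev, w_t, v_t))
    for name, z in (("a_t", a_t), ("f_prev", f_prev), ("W_t", w_t), ("v_t", v_t)):
        if np.any((z < 0) | (z > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    p_u = (1.0 - a_t) + ((1.0 - f_prev) * (1.0 - w_t) + f_prev) * a_t
    p_f = v_t * (1.0 - f_prev) * w_t * a_t
    p_o = (1.0 - v_t) * (1.0 - f_prev) * w_t * a_t
    return p_u, p_f, p_o


def selection_logit(dir_value=0.0, species_effect=0.0, gamma=0.0, rho=0.0,
                    n_family=0.0, beta0=0.0, beta1=0.0, eta=0.0,
                    dir_route=0.0, n_route=0.0):
    """Inverse-logit selection probability ``W`` from the linear predictor.

    The interaction term ``eta * dir_route * n_route`` is included only when
    a non-zero ``eta`` is passed.
    """
    lp = (beta0 + beta1 * np.asarray(dir_value, dtype=float) + species_effect
          + gamma + rho * n_family + eta * dir_route * n_route)
    return expit(lp)


def inclusion_probability(indicator_draws) -> float:
    """Posterior mean of a 0/1 inclusion-indicator chain."""
    draws = np.asarray(indicator_draws, dtype=float)
    if np.any((draws != 0) & (draws != 1)):
        raise ValueError("indicator draws must be 0/1")
    return float(draws.mean())


def categorical_loglik(obs: pd.DataFrame, coefficients: dict, v: float,
                       gammas: dict | None = None) -> float:
    """Categorical log-likelihood evaluated row by row from the three state
    probabilities — an independent (brute-force) route to the deviance.

    ``coefficients`` maps design-column names (``beta0``, covariate columns,
    ``sp_<level>``, ``rho``) to values; ``gammas`` maps woodpecker ids to
    random intercepts.
    """
    total = 0.0
    gammas = gammas or {}
    for row in obs.itertuples():
        lp = coefficients.get("beta0", 0.0)
        for nm, b in coefficients.items():
            if nm == "beta0":
                continue
            if nm.startswith("sp_"):
                lp += b * (getattr(row, "species", None) == nm.removeprefix("sp_"))
            elif nm == "rho":
                lp += b * row.family_size
            elif nm == "eta":
                lp += b * row.dir_route * row.route_length
            else:
                lp += b * getattr(row, nm)
        lp += gammas.get(row.woodpecker_id, 0.0)
        w = expit(lp)
        p_u, p_f, p_o = state_probabilities(row.a, row.f_prev, w, v)
        p_y = {"U": p_u, "F": p_f, "O": p_o}[row.y]
        total += np.log(p_y)
    return float(total)


@dataclass
class SelectionConfig:
    """Model structure and MCMC settings for the tree-use model."""

    fixed_effects: tuple[str, ...] = ("dir_local",)
    include_species: bool = False
    include_rho: bool = False
    include_eta: bool = False
    random_woodpecker: bool = True
    indicators: bool = False
    standardize: bool = False
    chains: int = 3
    iterations: int = 20000
    burnin: int = 10000
    thin: int = 3
    prior_sd: float = 10.0
    gamma_sd_prior: float = 10.0

    def validate(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burnin must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class SelectionFit:
    name: str
    n_obs: int
    summary: pd.DataFrame
    dic: float
    p_d: float
    deviance_draws: np.ndarray
    draws: dict
    inclusion: dict
    v_mean: float
    converged: bool
    config: SelectionConfig
    max_psrf: float

    def coef(self, parameter: str) -> float:
        row = self.summary.set_index("parameter")
        return float(row.loc[parameter, "mean"])


def build_observations(dir_table: pd.DataFrame, routes: pd.DataFrame) -> pd.DataFrame:
    """Assemble tree-use observations from the DIR table and route table.

    A row per (route, period, available tree): state F/O for the tree
    actually used at the period (with its recorded behaviour), U otherwise;
    ``f_prev`` flags the tree used at the preceding period.
    """
    used_at = {(r.route_id, int(r.step)): int(r.tree_id) for r in routes.itertuples()}
    meta = routes.groupby("route_id").agg(
        woodpecker_id=("woodpecker_id", "first"),
        family_size=("family_size", "first"),
        route_length=("step", "max"),
    )
    obs = dir_table.copy()
    obs["a"] = 1
    obs["y"] = np.where(obs["used"] == 1,
                        np.where(obs["behavior"] == "F", "F", "O"), "U")
    obs["f_prev"] = [
        int(used_at.get((r, p - 1)) == t)
        for r, p, t in zip(obs["route_id"], obs["period"], obs["tree_id"])
    ]
    obs = obs.merge(meta, left_on="route_id", right_index=True, how="left")
    return obs


def _design(obs: pd.DataFrame, config: SelectionConfig) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(obs))]
    names = ["beta0"]
    for c in config.fixed_effects:
        x = obs[c].to_numpy(dtype=float)
        if config.standardize:
            sd = x.std(ddof=1)
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        cols.append(x)
        names.append(c)
    if config.include_eta:
        x = (obs["dir_route"] * obs["route_length"]).to_numpy(dtype=float)
        if config.standardize:
            x = (x - x.mean()) / (x.std(ddof=1) or 1.0)
        cols.append(x)
        names.append("eta")
    if config.include_species:
        sp = obs["species"].astype(str)
        for lev in SPECIES_LEVELS:
            cols.append((sp == lev).to_numpy(dtype=float))
            names.append(f"sp_{lev}")
    if config.include_rho:
        cols.append(obs["family_size"].to_numpy(dtype=float))
        names.append("rho")
    return np.column_stack(cols), names


def fit_selection_model(obs: pd.DataFrame, config: SelectionConfig | None = None,
                        seed: int = 0, name: str | None = None) -> SelectionFit:
    """Fit the three-state model by Metropolis-within-Gibbs.

    Rows with ``a = 0`` or ``f_prev = 1`` are deterministically unused and
    contribute no likelihood; remaining rows follow a Bernoulli selection
    likelihood in ``W`` with the F/O split governed by ``v`` (conjugate
    Beta-updated). Non-convergence (any PSRF > 1.1) is flagged on the
    result, not raised.
    """
    config = config or SelectionConfig()
    config.validate()
    if set(obs["y"]) <= {"U"} or not (set(obs["y"]) & {"F", "O"}):
        raise ValueError("observations must include both used and unused trees")
    det = (obs["a"] == 0) | (obs["f_prev"] == 1)
    if np.any((obs.loc[det, "y"] != "U")):
        raise ValueError("a tree with a=0 or f_prev=1 cannot be in a used state")
    act = obs.loc[~det]

    x, names = _design(act, config)
    # sample in a centred parameterization (decorrelates the intercept from
    # the slopes); draws are mapped back to the raw scale afterwards
    x_means = np.zeros(x.shape[1])
    x_means[1:] = x[:, 1:].mean(axis=0)
    x = x - x_means[None, :]
    used = (act["y"] != "U").to_numpy(dtype=float)
    n_f = int((act["y"] == "F").sum())
    n_o = int((act["y"] == "O").sum())
    n, p = x.shape
    c = config.chains
    rng = np.random.default_rng(seed)

    if config.random_woodpecker:
        wp_codes, wp_levels = pd.factorize(act["woodpecker_id"])
        n_wp = len(wp_levels)
        order = np.argsort(wp_codes, kind="stable")
        bounds = np.searchsorted(wp_codes[order], np.arange(n_wp))
    else:
        n_wp = 0

    def softplus(z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))

    # --- state ---
    base_rate = used.mean()
    beta = np.zeros((c, p))
    beta[:, 0] = np.log(base_rate / (1 - base_rate)) + 0.2 * rng.standard_normal(c)
    beta[:, 1:] += 0.2 * rng.standard_normal((c, p - 1))
    g = np.ones((c, p - 1), dtype=float)
    gamma = np.zeros((c, n_wp))
    log_tau = np.full(c, 0.0)
    v = np.full(c, max(min(n_f / max(n_f + n_o, 1), 0.95), 0.05))

    def logits_of(beta_, g_, gamma_):
        eff = beta_.copy()
        eff[:, 1:] *= g_
        out = eff @ x.T
        if n_wp:
            out += gamma_[:, wp_codes]
        return out

    logits = logits_of(beta, g, gamma)
    sp_cur = softplus(logits)
    ll = logits @ used - sp_cur.sum(axis=1)
    if n_wp:
        used_per_wp = np.bincount(wp_codes, weights=used, minlength=n_wp)

    beta_scale = AdaptiveScale(c, initial=0.05, target=0.25)
    gamma_scale = AdaptiveScale(c, initial=0.2, target=0.3)
    tau_scale = AdaptiveScale(c, initial=0.4, target=0.4)
    prop_dir = np.full(p, 1.0 / np.sqrt(p))
    burn_buf = np.empty((min(500, max(config.burnin, 1)), c, p))
    buf_n = 0

    n_keep = (config.iterations - config.burnin) // config.thin
    keep_beta = np.empty((c, n_keep, p))
    keep_g = np.empty((c, n_keep, p - 1))
    keep_gamma = np.empty((c, n_keep, n_wp)) if n_wp else np.empty((c, n_keep, 0))
    keep_tau = np.empty((c, n_keep))
    keep_v = np.empty((c, n_keep))
    keep_dev = np.empty((c, n_keep))
    k = 0

    prior_var = config.prior_sd**2
    for it in range(config.iterations):
        in_burn = it < config.burnin

        # fixed-effect block
        step = beta_scale.scale[:, None] * prop_dir[None, :] * rng.standard_normal((c, p))
        beta_prop = beta + step
        logits_prop = logits_of(beta_prop, g, gamma)
        sp_prop = softplus(logits_prop)
        ll_prop = logits_prop @ used - sp_prop.sum(axis=1)
        lp_ratio = (beta**2 - beta_prop**2).sum(axis=1) / (2 * prior_var)
        acc = np.log(rng.random(c)) < ll_prop - ll + lp_ratio
        beta[acc] = beta_prop[acc]
        logits[acc] = logits_prop[acc]
        sp_cur[acc] = sp_prop[acc]
        ll[acc] = ll_prop[acc]
        if in_burn:
            beta_scale.update(acc)
            if buf_n < len(burn_buf):
                burn_buf[buf_n] = beta
                buf_n += 1
            if it % 250 == 249 and buf_n > 50:
                sd = burn_buf[:buf_n].reshape(-1, p).std(axis=0)
                prop_dir = np.clip(sd, 1e-3, None) / np.sqrt(p)
                buf_n = 0

        # inclusion indicators (Kuo-Mallick Gibbs flips)
        if config.indicators:
            for j in range(p - 1):
                contrib = beta[:, j + 1][:, None] * x[:, j + 1][None, :]
                l_off = logits - g[:, j][:, None] * contrib
                l_on = l_off + contrib
                sp_off, sp_on = softplus(l_off), softplus(l_on)
                ll_off = l_off @ used - sp_off.sum(axis=1)
                ll_on = l_on @ used - sp_on.sum(axis=1)
                p_on = 1.0 / (1.0 + np.exp(np.clip(ll_off - ll_on, -500, 500)))
                new = (rng.random(c) < p_on).astype(float)
                on = (new == 1)[:, None]
                logits = np.where(on, l_on, l_off)
                sp_cur = np.where(on, sp_on, sp_off)
                ll = np.where(new == 1, ll_on, ll_off)
                g[:, j] = new

        # per-forager random intercepts
        if n_wp:
            tau = np.exp(log_tau)
            dg = gamma_scale.scale[:, None] * rng.standard_normal((c, n_wp))
            logits_prop = logits + dg[:, wp_codes]
            sp_prop = softplus(logits_prop)
            dsp_by_wp = np.add.reduceat((sp_prop - sp_cur)[:, order], bounds, axis=1)
            d_by_wp = dg * used_per_wp[None, :] - dsp_by_wp
            gamma_prop = gamma + dg
            dprior = (gamma**2 - gamma_prop**2) / (2 * tau[:, None] ** 2)
            acc_g = np.log(rng.random((c, n_wp))) < d_by_wp + dprior
            gamma = np.where(acc_g, gamma_prop, gamma)
            acc_rows = acc_g[:, wp_codes]
            logits = np.where(acc_rows, logits_prop, logits)
            sp_cur = np.where(acc_rows, sp_prop, sp_cur)
            ll += (np.where(acc_g, d_by_wp, 0.0)).sum(axis=1)
            if in_burn:
                gamma_scale.update(acc_g.mean(axis=1))

            # translation sweep: likelihood-invariant shift between the
            # intercept and the random-intercept mean fixes their coupling
            shift = 0.5 * rng.standard_normal(c)
            b0_new = beta[:, 0] + shift
            gam_new = gamma - shift[:, None]
            dlp = ((beta[:, 0] ** 2 - b0_new**2) / (2 * prior_var)
                   + ((gamma**2).sum(axis=1) - (gam_new**2).sum(axis=1))
                   / (2 * np.exp(2 * log_tau)))
            acc_s = np.log(rng.random(c)) < dlp
            beta[acc_s, 0] = b0_new[acc_s]
            gamma[acc_s] = gam_new[acc_s]

            # random-effect SD (half-normal prior, log-scale walk)
            lt_prop = log_tau + tau_scale.scale * rng.standard_normal(c)
            tau_prop = np.exp(lt_prop)

            def tau_logpost(t, lt):
                like = -n_wp * np.log(t) - (gamma**2).sum(axis=1) / (2 * t**2)
                prior = -(t**2) / (2 * config.gamma_sd_prior**2)
                return like + prior + lt  # + Jacobian

            acc_t = (np.log(rng.random(c))
                     < tau_logpost(tau_prop, lt_prop) - tau_logpost(np.exp(log_tau), log_tau))
            log_tau = np.where(acc_t, lt_prop, log_tau)
            if in_burn:
                tau_scale.update(acc_t)

        # foraging-mode probability: conjugate Beta under the Uniform prior
        v = rng.beta(1 + n_f, 1 + n_o, size=c)

        if not in_burn and (it - config.burnin) % config.thin == 0 and k < n_keep:
            keep_beta[:, k] = beta
            keep_g[:, k] = g
            if n_wp:
                keep_gamma[:, k] = gamma
            keep_tau[:, k] = np.exp(log_tau)
            keep_v[:, k] = v
            keep_dev[:, k] = -2.0 * (ll + n_f * np.log(v) + n_o * np.log1p(-v))
            k += 1

    # plug-in deviance at posterior means (effective coefficients)
    eff_draws = keep_beta.copy()
    eff_draws[:, :, 1:] *= keep_g
    beta_hat = eff_draws.reshape(-1, p).mean(axis=0)  # centred scale
    gamma_hat = keep_gamma.reshape(-1, n_wp).mean(axis=0) if n_wp else np.zeros(0)
    v_hat = float(keep_v.mean())
    l_hat = x @ beta_hat + (gamma_hat[wp_codes] if n_wp else 0.0)
    # undo the internal centring on the reported intercept
    eff_draws[:, :, 0] -= eff_draws[:, :, 1:] @ x_means[1:]
    ll_hat = float((used * l_hat - np.logaddexp(0.0, l_hat)).sum()
                   + n_f * np.log(v_hat) + n_o * np.log1p(-v_hat))
    dic, p_d = compute_dic(keep_dev, -2.0 * ll_hat)

    summary = summarize_draws(eff_draws, names)
    extra_names, extra_draws = [], []
    if n_wp:
        extra_names.append("sd_gamma")
        extra_draws.append(keep_tau[:, :, None])
    extra_names.append("v")
    extra_draws.append(keep_v[:, :, None])
    summary = pd.concat(
        [summary, summarize_draws(np.concatenate(extra_draws, axis=2), extra_names)],
        ignore_index=True,
    )
    inclusion = {}
    if config.indicators:
        for j, nm in enumerate(names[1:]):
            inclusion[nm] = inclusion_probability(keep_g[:, :, j].ravel())
    summary["inclusion_p"] = [inclusion.get(nm, np.nan) for nm in summary["parameter"]]

    max_psrf = float(np.nanmax(summary["psrf"])) if config.chains > 1 else 1.0
    converged = max_psrf <= 1.1
    if not converged:
        logger.warning("selection model %s: max PSRF %.3f > 1.1", name, max_psrf)

    return SelectionFit(
        name=name or "+".join(config.fixed_effects) or "null",
        n_obs=int(len(obs)),
        summary=summary,
        dic=float(dic),
        p_d=float(p_d),
        deviance_draws=keep_dev,
        draws={"beta": keep_beta, "g": keep_g, "gamma": keep_gamma,
               "tau": keep_tau, "v": keep_v, "names": names},
        inclusion=inclusion,
        v_mean=v_hat,
        converged=converged,
        config=config,
        max_psrf=max_psrf,
    )


def candidate_models(scale_col: str) -> dict[str, tuple[str, ...]]:
    """The per-lag candidate set: lag-scale DIR, route DIR, both, null."""
    if scale_col == "dir_route":
        return {"dir_route": ("dir_route",), "null": ()}
    return {
        f"{scale_col}": (scale_col,),
        "dir_route": ("dir_route",),
        f"{scale_col}+dir_route": (scale_col, "dir_route"),
        "null": (),
    }


def fit_candidate_set(obs: pd.DataFrame, scale_col: str,
                      config: SelectionConfig | None = None, seed: int = 0,
                      residualized: bool = False) -> list[SelectionFit]:
    """Fit the four candidate models for one DIR scale on one observation set.

    With ``residualized=True`` the combined model uses the standardized
    residual of the lag DIR on the route DIR instead of the raw lag DIR.
    """
    base = config or SelectionConfig()
    fits = []
    for i, (name, effects) in enumerate(candidate_models(scale_col).items()):
        effects = list(effects)
        if residualized and len(effects) == 2:
            lag = {"dir_local": 0}.get(scale_col)
            if lag is None:
                lag = int(scale_col.removeprefix("dir_lag"))
            effects = [f"resid_lag{lag}", "dir_route"]
            name = f"resid_lag{lag}+dir_route"
        cfg = replace(base, fixed_effects=tuple(effects))
        fits.append(fit_selection_model(obs, cfg, seed=seed + 1000 * i, name=name))
    return fits
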