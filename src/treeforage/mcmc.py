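"""Shared MCMC machinery: convergence diagnostics, DIC, model ranking and
a small adaptive random-walk helper used by both Bayesian models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def psrf(chains: np.ndarray) -> float | np.ndarray:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape ``(m, n)`` or ``(m, n, p)`` with m >= 2 chains of
    n draws. Identical chains (zero between-chain variance) return exactly
    1.0 — they are converged by construction.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        return float(psrf(chains[:, :, None])[0])
    if chains.ndim != 3:
        raise ValueError("chains must be (m, n) or (m, n, p)")
    m, n = chains.shape[:2]
    if m < 2:
        raise ValueError("PSRF needs at least 2 chains")
    means = chains.mean(axis=1)  # (m, p)
    w = chains.var(axis=1, ddof=1).mean(axis=0)  # within-chain
    b_over_n = means.var(axis=0, ddof=1)  # B/n
    var_plus = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    out = np.ones(chains.shape[2])
    ok = (w > 0) & (b_over_n > 0)
    out[ok] = np.sqrt(var_plus[ok] / w[ok])
    return out


def compute_dic(deviance_draws: np.ndarray, deviance_at_posterior_mean: float,
                ) -> tuple[float, float]:
    """DIC and effective parameter count pD.

    ``pD = mean(D) - D(posterior mean)``; ``DIC = mean(D) + pD``.
    """
    draws = np.asarray(deviance_draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least 2 deviance draws")
    dbar = float(draws.mean())
    pd_ = dbar - float(deviance_at_posterior_mean)
    return dbar + pd_, pd_


def dic_weights(delta_dic: np.ndarray) -> np.ndarray:
    """Akaike-style weights ``exp(-delta/2)`` normalized to sum to 1."""
    d = np.asarray(delta_dic, dtype=float)
    w = np.exp(-d / 2.0)
    return w / w.sum()


def rank_models(fits: list, weights: bool = False) -> pd.DataFrame:
    """Rank fitted models by DIC within one observation set.

    ``fits`` is a list of objects (or dicts) exposing ``name``, ``dic`` and
    ``n_obs``. All fits must share ``n_obs`` — DIC is only comparable on
    identical data. Returns the table sorted ascending with ``delta_dic``
    and a support flag at the < 2 threshold.
    """
    if not fits:
        raise ValueError("no fits to rank")

    def get(f, key):
        return f[key] if isinstance(f, dict) else getattr(f, key)

    n_obs = {get(f, "n_obs") for f in fits}
    if len(n_obs) > 1:
        raise ValueError(f"fits cover differing observation counts {sorted(n_obs)}; "
                         "rank within blocks of equal N only")
    table = pd.DataFrame(
        {"model": [get(f, "name") for f in fits],
         "dic": [float(get(f, "dic")) for f in fits]}
    ).sort_values("dic", kind="stable").reset_index(drop=True)
    table["delta_dic"] = table["dic"] - table["dic"].iloc[0]
    table["supported"] = table["delta_dic"] < 2.0
    if weights:
        table["weight"] = dic_weights(table["delta_dic"].to_numpy())
    return table


@dataclass
class AdaptiveScale:
    """Per-chain random-walk scale adapted toward a target acceptance rate
    during burn-in (Robbins-Monro on the log scale)."""

    n_chains: int
    initial: float = 0.1
    target: float = 0.3
    gain: float = 0.05
    scale: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scale = np.full(self.n_chains, float(self.initial))

    def update(self, accepted: np.ndarray) -> None:
        self.scale *= np.exp(self.gain * (accepted.astype(float) - self.target))
        np.clip(self.scale, 1e-6, 1e3, out=self.scale)


def summarize_draws(draws: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Posterior summary table from draws of shape (chains, n, p)."""
    flat = draws.reshape(-1, draws.shape[-1])
    rhat = psrf(draws)
    return pd.DataFrame(
        {
            "parameter": names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "bci_2.5": np.percentile(flat, 2.5, axis=0),
            "bci_97.5": np.percentile(flat, 97.5, axis=0),
            "psrf": np.atleast_1d(rhat),
        }
    )
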