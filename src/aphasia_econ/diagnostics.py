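"""Posterior summaries and MCMC convergence diagnostics.

Produces one row per parameter in the layout used for reporting the
regression results: posterior mean ("estimate"), posterior sd, effective
sample size, split-R-hat, equal-tailed credible interval, and the
exponentiated estimate as an odds ratio.

R-hat and ESS are delegated to arviz (split-chain R-hat; mean-method ESS via
autocorrelation summation).  Zero-variance chains — e.g. a degenerate
constant parameter — are reported with R-hat 1 and ESS equal to the total
draw count by convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import PosteriorDraws

__all__ = ["summarize", "SUMMARY_COLUMNS"]

SUMMARY_COLUMNS = (
    "estimate",
    "std_dev",
    "effect_size",
    "rhat",
    "interval_low",
    "interval_high",
    "odds_ratio",
)


def _rhat_ess(chains: np.ndarray) -> tuple[float, float]:
    import arviz as az

    total = chains.size
    if np.allclose(chains, chains.flat[0]):
        return 1.0, float(total)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(chains, method="split"))
        ess = float(az.ess(chains, method="mean"))
    if not np.isfinite(rhat):
        rhat = 1.0
    if not np.isfinite(ess):
        ess = float(total)
    return rhat, ess


def summarize(draws: PosteriorDraws, credible_level: float = 0.95) -> pd.DataFrame:
    """Posterior summary table, one row per parameter.

    Requires at least 2 chains and 100 post-burn-in iterations (split-R-hat
    and the autocorrelation-based ESS are meaningless below that).
    """
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    if draws.n_draws < 100:
        raise ValueError("need at least 100 post-burn-in iterations per chain")
    if not 0 < credible_level < 1:
        raise ValueError("credible_level must be in (0, 1)")
    alpha = (1.0 - credible_level) / 2.0
    rows = []
    for j, name in enumerate(draws.param_names):
        chains = draws.values[:, :, j]
        pooled = chains.reshape(-1)
        rhat, ess = _rhat_ess(chains)
        estimate = float(pooled.mean())
        low, high = np.quantile(pooled, [alpha, 1.0 - alpha])
        rows.append(
            {
                "parameter": name,
                "estimate": estimate,
                "std_dev": float(pooled.std(ddof=1)),
                "effect_size": ess,
                "rhat": rhat,
                "interval_low": float(low),
                "interval_high": float(high),
                "odds_ratio": float(np.exp(estimate)),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    assert (table["interval_low"] <= table["interval_high"]).all()
    return table
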