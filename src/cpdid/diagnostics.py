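"""MCMC convergence diagnostics.

The Gelman-Rubin potential scale reduction factor compares within-chain to
between-chain variation: chains started from overdispersed points that have
converged to a common stationary distribution give R-hat near 1, while
chains stuck in different regions give R-hat well above 1. The classic
(non-split) formula is the default; halving each chain first (the "split"
variant, which also flags non-stationarity within a single chain) is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .changepoint import PosteriorChains

#: conventional convergence threshold on R-hat
RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class RHatReport:
    rhat: float
    within: float
    between: float

    @property
    def converged(self) -> bool:
        return np.isfinite(self.rhat) and self.rhat < RHAT_THRESHOLD


def gelman_rubin(chains: np.ndarray, split: bool = False) -> RHatReport:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains. With
    W the mean within-chain sample variance and B = n * var(chain means),
    the pooled variance estimate is ((n-1)/n) W + B/n and
    R-hat = sqrt(pooled / W).

    Degenerate case: if every chain is internally constant (W = 0) but the
    chains disagree (B > 0), R-hat is reported as +inf -- maximal
    non-convergence, not an error.
    """
    arr = np.asarray(chains, dtype=float)
    if split:
        half = arr.shape[1] // 2
        arr = np.vstack([arr[:, :half], arr[:, half : 2 * half]])
    m, n = arr.shape
    if m < 2:
        raise ValueError("at least two chains are required")
    if n < 2:
        raise ValueError("each chain needs at least two draws")

    within = float(arr.var(axis=1, ddof=1).mean())
    between = float(n * arr.mean(axis=1).var(ddof=1))
    if within == 0.0:
        rhat = np.inf if between > 0 else np.nan
    else:
        pooled = (n - 1) / n * within + between / n
        rhat = float(np.sqrt(pooled / within))
    return RHatReport(rhat=rhat, within=within, between=between)


def rhat_report(chains: PosteriorChains, split: bool = False) -> pd.DataFrame:
    """R-hat for every sampled parameter of a posterior, one row each."""
    rows = []
    for name in chains.param_names:
        rep = gelman_rubin(chains.draws[name], split=split)
        rows.append(
            {
                "parameter": name,
                "rhat": rep.rhat,
                "within": rep.within,
                "between": rep.between,
                "converged": rep.converged,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def traceplot_data(chains: PosteriorChains) -> pd.DataFrame:
    """Tidy long-format draws (chain, iteration, parameter, value) for
    trace inspection with any plotting tool."""
    first = next(iter(chains.draws.values()), None)
    if first is None or first.size == 0:
        raise ValueError("no draws to export")
    frames = []
    for name, arr in chains.draws.items():
        n_chains, n_kept = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "chain": np.repeat(np.arange(n_chains), n_kept),
                    "iteration": np.tile(np.arange(n_kept), n_chains),
                    "parameter": name,
                    "value": arr.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
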