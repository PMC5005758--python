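"""Overdispersed Poisson difference-in-differences regression.

The intervention effect around the changepoint is estimated from two
quarterly series (intervention and comparison group) with the log-linear
model

    log mu = b0 + b1*Period + b2*Group + b3*Period*Group + log O,

where Period flags quarters at or after the (ceilinged) changepoint and
Group flags the intervention series. ``exp(b3)`` is the ratio of post/pre
rate ratios between groups -- the difference in differences -- and
``1 - exp(b3)`` its risk reduction. Overdispersion is handled
quasi-Poisson style: the covariance of the Poisson fit is inflated by the
Pearson dispersion ``phi = X^2 / (n - p)``, and 95% Wald intervals use
``beta +/- 1.96 * se``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import QuarterlySeries

_Z95 = 1.96  # conventional normal quantile for 95% Wald intervals

COEF_NAMES = ["beta0", "beta1", "beta2", "beta3"]


@dataclass
class DiDFit:
    """Quasi-Poisson difference-in-differences fit.

    Coefficients are on the log scale; ``dispersion`` is the Pearson
    ``phi`` and ``cov`` is already scaled by it.
    """

    coef: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    dispersion: float
    ci_low: pd.Series
    ci_high: pd.Series
    n_obs: int

    def irr(self) -> pd.Series:
        """Incidence rate ratios exp(beta), with Wald CI endpoints mapped
        through the same exponential."""
        return pd.DataFrame(
            {
                "irr": np.exp(self.coef),
                "ci_low": np.exp(self.ci_low),
                "ci_high": np.exp(self.ci_high),
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def build_design(
    series_by_group: Mapping[str, QuarterlySeries],
    tau: float,
    intervention: str,
    comparison: str,
    collapse: str = "quarter",
) -> pd.DataFrame:
    """Assemble the regression frame from one series per group.

    Period is 1 for quarters t >= ceiling(tau) (a changepoint of 30.5 puts
    quarters 31..N in the post period). With ``collapse="quarter"`` each
    quarter x group pair is one observation; ``collapse="cell"`` aggregates
    counts and offsets into the four Period x Group cells.
    """
    for label in (intervention, comparison):
        if label not in series_by_group:
            raise KeyError(f"series for group {label!r} is missing")
    post_start = math.ceil(tau)

    frames = []
    for label, flag in ((comparison, 0), (intervention, 1)):
        s = series_by_group[label]
        frames.append(
            pd.DataFrame(
                {
                    "t": s.t,
                    "y": s.y,
                    "period": (s.t >= post_start).astype(int),
                    "group": flag,
                    "offset": s.O,
                    "label": label,
                }
            )
        )
    design = pd.concat(frames, ignore_index=True)
    if design["period"].nunique() < 2:
        warnings.warn(
            "changepoint lies outside the observation window: the period "
            "effect (and the interaction) is unidentifiable",
            UserWarning,
            stacklevel=2,
        )
    if collapse == "cell":
        design = (
            design.groupby(["period", "group"], as_index=False)
            .agg(y=("y", "sum"), offset=("offset", "sum"))
        )
    elif collapse != "quarter":
        raise ValueError("collapse must be 'quarter' or 'cell'")
    design["interaction"] = design["period"] * design["group"]
    return design


def fit_quasipoisson(design: pd.DataFrame) -> DiDFit:
    """Fit the difference-in-differences model by Poisson IRLS, then scale
    the covariance by the Pearson dispersion.

    The point estimates are the Poisson maximum-likelihood coefficients
    (quasi-Poisson leaves them untouched); ``phi`` is the Pearson
    chi-square divided by the residual degrees of freedom, and standard
    errors, covariance and Wald intervals all carry the ``sqrt(phi)``
    inflation.
    """
    X = np.column_stack(
        [
            np.ones(len(design)),
            design["period"].to_numpy(float),
            design["group"].to_numpy(float),
            design["interaction"].to_numpy(float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient: some Period x Group cell is "
            "empty or constant"
        )
    y = design["y"].to_numpy(float)
    offset = np.log(design["offset"].to_numpy(float))

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    n, p = X.shape
    with warnings.catch_warnings():
        if n == p:  # saturated: statsmodels misreads the exact fit as separation
            warnings.simplefilter("ignore")
        res = model.fit(tol=1e-10, maxiter=200)
    if not res.converged:
        raise RuntimeError("IRLS did not converge")

    mu = np.asarray(res.fittedvalues)
    if n > p:
        phi = float(np.sum((y - mu) ** 2 / mu) / (n - p))
    else:
        warnings.warn(
            "saturated design leaves no residual degrees of freedom; "
            "dispersion set to 1 (no quasi scaling)",
            UserWarning,
            stacklevel=2,
        )
        phi = 1.0
    coef = pd.Series(res.params, index=COEF_NAMES)
    cov = pd.DataFrame(
        res.cov_params() * phi, index=COEF_NAMES, columns=COEF_NAMES
    )
    se = pd.Series(np.sqrt(np.diag(cov)), index=COEF_NAMES)
    return DiDFit(
        coef=coef,
        se=se,
        cov=cov,
        dispersion=phi,
        ci_low=coef - _Z95 * se,
        ci_high=coef + _Z95 * se,
        n_obs=n,
    )


def risk_reduction(beta: float) -> float:
    """Proportional risk reduction implied by a log-scale coefficient:
    1 - exp(beta). Negative when the coefficient indicates an increase."""
    if not np.isfinite(beta):
        raise ValueError("coefficient must be finite")
    return 1.0 - math.exp(beta)
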