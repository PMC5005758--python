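"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately naive -- term-by-term scipy evaluations,
closed forms, brute-force loops -- and shares no code with the implementation
it verifies.
"""

from __future__ import annotations

import numpy as np
import scipy.stats as st


def naive_log_posterior(params, series, prior, model):
    """Term-by-term log posterior: scipy log-pmf/log-pdf per quarter and
    per coefficient, summed in a plain Python loop."""
    import math

    if not (prior.tau_low <= params.tau <= prior.tau_high):
        return -np.inf
    terms = []
    for t, y, O in zip(series.t, series.y, series.O):
        d = 1.0 if t >= params.tau else 0.0
        lm = params.beta0 + params.beta2 * d + np.log(O)
        if model == 1:
            lm += params.beta1 * t + params.beta3 * d * (t - params.tau)
        terms.append(st.poisson.logpmf(y, np.exp(lm)))
    betas = [params.beta0, params.beta1, params.beta2, params.beta3]
    if model == 2:
        betas = [params.beta0, params.beta2]
    for b in betas:
        terms.append(st.norm.logpdf(b, 0.0, prior.beta_sd))
    terms.append(
        st.uniform.logpdf(params.tau, prior.tau_low, prior.tau_high - prior.tau_low)
    )
    return math.fsum(terms)


def saturated_did_coefs(y, O):
    """Closed-form coefficients of the saturated 2x2 rate model.

    ``y[g][p]`` and ``O[g][p]`` are cell totals indexed by group g (0/1)
    and period p (0/1). Returns (b0, b1, b2, b3) on the log scale.
    """
    r = {(g, p): y[g][p] / O[g][p] for g in (0, 1) for p in (0, 1)}
    b0 = np.log(r[0, 0])
    b1 = np.log(r[0, 1] / r[0, 0])
    b2 = np.log(r[1, 0] / r[0, 0])
    b3 = np.log(r[1, 1] * r[0, 0] / (r[1, 0] * r[0, 1]))
    return b0, b1, b2, b3


def brute_force_quarterly_counts(records, start_year, n_quarters):
    """Re-filter and re-count generated records with independent logic.

    Returns {group: array of counts of length n_quarters} using its own
    restatement of the inclusion window (weekday, Sep-Jun, 7-9 or 14-16
    local) and the 5-19 age band.
    """
    out: dict[str, np.ndarray] = {}
    for rec in records:
        ts = rec.timestamp
        weekday_ok = ts.isoweekday() <= 5
        month_ok = ts.month not in (7, 8)
        hour_ok = (7 <= ts.hour < 9) or (14 <= ts.hour < 16)
        age_ok = 5 <= rec.age <= 19
        if not (weekday_ok and month_ok and hour_ok and age_ok):
            continue
        q = (ts.year - start_year) * 4 + (ts.month - 1) // 3
        if not 0 <= q < n_quarters:
            continue
        out.setdefault(rec.group, np.zeros(n_quarters, dtype=int))[q] += 1
    return out


def sort_based_quantile(values, q):
    """Linear-interpolation quantile computed from first principles on the
    sorted sample (the classic type-7 definition)."""
    xs = np.sort(np.asarray(values, dtype=float))
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
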