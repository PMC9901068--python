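"""Independent reference implementations used as test oracles.

These deliberately avoid the package's data structures: the clump
oracle recomputes correlations on the fly from dense vectors with no
sparse pair map, and the liability oracle re-derives the closed form
from its published definition step by step.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def exhaustive_clump(units, p, z, corr, r_thresh):
    """Greedy clump by exhaustive scan.

    units: list of (gene, panel) ids; p, z: arrays; corr: dense
    matrix aligned with units (r=0 where pairs are out of window).
    Ties in p break on larger |z| then lexicographic unit id.
    """
    order = sorted(range(len(units)),
                   key=lambda i: (p[i], -abs(z[i]), units[i]))
    removed = set()
    retained = []
    for i in order:
        if i in removed:
            continue
        retained.append(units[i])
        for j in order:
            if j != i and j not in removed and corr[i, j] > r_thresh:
                removed.add(j)
        removed.add(i)
    return set(retained)


def liability_r2_oracle(r2_obs, K, P):
    """Lee et al. (2012) ascertainment-corrected conversion, recoded
    independently from its definition."""
    t = norm.ppf(1.0 - K)
    z = np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)
    i_mean = z / K  # mean liability of cases
    c_factor = (K * (1.0 - K)) ** 2 / (z * z * P * (1.0 - P))
    shrink = i_mean * ((P - K) / (1.0 - K))
    theta = shrink * (shrink - t)
    return c_factor * r2_obs / (1.0 + c_factor * theta * r2_obs)


def ols_slope_test(y, d):
    """Closed-form OLS slope and its z statistic for y ~ 1 + d."""
    d = np.asarray(d, float)
    y = np.asarray(y, float)
    n = len(y)
    dc = d - d.mean()
    yc = y - y.mean()
    beta = float(dc @ yc / (dc @ dc))
    resid = yc - beta * dc
    sigma2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(sigma2 / float(dc @ dc))
    return beta, se, beta / se
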