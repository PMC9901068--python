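"""Shared statistical primitives: BH FDR, IVW pooling, liability-scale R2."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "ivw_pool", "obs_to_liability_r2", "z_to_p", "p_to_z"]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Input p-values must lie in (0, 1]; order of rows is preserved.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def z_to_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal-tail p-value of a Z statistic."""
    return 2.0 * sps.norm.sf(np.abs(z))


def p_to_z(p: np.ndarray | float, one_sided: bool = True) -> np.ndarray | float:
    """Normal quantile of a p-value (one-sided by default)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie in (0, 1) for quantile back-fill")
    z = sps.norm.isf(p if one_sided else p / 2.0)
    return float(z) if z.ndim == 0 else z


def ivw_pool(betas, ses) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted pooling.

    pooled beta = sum(b_i / se_i^2) / sum(1 / se_i^2);
    pooled se = sqrt(1 / sum(1 / se_i^2)); p from the normal approximation.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("need at least one estimate")
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)):
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(z_to_p(beta / se))
    return beta, se, p


def obs_to_liability_r2(r2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale R2 from a 0/1 linear regression to the
    liability scale with ascertainment correction.

    Uses the closed form of Lee et al. (2012): with ``t`` the upper-K
    standard-normal quantile, ``z`` the normal density at ``t`` and
    ``m = z / K`` the mean liability of cases,

        C = K(1-K)/z^2 * K(1-K)/(P(1-P))
        theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t)
        r2_liab = C r2_obs / (1 + C theta r2_obs)

    Parameters
    ----------
    r2_obs:
        Observed-scale R2 in [0, 1].
    K:
        Population prevalence of the binary outcome in (0, 1).
    P:
        Case fraction in the analysed sample in (0, 1).
    """
    if not 0.0 <= r2_obs <= 1.0:
        raise ValueError("r2_obs must lie in [0, 1]")
    if not 0.0 < K < 1.0 or not 0.0 < P < 1.0:
        raise ValueError("K and P must lie in (0, 1)")
    t = sps.norm.isf(K)
    z = sps.norm.pdf(t)
    m = z / K
    C = (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P)))
    d = m * (P - K) / (1 - K)
    theta = d * (d - t)
    return C * r2_obs / (1 + C * theta * r2_obs)
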