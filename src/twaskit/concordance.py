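"""Observed case-control differential expression and concordance calls.

Per cohort, differential expression is the Pearson (point-biserial)
correlation between case-control status and observed expression;
cohorts are pooled by inverse-variance weighting on the Fisher-z scale
and BH-corrected across genes. Each TWAS high-confidence gene is then
classified: concordant if its observed meta correlation is
FDR-significant with the same sign as the TWAS Z, discordant if
significant with the opposite sign, otherwise not significant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, ivw_pool

logger = logging.getLogger(__name__)

__all__ = ["de_correlation", "meta_de", "classify_concordance"]

_SHRINK = 1.0 - 1e-12


def de_correlation(expression: pd.DataFrame, case_status) -> pd.DataFrame:
    """Per-gene correlation of expression with 0/1 case status.

    Standard error via the Fisher transform, se_z = 1/sqrt(n-3);
    two-sided p from the z statistic. Constant genes are skipped;
    |r| = 1 is shrunk to keep the transform finite.

    Returns gene_id, r, z (Fisher), se_z, p, n.
    """
    status = np.asarray(case_status, dtype=float)
    if set(np.unique(status)) - {0.0, 1.0}:
        raise ValueError("case status must be binary 0/1")
    n = expression.shape[1]
    if n < 4 or status.std() == 0:
        raise ValueError("need >=4 samples with both cases and controls")
    mat = expression.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("skipping %d constant genes in DE", (~keep).sum())
    mat = mat[keep]
    xc = mat - mat.mean(axis=1, keepdims=True)
    yc = status - status.mean()
    r = (xc @ yc) / (np.sqrt((xc**2).sum(axis=1)) * np.sqrt((yc**2).sum()))
    clipped = np.abs(r) >= 1.0
    if clipped.any():
        logger.warning("shrinking %d perfect correlations", clipped.sum())
        r = np.clip(r, -_SHRINK, _SHRINK)
    z = np.arctanh(r)
    se_z = 1.0 / np.sqrt(n - 3)
    p = 2.0 * sps.norm.sf(np.abs(z) / se_z)
    return pd.DataFrame(
        {"gene_id": expression.index[keep], "r": r, "z": z,
         "se_z": se_z, "p": p, "n": n}
    )


def meta_de(per_cohort: dict[str, pd.DataFrame],
            fisher_scale: bool = True) -> pd.DataFrame:
    """IVW meta-analysis of per-cohort DE correlations across genes.

    Pooling is on the Fisher-z scale with weights n_i - 3 (the
    inverse squared standard error); the pooled z is back-transformed
    to r. Raw-r pooling is available for sensitivity. BH correction
    runs across all genes.

    Returns gene_id, meta_r, meta_z, meta_se, p, q, n_cohorts.
    """
    stacked = pd.concat(per_cohort.values(), keys=per_cohort.keys(),
                        names=["cohort"]).reset_index(level=0)
    rows = []
    for gid, grp in stacked.groupby("gene_id", sort=True):
        if fisher_scale:
            est, se = grp["z"].to_numpy(), grp["se_z"].to_numpy()
        else:
            est = grp["r"].to_numpy()
            se = grp["se_z"].to_numpy()  # same weights, raw scale
        z, se_pool, p = ivw_pool(est, se)
        meta_r = float(np.tanh(z)) if fisher_scale else float(z)
        rows.append({"gene_id": gid, "meta_r": meta_r, "meta_z": z,
                     "meta_se": se_pool, "p": p, "n_cohorts": len(grp)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out


def classify_concordance(
    high_conf: pd.DataFrame,
    de_meta: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify TWAS high-confidence genes against observed DE.

    Parameters
    ----------
    high_conf:
        Table with gene_id and twas_Z (the TWAS direction carrier).
    de_meta:
        ``meta_de`` output with q filled.

    A gene with observed q < fdr is concordant iff sign(twas_Z) equals
    sign(meta_r), else discordant; genes without significant observed
    DE are 'observed_not_significant'. Genes with TWAS Z exactly 0
    have no defined direction and are excluded with a warning.

    Returns (per-gene calls, summary counts).
    """
    dm = de_meta.set_index("gene_id")
    rows = []
    for _, g in high_conf.iterrows():
        gid = g["gene_id"]
        if gid not in dm.index:
            continue
        tz = float(g["twas_Z"])
        if tz == 0:
            logger.warning("gene %s has TWAS Z = 0; direction undefined, "
                           "excluded", gid)
            continue
        obs = dm.loc[gid]
        if obs["q"] < fdr:
            call = ("concordant" if np.sign(tz) == np.sign(obs["meta_r"])
                    else "discordant")
        else:
            call = "observed_not_significant"
        rows.append({"gene_id": gid, "twas_Z_sign": int(np.sign(tz)),
                     "meta_r_sign": int(np.sign(obs["meta_r"])),
                     "call": call})
    calls = pd.DataFrame(
        rows, columns=["gene_id", "twas_Z_sign", "meta_r_sign", "call"])
    counts = {k: int((calls["call"] == k).sum())
              for k in ("concordant", "discordant", "observed_not_significant")}
    return calls, counts
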