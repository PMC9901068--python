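"""Polytranscriptomic scoring (PTS) and association testing.

A PTS is the transcriptomic analogue of a polygenic score: for each
individual, the sum over genes of the standardized observed expression
Z-score weighted by the gene's TWAS Z-score, after correlation
clumping and p-value thresholding of the TWAS weights. Associations
with case-control status and clinical characteristics are tested by
linear regression with sex as a covariate; observed-scale R2 for
binary outcomes is converted to the liability scale, and per-cohort
estimates are pooled by fixed-effect inverse-variance weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import ivw_pool, obs_to_liability_r2

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_expression",
    "compute_pts",
    "associate",
    "ivw_meta",
    "PtsAssociation",
    "obs_to_liability_r2",
]

BINARY_OUTCOMES = {"case_control", "site_of_onset"}


def standardize_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression Z-scores across samples within one cohort.

    Rows are genes, columns samples; sd uses the n-1 denominator.
    Zero-variance genes are dropped with a warning. Standardization is
    always within cohort: platforms are analysed separately and only
    meta-analysed afterwards.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two samples to standardize")
    mat = expression.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes", (~keep).sum())
    mat = mat[keep]
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=expression.index[keep],
                        columns=expression.columns)


def compute_pts(
    expr_z: pd.DataFrame,
    weights: pd.DataFrame,
    thresholds,
) -> pd.DataFrame:
    """Scores per sample at each TWAS p-value threshold.

    PTS_s = sum over genes with min_p <= t of Z_twas(g) * z(g, s).
    Genes absent from the expression matrix are skipped;
    ``n_genes_used`` is recorded per threshold. A threshold with zero
    overlapping genes yields missing scores with a warning.

    Parameters
    ----------
    expr_z:
        Standardized genes x samples matrix.
    weights:
        gene_id, Z, min_p (clumped/averaged TWAS weights).

    Returns a samples x thresholds frame with ``n_genes_used`` in
    ``.attrs["n_genes_used"]``.
    """
    w = weights.set_index("gene_id")
    overlap = expr_z.index.intersection(w.index)
    if len(overlap) == 0:
        raise ValueError("no genes overlap between weights and expression")
    out = {}
    n_used = {}
    for t in thresholds:
        genes = [g for g in overlap if w.loc[g, "min_p"] <= t]
        n_used[t] = len(genes)
        if not genes:
            logger.warning("threshold %g selects no scored genes", t)
            out[t] = pd.Series(np.nan, index=expr_z.columns)
            continue
        out[t] = expr_z.loc[genes].T @ w.loc[genes, "Z"]
    res = pd.DataFrame(out)
    res.attrs["n_genes_used"] = n_used
    return res


@dataclass
class PtsAssociation:
    """Linear-regression association of a PTS with one outcome."""

    cohort: str
    outcome: str
    threshold: float
    stratum: str
    beta: float
    se: float
    p: float
    r2_obs: float
    r2_liability: float | None
    n: int
    n_genes_used: int
    K: float | None = None
    P: float | None = None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _prepare_outcome(phenotypes: pd.DataFrame, outcome: str) -> pd.Series:
    """Binary outcomes coded 0/1: control/spinal = 0, case/bulbar = 1."""
    if outcome == "case_control":
        return phenotypes["case"].astype(float)
    cases = phenotypes[phenotypes["case"] == 1]
    if outcome == "site_of_onset":
        y = cases["site_of_onset"].map({"spinal": 0.0, "bulbar": 1.0})
        return y.dropna()
    if outcome in {"age_at_onset", "survival"}:
        return cases[outcome].dropna().astype(float)
    raise ValueError(f"unknown outcome {outcome!r}")


def associate(
    pts: pd.Series,
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("sex",),
    prevalence: float | None = None,
    cohort: str = "",
    threshold: float = np.nan,
    stratum: str = "all",
    n_genes_used: int = 0,
) -> PtsAssociation:
    """OLS of outcome on PTS plus covariates.

    Clinical outcomes (site of onset, age at onset, survival) are
    tested within cases only. R2_obs is the incremental R2 of the PTS
    over the covariate-only model. Binary outcomes stay in a linear
    model — the liability conversion presumes an observed-scale linear
    R2 — and are converted with the stated prevalence ``K`` and the
    realised case fraction ``P``.
    """
    phen = phenotypes.set_index("sample_id")
    y = _prepare_outcome(phen, outcome)
    idx = y.index.intersection(pts.dropna().index)
    y = y.loc[idx]
    if y.nunique() <= 1:
        raise ValueError(f"outcome {outcome!r} is constant in the analysed samples")
    X = pd.DataFrame({"pts": pts.loc[idx]})
    for cov in covariates:
        X[cov] = phen.loc[idx, cov].astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("more parameters than samples")

    full = sm.OLS(y, sm.add_constant(X)).fit()
    if covariates:
        cov_only = sm.OLS(y, sm.add_constant(X[list(covariates)])).fit()
        r2_obs = max(0.0, full.rsquared - cov_only.rsquared)
    else:
        r2_obs = full.rsquared
    beta = float(full.params["pts"])
    se = float(full.bse["pts"])
    p = float(full.pvalues["pts"])

    r2_liab = None
    K = P = None
    if outcome in BINARY_OUTCOMES:
        if prevalence is None:
            raise ValueError(f"binary outcome {outcome!r} needs a prevalence K")
        K = prevalence
        P = float(y.mean())
        r2_liab = obs_to_liability_r2(min(r2_obs, 1.0), K, P)
    return PtsAssociation(
        cohort=cohort, outcome=outcome, threshold=float(threshold),
        stratum=stratum, beta=beta, se=se, p=p, r2_obs=float(r2_obs),
        r2_liability=r2_liab, n=int(len(y)), n_genes_used=n_genes_used,
        K=K, P=P,
    )


def ivw_meta(results: list[PtsAssociation]) -> dict:
    """Pool per-cohort associations for one outcome/threshold/stratum.

    Returns pooled beta/se/p plus sample-size-weighted mean R2
    summaries (observed and, for binary outcomes, liability scale).
    """
    if not results:
        raise ValueError("nothing to pool")
    keyset = {(r.outcome, r.threshold, r.stratum) for r in results}
    if len(keyset) != 1:
        raise ValueError(f"mismatched results in meta-analysis: {keyset}")
    beta, se, p = ivw_pool([r.beta for r in results], [r.se for r in results])
    n = sum(r.n for r in results)
    r2_obs = float(np.average([r.r2_obs for r in results],
                              weights=[r.n for r in results]))
    r2_liab = None
    if all(r.r2_liability is not None for r in results):
        r2_liab = float(np.average([r.r2_liability for r in results],
                                   weights=[r.n for r in results]))
    out = results[0].to_dict()
    out.update(cohort="meta", beta=beta, se=se, p=p, n=n,
               r2_obs=r2_obs, r2_liability=r2_liab)
    return out
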