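"""Directional drug-repurposing enrichment and ATC-class testing.

Drug-gene interactions are coded −1/0/+1 from their action labels.
Per-drug enrichment regresses gene-level TWAS Z-scores on the drug's
coded direction vector by generalized least squares, with the error
covariance set to the predicted-expression correlation matrix of the
tested genes (identity off known pairs), so co-regulated genes do not
count as independent evidence. The reported enrichment Z is the
negated slope Z: a positive value means the drug's induced expression
profile is predicted to reduce disease risk. Per-drug statistics from
external unsigned methods (MAGMA- or GCSC-style) can be ingested on
the same footing. Class-level signal is tested per ATC level-3 group
with a Wilcoxon rank-sum against all other drugs — one-sided for the
unsigned external methods, two-sided with a signed group Z for the
directional statistic — with BH correction across tested groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, p_to_z, z_to_p

logger = logging.getLogger(__name__)

__all__ = [
    "code_directions",
    "directional_enrichment",
    "import_external_enrichment",
    "fdr_drugs",
    "atc_wilcoxon",
    "DIRECTION_CODES",
]

DIRECTION_CODES = {
    "DECREASED_EXPRESSION": -1,
    "NEGATIVE_RESPONSE": -1,
    "OPPOSITE_RESPONSE": -1,
    "INCREASED_EXPRESSION": 1,
    "POSITIVE_RESPONSE": 1,
}


def code_directions(interactions: pd.DataFrame) -> pd.DataFrame:
    """Attach the −1/0/+1 direction code implied by each action label.

    The three decrease labels map to −1, the two increase labels to
    +1; anything else (non-directional evidence) codes 0. Total and
    idempotent: recoding a coded table is a no-op.
    """
    df = interactions.copy()
    labels = df["action_label"].astype(str)
    df["direction"] = labels.map(DIRECTION_CODES).fillna(0).astype(int)
    unknown = sorted(set(labels) - set(DIRECTION_CODES))
    if unknown:
        logger.info("labels coded 0 (no directional evidence): %s", unknown)
    return df


def _correlation_submatrix(genes: list[str], gene_corr: pd.DataFrame | None
                           ) -> np.ndarray:
    """Gene-gene predicted-expression correlation, identity off known
    pairs."""
    n = len(genes)
    S = np.eye(n)
    if gene_corr is None or gene_corr.empty:
        return S
    pos = {g: i for i, g in enumerate(genes)}
    for _, row in gene_corr.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        if a in pos and b in pos:
            S[pos[a], pos[b]] = S[pos[b], pos[a]] = row["r"]
    return S


def directional_enrichment(
    twas_genes: pd.DataFrame,
    coded_interactions: pd.DataFrame,
    gene_corr: pd.DataFrame | None = None,
    min_genes: int = 2,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Per-drug directional enrichment by co-regulation-aware GLS.

    For each drug, gene-level TWAS Z-scores over the full universe of
    genes with available statistics are regressed on the drug's coded
    direction vector (0 for genes the drug does not directionally
    target, matching the 0-coding of non-directional evidence), with
    error covariance equal to the predicted-expression correlation
    matrix (identity off known pairs). The slope test is the enrichment
    statistic, negated so that a drug whose direction opposes the
    risk-raising expression signature scores positive (protective);
    its p-value uses the t reference with n - 2 degrees of freedom.

    Parameters
    ----------
    twas_genes:
        Per-gene TWAS statistics with columns gene_id, Z (positive =
        increased expression raises risk). Defines the gene universe.
    coded_interactions:
        ``code_directions`` output (drug_id, gene_id, direction).
    gene_corr:
        Optional long frame gene_a, gene_b, r of predicted-expression
        correlations; unknown pairs are treated as uncorrelated.
    min_genes:
        Drugs interacting with fewer genes that have TWAS statistics
        are skipped (the at-least-2-genes rule).

    Returns drug_id, method='directional_twas', Z, p, n_genes_tested.
    """
    universe = list(twas_genes["gene_id"])
    zmap = twas_genes.set_index("gene_id")["Z"]
    y = zmap.loc[universe].to_numpy(dtype=float)
    n = len(universe)
    pos = {g: i for i, g in enumerate(universe)}
    S = _correlation_submatrix(universe, gene_corr)
    try:
        Si = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        logger.warning("singular gene covariance; ridge %.1e added", ridge)
        Si = np.linalg.inv(S + ridge * np.eye(n))
    ones = np.ones(n)
    Si_ones = Si @ ones
    Si_y = Si @ y
    dof = n - 2

    rows = []
    for drug, grp in coded_interactions.groupby("drug_id", sort=True):
        grp = grp[grp["gene_id"].isin(zmap.index)].drop_duplicates("gene_id")
        if len(grp) < min_genes:
            continue
        d = np.zeros(n)
        for g, c in zip(grp["gene_id"], grp["direction"]):
            d[pos[g]] = c
        if np.all(d == d[0]):
            # no contrast against the intercept: slope inestimable
            continue
        Si_d = Si @ d
        A = np.array([[ones @ Si_ones, ones @ Si_d],
                      [d @ Si_ones, d @ Si_d]])
        try:
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            cov = np.linalg.inv(A + ridge * np.eye(2))
        beta = cov @ np.array([ones @ Si_y, d @ Si_y])
        resid = y - beta[0] - beta[1] * d
        sigma2 = float(resid @ Si @ resid / dof) if dof > 0 else 1.0
        se = float(np.sqrt(max(sigma2 * cov[1, 1], 1e-300)))
        t_slope = float(beta[1] / se)
        z_enrich = -t_slope  # positive = predicted risk reduction
        p = 2.0 * sps.t.sf(abs(t_slope), dof) if dof > 0 else \
            float(z_to_p(t_slope))
        rows.append({
            "drug_id": drug, "method": "directional_twas",
            "Z": z_enrich,
            # floor keeps extreme statistics inside (0, 1] for BH
            "p": max(float(p), 1e-300),
            "n_genes_tested": len(grp),
        })
    return pd.DataFrame(
        rows, columns=["drug_id", "method", "Z", "p", "n_genes_tested"])


def import_external_enrichment(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Normalize per-drug statistics from an external unsigned method.

    ``method`` must be 'external_magma' or 'external_gcsc'. Missing Z
    is back-filled from p as the one-sided normal quantile (unsigned
    methods: larger Z = stronger enrichment).
    """
    if method not in {"external_magma", "external_gcsc"}:
        raise ValueError(f"unknown external method {method!r}")
    df = table.copy()
    if df["drug_id"].duplicated().any():
        raise ValueError("duplicate drug rows in external table")
    has_z = "Z" in df.columns and df["Z"].notna().all()
    has_p = "p" in df.columns and df["p"].notna().all()
    if not has_z and not has_p:
        raise ValueError("external table needs a Z or p column")
    if not has_z:
        df["Z"] = p_to_z(df["p"].to_numpy(), one_sided=True)
    if not has_p:
        df["p"] = np.maximum(sps.norm.sf(df["Z"].to_numpy()), 1e-300)
    df["method"] = method
    if "n_genes_tested" not in df.columns:
        df["n_genes_tested"] = np.nan
    return df[["drug_id", "method", "Z", "p", "n_genes_tested"]]


def fdr_drugs(enrichments: pd.DataFrame) -> pd.DataFrame:
    """BH q-values across drugs, stratified by method."""
    df = enrichments.copy()
    df["q"] = np.nan
    for _, idx in df.groupby("method").groups.items():
        df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"])
    return df


def atc_wilcoxon(
    enrichments: pd.DataFrame,
    atc_map: pd.DataFrame,
    method: str,
    min_drugs: int = 5,
) -> pd.DataFrame:
    """ATC level-3 class enrichment by Wilcoxon rank-sum.

    Tests drugs in each group against all other drugs with statistics
    for ``method``. One-sided (greater) for the external unsigned
    methods; two-sided for the directional statistic, reporting a
    signed group Z (positive = the class is predicted to reduce risk).
    Groups with fewer than ``min_drugs`` drugs are skipped; BH across
    tested groups.

    scipy's exact Mann-Whitney null is used for small untied samples
    and the tie-corrected normal approximation otherwise.
    """
    df = enrichments[enrichments["method"] == method].merge(
        atc_map[["drug_id", "atc_code"]], on="drug_id", how="inner")
    if df["drug_id"].duplicated().any():
        raise ValueError("each drug must map to exactly one ATC code")
    one_sided = method in {"external_magma", "external_gcsc"}
    rows = []
    for code, grp in df.groupby("atc_code", sort=True):
        if len(grp) < min_drugs:
            continue
        rest = df[df["atc_code"] != code]
        if rest.empty:
            continue
        x = grp["Z"].to_numpy()
        y = rest["Z"].to_numpy()
        alt = "greater" if one_sided else "two-sided"
        res = sps.mannwhitneyu(x, y, alternative=alt, method="auto")
        u = float(res.statistic)
        mu = len(x) * len(y) / 2.0
        direction = 1.0 if u >= mu else -1.0
        p = float(res.pvalue)
        if one_sided:
            z = float(p_to_z(min(max(p, 1e-300), 1 - 1e-16)))
        else:
            z = direction * float(p_to_z(min(max(p / 2, 1e-300), 1 - 1e-16)))
        rows.append({
            "atc_code": code, "method": method, "n_drugs_in_group": len(grp),
            "statistic": u, "Z": z, "p": p,
        })
    out = pd.DataFrame(
        rows, columns=["atc_code", "method", "n_drugs_in_group",
                       "statistic", "Z", "p"])
    if out.empty:
        logger.warning("no ATC group passes the %d-drug filter", min_drugs)
        out["q"] = pd.Series(dtype=float)
        return out
    out["q"] = bh_adjust(out["p"])
    return out
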