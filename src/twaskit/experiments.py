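"""Replicated simulation experiments over the synthetic study.

These are the calibration and parameter-recovery studies the package
uses to validate itself: PTS liability-R2 recovery across an effect
grid, null calibration of the PTS association test, false-positive
control of the drug/ATC enrichment layers, and separation of planted
protective drugs. Each replicate is a pure function of its seed.

The recovery and calibration experiments score unclumped per-gene
averaged TWAS weights: the generator draws unlinked variants, so
cross-locus predicted-expression correlation carries no confounding
here and the clump step (validated separately against an exhaustive
oracle) would only drop near-duplicate panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import drugs as dr
from . import pts as pt
from .config import SyntheticConfig
from .synthetic import (
    generate_drug_database,
    generate_expression_cohorts,
    generate_gene_map,
    generate_twas_results,
)

__all__ = [
    "pts_recovery_replicate",
    "pts_recovery_grid",
    "pts_null_calibration",
    "drug_null_calibration",
    "protective_drug_separation",
]

PREV_CASE_CONTROL = 1.0 / 300.0


def _gene_weights(associations: pd.DataFrame) -> pd.DataFrame:
    g = associations.groupby("gene_id").agg(Z=("Z", "mean"), min_p=("p", "min"))
    return g.reset_index()


def pts_recovery_replicate(
    de_effect_size: float,
    seed: int,
    n_genes: int = 500,
    n_cases: int = 300,
    n_controls: int = 300,
    prop_concordant: float = 1.0,
) -> float:
    """One two-cohort replicate; returns the meta liability R2 of the
    case-control PTS (all genes, threshold p <= 1)."""
    cfg = SyntheticConfig(
        n_genes=n_genes, n_chromosomes=5, n_panels=2, n_ref_samples=50,
        snps_per_gene=2, prop_signal_genes=0.10, twas_effect_sd=5.0,
        prop_coloc=0.6, n_cases=n_cases, n_controls=n_controls,
        de_effect_size=de_effect_size, prop_concordant=prop_concordant,
        seed=seed)
    gene_map = generate_gene_map(cfg)
    assoc, _, truth = generate_twas_results(cfg, gene_map)
    expression, phenotypes, truth = generate_expression_cohorts(cfg, truth)
    weights = _gene_weights(assoc)
    per_cohort = []
    for cohort, expr in expression.items():
        z = pt.standardize_expression(expr)
        scores = pt.compute_pts(z, weights, [1.0])
        res = pt.associate(
            scores[1.0], phenotypes[cohort], "case_control",
            prevalence=PREV_CASE_CONTROL, cohort=cohort, threshold=1.0,
            n_genes_used=scores.attrs["n_genes_used"][1.0])
        per_cohort.append(res)
    pooled = pt.ivw_meta(per_cohort)
    return float(pooled["r2_liability"])


def pts_recovery_grid(
    effects=(0.0, 0.1, 0.2, 0.3, 0.5),
    n_replicates: int = 50,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Liability-R2 recovery across a case-control effect grid.

    Returns a long frame (de_effect_size, replicate, r2_liability)
    plus Spearman rho between effect and R2 in ``.attrs``.
    """
    rows = []
    for ei, eff in enumerate(effects):
        for rep in range(n_replicates):
            rep_seed = (seed * 100_003 + ei * 1_009 + rep) % (2**31)
            r2 = pts_recovery_replicate(eff, rep_seed, **kwargs)
            rows.append({"de_effect_size": eff, "replicate": rep,
                         "r2_liability": r2})
    out = pd.DataFrame(rows)
    rho = sps.spearmanr(out["de_effect_size"], out["r2_liability"]).statistic
    out.attrs["spearman_rho"] = float(rho)
    return out


def expected_null_r2_liability(n: int, K: float = PREV_CASE_CONTROL,
                               P: float = 0.5) -> float:
    """Analytic null expectation of the incremental liability R2.

    Adding one independent regressor to a model with k covariates
    inflates observed R2 by 1/(n - k - 1) in expectation; with the sex
    covariate k = 1. The liability transform is effectively linear at
    this magnitude, slope C.
    """
    from .stats import obs_to_liability_r2

    r2_obs = 1.0 / (n - 2)
    return obs_to_liability_r2(r2_obs, K, P)


def pts_null_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    n_genes: int = 200,
    n_cases: int = 150,
    n_controls: int = 150,
) -> pd.DataFrame:
    """Association p-values of the case-control PTS when expression
    carries no case-control signal (de_effect_size = 0)."""
    rows = []
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            n_genes=n_genes, n_chromosomes=4, n_panels=2, n_ref_samples=50,
            snps_per_gene=2, prop_signal_genes=0.10, twas_effect_sd=5.0,
            n_cases=n_cases, n_controls=n_controls, de_effect_size=0.0,
            seed=(seed * 99_991 + rep) % (2**31))
        gene_map = generate_gene_map(cfg)
        assoc, _, truth = generate_twas_results(cfg, gene_map)
        expression, phenotypes, _ = generate_expression_cohorts(cfg, truth)
        weights = _gene_weights(assoc)
        cohort = next(iter(expression))
        z = pt.standardize_expression(expression[cohort])
        scores = pt.compute_pts(z, weights, [1.0])
        res = pt.associate(scores[1.0], phenotypes[cohort], "case_control",
                           prevalence=PREV_CASE_CONTROL)
        rows.append({"replicate": rep, "p": res.p,
                     "r2_liability": res.r2_liability, "n": res.n})
    return pd.DataFrame(rows)


def drug_null_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    n_genes: int = 120,
    n_drugs: int = 48,
    n_atc_groups: int = 8,
) -> pd.DataFrame:
    """False-positive rates of the drug FDR and ATC Wilcoxon layers
    under a global null: no TWAS signal, no planted protective drugs
    (equivalent to permuting drug labels against null statistics)."""
    rows = []
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            n_genes=n_genes, n_chromosomes=4, n_panels=2, n_ref_samples=50,
            snps_per_gene=2, prop_signal_genes=0.0, twas_effect_sd=0.0,
            n_drugs=n_drugs, n_atc_groups=n_atc_groups,
            genes_per_drug_mean=5.0, prop_protective_drugs=0.0,
            n_enriched_atc=0, seed=(seed * 7_919 + rep) % (2**31))
        gene_map = generate_gene_map(cfg)
        assoc, _, truth = generate_twas_results(cfg, gene_map)
        drug_gene, truth = generate_drug_database(cfg, truth)
        coded = dr.code_directions(drug_gene)
        enr = dr.directional_enrichment(_gene_weights(assoc), coded)
        if enr.empty:
            continue
        enr = dr.fdr_drugs(enr)
        atc_map = drug_gene[["drug_id", "atc_code"]].drop_duplicates()
        atc = dr.atc_wilcoxon(enr, atc_map, "directional_twas", min_drugs=5)
        rows.append({
            "replicate": rep,
            "n_drugs_tested": len(enr),
            "frac_drugs_fdr_sig": float((enr["q"] < 0.05).mean()),
            "n_atc_tested": len(atc),
            "frac_atc_fdr_sig": float((atc["q"] < 0.05).mean()) if len(atc)
            else 0.0,
        })
    return pd.DataFrame(rows)


def protective_drug_separation(
    n_replicates: int = 50,
    seed: int = 0,
    n_genes: int = 120,
    n_drugs: int = 60,
) -> pd.DataFrame:
    """Mean directional enrichment Z of planted protective vs neutral
    drugs, one row per replicate synthetic database."""
    rows = []
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            n_genes=n_genes, n_chromosomes=4, n_panels=2, n_ref_samples=50,
            snps_per_gene=2, prop_signal_genes=0.25, twas_effect_sd=5.0,
            n_drugs=n_drugs, n_atc_groups=6, genes_per_drug_mean=5.0,
            prop_protective_drugs=0.2, drug_direction_consistency=0.9,
            seed=(seed * 104_729 + rep) % (2**31))
        gene_map = generate_gene_map(cfg)
        assoc, _, truth = generate_twas_results(cfg, gene_map)
        drug_gene, truth = generate_drug_database(cfg, truth)
        coded = dr.code_directions(drug_gene)
        enr = dr.directional_enrichment(_gene_weights(assoc), coded)
        merged = enr.merge(truth.drugs[["drug_id", "drug_class"]], on="drug_id")
        by = merged.groupby("drug_class")["Z"].mean()
        if {"protective", "neutral"} <= set(by.index):
            rows.append({"replicate": rep,
                         "mean_z_protective": float(by["protective"]),
                         "mean_z_neutral": float(by["neutral"])})
    return pd.DataFrame(rows)
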