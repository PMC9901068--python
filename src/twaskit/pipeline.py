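"""End-to-end orchestration: simulate, call genes, clump, score, enrich
drugs, and compare predicted vs observed expression, from one config.

Every stage writes plain-text tables into the output directory; the run
manifest records each file with a content checksum, so re-running with
an identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clump as cl
from . import concordance as cc
from . import drugs as dr
from . import genes as gn
from . import pts as pt
from .config import PipelineConfig
from .io import write_study, write_table
from .synthetic import generate_study, SyntheticStudy

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "demo_config", "pts_stage", "clump_stage"]

STRATA = [("all", False), ("blood", False), ("brain", False),
          ("all", True), ("blood", True), ("brain", True)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stratum_name(tissue: str, coloc_only: bool) -> str:
    return f"{tissue}_{'coloc' if coloc_only else 'any'}"


def clump_stage(study: SyntheticStudy, config: PipelineConfig):
    """Predicted expression, windowed correlations, and the gene-level
    correlation table used by the drug GLS."""
    predicted = cl.predict_expression(study.weights, study.genotypes,
                                      study.variants)
    correlations = cl.pairwise_predicted_correlation(
        predicted, study.gene_map, window_bp=config.window_bp,
        anchor=config.window_anchor)
    # gene-level predicted expression: mean of a gene's unit vectors,
    # restandardized, for the co-regulation covariance of the drug test
    by_gene: dict[str, list[str]] = {}
    for col in predicted.columns:
        by_gene.setdefault(col.split("::")[0], []).append(col)
    gmat = {}
    for gid, cols in by_gene.items():
        v = predicted[cols].mean(axis=1)
        sd = v.std(ddof=1)
        if sd > 0:
            gmat[f"{gid}::gene"] = (v - v.mean()) / sd
    gene_pred = pd.DataFrame(gmat)
    gcorr_units = cl.pairwise_predicted_correlation(
        gene_pred, study.gene_map, window_bp=config.window_bp,
        anchor=config.window_anchor)
    gene_corr = pd.DataFrame({
        "gene_a": [u.split("::")[0] for u in gcorr_units["unit_a"]],
        "gene_b": [u.split("::")[0] for u in gcorr_units["unit_b"]],
        "r": gcorr_units["r"],
    })
    return predicted, correlations, gene_corr


def pts_weights_for_stratum(
    associations: pd.DataFrame,
    correlations: pd.DataFrame,
    tissue: str,
    coloc_only: bool,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Filter associations to a stratum, clump, and average duplicates."""
    sub = associations
    if tissue != "all":
        sub = sub[sub["tissue_class"] == tissue]
    if coloc_only:
        sub = sub[sub["coloc_pp4"] > 0.8]
    if sub.empty:
        return pd.DataFrame(columns=["gene_id", "Z", "min_p", "n_panels"])
    result = cl.clump(sub, correlations, r_thresh=config.r_thresh)
    return cl.average_duplicate_genes(result)


def pts_stage(
    study: SyntheticStudy,
    correlations: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every cohort across strata and thresholds; associate with
    all outcomes; IVW-pool across cohorts.

    Returns (per-cohort association table, meta table).
    """
    prevalence = {"case_control": config.prevalence_case_control,
                  "site_of_onset": config.prevalence_onset}
    expr_z = {c: pt.standardize_expression(e)
              for c, e in study.expression.items()}
    rows = []
    meta_rows = []
    for tissue, coloc_only in STRATA:
        weights = pts_weights_for_stratum(
            study.associations, correlations, tissue, coloc_only, config)
        if weights.empty:
            continue
        stratum = _stratum_name(tissue, coloc_only)
        scores = {c: pt.compute_pts(z, weights, config.p_thresholds)
                  for c, z in expr_z.items()}
        for outcome in ("case_control", "site_of_onset", "age_at_onset",
                        "survival"):
            for t in config.p_thresholds:
                per_cohort = []
                for cohort, sc in scores.items():
                    if sc[t].isna().all():
                        continue
                    try:
                        res = pt.associate(
                            sc[t], study.phenotypes[cohort], outcome,
                            prevalence=prevalence.get(outcome),
                            cohort=cohort, threshold=t, stratum=stratum,
                            n_genes_used=sc.attrs["n_genes_used"][t])
                    except ValueError:
                        continue
                    per_cohort.append(res)
                    rows.append(res.to_dict())
                if per_cohort:
                    meta_rows.append(pt.ivw_meta(per_cohort))
    return pd.DataFrame(rows), pd.DataFrame(meta_rows)


def drug_stage(
    study: SyntheticStudy,
    gene_weights: pd.DataFrame,
    gene_corr: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional per-drug enrichment plus the ATC Wilcoxon layer."""
    coded = dr.code_directions(study.drug_gene)
    enr = dr.directional_enrichment(
        gene_weights.rename(columns={"Z": "Z"}), coded, gene_corr,
        min_genes=config.min_genes_per_drug)
    enr = dr.fdr_drugs(enr)
    atc_map = study.drug_gene[["drug_id", "atc_code"]].drop_duplicates()
    atc = dr.atc_wilcoxon(enr, atc_map, "directional_twas",
                          min_drugs=config.min_drugs_per_atc)
    return enr, atc


def de_stage(study: SyntheticStudy, high_conf: pd.DataFrame,
             associations: pd.DataFrame, config: PipelineConfig):
    """Observed DE per cohort, IVW meta, and concordance calls."""
    per_cohort = {}
    for cohort, expr in study.expression.items():
        status = study.phenotypes[cohort]["case"].to_numpy()
        per_cohort[cohort] = cc.de_correlation(expr, status)
    de_meta = cc.meta_de(per_cohort)
    mean_z = associations.groupby("gene_id")["Z"].mean()
    hc = high_conf.assign(
        twas_Z=high_conf["gene_id"].map(mean_z).fillna(0.0))
    calls, counts = cc.classify_concordance(hc, de_meta, fdr=config.fdr)
    return per_cohort, de_meta, calls, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    study = generate_study(config.synthetic)
    input_files = write_study(study, out / "inputs")

    assoc = gn.fdr_correct(study.associations)
    high_conf = gn.call_high_confidence(
        assoc, study.credible_sets, study.gene_map,
        fdr_threshold=config.fdr, coloc_ratio=config.coloc_ratio,
        heidi_alpha=config.heidi_alpha)
    write_table(high_conf, out / "high_confidence_genes.tsv")

    predicted, correlations, gene_corr = clump_stage(study, config)
    write_table(correlations, out / "predicted_correlations.tsv")
    all_result = cl.clump(assoc, correlations, r_thresh=config.r_thresh)
    gene_weights = cl.average_duplicate_genes(all_result)
    write_table(gene_weights, out / "pts_weights_all.tsv")
    write_table(all_result.removed, out / "clump_removed.tsv")

    assoc_tbl, meta_tbl = pts_stage(study, correlations, config)
    write_table(assoc_tbl, out / "pts_associations.tsv")
    write_table(meta_tbl, out / "pts_meta.tsv")

    drug_enr, atc_enr = drug_stage(study, gene_weights, gene_corr, config)
    write_table(drug_enr, out / "drug_enrichment.tsv")
    write_table(atc_enr, out / "atc_enrichment.tsv")

    per_de, de_meta, calls, counts = de_stage(study, high_conf, assoc, config)
    for cohort, de in per_de.items():
        write_table(de, out / f"de_{cohort}.tsv")
    write_table(de_meta, out / "de_meta.tsv")
    write_table(calls, out / "concordance_calls.tsv")

    manifest = {
        "config": config.to_dict(),
        "counts": {
            "high_confidence_genes": int(len(high_conf)),
            "clump_retained": int(len(all_result.retained)),
            "clump_removed": int(len(all_result.removed)),
            "drugs_tested": int(len(drug_enr)),
            "atc_groups_tested": int(len(atc_enr)),
            **{f"concordance_{k}": v for k, v in counts.items()},
        },
        "files": {},
        "warnings": warnings_log,
    }
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            rel = str(f.relative_to(out))
            manifest["files"][rel] = _sha256(f)
    _ = input_files
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def demo_config(out_dir: str = "results/demo", seed: int = 0) -> PipelineConfig:
    """Small, fast configuration exercising every stage."""
    from .config import SyntheticConfig

    synth = SyntheticConfig(
        n_genes=120, n_chromosomes=3, n_panels=4, n_ref_samples=200,
        snps_per_gene=4, prop_signal_genes=0.15, twas_effect_sd=5.0,
        prop_coloc=0.6, n_cases=120, n_controls=120, de_effect_size=0.4,
        prop_concordant=0.8, n_drugs=80, n_atc_groups=8,
        genes_per_drug_mean=4.0, prop_protective_drugs=0.15, seed=seed)
    return PipelineConfig(synthetic=synth, out_dir=out_dir, seed=seed)
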