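"""Synthetic study generator with embedded ground truth.

Generates every input the pipeline consumes — gene map, reference
genotypes, SNP-weight models, TWAS/PWAS association tables, two
case-control expression cohorts on distinct array platforms, and a
directional drug-gene interaction database with ATC level-3 codes —
so the full analysis runs with no external downloads. Every output is
a pure function of (config, seed): stage-specific generators derive
independent streams from the config seed, so regenerating one stage
never perturbs another.

Coordinates are 1-based inclusive throughout. Reference minor allele
frequencies are Uniform(0.05, 0.5) and variants are unlinked:
linkage realism is unnecessary because clumping operates on
predicted-expression correlation, which is induced through shared
weight vectors, not LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SyntheticConfig
from .stats import z_to_p

__all__ = [
    "GroundTruth",
    "SyntheticStudy",
    "generate_gene_map",
    "generate_reference_genotypes",
    "generate_twas_results",
    "generate_expression_cohorts",
    "generate_drug_database",
    "generate_credible_sets",
    "generate_study",
    "DIRECTION_DECREASE_LABELS",
    "DIRECTION_INCREASE_LABELS",
    "NONDIRECTIONAL_LABELS",
]

# Directional vocabulary of the drug-gene interaction source database.
DIRECTION_DECREASE_LABELS = (
    "DECREASED_EXPRESSION",
    "NEGATIVE_RESPONSE",
    "OPPOSITE_RESPONSE",
)
DIRECTION_INCREASE_LABELS = ("INCREASED_EXPRESSION", "POSITIVE_RESPONSE")
NONDIRECTIONAL_LABELS = ("BINDING", "MODULATOR", "AFFECTS_RESPONSE")

COHORT_IDS = ("GPL6947", "GPL10558")

# Per-stage offsets mixed into the seed so stages draw independent streams.
_STAGE = {"gene_map": 1, "genotypes": 2, "twas": 3, "cohorts": 4, "drugs": 5,
          "credible_sets": 6}


def _rng(config: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), _STAGE[stage]])


@dataclass
class GroundTruth:
    """Planted truths recorded alongside the generated data."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # gene_id, is_signal, true_direction, true_mu, is_coloc, true_shift
    drugs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # drug_id, drug_class in {protective, neutral}
    atc: pd.DataFrame = field(default_factory=pd.DataFrame)
    # atc_code, enriched

    @property
    def signal_gene_ids(self) -> set[str]:
        g = self.genes
        return set(g.loc[g["is_signal"], "gene_id"]) if len(g) else set()


def generate_gene_map(config: SyntheticConfig) -> pd.DataFrame:
    """Place non-overlapping genes on chromosomes.

    Genes are sorted by position within chromosome, with gaps short
    enough that many neighbours fall inside a 500 kb proximity window.

    Returns a frame with columns gene_id, chrom, start, end
    (1-based inclusive).
    """
    rng = _rng(config, "gene_map")
    per_chrom = [len(a) for a in np.array_split(np.arange(config.n_genes),
                                               config.n_chromosomes)]
    rows = []
    gene_idx = 0
    for ci, n_on_chrom in enumerate(per_chrom, start=1):
        # worst case space: n * (max gene length + max gap)
        if n_on_chrom * (50_000 + 200_000) > config.chrom_length_bp:
            raise ValueError(
                f"cannot place {n_on_chrom} genes on a "
                f"{config.chrom_length_bp} bp chromosome without overlap"
            )
        pos = 1
        for _ in range(n_on_chrom):
            gap = int(rng.integers(10_000, 200_001))
            length = int(rng.integers(5_000, 50_001))
            start = pos + gap
            rows.append(
                {"gene_id": f"GENE{gene_idx:04d}", "chrom": f"chr{ci}",
                 "start": start, "end": start + length - 1}
            )
            pos = start + length - 1
            gene_idx += 1
    return pd.DataFrame(rows)


def generate_reference_genotypes(
    config: SyntheticConfig, gene_map: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate an unlinked reference genotype panel.

    Returns (genotypes, variants): an n_ref_samples x n_variants matrix
    of allele counts in {0, 1, 2}, and a variant table with columns
    variant_id, gene_id, chrom, pos, maf. MAF ~ Uniform(0.05, 0.5);
    each variant lies inside its gene's interval. Zero-variance columns
    are redrawn so every variant is usable for prediction.
    """
    rng = _rng(config, "genotypes")
    var_rows = []
    cols = []
    for _, g in gene_map.iterrows():
        positions = np.sort(
            rng.integers(g["start"], g["end"] + 1, size=config.snps_per_gene)
        )
        for j, pos in enumerate(positions):
            maf = rng.uniform(0.05, 0.5)
            col = rng.binomial(2, maf, size=config.n_ref_samples)
            tries = 0
            while col.std() == 0 and tries < 10:
                col = rng.binomial(2, maf, size=config.n_ref_samples)
                tries += 1
            var_rows.append(
                {"variant_id": f"{g['gene_id']}_v{j}", "gene_id": g["gene_id"],
                 "chrom": g["chrom"], "pos": int(pos), "maf": maf}
            )
            cols.append(col)
    genotypes = np.column_stack(cols)
    return genotypes, pd.DataFrame(var_rows)


def _assign_panels(config: SyntheticConfig) -> pd.DataFrame:
    """Panel metadata: id, tissue class (cycled), method (alternating)."""
    tissues = list(config.panel_tissue_classes)
    rows = []
    for i in range(config.n_panels):
        rows.append(
            {"panel_id": f"PANEL{i}",
             "tissue_class": tissues[i % len(tissues)],
             "method": "FUSION" if i % 2 == 0 else "SMR",
             "molecular_type": "expression"}
        )
    return pd.DataFrame(rows)


def generate_twas_results(
    config: SyntheticConfig, gene_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate TWAS association tables plus SNP-weight models.

    Signal genes carry Z ~ Normal(direction * |effect|, 1) with the
    effect magnitude drawn from |Normal(0, twas_effect_sd)|; null genes
    are standard normal. p is the exact two-sided tail of Z. The
    colocalised subset of signal genes receives high PP4 (Beta near 1)
    and HEIDI p above 0.05. Genes recur across panels at
    ``panel_dup_rate``; duplicated weight vectors are near-identical
    with probability ``cross_panel_similarity`` so predicted-expression
    correlations span [0, 1].

    Returns (associations, weights, truth).
    """
    rng = _rng(config, "twas")
    panels = _assign_panels(config)
    n = config.n_genes
    n_signal = int(round(config.prop_signal_genes * n))
    if config.prop_signal_genes > 0 and n_signal < 1:
        warnings.warn("prop_signal_genes * n_genes < 1: emitting a pure-null dataset")
    gene_ids = gene_map["gene_id"].to_numpy()
    signal_idx = rng.choice(n, size=n_signal, replace=False)
    is_signal = np.zeros(n, dtype=bool)
    is_signal[signal_idx] = True
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    magnitude = np.abs(rng.normal(0.0, config.twas_effect_sd, size=n))
    mu = np.where(is_signal, direction * magnitude, 0.0)

    coloc = np.zeros(n, dtype=bool)
    if n_signal:
        n_coloc = int(round(config.prop_coloc * n_signal))
        coloc[rng.choice(signal_idx, size=n_coloc, replace=False)] = True

    assoc_rows = []
    weight_rows = []
    base_weights: dict[str, np.ndarray] = {}
    for gi in range(n):
        gid = gene_ids[gi]
        n_extra = rng.binomial(config.n_panels - 1, config.panel_dup_rate) \
            if config.n_panels > 1 else 0
        panel_idx = rng.choice(config.n_panels, size=1 + n_extra, replace=False)
        w0 = rng.normal(0.0, 1.0, size=config.snps_per_gene)
        base_weights[gid] = w0
        for k, pi in enumerate(panel_idx):
            prow = panels.iloc[pi]
            z = rng.normal(mu[gi], 1.0)
            p = float(z_to_p(z))
            # draw the coloc ratio PP4/(PP3+PP4) directly so planted
            # colocalised rows always pass the >0.8 rule (with PP4>0.8)
            # and non-coloc rows always fail it
            if coloc[gi]:
                ratio = rng.uniform(0.9, 0.995)
                pp4 = ratio * rng.uniform(0.92, 1.0)
                heidi_p = rng.uniform(0.06, 1.0)
            else:
                ratio = rng.uniform(0.05, 0.75)
                pp4 = ratio * rng.uniform(0.1, 1.0)
                heidi_p = rng.uniform(0.0, 1.0)
            pp3 = pp4 * (1.0 - ratio) / ratio
            row = {
                "gene_id": gid, "panel_id": prow["panel_id"],
                "tissue_class": prow["tissue_class"],
                "method": prow["method"],
                "molecular_type": prow["molecular_type"],
                "Z": z, "p": p,
                "PP3": pp3 if prow["method"] == "FUSION" else np.nan,
                "PP4": pp4 if prow["method"] == "FUSION" else np.nan,
                "heidi_p": heidi_p if prow["method"] == "SMR" else np.nan,
                # generator-side coloc flag usable in PP4>0.8 strata for
                # SMR rows too (real SMR lacks PP4; recorded for scoring)
                "coloc_pp4": pp4,
            }
            assoc_rows.append(row)
            if k == 0 or rng.random() < config.cross_panel_similarity:
                w = w0 + rng.normal(0.0, 1e-3, size=w0.size)
            else:
                w = rng.normal(0.0, 1.0, size=w0.size)
            for j, wj in enumerate(w):
                weight_rows.append(
                    {"gene_id": gid, "panel_id": prow["panel_id"],
                     "variant_id": f"{gid}_v{j}", "weight": wj}
                )

    truth = GroundTruth(
        genes=pd.DataFrame(
            {"gene_id": gene_ids, "is_signal": is_signal,
             "true_direction": np.where(is_signal, np.sign(mu), 0.0),
             "true_mu": mu, "is_coloc": coloc}
        )
    )
    return pd.DataFrame(assoc_rows), pd.DataFrame(weight_rows), truth


def generate_expression_cohorts(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], GroundTruth]:
    """Simulate two case-control blood expression cohorts.

    Emulates a two-platform expression series: log2-scale genes x
    samples matrices with per-sample phenotypes (case status, sex,
    site of onset and age at onset for cases, survival in years).
    For a ``prop_concordant`` subset of signal genes, cases shift by
    +de_effect_size * sign(TWAS direction); the remainder shift
    opposite, creating discordant genes. Survival is uncensored
    log-normal.

    Returns ({cohort: expression}, {cohort: phenotypes}, truth with
    per-gene true shifts filled in).
    """
    if config.n_cases < 1 or config.n_controls < 1:
        raise ValueError("both cohorts need at least one case and one control")
    rng = _rng(config, "cohorts")
    genes = truth.genes["gene_id"].to_numpy()
    is_signal = truth.genes["is_signal"].to_numpy()
    direction = truth.genes["true_direction"].to_numpy()

    concordant = np.zeros(len(genes), dtype=bool)
    sig_idx = np.flatnonzero(is_signal)
    if sig_idx.size:
        n_conc = int(round(config.prop_concordant * sig_idx.size))
        concordant[rng.choice(sig_idx, size=n_conc, replace=False)] = True
    shift_sign = np.where(concordant, direction, -direction)
    true_shift = np.where(is_signal, config.de_effect_size * shift_sign, 0.0)

    truth.genes = truth.genes.assign(
        true_shift=true_shift, concordant=np.where(is_signal, concordant, False)
    )

    expr: dict[str, pd.DataFrame] = {}
    phen: dict[str, pd.DataFrame] = {}
    baseline = rng.normal(8.0, 1.0, size=len(genes))
    for cohort in COHORT_IDS:
        n_s = config.n_cases + config.n_controls
        status = np.r_[np.ones(config.n_cases, int), np.zeros(config.n_controls, int)]
        mat = baseline[:, None] + rng.normal(0.0, 1.0, size=(len(genes), n_s))
        mat += true_shift[:, None] * status[None, :]
        sample_ids = [f"{cohort}_S{i:04d}" for i in range(n_s)]
        expr[cohort] = pd.DataFrame(mat, index=genes, columns=sample_ids)
        sex = rng.integers(0, 2, size=n_s)
        site = np.where(
            status == 1,
            np.where(rng.random(n_s) < 0.3, "bulbar", "spinal"), "")
        age = np.where(status == 1, np.round(rng.normal(60, 10, n_s), 1), np.nan)
        surv = np.where(
            status == 1, np.round(rng.lognormal(np.log(3.0), 0.5, n_s), 2), np.nan)
        phen[cohort] = pd.DataFrame(
            {"sample_id": sample_ids, "case": status, "sex": sex,
             "site_of_onset": site, "age_at_onset": age, "survival": surv}
        )
    return expr, phen, truth


def generate_drug_database(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a directional drug-gene interaction database.

    Each drug carries one ATC level-3 code. Protective drugs
    preferentially target signal genes with an action label whose
    coded direction opposes the gene's TWAS direction (down-regulating
    risk-raising genes); neutral drugs draw genes and labels at
    random, including non-directional labels coded 0. Protective drugs
    are concentrated into ``n_enriched_atc`` groups so a class-level
    signal exists for the ATC Wilcoxon layer.

    Returns (interaction table, truth with drug/ATC labels filled in).
    """
    rng = _rng(config, "drugs")
    genes = truth.genes
    sig = genes.loc[genes["is_signal"]]
    letters = "ACDGJLMNRS"
    atc_codes = [
        f"{letters[i % len(letters)]}{i // len(letters):02d}{chr(65 + i % 26)}"
        for i in range(config.n_atc_groups)
    ]
    n_enriched = min(config.n_enriched_atc, config.n_atc_groups)
    enriched = set(atc_codes[:n_enriched])

    n_protective = int(round(config.prop_protective_drugs * config.n_drugs))
    rows = []
    drug_rows = []
    for di in range(config.n_drugs):
        drug = f"DRUG{di:04d}"
        protective = di < n_protective
        if protective and enriched:
            code = atc_codes[di % n_enriched]
        else:
            code = atc_codes[int(rng.integers(0, config.n_atc_groups))]
        n_targets = max(1, int(rng.poisson(config.genes_per_drug_mean)))
        if protective and len(sig):
            n_from_sig = min(len(sig), max(2, int(round(0.8 * n_targets))))
            target_ids = list(rng.choice(sig["gene_id"], n_from_sig, replace=False))
            n_rest = n_targets - n_from_sig
            if n_rest > 0:
                pool = genes.loc[~genes["gene_id"].isin(target_ids), "gene_id"]
                target_ids += list(rng.choice(pool, min(n_rest, len(pool)),
                                              replace=False))
        else:
            target_ids = list(rng.choice(genes["gene_id"],
                                         min(n_targets, len(genes)), replace=False))
        for gid in target_ids:
            gdir = float(genes.loc[genes["gene_id"] == gid, "true_direction"].iloc[0])
            if protective and gdir != 0 and \
                    rng.random() < config.drug_direction_consistency:
                want = -int(gdir)  # oppose the risk direction
            elif rng.random() < 0.6:
                want = int(rng.choice([-1, 1]))
            else:
                want = 0
            if want == -1:
                label = str(rng.choice(DIRECTION_DECREASE_LABELS))
            elif want == 1:
                label = str(rng.choice(DIRECTION_INCREASE_LABELS))
            else:
                label = str(rng.choice(NONDIRECTIONAL_LABELS))
            rows.append({"drug_id": drug, "gene_id": gid,
                         "action_label": label, "atc_code": code})
        drug_rows.append({"drug_id": drug, "atc_code": code,
                          "drug_class": "protective" if protective else "neutral"})

    truth.drugs = pd.DataFrame(drug_rows)
    drug_by_atc = truth.drugs.groupby("atc_code")["drug_class"]
    truth.atc = pd.DataFrame(
        {"atc_code": atc_codes,
         "enriched": [c in enriched for c in atc_codes]}
    )
    _ = drug_by_atc  # summarised downstream
    return pd.DataFrame(rows), truth


def generate_credible_sets(
    config: SyntheticConfig,
    gene_map: pd.DataFrame,
    truth: GroundTruth,
    n_contained: int = 3,
    n_spanning: int = 2,
) -> pd.DataFrame:
    """Simulate 95% fine-mapping credible sets.

    ``n_contained`` sets fall entirely inside a signal gene's body
    (these genes should be called via the fine-mapping route);
    ``n_spanning`` sets place one variant outside any gene interval,
    so containment fails. Returns a long table locus_id, variant_id,
    chrom, pos (1-based).
    """
    rng = _rng(config, "credible_sets")
    sig = truth.genes.loc[truth.genes["is_signal"], "gene_id"]
    pool = sig if len(sig) >= n_contained else truth.genes["gene_id"]
    n_contained = min(n_contained, len(pool))
    chosen = rng.choice(pool, size=n_contained, replace=False)
    gmap = gene_map.set_index("gene_id")
    rows = []
    locus = 0
    for gid in chosen:
        g = gmap.loc[gid]
        k = int(rng.integers(1, 5))
        positions = rng.integers(g["start"], g["end"] + 1, size=k)
        for j, pos in enumerate(np.sort(positions)):
            rows.append({"locus_id": f"LOCUS{locus:03d}",
                         "variant_id": f"cs{locus}_{j}",
                         "chrom": g["chrom"], "pos": int(pos)})
        locus += 1
    others = gene_map[~gene_map["gene_id"].isin(chosen)]
    for _ in range(min(n_spanning, len(others))):
        g = others.iloc[int(rng.integers(0, len(others)))]
        inside = int(rng.integers(g["start"], g["end"] + 1))
        outside = int(g["end"] + rng.integers(1_000, 5_000))
        for j, pos in enumerate((inside, outside)):
            rows.append({"locus_id": f"LOCUS{locus:03d}",
                         "variant_id": f"cs{locus}_{j}",
                         "chrom": g["chrom"], "pos": pos})
        locus += 1
    return pd.DataFrame(rows, columns=["locus_id", "variant_id", "chrom", "pos"])


@dataclass
class SyntheticStudy:
    """Complete generated study: all inputs plus recorded truth."""

    config: SyntheticConfig
    gene_map: pd.DataFrame
    genotypes: np.ndarray
    variants: pd.DataFrame
    associations: pd.DataFrame
    weights: pd.DataFrame
    expression: dict[str, pd.DataFrame]
    phenotypes: dict[str, pd.DataFrame]
    drug_gene: pd.DataFrame
    credible_sets: pd.DataFrame
    truth: GroundTruth


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Run every generator in order and bundle the results."""
    gene_map = generate_gene_map(config)
    genotypes, variants = generate_reference_genotypes(config, gene_map)
    associations, weights, truth = generate_twas_results(config, gene_map)
    expression, phenotypes, truth = generate_expression_cohorts(config, truth)
    drug_gene, truth = generate_drug_database(config, truth)
    credible_sets = generate_credible_sets(config, gene_map, truth)
    return SyntheticStudy(
        config=config, gene_map=gene_map, genotypes=genotypes,
        variants=variants, associations=associations, weights=weights,
        expression=expression, phenotypes=phenotypes,
        drug_gene=drug_gene, credible_sets=credible_sets, truth=truth,
    )
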