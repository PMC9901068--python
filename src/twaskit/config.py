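"""Configuration objects for the synthetic study and the pipeline.

The synthetic generator emulates the statistical structure of a
post-GWAS ALS analysis: TWAS/PWAS summary tables over multiple
expression panels, a reference genotype panel for predicted-expression
correlations, two case-control blood expression cohorts on different
array platforms, and a directional drug-gene interaction database with
ATC level-3 class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = ["SyntheticConfig", "PipelineConfig"]


@dataclass
class SyntheticConfig:
    """Parameters controlling every synthetic input.

    All downstream inputs are pure functions of this object plus its
    ``seed``; identical config and seed reproduce byte-identical files.

    Parameters
    ----------
    n_genes:
        Number of genes in the gene map.
    n_chromosomes:
        Chromosomes over which genes are spread.
    chrom_length_bp:
        Length budget per chromosome; generation fails if the genes
        cannot be placed without overlap.
    n_panels:
        Number of expression panels (FUSION and SMR alternate).
    panel_tissue_classes:
        Tissue class per panel, cycled if shorter than ``n_panels``.
    n_ref_samples:
        Reference-panel individuals for predicted expression.
    snps_per_gene:
        Variants per gene locus in the reference panel.
    prop_signal_genes:
        Fraction of genes with a true TWAS signal.
    twas_effect_sd:
        Scale of true TWAS effects; a signal gene's mean Z is
        ``direction * |N(0, twas_effect_sd)|``.
    prop_coloc:
        Fraction of signal genes with colocalisation support
        (high PP4, HEIDI p above 0.05).
    panel_dup_rate:
        Probability a gene enters each additional panel beyond its
        first, creating cross-panel duplicates.
    cross_panel_similarity:
        Probability that a duplicated gene's weight vectors are nearly
        identical across panels (predicted-expression r > 0.95),
        exercising the clump/average path.
    n_cases, n_controls:
        Per-cohort sample sizes (two cohorts are generated).
    de_effect_size:
        Standardised case-control expression shift for signal genes.
    prop_concordant:
        Fraction of shifted genes whose observed shift sign matches
        the TWAS direction; the remainder are discordant.
    n_drugs, n_atc_groups:
        Size of the drug-gene interaction database.
    genes_per_drug_mean:
        Poisson mean of targets per drug (floored at 1).
    prop_protective_drugs:
        Fraction of drugs planted as protective (their directional
        codes oppose the risk-raising expression signature).
    drug_direction_consistency:
        Fraction of a protective drug's targets whose code opposes
        the gene's true TWAS direction.
    n_enriched_atc:
        ATC groups into which protective drugs are concentrated.
    """

    n_genes: int = 500
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    n_panels: int = 4
    panel_tissue_classes: Sequence[str] = ("blood", "brain")
    n_ref_samples: int = 500
    snps_per_gene: int = 5
    prop_signal_genes: float = 0.10
    twas_effect_sd: float = 5.0
    prop_coloc: float = 0.6
    panel_dup_rate: float = 0.4
    cross_panel_similarity: float = 0.5
    n_cases: int = 300
    n_controls: int = 300
    de_effect_size: float = 0.3
    prop_concordant: float = 0.8
    n_drugs: int = 200
    n_atc_groups: int = 20
    genes_per_drug_mean: float = 4.0
    prop_protective_drugs: float = 0.10
    drug_direction_consistency: float = 0.9
    n_enriched_atc: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
            "n_panels": self.n_panels,
            "n_ref_samples": self.n_ref_samples,
            "snps_per_gene": self.snps_per_gene,
            "n_drugs": self.n_drugs,
            "n_atc_groups": self.n_atc_groups,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        fracs = {
            "prop_signal_genes": self.prop_signal_genes,
            "prop_coloc": self.prop_coloc,
            "panel_dup_rate": self.panel_dup_rate,
            "cross_panel_similarity": self.cross_panel_similarity,
            "prop_concordant": self.prop_concordant,
            "prop_protective_drugs": self.prop_protective_drugs,
            "drug_direction_consistency": self.drug_direction_consistency,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1 per cohort")
        if self.n_atc_groups > self.n_drugs:
            raise ValueError("n_atc_groups cannot exceed n_drugs")
        tissues = set(self.panel_tissue_classes)
        if not tissues <= {"blood", "brain"}:
            raise ValueError(f"tissue classes must be blood/brain, got {tissues}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel_tissue_classes"] = list(self.panel_tissue_classes)
        return d


# Defaults below echo the source analysis: FDR 0.05, coloc ratio 0.8,
# HEIDI 0.05, clump r 0.95 in a 500 kb window, >=2 genes per drug,
# >=5 drugs per ATC group, case-control prevalence 1/300 and an
# arbitrary 0.5 for spinal-vs-bulbar onset.
DEFAULT_THRESHOLD_GRID = (1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class PipelineConfig:
    """End-to-end run configuration with the analysis defaults."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    fdr: float = 0.05
    coloc_ratio: float = 0.8
    heidi_alpha: float = 0.05
    r_thresh: float = 0.95
    window_bp: int = 500_000
    window_anchor: str = "start"
    p_thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID
    prevalence_case_control: float = 1.0 / 300.0
    prevalence_onset: float = 0.5
    min_genes_per_drug: int = 2
    min_drugs_per_atc: int = 5
    out_dir: str = "results/pipeline"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.window_anchor not in {"start", "midpoint"}:
            raise ValueError("window_anchor must be 'start' or 'midpoint'")
        if self.min_genes_per_drug < 1 or self.min_drugs_per_atc < 1:
            raise ValueError("drug/ATC filters must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["p_thresholds"] = list(self.p_thresholds)
        return d
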