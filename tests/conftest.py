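import pandas as pd
import pytest

from twaskit.config import SyntheticConfig
from twaskit.synthetic import generate_study


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=60, n_chromosomes=3, n_panels=4, n_ref_samples=150,
        snps_per_gene=4, prop_signal_genes=0.2, twas_effect_sd=5.0,
        prop_coloc=0.6, n_cases=80, n_controls=80, de_effect_size=0.5,
        prop_concordant=0.8, n_drugs=40, n_atc_groups=6,
        genes_per_drug_mean=4.0, prop_protective_drugs=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def study(small_config):
    return generate_study(small_config)


@pytest.fixture()
def hand_twas_table() -> pd.DataFrame:
    """Three constructed genes, one per high-confidence criterion.

    GENE_A: FUSION q<0.05 and colocalised. GENE_B: SMR q<0.05 with
    HEIDI pass. GENE_C: carries no association evidence (called via a
    credible set contained in its body). GENE_D: SMR significant but
    HEIDI fails, must not be called.
    """
    return pd.DataFrame([
        dict(gene_id="GENE_A", panel_id="P1", tissue_class="blood",
             method="FUSION", molecular_type="expression",
             Z=5.0, p=1e-6, PP3=0.01, PP4=0.95, heidi_p=float("nan")),
        dict(gene_id="GENE_B", panel_id="P2", tissue_class="brain",
             method="SMR", molecular_type="expression",
             Z=-4.5, p=1e-5, PP3=float("nan"), PP4=float("nan"), heidi_p=0.5),
        dict(gene_id="GENE_C", panel_id="P1", tissue_class="blood",
             method="FUSION", molecular_type="expression",
             Z=0.5, p=0.6, PP3=0.3, PP4=0.3, heidi_p=float("nan")),
        dict(gene_id="GENE_D", panel_id="P2", tissue_class="brain",
             method="SMR", molecular_type="expression",
             Z=4.0, p=1e-4, PP3=float("nan"), PP4=float("nan"), heidi_p=0.001),
    ])


@pytest.fixture()
def hand_gene_map() -> pd.DataFrame:
    return pd.DataFrame([
        dict(gene_id="GENE_A", chrom="chr1", start=1_000, end=5_000),
        dict(gene_id="GENE_B", chrom="chr1", start=600_000, end=610_000),
        dict(gene_id="GENE_C", chrom="chr2", start=50, end=300),
        dict(gene_id="GENE_D", chrom="chr2", start=10_000, end=20_000),
    ])


@pytest.fixture()
def hand_credible_sets() -> pd.DataFrame:
    # LOCUS0 contained in GENE_C; LOCUS1 has a variant outside GENE_D
    return pd.DataFrame([
        dict(locus_id="LOCUS0", variant_id="v0", chrom="chr2", pos=100),
        dict(locus_id="LOCUS0", variant_id="v1", chrom="chr2", pos=200),
        dict(locus_id="LOCUS1", variant_id="v2", chrom="chr2", pos=10_500),
        dict(locus_id="LOCUS1", variant_id="v3", chrom="chr2", pos=40_000),
    ])
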