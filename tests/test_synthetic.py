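"""Generator invariants: determinism, domains, and planted truths."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from twaskit.config import SyntheticConfig
from twaskit.synthetic import (
    generate_drug_database,
    generate_expression_cohorts,
    generate_gene_map,
    generate_reference_genotypes,
    generate_twas_results,
    generate_credible_sets,
    generate_study,
    DIRECTION_DECREASE_LABELS,
    DIRECTION_INCREASE_LABELS,
)
from twaskit.drugs import code_directions


def test_gene_map_deterministic_sorted_nonoverlapping():
    cfg = SyntheticConfig(n_genes=40, n_chromosomes=2, seed=1)
    m1 = generate_gene_map(cfg)
    m2 = generate_gene_map(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    assert (m1["start"] < m1["end"]).all()
    for _, grp in m1.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        assert (np.diff(starts) > 0).all()
        assert (starts[1:] > ends[:-1]).all()  # non-overlapping


def test_gene_map_single_chromosome_and_sizing_error():
    cfg = SyntheticConfig(n_genes=10, n_chromosomes=1, seed=3)
    assert generate_gene_map(cfg)["chrom"].nunique() == 1
    tight = SyntheticConfig(n_genes=300, n_chromosomes=1,
                            chrom_length_bp=1_000_000, seed=3)
    with pytest.raises(ValueError, match="cannot place"):
        generate_gene_map(tight)


def test_genotypes_domain_and_determinism(small_config):
    gene_map = generate_gene_map(small_config)
    g1, v1 = generate_reference_genotypes(small_config, gene_map)
    g2, _ = generate_reference_genotypes(small_config, gene_map)
    assert np.array_equal(g1, g2)
    assert set(np.unique(g1)) <= {0, 1, 2}
    assert len(v1) == small_config.n_genes * small_config.snps_per_gene
    assert (g1.std(axis=0) > 0).all()


def test_genotype_column_mean_matches_binomial_theory():
    # maf in U(0.05, 0.5): E[count] = 2*maf; check each column against
    # its own binomial standard error at n=4000 samples
    cfg = SyntheticConfig(n_genes=10, n_ref_samples=4000, snps_per_gene=3,
                          seed=11)
    gmap = generate_gene_map(cfg)
    geno, variants = generate_reference_genotypes(cfg, gmap)
    maf = variants["maf"].to_numpy()
    se = np.sqrt(2 * maf * (1 - maf) / cfg.n_ref_samples)
    assert (np.abs(geno.mean(axis=0) - 2 * maf) < 3.5 * se).mean() > 0.95


def test_null_twas_tail_fraction_matches_normal_theory():
    cfg = SyntheticConfig(n_genes=5000, n_chromosomes=10,
                          chrom_length_bp=300_000_000,
                          prop_signal_genes=0.0, n_panels=1, seed=5)
    gmap = generate_gene_map(cfg)
    assoc, _, truth = generate_twas_results(cfg, gmap)
    frac = (assoc["Z"].abs() > 1.96).mean()
    se = np.sqrt(0.05 * 0.95 / len(assoc))
    assert abs(frac - 0.05) < 3 * se
    assert not truth.genes["is_signal"].any()


def test_twas_bookkeeping_and_p_definition(study):
    assoc, truth = study.associations, study.truth
    # p equals the exact two-sided normal tail of Z
    expected_p = 2 * sps.norm.sf(assoc["Z"].abs())
    assert np.allclose(assoc["p"], expected_p, atol=1e-12)
    # recorded direction equals the sign of the generated mean
    sig = truth.genes[truth.genes["is_signal"]]
    assert (sig["true_direction"] == np.sign(sig["true_mu"])).all()
    # FUSION rows carry PP3/PP4, SMR rows carry heidi_p
    fus = assoc[assoc["method"] == "FUSION"]
    smr = assoc[assoc["method"] == "SMR"]
    assert fus[["PP3", "PP4"]].notna().all().all()
    assert smr["heidi_p"].notna().all()
    assert ((fus["PP3"] + fus["PP4"]) <= 1 + 1e-12).all()


def test_pure_null_warning():
    cfg = SyntheticConfig(n_genes=10, prop_signal_genes=0.01, seed=2)
    gmap = generate_gene_map(cfg)
    with pytest.warns(UserWarning, match="pure-null"):
        generate_twas_results(cfg, gmap)


def test_cohort_shifts_follow_concordance_truth(study):
    truth = study.truth.genes
    cfg = study.config
    sig = truth[truth["is_signal"]]
    assert np.allclose(np.abs(sig["true_shift"]), cfg.de_effect_size)
    conc = sig[sig["concordant"]]
    disc = sig[~sig["concordant"]]
    assert (np.sign(conc["true_shift"]) == conc["true_direction"]).all()
    assert (np.sign(disc["true_shift"]) == -disc["true_direction"]).all()
    null = truth[~truth["is_signal"]]
    assert (null["true_shift"] == 0).all()


def test_prop_concordant_one_forces_agreement(small_config):
    cfg = SyntheticConfig(**{**small_config.to_dict(), "prop_concordant": 1.0})
    gmap = generate_gene_map(cfg)
    _, _, truth = generate_twas_results(cfg, gmap)
    _, _, truth = generate_expression_cohorts(cfg, truth)
    sig = truth.genes[truth.genes["is_signal"]]
    assert (np.sign(sig["true_shift"]) == sig["true_direction"]).all()


def test_zero_effect_cohorts_centred_on_null():
    cfg = SyntheticConfig(n_genes=200, de_effect_size=0.0, n_cases=200,
                          n_controls=200, seed=9)
    gmap = generate_gene_map(cfg)
    _, _, truth = generate_twas_results(cfg, gmap)
    expr, phen, truth = generate_expression_cohorts(cfg, truth)
    assert (truth.genes["true_shift"] == 0).all()
    e = expr["GPL6947"]
    status = phen["GPL6947"]["case"].to_numpy()
    diff = e.loc[:, status == 1].mean(axis=1) - e.loc[:, status == 0].mean(axis=1)
    assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(len(diff))


def test_drug_database_construction(study):
    drug_gene, truth = study.drug_gene, study.truth
    # each drug has exactly one ATC code
    assert (drug_gene.groupby("drug_id")["atc_code"].nunique() == 1).all()
    # protective drugs oppose the risk direction for most targets
    coded = code_directions(drug_gene)
    gmap = truth.genes.set_index("gene_id")["true_direction"]
    prot = truth.drugs.loc[truth.drugs["drug_class"] == "protective", "drug_id"]
    fracs = []
    for drug in prot:
        rows = coded[coded["drug_id"] == drug]
        gd = gmap.loc[rows["gene_id"]].to_numpy()
        code = rows["direction"].to_numpy()
        opposing = (code * gd < 0)
        informative = gd != 0
        if informative.sum():
            fracs.append(opposing[informative].mean())
    assert np.mean(fracs) > 0.6
    labels = set(drug_gene["action_label"])
    assert labels & set(DIRECTION_DECREASE_LABELS + DIRECTION_INCREASE_LABELS)


def test_drug_database_deterministic(small_config, study):
    dg2, _ = generate_drug_database(small_config, study.truth)
    pd.testing.assert_frame_equal(study.drug_gene, dg2)


def test_credible_sets_single_chromosome_and_containment(study):
    cs = study.credible_sets
    assert len(cs)
    gmap = study.gene_map
    contained = 0
    for _, grp in cs.groupby("locus_id"):
        assert grp["chrom"].nunique() == 1
        inside = (
            (gmap["chrom"] == grp["chrom"].iloc[0])
            & (gmap["start"] <= grp["pos"].min())
            & (gmap["end"] >= grp["pos"].max())
        )
        contained += int(inside.any())
    assert 0 < contained < cs["locus_id"].nunique()


def test_study_determinism_and_atc_group_bounds(small_config, study):
    s2 = generate_study(small_config)
    pd.testing.assert_frame_equal(study.associations, s2.associations)
    pd.testing.assert_frame_equal(study.drug_gene, s2.drug_gene)
    assert study.truth.atc["enriched"].sum() == small_config.n_enriched_atc
    with pytest.raises(ValueError, match="n_atc_groups"):
        SyntheticConfig(n_drugs=3, n_atc_groups=5)
    with pytest.raises(ValueError, match="n_cases"):
        SyntheticConfig(n_cases=0)
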