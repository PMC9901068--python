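"""Direction coding, GLS enrichment, external import, ATC Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from helpers import ols_slope_test
from twaskit import drugs as dr


ALL_LABELS = [
    ("DECREASED_EXPRESSION", -1),
    ("NEGATIVE_RESPONSE", -1),
    ("OPPOSITE_RESPONSE", -1),
    ("INCREASED_EXPRESSION", 1),
    ("POSITIVE_RESPONSE", 1),
    ("BINDING", 0),
]


@pytest.mark.parametrize("label,code", ALL_LABELS)
def test_direction_coding_of_every_label(label, code):
    df = pd.DataFrame({"drug_id": ["D"], "gene_id": ["G"],
                       "action_label": [label]})
    assert dr.code_directions(df)["direction"].iloc[0] == code


def test_direction_coding_total_and_idempotent():
    df = pd.DataFrame({
        "drug_id": "D", "gene_id": [f"G{i}" for i in range(7)],
        "action_label": [lbl for lbl, _ in ALL_LABELS] + ["SOMETHING_NEW"]})
    once = dr.code_directions(df)
    twice = dr.code_directions(once)
    pd.testing.assert_frame_equal(once, twice)
    assert once["direction"].iloc[-1] == 0  # unknown labels code 0


def _coded(drug, genes, codes):
    return pd.DataFrame({"drug_id": drug, "gene_id": genes,
                         "direction": codes,
                         "action_label": "x", "atc_code": "A01A"})


def _twas(genes, z):
    return pd.DataFrame({"gene_id": genes, "Z": z})


def test_gls_identity_covariance_equals_ols():
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(8)]
    z = rng.normal(size=8)
    codes = rng.choice([-1, 0, 1], size=8)
    while len(set(codes)) < 2:
        codes = rng.choice([-1, 0, 1], size=8)
    enr = dr.directional_enrichment(_twas(genes, z), _coded("D1", genes, codes))
    _, _, z_ols = ols_slope_test(z, codes)
    assert enr["Z"].iloc[0] == pytest.approx(-z_ols, abs=1e-8)


def test_protective_pattern_scores_positive():
    # drug decreases the risk-raising genes and increases the
    # risk-lowering genes: enrichment Z must be positive
    genes = ["G1", "G2", "G3", "G4"]
    enr = dr.directional_enrichment(
        _twas(genes, [3.0, 3.0, -3.0, -3.0]),
        _coded("D1", genes, [-1, -1, 1, 1]))
    assert enr["Z"].iloc[0] > 0


def test_gls_matches_matrix_algebra_oracle_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = int(rng.integers(3, 11))
        genes = [f"G{i}" for i in range(n)]
        y = rng.normal(size=n)
        d = rng.choice([-1.0, 0.0, 1.0], size=n)
        if len(set(d)) < 2:
            continue
        lat = rng.normal(size=(n, 40))
        S = np.corrcoef(lat)
        corr = pd.DataFrame(
            [(genes[i], genes[j], S[i, j])
             for i in range(n) for j in range(i + 1, n)],
            columns=["gene_a", "gene_b", "r"])
        enr = dr.directional_enrichment(_twas(genes, y),
                                        _coded("D", genes, d), corr)
        # direct solve of the GLS normal equations
        X = np.column_stack([np.ones(n), d])
        Si = np.linalg.inv(S)
        beta = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        resid = y - X @ beta
        sigma2 = resid @ Si @ resid / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ Si @ X)[1, 1])
        assert enr["Z"].iloc[0] == pytest.approx(-beta[1] / se, abs=1e-8)


def test_min_genes_filter_skips_small_drugs():
    genes = ["G1"]
    enr = dr.directional_enrichment(_twas(genes, [2.0]),
                                    _coded("D1", genes, [-1]))
    assert enr.empty
    # genes without TWAS statistics are excluded before the filter
    coded = _coded("D2", ["G1", "GX", "GY"], [-1, 1, 1])
    enr2 = dr.directional_enrichment(_twas(["G1"], [2.0]), coded)
    assert enr2.empty


def test_import_external_passthrough_backfill_and_duplicates():
    tbl = pd.DataFrame({"drug_id": ["d1"], "Z": [2.5]})
    out = dr.import_external_enrichment(tbl, "external_gcsc")
    assert out["Z"].iloc[0] == 2.5
    assert out["method"].iloc[0] == "external_gcsc"

    tbl_p = pd.DataFrame({"drug_id": ["d1"], "p": [0.025]})
    out_p = dr.import_external_enrichment(tbl_p, "external_magma")
    assert out_p["Z"].iloc[0] == pytest.approx(sps.norm.isf(0.025), abs=1e-9)

    dup = pd.DataFrame({"drug_id": ["d1", "d1"], "Z": [1.0, 2.0]})
    with pytest.raises(ValueError, match="duplicate"):
        dr.import_external_enrichment(dup, "external_magma")
    with pytest.raises(ValueError, match="unknown external"):
        dr.import_external_enrichment(tbl, "something")
    with pytest.raises(ValueError, match="Z or p"):
        dr.import_external_enrichment(pd.DataFrame({"drug_id": ["d1"]}),
                                      "external_magma")


def test_fdr_drugs_bh_by_hand_within_method():
    enr = pd.DataFrame({
        "drug_id": [f"d{i}" for i in range(5)],
        "method": ["external_magma"] * 4 + ["external_gcsc"],
        "Z": 1.0, "p": [0.01, 0.02, 0.03, 0.04, 0.2],
        "n_genes_tested": 3})
    out = dr.fdr_drugs(enr)
    assert np.allclose(out.loc[out["method"] == "external_magma", "q"], 0.04)
    assert out.loc[out["method"] == "external_gcsc", "q"].iloc[0] == \
        pytest.approx(0.2)  # m=1 identity


def _enrichment_table(stats, method="external_magma"):
    return pd.DataFrame({
        "drug_id": [f"d{i}" for i in range(len(stats))],
        "method": method, "Z": stats, "p": 0.5, "n_genes_tested": 3})


def _atc_map(codes):
    return pd.DataFrame({"drug_id": [f"d{i}" for i in range(len(codes))],
                         "atc_code": codes})


def test_wilcoxon_exact_enumeration_small_group():
    # group {3, 4} vs others {-1, 0, 1}: both group values exceed all
    # others, the single most extreme of C(5,2)=10 assignments -> 0.1
    enr = _enrichment_table([3.0, 4.0, -1.0, 0.0, 1.0])
    atc = _atc_map(["A01A", "A01A", "B01B", "B01B", "B01B"])
    out = dr.atc_wilcoxon(enr, atc, "external_magma", min_drugs=2)
    p = out.set_index("atc_code").loc["A01A", "p"]
    assert p == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_exact_matches_full_enumeration():
    rng = np.random.default_rng(5)
    stats = rng.normal(size=9)
    codes = ["G1"] * 4 + ["G2"] * 5
    out = dr.atc_wilcoxon(_enrichment_table(stats), _atc_map(codes),
                          "external_magma", min_drugs=4)
    # brute-force: p = fraction of label reassignments with U >= observed
    from itertools import combinations
    x = stats[:4]
    obs_u = sum((xi > yj) + 0.5 * (xi == yj)
                for xi in x for yj in stats[4:])
    count = 0
    total = 0
    for comb in combinations(range(9), 4):
        g = stats[list(comb)]
        rest = np.delete(stats, list(comb))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in g for yj in rest)
        count += u >= obs_u
        total += 1
    p_exact = count / total
    assert out.set_index("atc_code").loc["G1", "p"] == \
        pytest.approx(p_exact, abs=1e-12)


def test_group_size_filter():
    enr = _enrichment_table(np.arange(10, dtype=float))
    codes = ["A01A"] * 4 + ["B01B"] * 6  # A01A has only 4 drugs
    out = dr.atc_wilcoxon(enr, _atc_map(codes), "external_magma", min_drugs=5)
    assert "A01A" not in set(out["atc_code"])
    assert "B01B" in set(out["atc_code"])


def test_directional_method_uses_two_sided_signed_z():
    rng = np.random.default_rng(9)
    low = list(-np.abs(rng.normal(size=6)) - 2)   # group below background
    rest = list(rng.normal(size=20))
    enr = _enrichment_table(low + rest, method="directional_twas")
    codes = ["A01A"] * 6 + ["B01B"] * 20
    out = dr.atc_wilcoxon(enr, _atc_map(codes), "directional_twas",
                          min_drugs=5)
    row = out.set_index("atc_code").loc["A01A"]
    assert row["Z"] < 0  # signed: group predicted to increase risk
    # two-sided p is consistent with |Z|
    assert row["p"] == pytest.approx(2 * sps.norm.sf(abs(row["Z"])), rel=1e-6)


def test_empty_result_when_no_group_passes(caplog):
    enr = _enrichment_table([1.0, 2.0])
    with caplog.at_level("WARNING"):
        out = dr.atc_wilcoxon(enr, _atc_map(["A01A", "B01B"]),
                              "external_magma", min_drugs=5)
    assert out.empty
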