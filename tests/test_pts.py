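"""PTS computation, association testing, liability R2, IVW pooling."""

import numpy as np
import pandas as pd
import pytest

from helpers import liability_r2_oracle
from twaskit import pts as pt
from twaskit.stats import ivw_pool, obs_to_liability_r2


def _expr(mat, genes, samples=None):
    samples = samples or [f"S{i}" for i in range(np.shape(mat)[1])]
    return pd.DataFrame(mat, index=genes, columns=samples)


def test_standardize_rows_and_drop_constant(caplog):
    mat = [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]]
    with caplog.at_level("WARNING"):
        z = pt.standardize_expression(_expr(mat, ["G1", "G2"]))
    assert list(z.index) == ["G1"]
    assert abs(z.loc["G1"].mean()) < 1e-10
    assert abs(z.loc["G1"].std(ddof=1) - 1) < 1e-10
    assert "zero-variance" in caplog.text


def test_standardize_two_samples_hand_value():
    # (a, b) with n-1 denominator: z = (-1/sqrt(2), +1/sqrt(2))
    z = pt.standardize_expression(_expr([[3.0, 7.0]], ["G1"]))
    assert np.allclose(z.loc["G1"], [-np.sqrt(0.5), np.sqrt(0.5)])


def test_standardize_needs_two_samples():
    with pytest.raises(ValueError):
        pt.standardize_expression(_expr([[1.0]], ["G1"]))


def _weights(rows):
    return pd.DataFrame(rows, columns=["gene_id", "Z", "min_p"])


def test_compute_pts_arithmetic():
    z = _expr([[1.5, 0.0]], ["G1"])
    w = _weights([("G1", 2.0, 1e-6)])
    s = pt.compute_pts(z, w, [1.0])
    assert s[1.0]["S0"] == pytest.approx(3.0)  # single-term sum

    z2 = _expr([[1.0, 0.0], [1.0, 0.0]], ["G1", "G2"])
    w2 = _weights([("G1", 2.0, 1e-6), ("G2", -1.0, 1e-6)])
    s2 = pt.compute_pts(z2, w2, [1.0])
    assert s2[1.0]["S0"] == pytest.approx(1.0)  # 2*1 + (-1)*1


def test_compute_pts_thresholding_reduces_to_single_gene():
    z = _expr([[1.0, -1.0], [0.5, 2.0]], ["G1", "G2"])
    w = _weights([("G1", 2.0, 1e-8), ("G2", 3.0, 0.5)])
    s = pt.compute_pts(z, w, [1e-6, 1.0])
    single = pt.compute_pts(z.loc[["G1"]], w.iloc[[0]], [1e-6])
    assert np.allclose(s[1e-6], single[1e-6])
    assert s.attrs["n_genes_used"] == {1e-6: 1, 1.0: 2}


def test_compute_pts_no_overlap_paths(caplog):
    z = _expr([[1.0, -1.0]], ["G1"])
    with pytest.raises(ValueError, match="no genes overlap"):
        pt.compute_pts(z, _weights([("GX", 1.0, 0.5)]), [1.0])
    with caplog.at_level("WARNING"):
        s = pt.compute_pts(z, _weights([("G1", 1.0, 0.5)]), [1e-8])
    assert s[1e-8].isna().all()


def test_pts_linear_in_weights():
    rng = np.random.default_rng(0)
    z = _expr(rng.normal(size=(5, 40)), [f"G{i}" for i in range(5)])
    w = _weights([(f"G{i}", rng.normal(), 0.01) for i in range(5)])
    s1 = pt.compute_pts(z, w, [1.0])[1.0]
    w3 = w.assign(Z=3.0 * w["Z"])
    s3 = pt.compute_pts(z, w3, [1.0])[1.0]
    assert np.allclose(s3, 3.0 * s1)


def _phen(n, case=None, sex=None):
    case = case if case is not None else np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    sex = sex if sex is not None else np.zeros(n)
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)], "case": case.astype(int),
        "sex": sex,
        "site_of_onset": np.where(case == 1, "spinal", ""),
        "age_at_onset": np.where(case == 1, 60.0, np.nan),
        "survival": np.where(case == 1, 3.0, np.nan)})


def test_associate_perfect_fit_r2_one():
    n = 40
    phen = _phen(n, sex=np.random.default_rng(0).integers(0, 2, n).astype(float))
    y = phen["case"].to_numpy(dtype=float)
    pts = pd.Series(y, index=phen["sample_id"])
    res = pt.associate(pts, phen, "case_control", covariates=(),
                       prevalence=1 / 300)
    assert res.r2_obs == pytest.approx(1.0, abs=1e-10)
    assert res.r2_liability is not None and res.r2_liability > 0


def test_associate_null_r2_near_zero_p_uniform():
    rng = np.random.default_rng(1)
    pvals = []
    r2s = []
    for _ in range(200):
        n = 200
        phen = _phen(n, sex=rng.integers(0, 2, n).astype(float))
        pts = pd.Series(rng.normal(size=n), index=phen["sample_id"])
        res = pt.associate(pts, phen, "case_control", prevalence=1 / 300)
        pvals.append(res.p)
        r2s.append(res.r2_obs)
    assert np.mean(r2s) < 0.02
    frac = np.mean(np.array(pvals) < 0.05)
    assert abs(frac - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / 200)


def test_associate_outcome_as_covariate_zeroes_increment():
    rng = np.random.default_rng(2)
    n = 100
    phen = _phen(n)
    phen["sex"] = phen["case"].astype(float)  # covariate equals outcome
    pts = pd.Series(rng.normal(size=n), index=phen["sample_id"])
    res = pt.associate(pts, phen, "case_control", prevalence=1 / 300)
    assert res.r2_obs == pytest.approx(0.0, abs=1e-10)


def test_associate_clinical_outcomes_restricted_to_cases():
    rng = np.random.default_rng(3)
    n = 120
    phen = _phen(n)
    phen.loc[phen["case"] == 1, "site_of_onset"] = \
        rng.choice(["spinal", "bulbar"], size=(phen["case"] == 1).sum())
    phen.loc[phen["case"] == 1, "age_at_onset"] = \
        rng.normal(60, 10, (phen["case"] == 1).sum())
    pts = pd.Series(rng.normal(size=n), index=phen["sample_id"])
    res = pt.associate(pts, phen, "age_at_onset")
    assert res.n == int((phen["case"] == 1).sum())
    res2 = pt.associate(pts, phen, "site_of_onset", prevalence=0.5)
    assert res2.r2_liability is not None


def test_associate_errors():
    phen = _phen(20, case=np.ones(20))
    pts = pd.Series(np.random.default_rng(0).normal(size=20),
                    index=phen["sample_id"])
    with pytest.raises(ValueError, match="constant"):
        pt.associate(pts, phen, "case_control", prevalence=1 / 300)
    with pytest.raises(ValueError, match="prevalence"):
        pt.associate(pts, _phen(20), "case_control")


@pytest.mark.parametrize("K,P,r2", [(0.1, 0.3, 0.05), (1 / 300, 0.5, 0.04),
                                    (0.5, 0.5, 0.1), (0.01, 0.2, 0.3)])
def test_liability_conversion_matches_independent_oracle(K, P, r2):
    assert obs_to_liability_r2(r2, K, P) == \
        pytest.approx(liability_r2_oracle(r2, K, P), abs=1e-10)


def test_liability_conversion_zero_and_no_ascertainment_limits():
    assert obs_to_liability_r2(0.0, 0.1, 0.4) == 0.0
    # K = P: theta = 0, so the map is exactly linear with slope C;
    # at K = P = 0.5, C = 0.25 / phi(0)^2 = pi/2
    C = np.pi / 2
    assert obs_to_liability_r2(0.1, 0.5, 0.5) == pytest.approx(0.1 * C,
                                                               abs=1e-10)
    for K in (0.05, 0.2, 0.5):
        r2a = obs_to_liability_r2(0.02, K, K)
        r2b = obs_to_liability_r2(0.04, K, K)
        assert r2b == pytest.approx(2 * r2a, rel=1e-9)  # linear when K=P


def test_liability_conversion_validates_arguments():
    for bad in [(-0.1, 0.1, 0.5), (0.1, 0.0, 0.5), (0.1, 0.5, 1.0)]:
        with pytest.raises(ValueError):
            obs_to_liability_r2(*bad)


def test_ivw_hand_values():
    beta, se, _ = ivw_pool([1.0, 3.0], [1.0, 1.0])
    assert beta == pytest.approx(2.0, abs=1e-12)
    assert se == pytest.approx(np.sqrt(0.5), abs=1e-10)
    beta, se, _ = ivw_pool([1.0, 3.0], [1.0, 2.0])
    assert beta == pytest.approx(1.4, abs=1e-12)
    assert se == pytest.approx(2 / np.sqrt(5), abs=1e-10)  # 0.894427...


def test_ivw_single_estimate_identity_and_validation():
    beta, se, p = ivw_pool([1.7], [0.3])
    assert beta == pytest.approx(1.7, abs=1e-12)
    assert se == pytest.approx(0.3, abs=1e-12)
    with pytest.raises(ValueError):
        ivw_pool([1.0], [0.0])


def test_ivw_meta_of_associations_pools_and_checks_keys():
    mk = lambda cohort, beta, se: pt.PtsAssociation(
        cohort=cohort, outcome="case_control", threshold=0.05, stratum="all",
        beta=beta, se=se, p=0.5, r2_obs=0.01, r2_liability=0.02, n=100,
        n_genes_used=10, K=1 / 300, P=0.5)
    pooled = pt.ivw_meta([mk("A", 1.0, 1.0), mk("B", 3.0, 2.0)])
    assert pooled["beta"] == pytest.approx(1.4)
    assert pooled["se"] <= 1.0  # pooled se never exceeds the best cohort
    other = mk("B", 3.0, 2.0)
    other.outcome = "survival"
    with pytest.raises(ValueError, match="mismatched"):
        pt.ivw_meta([mk("A", 1.0, 1.0), other])
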