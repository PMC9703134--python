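import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests

from methdrift.drift import (
    PassageDesign,
    PassageDriftModel,
    bh_fdr,
    breusch_pagan,
    classify_cpgs,
    cross_cohort_concordance,
    delta_beta,
    fit_passage_linear_model,
)
from methdrift.simulate import SimulationConfig, generate_cohort


# ---------------------------------------------------------------------------
# per-CpG linear model


def test_noiseless_linear_fit_is_exact(toy_sheet):
    y = 0.3 + 0.02 * toy_sheet["passage"].to_numpy()
    slope, p, resid = fit_passage_linear_model(y, toy_sheet)
    assert slope == pytest.approx(0.02, abs=1e-12)
    assert np.allclose(resid, 0, atol=1e-12)
    assert p < 1e-10


def test_constant_beta_gives_zero_slope_p_one(toy_sheet):
    slope, p, _ = fit_passage_linear_model(np.full(10, 0.4), toy_sheet)
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert p == 1.0


@pytest.mark.parametrize("donor_covariate", [False, True])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ols_matches_statsmodels(seed, donor_covariate, toy_sheet):
    rng = np.random.default_rng(seed)
    sheet = pd.concat([toy_sheet, toy_sheet.assign(sample_id=toy_sheet.sample_id + "b")], ignore_index=True)
    y = 0.4 + 0.01 * sheet["passage"].to_numpy() + rng.normal(0, 0.05, len(sheet))
    slope, p, resid = fit_passage_linear_model(y, sheet, donor_covariate=donor_covariate)
    X = pd.DataFrame({"passage": sheet["passage"].astype(float)})
    if donor_covariate:
        X = pd.concat([X, pd.get_dummies(sheet["donor_id"], drop_first=True, dtype=float)], axis=1)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    assert slope == pytest.approx(fit.params["passage"], abs=1e-10)
    assert p == pytest.approx(fit.pvalues["passage"], abs=1e-10)
    assert np.allclose(resid, fit.resid, atol=1e-10)


def test_constant_passage_rejected():
    sheet = pd.DataFrame(
        {"sample_id": list("abcd"), "donor_id": ["D"] * 4, "passage": [3] * 4, "segment": ["TI"] * 4}
    )
    with pytest.raises(ValueError, match="distinct passage"):
        fit_passage_linear_model(np.r_[0.1, 0.2, 0.3, 0.4], sheet)


def test_singleton_donor_design_named_in_error():
    sheet = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(4)],
            "donor_id": ["A", "B", "C", "D"],  # one sample each: saturated
            "passage": [1, 4, 8, 12],
            "segment": ["TI"] * 4,
        }
    )
    with pytest.raises(ValueError, match="rank deficient|more coefficients"):
        fit_passage_linear_model(np.r_[0.1, 0.2, 0.3, 0.4], sheet, donor_covariate=True)


# ---------------------------------------------------------------------------
# Breusch–Pagan


def test_bp_exact_homoskedastic_case():
    resid = np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
    lm, p = breusch_pagan(resid, np.arange(6))
    assert lm == 0.0 and p == 1.0


def test_bp_zero_residuals():
    assert breusch_pagan(np.zeros(10), np.arange(10)) == (0.0, 1.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_bp_matches_statsmodels(seed):
    rng = np.random.default_rng(seed)
    passage = rng.choice(np.arange(1, 17), size=20)
    y = 0.5 + rng.normal(0, 0.02 + 0.01 * passage)
    X = sm.add_constant(passage.astype(float))
    resid = sm.OLS(y, X).fit().resid
    lm, p = breusch_pagan(resid, passage)
    lm_sm, p_sm, *_ = het_breuschpagan(resid, X)
    assert lm == pytest.approx(lm_sm, abs=1e-10)
    assert p == pytest.approx(p_sm, abs=1e-10)


def test_bp_detects_passage_proportional_spread():
    passage = np.tile(np.arange(1, 11), 2)
    resid = passage * np.resize([0.01, -0.01], 20)
    lm, p = breusch_pagan(resid, passage)
    # oracle: n * R^2 with R from the squared-residual regression
    r = np.corrcoef(resid**2, passage)[0, 1]
    assert lm == pytest.approx(20 * r * r, abs=1e-10)
    assert p < 0.05


# ---------------------------------------------------------------------------
# delta-beta


def test_delta_beta_arithmetic(toy_sheet):
    design = PassageDesign(low_passages=(1, 4), high_passages=(5, 10))
    y = 0.3 + 0.02 * toy_sheet["passage"].to_numpy()
    # mean over 5..10 = 0.45, mean over 1..4 = 0.35
    assert delta_beta(y, toy_sheet, design) == pytest.approx(0.10, abs=1e-12)


def test_delta_beta_antisymmetric(toy_sheet, rng):
    y = rng.uniform(0, 1, 10)
    d1 = delta_beta(y, toy_sheet, PassageDesign(low_passages=(1, 4), high_passages=(5, 10)))
    d2 = delta_beta(y, toy_sheet, PassageDesign(low_passages=(5, 10), high_passages=(1, 4)))
    assert d1 == pytest.approx(-d2, abs=1e-12)


def test_delta_beta_empty_group_raises(toy_sheet):
    design = PassageDesign(low_passages=(11, 12), high_passages=(13, 16))
    with pytest.raises(ValueError, match="empty passage group"):
        delta_beta(np.full(10, 0.5), toy_sheet, design)


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_single_p_is_identity():
    assert bh_fdr([0.05])[0] == pytest.approx(0.05)


def test_bh_hand_computed_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12)


def test_bh_ties_and_nan():
    q = bh_fdr([0.2, np.nan, 0.2, 0.2])
    assert np.isnan(q[1]) and np.allclose(q[[0, 2, 3]], 0.2)


@given(st.integers(0, 2**32 - 1))
@settings(deadline=None, max_examples=30)
def test_bh_matches_statsmodels(seed):
    p = np.random.default_rng(seed).uniform(size=50)
    expected = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


def test_bh_monotone_in_p_rank(rng):
    p = rng.uniform(size=200)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# classification rules


def _stats_row(slope_q, bp_q, delta):
    return pd.DataFrame({"slope_q": [slope_q], "bp_q": [bp_q], "delta_beta": [delta]})


@pytest.mark.parametrize(
    "slope_q,bp_q,delta,label",
    [
        (0.01, 0.9, -0.2, "hypo"),
        (0.01, 0.9, 0.2, "hyper"),
        (0.9, 0.01, 0.0, "hetero"),
        (0.9, 0.9, 0.5, "stable"),  # large delta without significance
        (0.01, 0.9, 0.1, "stable"),  # significant but below threshold
    ],
)
def test_classification_rules(slope_q, bp_q, delta, label):
    out = classify_cpgs(_stats_row(slope_q, bp_q, delta), PassageDesign())
    assert out["label"].iloc[0] == label


def test_flags_are_non_exclusive_with_directional_precedence():
    out = classify_cpgs(_stats_row(0.01, 0.01, -0.3), PassageDesign())
    assert bool(out["hypo"].iloc[0]) and bool(out["hetero"].iloc[0])
    assert out["label"].iloc[0] == "hypo"


# ---------------------------------------------------------------------------
# the model on cohorts


def test_vectorized_fit_matches_per_cpg_path(small_cohort):
    """Mass matrix OLS/BP equals the single-CpG reference implementation."""
    _, beta, sheet, _ = small_cohort
    res = PassageDriftModel(beta.iloc[:25], sheet).fit()
    passage = sheet["passage"].to_numpy(dtype=float)
    for probe in beta.index[:25]:
        slope, p, resid = fit_passage_linear_model(beta.loc[probe], sheet)
        lm, bp_p = breusch_pagan(resid, passage)
        row = res.frame.loc[probe]
        assert row["slope"] == pytest.approx(slope, abs=1e-10)
        assert row["slope_p"] == pytest.approx(p, abs=1e-10)
        assert row["bp_lm"] == pytest.approx(lm, abs=1e-8)
        assert row["bp_p"] == pytest.approx(bp_p, abs=1e-10)


def test_missing_values_fall_back_to_complete_samples(small_cohort):
    _, beta, sheet, _ = small_cohort
    sub = beta.iloc[:10].copy()
    sub.iloc[0, [3, 7]] = np.nan
    res = PassageDriftModel(sub, sheet).fit()
    keep = ~sub.iloc[0].isna()
    slope, p, _ = fit_passage_linear_model(
        sub.iloc[0][keep], sheet[keep.to_numpy()].reset_index(drop=True)
    )
    assert res.frame["slope"].iloc[0] == pytest.approx(slope, abs=1e-10)
    assert res.frame["slope_p"].iloc[0] == pytest.approx(p, abs=1e-10)


def test_classification_invariant_to_sample_and_probe_order(small_cohort):
    _, beta, sheet, _ = small_cohort
    beta = beta.iloc[:200]
    res = PassageDriftModel(beta, sheet).fit()
    rng = np.random.default_rng(0)
    perm_rows = rng.permutation(len(beta))
    perm_cols = rng.permutation(beta.shape[1])
    shuffled = beta.iloc[perm_rows, perm_cols]
    res2 = PassageDriftModel(shuffled, sheet).fit()
    pd.testing.assert_frame_equal(
        res.frame.sort_index(), res2.frame.sort_index(), atol=1e-9
    )


def test_slope_and_delta_agree_in_sign_for_clean_trends(toy_sheet):
    beta = pd.DataFrame(
        {s: [0.2 + 0.03 * p, 0.8 - 0.03 * p] for s, p in zip(toy_sheet["sample_id"], toy_sheet["passage"])},
    )
    beta.index = ["up", "down"]
    res = PassageDriftModel(beta, toy_sheet, PassageDesign(high_passages=(5, 10))).fit()
    assert np.sign(res.frame.loc["up", "slope"]) == np.sign(res.frame.loc["up", "delta_beta"]) == 1
    assert np.sign(res.frame.loc["down", "slope"]) == np.sign(res.frame.loc["down", "delta_beta"]) == -1


def test_model_delta_beta_mode(toy_sheet):
    y = 0.3 + 0.02 * toy_sheet["passage"].to_numpy()
    beta = pd.DataFrame([y], index=["cg"], columns=toy_sheet["sample_id"])
    res = PassageDriftModel(
        beta, toy_sheet, PassageDesign(high_passages=(5, 10), delta_beta_mode="model")
    ).fit()
    # slope * observed span = 0.02 * 9
    assert res.frame["delta_beta"].iloc[0] == pytest.approx(0.18, abs=1e-9)


def test_null_cohort_directional_fdr_controlled():
    cfg = SimulationConfig(
        n_cpgs=4000, n_samples=40, n_donors=12,
        fraction_hypo=0, fraction_hyper=0, fraction_hetero=0, seed=21,
    )
    beta, sheet, _ = generate_cohort(cfg)
    res = PassageDriftModel(beta, sheet).fit()
    frac_directional = (res.frame["slope_q"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(beta))
    assert frac_directional <= 0.05 + 3 * se
    # BP at roughly nominal level (bounded beta noise is mildly conservative)
    assert 0.03 <= (res.frame["bp_p"] < 0.05).mean() <= 0.065


def test_donor_covariate_preserves_directional_calls(medium_cohort):
    _, beta, sheet, truth = medium_cohort
    res_plain = PassageDriftModel(beta, sheet).fit()
    res_donor = PassageDriftModel(beta, sheet, PassageDesign(donor_covariate=True)).fit()
    planted = truth.loc[truth["true_class"].isin(["hypo", "hyper"]), "probe_id"]
    a = res_plain.frame.loc[planted, ["hypo", "hyper"]]
    b = res_donor.frame.loc[planted, ["hypo", "hyper"]]
    agreement = (a.to_numpy() == b.to_numpy()).all(axis=1).mean()
    assert agreement > 0.95


def test_summary_reports_counts(small_cohort):
    _, beta, sheet, _ = small_cohort
    res = PassageDriftModel(beta, sheet).fit()
    text = res.summary()
    assert "hypo" in text and str(res.n_cpgs) in text
    counts = res.class_counts()
    assert counts["hypo"] + counts["hyper"] >= 1


# ---------------------------------------------------------------------------
# cross-cohort concordance


def test_identical_classifications_fully_concordant(small_cohort):
    _, beta, sheet, _ = small_cohort
    res = PassageDriftModel(beta, sheet).fit()
    rep = cross_cohort_concordance(res, res)
    for _, row in rep.class_overlap.iterrows():
        assert row["n_both"] == row["n_a"] == row["n_b"]
    assert rep.sign_agreement == 1.0


def test_all_stable_cohort_has_empty_intersections(small_cohort):
    _, beta, sheet, _ = small_cohort
    res = PassageDriftModel(beta, sheet).fit()
    cfg = SimulationConfig(
        n_cpgs=2000, n_samples=40, n_donors=12,
        fraction_hypo=0, fraction_hyper=0, fraction_hetero=0, seed=1,
    )
    beta_b, sheet_b, _ = generate_cohort(cfg)
    res_b = PassageDriftModel(beta_b, sheet_b).fit()
    rep = cross_cohort_concordance(res, res_b)
    assert (rep.class_overlap["n_both"] == 0).all()


def test_disjoint_probe_universes_raise(small_cohort):
    _, beta, sheet, _ = small_cohort
    res = PassageDriftModel(beta, sheet).fit()
    renamed = beta.copy()
    renamed.index = ["x" + p for p in beta.index]
    res_b = PassageDriftModel(renamed, sheet).fit()
    with pytest.raises(ValueError, match="share no probes"):
        cross_cohort_concordance(res, res_b)


def test_independent_cohorts_same_truth_agree_in_sign():
    """Two cohorts with the same planted classes but independent noise
    replicate the direction of drift on truly directional CpGs."""
    base = dict(n_cpgs=3000, n_samples=60, n_donors=15, fraction_hypo=0.05, fraction_hyper=0.03)
    beta_a, sheet_a, truth = generate_cohort(SimulationConfig(seed=100, **base))
    beta_b, sheet_b, _ = generate_cohort(SimulationConfig(seed=101, **base), ground_truth=truth)
    res_a = PassageDriftModel(beta_a, sheet_a).fit()
    res_b = PassageDriftModel(beta_b, sheet_b).fit()
    ids = truth.loc[truth["true_class"].isin(["hypo", "hyper"]), "probe_id"]
    called = (
        res_a.frame.loc[ids, ["hypo", "hyper"]].any(axis=1)
        | res_b.frame.loc[ids, ["hypo", "hyper"]].any(axis=1)
    )
    ids = ids[called.to_numpy()]
    assert len(ids) > 50
    sign_a = np.sign(res_a.frame.loc[ids, "delta_beta"])
    sign_b = np.sign(res_b.frame.loc[ids, "delta_beta"])
    assert (sign_a == sign_b).mean() > 0.9
    rep = cross_cohort_concordance(res_a, res_b)
    assert rep.n_shared == 3000
    assert rep.sign_agreement > 0.8
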