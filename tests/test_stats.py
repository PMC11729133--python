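import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasmorph import (
    fit_lmm,
    flow_ratio,
    group_contrast,
    icc_intra_rater,
    lrt_protrusion,
    stopbang_category,
    threshold_rules,
)


def _cohort(n_patients, slope=24.9, intercept=236.4, sd_b=50.0, sd_e=30.0,
            seed=0, keep=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        b = rng.normal(0, sd_b)
        for p in (0.0, 4.0, 8.0):
            if rng.random() <= keep:
                rows.append(
                    dict(patient_id=f"p{i:03d}", protrusion_mm=p,
                         y=intercept + slope * p + b + rng.normal(0, sd_e))
                )
    return pd.DataFrame(rows)


def test_noise_free_data_fit_exactly():
    rows = [
        dict(patient_id=f"p{i}", protrusion_mm=p, y=10.0 + 3.0 * p)
        for i in range(4)
        for p in (0.0, 4.0, 8.0)
    ]
    res = fit_lmm(pd.DataFrame(rows), "y")
    assert res.beta1 == pytest.approx(3.0, abs=1e-12)
    assert res.beta0 == pytest.approx(10.0, abs=1e-12)
    assert res.sigma_e == pytest.approx(0.0, abs=1e-9)


def test_zero_variance_outcome_gives_zero_slope_and_sigmas():
    rows = [
        dict(patient_id=f"p{i}", protrusion_mm=p, y=5.0)
        for i in range(3)
        for p in (0.0, 4.0, 8.0)
    ]
    res = fit_lmm(pd.DataFrame(rows), "y")
    assert res.beta1 == 0.0
    assert res.sigma_e == 0.0 and res.sigma_b == 0.0


def test_single_protrusion_level_is_singular():
    rows = [dict(patient_id=f"p{i}", protrusion_mm=4.0, y=float(i)) for i in range(6)]
    with pytest.raises(ValueError):
        fit_lmm(pd.DataFrame(rows), "y")


def test_balanced_fit_equals_direct_gls_oracle():
    """On a balanced 6-patient set the estimate equals the dense-matrix GLS
    solution at the fitted variance ratio (and the OLS slope) to 1e-8."""
    df = _cohort(6, seed=42)
    res = fit_lmm(df, "y")
    y = df["y"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df["protrusion_mm"].to_numpy()])
    groups = df["patient_id"].to_numpy()
    lam = (res.sigma_b / res.sigma_e) ** 2
    V = np.eye(len(df))
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        V[np.ix_(idx, idx)] += lam
    Vi = np.linalg.inv(V)
    beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    assert res.beta1 == pytest.approx(beta_gls[1], abs=1e-8)
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert res.beta1 == pytest.approx(beta_ols[1], abs=1e-8)


def test_unbalanced_fit_matches_statsmodels_mixedlm():
    import statsmodels.formula.api as smf

    df = _cohort(25, seed=3, keep=0.8)
    res = fit_lmm(df, "y")
    md = smf.mixedlm("y ~ protrusion_mm", df, groups=df["patient_id"]).fit(reml=True)
    assert res.beta1 == pytest.approx(md.params["protrusion_mm"], rel=1e-5)
    assert res.sigma_e == pytest.approx(np.sqrt(md.scale), rel=1e-4)
    assert res.sigma_b == pytest.approx(np.sqrt(md.cov_re.iloc[0, 0]), rel=1e-4)
    assert res.se_beta1 == pytest.approx(md.bse["protrusion_mm"], rel=0.02)


def test_lrt_is_zero_for_identical_outcomes_and_large_for_real_slopes():
    rows = [
        dict(patient_id=f"p{i}", protrusion_mm=p, y=7.0)
        for i in range(5)
        for p in (0.0, 4.0, 8.0)
    ]
    stat, p = lrt_protrusion(pd.DataFrame(rows), "y")
    assert stat == 0.0 and p == 1.0
    stat, p = lrt_protrusion(_cohort(40, seed=11, keep=0.9), "y")
    assert p < 0.001


def test_icc_of_exact_repeats_is_one():
    m = np.column_stack([np.arange(10.0) * 3 + 1] * 2)
    res = icc_intra_rater(m)
    assert res.icc == pytest.approx(1.0, abs=1e-12)
    assert res.high_consistency


def test_icc_matches_hand_computed_anova_table():
    """4 subjects x 2 repeats, worked through the mean-squares formula."""
    m = np.array([[10.0, 12.0], [20.0, 21.0], [30.0, 28.0], [40.0, 41.0]])
    n, k = m.shape
    grand = m.mean()
    ms_subj = k * np.sum((m.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_occ = n * np.sum((m.mean(axis=0) - grand) ** 2) / (k - 1)
    ms_err = (np.sum((m - grand) ** 2) - ms_subj * (n - 1) - ms_occ * (k - 1)) / ((n - 1) * (k - 1))
    expected = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    res = icc_intra_rater(m)
    assert res.icc == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin_icc3():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    truth = rng.normal(200, 80, 15)
    m = np.column_stack([truth + rng.normal(0, 5, 15), truth + rng.normal(0, 5, 15)])
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile([0, 1], 15),
            "score": m.ravel(),
        }
    )
    table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    mask = table["Type"].astype(str).str.replace(" ", "").isin(["ICC3", "ICC(C,1)"])
    icc3 = float(table.loc[mask, "ICC"].iloc[0])
    assert icc_intra_rater(m).icc == pytest.approx(icc3, abs=1e-10)


def test_icc_decreases_monotonically_with_noise():
    rng = np.random.default_rng(2)
    truth = rng.normal(200, 80, 40)
    iccs = []
    for sd in (0.0, 5.0, 20.0, 80.0):
        noise = rng.normal(0, 1, (40, 2))
        m = np.column_stack([truth, truth]) + sd * noise
        iccs.append(icc_intra_rater(m).icc)
    assert all(a > b for a, b in zip(iccs[:-1], iccs[1:]))


def test_icc_needs_three_subjects_and_two_repeats():
    with pytest.raises(ValueError):
        icc_intra_rater(np.ones((2, 2)))
    with pytest.raises(ValueError):
        icc_intra_rater(np.ones((5, 1)))


def test_threshold_rules_fractions_and_required_protrusion():
    rows = []
    vals = [40.0] * 4 + [200.0] * 44  # 4 of 48 below 52 mm^2 -> 8.3%
    for i, v in enumerate(vals):
        rows.append(dict(patient_id=f"p{i}", protrusion_mm=0.0, minCSA_mm2=v))
    rows.append(dict(patient_id="q0", protrusion_mm=4.0, minCSA_mm2=60.0))
    report = threshold_rules(pd.DataFrame(rows))
    assert report["fraction_below_small"][0.0] == pytest.approx(4 / 48, abs=1e-12)
    assert round(100 * report["fraction_below_small"][0.0], 1) == 8.3
    req = threshold_rules(
        pd.DataFrame([dict(patient_id="a", protrusion_mm=0.0, minCSA_mm2=60.0),
                      dict(patient_id="b", protrusion_mm=0.0, minCSA_mm2=140.0)])
    )["required_protrusion_mm"]
    assert req["a"] == pytest.approx((110.0 - 60.0) / 24.9)
    assert req["b"] == 0.0
    with pytest.raises(ValueError):
        threshold_rules(pd.DataFrame(rows), slope_mm2_per_mm=0.0)


def test_flow_ratio_values_and_errors():
    assert flow_ratio(123.4, 123.4) == 1.0
    assert flow_ratio(100.0, 200.0) == 4.0
    with pytest.raises(ValueError):
        flow_ratio(0.0, 100.0)
    with pytest.raises(ValueError):
        flow_ratio(100.0, -1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.floats(1e-3, 1e4),
    b=st.floats(1e-3, 1e4),
    b2=st.floats(1e-3, 1e4),
    c=st.floats(1e-3, 1e3),
)
def test_flow_ratio_is_scale_invariant_and_monotone(a, b, b2, c):
    assert flow_ratio(c * a, c * b) == pytest.approx(flow_ratio(a, b), rel=1e-9)
    lo, hi = sorted((b, b2))
    assert flow_ratio(a, lo) <= flow_ratio(a, hi)


def test_group_contrast_identical_groups_and_welch_oracle():
    rows = []
    for i, v in enumerate([1.0, 2.0, 3.0]):
        rows.append(dict(patient_id=f"a{i}", protrusion_mm=0.0, minCSA_mm2=v, arm="x"))
        rows.append(dict(patient_id=f"b{i}", protrusion_mm=0.0, minCSA_mm2=v, arm="y"))
    c = group_contrast(pd.DataFrame(rows), "arm", "minCSA_mm2", 0.0)
    assert c.difference == 0.0 and c.p_value == 1.0

    a = np.array([10.0, 12.0, 15.0])
    b = np.array([20.0, 18.0, 25.0])
    rows = [dict(patient_id=f"a{i}", protrusion_mm=4.0, minCSA_mm2=v, arm="x") for i, v in enumerate(a)]
    rows += [dict(patient_id=f"b{i}", protrusion_mm=4.0, minCSA_mm2=v, arm="y") for i, v in enumerate(b)]
    c = group_contrast(pd.DataFrame(rows), "arm", "minCSA_mm2", 4.0)
    # textbook Welch statistic
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (b.mean() - a.mean()) / np.sqrt(va + vb)
    assert abs(c.t_stat) == pytest.approx(abs(t), abs=1e-10)
    with pytest.raises(ValueError):
        group_contrast(pd.DataFrame(rows[:4]), "arm", "minCSA_mm2", 4.0)


def test_table2_style_contrast_detects_the_printed_p4_difference():
    """Groups drawn with the study's P4 radial-forearm vs other means/SDs
    (384.1 +/- 286.2 vs 243.7 +/- 158.8, n = 24/26) separate at p < 0.05 in
    the majority of replicates."""
    rng = np.random.default_rng(12)
    hits = 0
    reps = 40
    for _ in range(reps):
        rows = [
            dict(patient_id=f"a{i}", protrusion_mm=4.0, arm="rff",
                 minCSA_mm2=rng.normal(384.1, 286.2))
            for i in range(24)
        ] + [
            dict(patient_id=f"b{i}", protrusion_mm=4.0, arm="other",
                 minCSA_mm2=rng.normal(243.7, 158.8))
            for i in range(26)
        ]
        hits += group_contrast(pd.DataFrame(rows), "arm", "minCSA_mm2", 4.0).p_value < 0.05
    assert hits > reps / 2


@pytest.mark.parametrize(
    "score,cat",
    [(0, "low"), (2, "low"), (3, "moderate"), (4, "moderate"), (5, "high"), (8, "high")],
)
def test_stopbang_categories(score, cat):
    assert stopbang_category(score) == cat


@pytest.mark.parametrize("score", [-1, 9])
def test_stopbang_out_of_range(score):
    with pytest.raises(ValueError):
        stopbang_category(score)
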