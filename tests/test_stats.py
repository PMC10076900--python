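"""Agreement statistics against formula oracles and reference packages."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cartithick.errors import InsufficientDataError, PairingError
from cartithick.stats import (
    BlandAltman,
    agreement_report,
    bland_altman,
    detect_outlier_knees,
    lin_ccc,
    rm_anova_tukey,
    summarize,
)
from cartithick.thickness.base import ThicknessMap


def make_map(values, subregions, method="3D-NN", structure="tibia", knee="k0"):
    n = len(values)
    return ThicknessMap(
        method=method,
        structure=structure,
        origins=np.zeros((n, 3)),
        values=np.asarray(values, float),
        subregions=np.asarray(subregions),
        knee_id=knee,
    )


# ------------------------------------------------------------- summarize


def test_summarize_constant_samples():
    m = make_map([2.0] * 10, ["cLT"] * 5 + ["aLT"] * 5)
    s = summarize([m], knee_id="k0")
    assert (s["mean_mm"] == 2.0).all()


def test_summarize_matches_hand_computed_means():
    m = make_map([1.0, 2.0, 3.0, 10.0], ["cLT", "cLT", "aLT", "aLT"])
    s = summarize([m]).set_index(["level", "name"])["mean_mm"]
    assert s[("subregion", "cLT")] == pytest.approx(1.5)
    assert s[("subregion", "aLT")] == pytest.approx(6.5)
    assert s[("global", "joint")] == pytest.approx(4.0)


def test_global_mean_is_count_weighted_mean_of_subregions():
    rng = np.random.default_rng(3)
    vals = rng.uniform(1, 3, 50)
    subs = np.array(["cLT"] * 30 + ["pMF"] * 20)
    m = make_map(vals, subs)
    s = summarize([m])
    sub = s[s.level == "subregion"]
    weighted = (sub["mean_mm"] * sub["n"]).sum() / sub["n"].sum()
    assert s[s.level == "global"]["mean_mm"].iloc[0] == pytest.approx(weighted)


# ------------------------------------------------------------- outliers


def cohort_frame(values):
    """values: dict (knee, method) -> subregional mean for one subregion."""
    rows = [
        (k, m, "subregion", "cLT", v, 10) for (k, m), v in values.items()
    ]
    return pd.DataFrame(rows, columns=["knee_id", "method", "level", "name", "mean_mm", "n"])


def test_no_outliers_in_identical_cohort():
    vals = {(f"k{i}", m): 2.0 for i in range(5) for m in ("A", "B")}
    assert detect_outlier_knees(cohort_frame(vals)) == []


def planted_cohort(z):
    """Cohort where knee k0/method A sits exactly z pooled SDs from the mean."""
    rng = np.random.default_rng(0)
    vals = {(f"k{i}", m): float(v) for i, v in enumerate(rng.normal(2.0, 0.1, 30))
            for m in ("A", "B")}
    # iterate once: place the planted value so its z-score is exact by construction
    base = cohort_frame(vals)
    v = base["mean_mm"].to_numpy()
    for _ in range(40):
        mu, sd = v.mean(), v.std(ddof=1)
        planted = mu + z * sd
        v2 = v.copy()
        v2[0] = planted
        if abs((v2[0] - v2.mean()) / v2.std(ddof=1) - z) < 1e-12:
            break
        v = v2
    base["mean_mm"] = v2
    return base


def test_six_sd_knee_flagged_49_not():
    assert detect_outlier_knees(planted_cohort(6.0)) == ["k0"]
    assert detect_outlier_knees(planted_cohort(4.9)) == []


def test_outlier_removal_single_pass_idempotent():
    c = planted_cohort(6.0)
    first = detect_outlier_knees(c)
    clean = c[~c["knee_id"].isin(first)]
    assert detect_outlier_knees(clean) == [] or set(detect_outlier_knees(clean)) < set(
        clean["knee_id"]
    )


def test_zero_sd_subregion_flags_nobody():
    vals = {(f"k{i}", m): 2.0 for i in range(4) for m in ("A", "B")}
    c = cohort_frame(vals)
    assert detect_outlier_knees(c) == []


# ------------------------------------------------------------- RM-ANOVA


def rm_anova_oracle(mat):
    """Brute-force sums of squares by explicit loops."""
    n, k = mat.shape
    grand = mat.sum() / (n * k)
    ss_t = sum(n * (mat[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_s = sum(k * (mat[i, :].sum() / k - grand) ** 2 for i in range(n))
    ss_tot = sum((mat[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_e = ss_tot - ss_t - ss_s
    df_t, df_e = k - 1, (n - 1) * (k - 1)
    return (ss_t / df_t) / (ss_e / df_e), df_t, df_e, ss_e / df_e


def test_rm_anova_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    mat = 2.0 + rng.normal(0, 0.3, (6, 4))
    res = rm_anova_tukey(mat)
    f, df_t, df_e, ms_e = rm_anova_oracle(mat)
    assert res.f_value == pytest.approx(f, abs=1e-10)
    assert (res.df_treatment, res.df_error) == (df_t, df_e)
    assert res.ms_error == pytest.approx(ms_e, abs=1e-12)


def test_rm_anova_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(9)
    mat = 2.0 + rng.normal(0, 0.2, (8, 5))
    long = pd.DataFrame(
        [(i, j, mat[i, j]) for i in range(8) for j in range(5)],
        columns=["subject", "method", "value"],
    )
    ref = AnovaRM(long, "value", "subject", within=["method"]).fit()
    res = rm_anova_tukey(mat)
    assert res.f_value == pytest.approx(ref.anova_table["F Value"].iloc[0], rel=1e-9)
    assert res.p_value == pytest.approx(ref.anova_table["Pr > F"].iloc[0], rel=1e-9)


def test_rm_anova_identical_methods_f_zero_p_one():
    mat = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
    res = rm_anova_tukey(mat)
    assert res.f_value == 0.0
    assert res.p_value == 1.0
    assert (res.pairwise["p_adj"] == 1.0).all()


def test_rm_anova_invariant_to_constant_shift():
    rng = np.random.default_rng(1)
    mat = rng.normal(2, 0.3, (5, 3))
    a = rm_anova_tukey(mat)
    b = rm_anova_tukey(mat + 17.3)
    assert a.f_value == pytest.approx(b.f_value, rel=1e-9)
    pd.testing.assert_frame_equal(a.pairwise, b.pairwise, atol=1e-9)


def test_tukey_pairwise_matches_formula_oracle():
    from scipy.stats import studentized_range

    rng = np.random.default_rng(4)
    mat = 2.0 + rng.normal(0, 0.2, (7, 3))
    res = rm_anova_tukey(mat)
    _, _, df_e, ms_e = rm_anova_oracle(mat)
    means = mat.mean(axis=0)
    for _, row in res.pairwise.iterrows():
        i, j = int(row.method_a[1:]), int(row.method_b[1:])
        q = abs(means[i] - means[j]) / np.sqrt(ms_e / 7)
        assert row.p_adj == pytest.approx(studentized_range.sf(q, 3, df_e), abs=1e-10)


def test_rm_anova_insufficient_data():
    with pytest.raises(InsufficientDataError):
        rm_anova_tukey(np.ones((2, 5)))
    with pytest.raises(InsufficientDataError):
        rm_anova_tukey(np.ones((5, 1)))


# ------------------------------------------------------------- Bland-Altman / CCC


def test_bland_altman_identity_and_constant_shift():
    a = np.array([1.0, 2.0, 3.0])
    assert bland_altman(a, a) == BlandAltman(0.0, 0.0, 0.0, 0.0)
    ba = bland_altman(a, a - 0.5)
    assert ba.bias == pytest.approx(0.5)
    assert ba.loa_lower == pytest.approx(0.5) and ba.loa_upper == pytest.approx(0.5)


def test_bland_altman_matches_direct_formula():
    rng = np.random.default_rng(12)
    a, b = rng.normal(2, 0.3, 40), rng.normal(2, 0.3, 40)
    ba = bland_altman(a, b)
    d = a - b
    assert ba.bias == pytest.approx(d.mean(), abs=1e-12)
    assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
    assert ba.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)


def test_bland_altman_pairing_error():
    with pytest.raises(PairingError):
        bland_altman(np.ones(3), np.ones(4))


def test_ccc_limits_and_formula():
    a = np.array([0.5, -0.2, 1.3, 0.9])
    assert lin_ccc(a, a) == pytest.approx(1.0)
    z = a - a.mean()
    assert lin_ccc(z, -z) == pytest.approx(-1.0)
    b = a + 0.7
    expect = 2 * np.cov(a, b, bias=True)[0, 1] / (a.var() + b.var() + 0.7**2)
    assert lin_ccc(a, b) == pytest.approx(expect, abs=1e-12)
    assert lin_ccc(a, b) < np.corrcoef(a, b)[0, 1]


def test_ccc_undefined_for_two_constants():
    with pytest.raises(InsufficientDataError):
        lin_ccc(np.ones(5), np.ones(5))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-10, 10), min_size=3, max_size=20),
    st.integers(0, 2**31 - 1),
)
def test_ccc_symmetry_and_bounded_by_pearson(xs, seed):
    a = np.asarray(xs)
    rng = np.random.default_rng(seed)
    b = a + rng.normal(0, 1.0, len(a))
    if a.var() == 0 and b.var() == 0:
        return
    c1 = lin_ccc(a, b)
    assert c1 == pytest.approx(lin_ccc(b, a), abs=1e-12)
    assert -1.0 - 1e-12 <= c1 <= 1.0 + 1e-12
    if a.var() > 0 and b.var() > 0:
        r = np.corrcoef(a, b)[0, 1]
        assert abs(c1) <= abs(r) + 1e-9


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_bland_altman_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
    x, y = bland_altman(a, b), bland_altman(b, a)
    assert x.bias == pytest.approx(-y.bias, abs=1e-12)
    assert x.loa_upper == pytest.approx(-y.loa_lower, abs=1e-12)


# ------------------------------------------------------------- report


def test_agreement_report_identical_methods():
    rng = np.random.default_rng(8)
    rows = []
    for i in range(6):
        base = rng.normal(2, 0.2)
        for m in ("A", "B"):
            rows.append((f"k{i}", m, "subregion", "cLT", base, 10))
    cohort = pd.DataFrame(rows, columns=["knee_id", "method", "level", "name", "mean_mm", "n"])
    rep = agreement_report(cohort)
    assert rep["outliers"].empty
    pw = rep["pairwise"].iloc[0]
    assert pw["ccc"] == pytest.approx(1.0)
    assert pw["ba_bias"] == pytest.approx(0.0, abs=1e-12)
    assert not pw["significant"]
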