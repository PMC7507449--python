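"""Statistics: every result must match an independent computation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thighcomp import stats as ts
from thighcomp.errors import (
    DesignError,
    InputError,
    InsufficientDataError,
    UndefinedCorrelationError,
)


def _brute_force_mixed_anova(y, groups):
    """Textbook sums-of-squares decomposition via explicit loops.

    y is subjects x 2 (before, after); independent of the implementation
    under test.
    """
    labels = sorted(set(groups))
    n, k = y.shape
    gm = y.mean()
    ss_total = sum((y[i, t] - gm) ** 2 for i in range(n) for t in range(k))
    subj_mean = [y[i].mean() for i in range(n)]
    ss_bs = k * sum((sm - gm) ** 2 for sm in subj_mean)
    ss_group = 0.0
    for lab in labels:
        idx = [i for i in range(n) if groups[i] == lab]
        mg = np.mean([subj_mean[i] for i in idx])
        ss_group += k * len(idx) * (mg - gm) ** 2
    ss_subj = ss_bs - ss_group
    ss_time = sum(n * (y[:, t].mean() - gm) ** 2 for t in range(k))
    ss_cells = 0.0
    for lab in labels:
        idx = [i for i in range(n) if groups[i] == lab]
        for t in range(k):
            mgt = np.mean([y[i, t] for i in idx])
            ss_cells += len(idx) * (mgt - gm) ** 2
    ss_int = ss_cells - ss_group - ss_time
    ss_err = ss_total - ss_bs - ss_time - ss_int
    g = len(labels)
    out = {}
    out["time"] = (ss_time / (ss_err / ((n - g) * (k - 1))),
                   ss_time / (ss_time + ss_err))
    out["group"] = ((ss_group / (g - 1)) / (ss_subj / (n - g)),
                    ss_group / (ss_group + ss_subj))
    out["time x group"] = ((ss_int / (g - 1)) / (ss_err / ((n - g) * (k - 1))),
                           ss_int / (ss_int + ss_err))
    return out


def test_mixed_anova_matches_brute_force_to_1e8():
    rng = np.random.default_rng(7)
    n = 4  # per group
    before = rng.normal(100, 12, 2 * n)
    after = before + rng.normal(3, 6, 2 * n)
    groups = ["A"] * n + ["B"] * n
    res = {r.effect: r for r in ts.rm_anova(before, after, np.array(groups))}
    brute = _brute_force_mixed_anova(np.column_stack([before, after]), groups)
    for effect, (f, eta) in brute.items():
        assert res[effect].F == pytest.approx(f, abs=1e-8)
        assert res[effect].partial_eta_sq == pytest.approx(eta, abs=1e-8)
        assert 0.0 <= res[effect].partial_eta_sq <= 1.0


def test_mixed_anova_matches_pingouin_unbalanced():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    n1, n2 = 7, 13
    before = rng.normal(2000, 200, n1 + n2)
    after = before + np.where(np.arange(n1 + n2) < n1,
                              rng.normal(-342, 150, n1 + n2),
                              rng.normal(0, 150, n1 + n2))
    groups = np.array(["CTR"] * n1 + ["TR"] * n2)
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n1 + n2), 2),
        "time": ["before", "after"] * (n1 + n2),
        "group": np.repeat(groups, 2),
        "y": np.column_stack([before, after]).ravel(),
    })
    ref = pg.mixed_anova(long, dv="y", within="time", between="group",
                         subject="subject").set_index("Source")
    res = {r.effect: r for r in ts.rm_anova(before, after, groups)}
    for effect, src in [("time", "time"), ("group", "group"),
                        ("time x group", "Interaction")]:
        assert res[effect].F == pytest.approx(ref.loc[src, "F"], abs=1e-8)
        assert res[effect].p == pytest.approx(ref.loc[src, "p_unc"], abs=1e-8)
        assert res[effect].partial_eta_sq == pytest.approx(
            ref.loc[src, "np2"], abs=1e-8)


def test_anova_degenerate_and_null_constructions():
    # all values identical -> degenerate, zero SS
    res = ts.rm_anova([5.0] * 6, [5.0] * 6, ["A"] * 3 + ["B"] * 3)
    assert all(r.degenerate for r in res)
    assert all(r.F == 0.0 for r in res)
    # pure group offset, no time effect -> interaction exactly 0
    before = np.array([10.0, 11.0, 20.0, 21.0])
    after = before.copy()
    res = {r.effect: r for r in ts.rm_anova(before, after,
                                            np.array(["A", "A", "B", "B"]))}
    assert res["time x group"].partial_eta_sq == pytest.approx(0.0, abs=1e-12)


def test_anova_input_validation():
    with pytest.raises(DesignError):
        ts.rm_anova([1, 2], [1, 2], ["A", "A"])
    with pytest.raises(InputError):
        ts.rm_anova([1, np.nan], [1, 2], ["A", "B"])


def test_within_group_change_against_formula():
    rng = np.random.default_rng(3)
    b = rng.normal(700, 80, 9)
    a = b + rng.normal(-40, 25, 9)
    ch = ts.within_group_change(b, a)
    d = a - b
    assert ch.mean_change == pytest.approx(d.mean(), abs=1e-10)
    half = sps.t.ppf(0.975, 8) * d.std(ddof=1) / 3.0
    assert ch.ci_low == pytest.approx(d.mean() - half, abs=1e-10)
    assert ch.ci_high == pytest.approx(d.mean() + half, abs=1e-10)
    assert ch.ci_low <= ch.mean_change <= ch.ci_high


def test_within_group_change_constant_shift_has_zero_width_ci():
    ch = ts.within_group_change([1.0, 2.0, 3.0], [6.0, 7.0, 8.0])
    assert ch.mean_change == 5.0
    assert ch.ci_low == ch.ci_high == 5.0
    with pytest.raises(InsufficientDataError):
        ts.within_group_change([1.0], [2.0])


def test_aspin_welch_df_matches_hand_formula():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 8)
    b = rng.normal(2, 3, 6)
    t, df, p, d = ts.aspin_welch(a, b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df_hand = (va / 8 + vb / 6) ** 2 / (
        (va / 8) ** 2 / 7 + (vb / 6) ** 2 / 5)
    assert df == pytest.approx(df_hand, abs=1e-8)
    t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(t_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)


def test_aspin_welch_reduces_to_student_when_variances_equal():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, 10)
    b = a + 0.5  # same variance, same n
    t_w, df_w, p_w, _ = ts.aspin_welch(a, b)
    t_s, p_s = sps.ttest_ind(a, b, equal_var=True)
    assert t_w == pytest.approx(t_s, abs=1e-8)
    assert df_w == pytest.approx(18.0, abs=1e-8)
    assert p_w == pytest.approx(p_s, abs=1e-8)


def test_aspin_welch_degenerate_and_separation():
    t, df, p, d = ts.aspin_welch([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert t == 0.0 and p == 1.0
    rng = np.random.default_rng(8)
    for eps in (1.0, 0.1, 0.01):
        a = rng.normal(0, eps, 4)
        b = 10 + rng.normal(0, eps, 4)
        *_, p, _ = ts.aspin_welch(a, b)
        assert p < 0.05
    # p shrinks as the jitter shrinks
    ps = []
    for eps in (1.0, 0.1, 0.01):
        rng2 = np.random.default_rng(9)
        a = rng2.normal(0, eps, 4)
        b = 10 + rng2.normal(0, eps, 4)
        ps.append(ts.aspin_welch(a, b)[2])
    assert ps[2] < ps[1] < ps[0]


def test_bonferroni_monotone_and_capped():
    assert ts.bonferroni(0.01, 3) == pytest.approx(0.03)
    assert ts.bonferroni(0.5, 10) == 1.0
    ps = np.linspace(0, 1, 11)
    adj = [ts.bonferroni(p, 4) for p in ps]
    assert all(a2 >= a1 for a1, a2 in zip(adj, adj[1:]))
    assert max(adj) <= 1.0


def test_pearson_basics_and_errors(rng):
    x = np.arange(10.0)
    res = ts.pearson_with_power(x, x)
    assert res.r == pytest.approx(1.0)
    big = rng.standard_normal((2, 1000))
    res = ts.pearson_with_power(big[0], big[1])
    assert abs(res.r) < 0.1
    with pytest.raises(UndefinedCorrelationError):
        ts.pearson_with_power(np.ones(5), np.arange(5.0))
    with pytest.raises(InsufficientDataError):
        ts.pearson_with_power([1.0, 2.0], [1.0, 2.0])


def test_correlation_power_matches_published_value():
    # |r| = 0.626, n = 13, two-sided alpha .05 -> about 0.68 by Fisher z
    assert ts.correlation_power(-0.626, 13) == pytest.approx(0.677, abs=0.03)
    # power grows with n and with |r|
    assert ts.correlation_power(0.626, 20) > ts.correlation_power(0.626, 13)
    assert ts.correlation_power(0.8, 13) > ts.correlation_power(0.626, 13)


def _brute_force_icc(x):
    n, k = x.shape
    gm = x.mean()
    msr = k * sum((x[i].mean() - gm) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - gm) ** 2 for j in range(k)) / (k - 1)
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + gm) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_matches_brute_force_and_pingouin():
    rng = np.random.default_rng(21)
    x = rng.normal(50, 8, (10, 2))
    x[:, 1] = x[:, 0] + rng.normal(0, 2, 10)
    res = ts.icc_2_1(x)
    assert res.icc_2_1 == pytest.approx(_brute_force_icc(x), abs=1e-10)
    pg = pytest.importorskip("pingouin")
    long = pd.DataFrame({"targets": np.repeat(np.arange(10), 2),
                         "raters": ["r1", "r2"] * 10, "y": x.ravel()})
    ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                             ratings="y")
    icc_a1 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
    assert res.icc_2_1 == pytest.approx(icc_a1, abs=1e-10)


def test_icc_limits():
    rng = np.random.default_rng(22)
    base = rng.normal(10, 3, 8)
    dup = np.column_stack([base, base])
    res = ts.icc_2_1(dup)
    assert res.icc_2_1 == pytest.approx(1.0)
    assert res.sem == pytest.approx(0.0, abs=1e-6)
    wide = rng.normal(10, 3, 300)
    noisy = np.column_stack([wide, wide]) + rng.normal(0, 100, (300, 2))
    assert abs(ts.icc_2_1(noisy).icc_2_1) < 0.15
    with pytest.raises(InputError):
        ts.icc_2_1(np.array([[1.0, np.nan], [2.0, 3.0]]))


def test_analyze_cohort_produces_full_battery():
    rng = np.random.default_rng(30)
    rows = []
    for g, n, delta in [("TR", 6, 0.0), ("CTR", 6, -300.0)]:
        for i in range(n):
            b = rng.normal(2000, 150)
            a = b + delta + rng.normal(0, 100)
            for session, v in [("before", b), ("after", a)]:
                rows.append(dict(subject=f"{g}{i}", group=g, session=session,
                                 structure="QF", muscle_volume_cm3=v))
    report = ts.analyze_cohort(pd.DataFrame(rows))
    anova = report["anova"].set_index("effect")
    assert anova.loc["time x group", "p"] < 0.05
    assert set(report) == {"anova", "changes", "posthoc", "percent_change"}
    assert len(report["changes"]) == 2
    assert report["percent_change"].iloc[0].p < 0.05
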