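"""Statistical battery for longitudinal volume tables.

The analyses mirror the battery typically applied to before/after
muscle-volumetry cohorts:

* two-factor repeated-measures (mixed) ANOVA — time (before, after) as the
  within-subject factor, group as the between-subject factor — with partial
  eta squared (SS_effect / (SS_effect + SS_error)) as effect size, computed
  from an explicit sums-of-squares decomposition;
* Bonferroni-adjusted post-hoc paired comparisons with Cohen's d;
* within-group mean change with a t-based 95% confidence interval;
* the Aspin–Welch unequal-variance t test (Welch–Satterthwaite degrees of
  freedom) for between-group comparison of percentage changes;
* Pearson correlation with post-hoc power for the observed |r| at the given
  n via the Fisher z approximation (critical r from the exact t-based null,
  Fisher z with the r/(2(n-1)) bias term under the alternative — the
  formulation used by standard correlation power routines);
* ICC(2,1): two-way random-effects, absolute-agreement, single-measure
  intraclass correlation, with the standard error of measurement
  SEM = sd * sqrt(1 - ICC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DesignError,
    InputError,
    InsufficientDataError,
    UndefinedCorrelationError,
)


@dataclass
class AnovaResult:
    effect: str  # "time", "group" or "time x group"
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    degenerate: bool = False


@dataclass
class PosthocResult:
    comparison: str
    p_adjusted: float
    p_raw: float
    cohen_d: float


@dataclass
class ChangeSummary:
    mean_change: float
    ci_low: float
    ci_high: float
    n: int
    sd: float


@dataclass
class ReliabilityResult:
    icc_2_1: float
    sem: float
    n_subjects: int
    k_repetitions: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    ci_mean_x: tuple[float, float]
    ci_mean_y: tuple[float, float]
    power: float
    alpha: float


# ---------------------------------------------------------------------------
# mixed ANOVA

def rm_anova(before, after, groups) -> list[AnovaResult]:
    """Two-factor mixed ANOVA on paired before/after values.

    ``before``/``after`` are aligned per-subject arrays; ``groups`` the
    between-subject labels.  Returns results for the time and group main
    effects and the time-by-group interaction, each with partial eta
    squared.  Completely constant data are reported as degenerate with
    F = 0.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    g = np.asarray(groups)
    if b.shape != a.shape or b.shape != g.shape:
        raise InputError("before, after and groups must be aligned 1-D arrays")
    if np.isnan(b).any() or np.isnan(a).any():
        raise InputError("every subject needs both sessions (no missing values)")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise DesignError("mixed ANOVA needs at least two groups")
    ns = {lab: int((g == lab).sum()) for lab in labels}
    if min(ns.values()) < 2:
        raise DesignError("need at least 2 subjects per group")

    y = np.column_stack([b, a])  # subjects x time
    n_subj, k = y.shape
    gm = y.mean()
    ss_total = ((y - gm) ** 2).sum()

    subj_means = y.mean(axis=1)
    ss_between_subj = k * ((subj_means - gm) ** 2).sum()
    ss_group = k * sum(
        ns[lab] * (subj_means[g == lab].mean() - gm) ** 2 for lab in labels
    )
    ss_subj_within = ss_between_subj - ss_group

    time_means = y.mean(axis=0)
    ss_time = n_subj * ((time_means - gm) ** 2).sum()
    ss_cells = sum(
        ns[lab] * (y[g == lab, t].mean() - gm) ** 2
        for lab in labels for t in range(k)
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_inter

    n_groups = len(labels)
    df_group = (n_groups - 1, n_subj - n_groups)
    df_within = ((k - 1), (n_subj - n_groups) * (k - 1))

    def make(effect, ss_eff, ss_err, df_pair):
        df1, df2 = df_pair
        denom = ss_err / df2 if df2 > 0 else 0.0
        if denom <= 0 or ss_eff < 0:
            degenerate = ss_eff <= 0 or denom <= 0
            f = 0.0 if denom <= 0 else max(ss_eff, 0.0) / df1 / denom
            p = 1.0 if denom <= 0 else float(sps.f.sf(f, df1, df2))
            eta = 0.0 if (ss_eff + ss_err) <= 0 else max(ss_eff, 0.0) / (ss_eff + ss_err)
            return AnovaResult(effect, f, df_pair, p, eta, ss_eff, ss_err,
                               degenerate=degenerate)
        f = (ss_eff / df1) / denom
        p = float(sps.f.sf(f, df1, df2))
        eta = ss_eff / (ss_eff + ss_err)
        return AnovaResult(effect, float(f), df_pair, p, float(eta),
                           float(ss_eff), float(ss_err))

    return [
        make("time", ss_time, ss_err_within, df_within),
        make("group", ss_group, ss_subj_within, df_group),
        make("time x group", ss_inter, ss_err_within,
             ((n_groups - 1) * (k - 1), df_within[1])),
    ]


# ---------------------------------------------------------------------------
# within-group change and post-hoc tests

def within_group_change(before, after, confidence: float = 0.95) -> ChangeSummary:
    """Mean per-subject (after - before) with a t-based confidence interval."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise InputError("before and after must be paired (same shape)")
    n = b.size
    if n < 2:
        raise InsufficientDataError("need at least 2 paired observations")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n)
    return ChangeSummary(mean_change=mean, ci_low=mean - half, ci_high=mean + half,
                         n=n, sd=sd)


def bonferroni(p: float, n_comparisons: int) -> float:
    """min(1, p x number of comparisons)."""
    if not 0.0 <= p <= 1.0:
        raise InputError("p must lie in [0, 1]")
    if n_comparisons < 1:
        raise InputError("need at least one comparison")
    return min(1.0, p * n_comparisons)


def cohen_d_independent(a, b) -> float:
    """Cohen's d with the pooled standard deviation of the two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def posthoc_paired(before, after, comparison: str,
                   n_comparisons: int = 1) -> PosthocResult:
    """Bonferroni-adjusted paired t test with Cohen's d (pooled sd)."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size or b.size < 2:
        raise InsufficientDataError("need at least 2 paired observations")
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    return PosthocResult(comparison=comparison,
                         p_adjusted=bonferroni(float(p), n_comparisons),
                         p_raw=float(p),
                         cohen_d=cohen_d_independent(a, b))


# ---------------------------------------------------------------------------
# Aspin–Welch t test

def aspin_welch(group_a, group_b):
    """Unequal-variance t test: (t, df, p, cohen_d).

    Degrees of freedom by Welch–Satterthwaite; Cohen's d uses the pooled
    standard deviation.  Two zero-variance samples with equal means are
    degenerate and reported as t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0, 0.0
        return np.inf * np.sign(a.mean() - b.mean()), float(na + nb - 2), 0.0, \
            cohen_d_independent(a, b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p), cohen_d_independent(a, b)


# ---------------------------------------------------------------------------
# Pearson correlation with post-hoc power

def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sided Pearson test at the observed |r|.

    Fisher z approximation: the critical r comes from the exact t-based
    null (df = n - 2); under the alternative, atanh(r) is normal with mean
    atanh(rho) + rho / (2(n - 1)) and sd 1 / sqrt(n - 3).
    """
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must lie in (0, 1)")
    if n < 4:
        raise InsufficientDataError("power needs n >= 4")
    r = abs(float(r))
    if r >= 1.0:
        return 1.0
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, n - 2)
    r_crit = np.sqrt(t_crit ** 2 / (t_crit ** 2 + n - 2))
    zr = np.arctanh(r) + r / (2.0 * (n - 1))
    zc = np.arctanh(r_crit)
    s = np.sqrt(n - 3)
    return float(sps.norm.cdf((zr - zc) * s) + sps.norm.cdf((-zr - zc) * s))


def _mean_ci(x, confidence=0.95):
    n = x.size
    half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * x.std(ddof=1) / np.sqrt(n)
    return (float(x.mean() - half), float(x.mean() + half))


def pearson_with_power(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with two-sided p, mean CIs of both variables, and power."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be aligned 1-D arrays")
    if x.size < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), n=x.size,
        ci_mean_x=_mean_ci(x), ci_mean_y=_mean_ci(y),
        power=correlation_power(r, x.size, alpha), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# reliability

def icc_2_1(measurements) -> ReliabilityResult:
    """ICC(2,1) with SEM, from the two-way ANOVA mean squares.

    ``measurements`` is a complete subjects x repetitions grid (n >= 2,
    k >= 2).  ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n);
    SEM = sd x sqrt(1 - ICC) with sd the standard deviation of all
    measurements.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise InputError("measurements must be a 2-D subjects x repetitions grid")
    if np.isnan(x).any():
        raise InputError("measurement grid must be complete")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("ICC needs >= 2 subjects and >= 2 repetitions")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - gm) ** 2).sum()
    ss_cols = n * ((col_means - gm) ** 2).sum()
    ss_total = ((x - gm) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = 0.0 if denom == 0 else (msr - mse) / denom
    sd = x.std(ddof=1)
    sem = float(sd * np.sqrt(max(0.0, 1.0 - icc)))
    return ReliabilityResult(icc_2_1=float(icc), sem=sem, n_subjects=n,
                             k_repetitions=k)


# ---------------------------------------------------------------------------
# cohort-level battery

def analyze_cohort(volume_table: pd.DataFrame,
                   value_column: str = "muscle_volume_cm3",
                   alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Run the full battery on a tidy volume table.

    Expects columns subject, group, session ("before"/"after"), structure
    and the value column.  Returns tidy frames: "anova" (per structure),
    "changes" (within-group change with CI), "posthoc" (Bonferroni paired
    tests), and "percent_change" (Aspin–Welch on percentage changes).
    """
    required = {"subject", "group", "session", "structure", value_column}
    missing = required - set(volume_table.columns)
    if missing:
        raise InputError(f"volume table missing columns: {sorted(missing)}")
    wide = volume_table.pivot_table(
        index=["subject", "group", "structure"], columns="session",
        values=value_column, aggfunc="first",
    ).reset_index()
    if not {"before", "after"} <= set(wide.columns):
        raise InputError('sessions must include "before" and "after"')

    anova_rows, change_rows, posthoc_rows, pct_rows = [], [], [], []
    for structure, sub in wide.groupby("structure"):
        sub = sub.dropna(subset=["before", "after"])
        groups = pd.unique(sub["group"])
        if len(groups) >= 2 and min((sub["group"] == g).sum() for g in groups) >= 2:
            for res in rm_anova(sub["before"].values, sub["after"].values,
                                sub["group"].values):
                anova_rows.append(dict(structure=structure, effect=res.effect,
                                       F=res.F, df1=res.df[0], df2=res.df[1],
                                       p=res.p, partial_eta_sq=res.partial_eta_sq,
                                       degenerate=res.degenerate))
        pct = {}
        for grp, cell in sub.groupby("group"):
            if len(cell) < 2:
                continue
            ch = within_group_change(cell["before"].values, cell["after"].values)
            change_rows.append(dict(structure=structure, group=grp,
                                    mean_change=ch.mean_change, ci_low=ch.ci_low,
                                    ci_high=ch.ci_high, n=ch.n, sd=ch.sd))
            ph = posthoc_paired(cell["before"].values, cell["after"].values,
                                comparison=f"{structure}/{grp}: before vs after",
                                n_comparisons=len(groups))
            posthoc_rows.append(dict(structure=structure, group=grp,
                                     p_adjusted=ph.p_adjusted, p_raw=ph.p_raw,
                                     cohen_d=ph.cohen_d))
            ok = cell["before"] > 0
            if ok.sum() >= 2:
                pct[grp] = (100.0 * (cell["after"][ok] - cell["before"][ok])
                            / cell["before"][ok]).values
        if len(pct) == 2:
            (ga, xa), (gb, xb) = sorted(pct.items())
            t, df, p, d = aspin_welch(xa, xb)
            pct_rows.append(dict(structure=structure, comparison=f"{ga} vs {gb}",
                                 t=t, df=df, p=p, cohen_d=d,
                                 mean_a=float(np.mean(xa)), mean_b=float(np.mean(xb))))
    return {
        "anova": pd.DataFrame(anova_rows),
        "changes": pd.DataFrame(change_rows),
        "posthoc": pd.DataFrame(posthoc_rows),
        "percent_change": pd.DataFrame(pct_rows),
    }
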