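"""Cerebrovascular-reactivity metrics and group statistics.

From a Δ[HbT]% time course around a vasoconstrictive stimulus three
summary statistics are extracted:

* peak response — the most negative value of the (lightly smoothed) trace
  after the injection; % change, ≤ 0 for constriction;
* recovery time (RT) — minutes from injection until the trace re-enters
  the baseline band (baseline mean − k·baseline sd, k = 1 by default) and
  stays there for a dwell period (60 s default);
* integrated reactivity (IR) — the signed trapezoidal integral of the
  trace from injection to recovery, in %·min.

Group comparisons use the pooled-variance two-sample two-tailed t-test and
a 2×2 (sex × group) ANOVA with Bonferroni-adjusted pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CvrMetrics",
    "smooth_trace",
    "peak_response",
    "recovery_time",
    "integrated_reactivity",
    "cvr_metrics",
    "group_ttest",
    "sex_by_group_anova",
]


@dataclass
class CvrMetrics:
    peak_response_pct: float
    integrated_reactivity: float  # %·min (often reported as a.u.)
    recovery_time_min: float
    recovered: bool
    note: str = ""


def smooth_trace(time_s: np.ndarray, y: np.ndarray,
                 window_s: float = 30.0) -> np.ndarray:
    """Centred moving average on the actual timestamps.

    Handles irregular sampling: each output sample is the mean of all
    samples within ±window/2.  window_s <= 0 returns the input unchanged.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(y, dtype=float)
    if window_s <= 0:
        return y.copy()
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    c = np.concatenate([[0.0], np.cumsum(y)])
    return (c[hi] - c[lo]) / (hi - lo)


def peak_response(time_s: np.ndarray, y_pct: np.ndarray, t_inject_s: float,
                  smooth_window_s: float = 30.0) -> float:
    """Maximum decrease of Δ[HbT]% after the injection (minimum of the
    smoothed trace on the post-injection interval)."""
    t = np.asarray(time_s, dtype=float)
    post = t > t_inject_s
    if not post.any():
        raise ValueError("no samples after the injection time")
    ys = smooth_trace(t, y_pct, smooth_window_s)
    return float(ys[post].min())


def _baseline_stats(t: np.ndarray, y: np.ndarray,
                    baseline_window_s: tuple[float, float]) -> tuple[float, float]:
    t0, t1 = baseline_window_s
    m = (t >= t0) & (t <= t1)
    if m.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    return float(y[m].mean()), float(y[m].std(ddof=1))


def recovery_time(time_s: np.ndarray, y_pct: np.ndarray, t_inject_s: float,
                  baseline_window_s: tuple[float, float],
                  k: float = 1.0, dwell_s: float = 60.0,
                  smooth_window_s: float = 30.0) -> tuple[float, bool, str]:
    """Time for the trace to return to the baseline band.

    Returns (RT in minutes from injection, recovered flag, note).  The band
    threshold is baseline mean − k·baseline sd.  RT is the first time after
    the nadir at which the smoothed trace rises above the threshold and
    stays above it for ``dwell_s``.  If the trace never departs the band
    (no response) RT = 0 with a note; if it never recovers, RT spans the
    record and the flag is False.
    """
    t = np.asarray(time_s, dtype=float)
    mean, sd = _baseline_stats(t, np.asarray(y_pct, dtype=float),
                               baseline_window_s)
    thresh = mean - k * sd
    ys = smooth_trace(t, y_pct, smooth_window_s)
    post = np.nonzero(t > t_inject_s)[0]
    if post.size == 0:
        raise ValueError("no samples after the injection time")
    nadir_idx = post[np.argmin(ys[post])]
    if ys[nadir_idx] > thresh:
        return 0.0, True, "no response: trace never departs the baseline band"
    above = ys > thresh
    record_end = t[-1]
    for i in range(nadir_idx + 1, t.size):
        if not above[i]:
            continue
        j = np.searchsorted(t, t[i] + dwell_s, side="left")
        seg = above[i:j] if j > i else above[i:i + 1]
        if seg.all():
            return (t[i] - t_inject_s) / 60.0, True, ""
    return (record_end - t_inject_s) / 60.0, False, "not recovered within record"


def integrated_reactivity(time_s: np.ndarray, y_pct: np.ndarray,
                          t_inject_s: float, rt_min: float,
                          smooth_window_s: float = 30.0) -> float:
    """Signed trapezoidal integral of the smoothed trace over
    [t_inject, t_inject + RT], in %·min."""
    if rt_min <= 0:
        return 0.0
    t = np.asarray(time_s, dtype=float)
    ys = smooth_trace(t, y_pct, smooth_window_s)
    t_end = t_inject_s + rt_min * 60.0
    m = (t >= t_inject_s) & (t <= t_end)
    if m.sum() < 2:
        return 0.0
    tt, yy = t[m], ys[m]
    # close the window ends by linear interpolation so IR does not depend
    # on where samples happen to fall
    if tt[0] > t_inject_s and m.argmax() > 0:
        y0 = float(np.interp(t_inject_s, t, ys))
        tt, yy = np.concatenate([[t_inject_s], tt]), np.concatenate([[y0], yy])
    if tt[-1] < t_end and t[-1] >= t_end:
        y1 = float(np.interp(t_end, t, ys))
        tt, yy = np.concatenate([tt, [t_end]]), np.concatenate([yy, [y1]])
    return float(np.trapezoid(yy, tt) / 60.0)


def cvr_metrics(time_s: np.ndarray, y_pct: np.ndarray, t_inject_s: float,
                baseline_window_s: tuple[float, float], k: float = 1.0,
                dwell_s: float = 60.0,
                smooth_window_s: float = 30.0) -> CvrMetrics:
    """Peak response, RT and IR of one Δ[HbT]% trace."""
    peak = peak_response(time_s, y_pct, t_inject_s, smooth_window_s)
    rt, recovered, note = recovery_time(time_s, y_pct, t_inject_s,
                                        baseline_window_s, k, dwell_s,
                                        smooth_window_s)
    ir = integrated_reactivity(time_s, y_pct, t_inject_s, rt, smooth_window_s)
    return CvrMetrics(peak_response_pct=peak, integrated_reactivity=ir,
                      recovery_time_min=rt, recovered=recovered, note=note)


def group_ttest(values_a, values_b) -> tuple[float, int, float]:
    """Pooled-variance two-sample two-tailed Student t-test.

    Returns (t, df, p).  Degenerate case: zero pooled variance with equal
    means gives (0, df, 1); with unequal means it is an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    from scipy import stats

    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def sex_by_group_anova(table, value_col: str = "value",
                       sex_col: str = "sex", group_col: str = "group"):
    """2×2 (sex × group) ANOVA with Bonferroni-adjusted pairwise t-tests.

    ``table`` is a long-format DataFrame with one row per animal.  Type-II
    sums of squares (robust to the mildly unbalanced cells of a typical
    cohort; identical to Type I/III when balanced).  Returns a dict with
    the ANOVA table and the four pairwise contrasts (within-sex group
    differences and within-group sex differences), each with raw and
    Bonferroni-corrected p (×4, capped at 1).
    """
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(table).rename(columns={value_col: "value",
                                             sex_col: "sex",
                                             group_col: "group"})
    cells = df.groupby(["sex", "group"])["value"]
    if len(cells.count()) < 4 or (cells.count() < 1).any():
        raise ValueError("all four sex × group cells must be nonempty")
    if (cells.var(ddof=1).fillna(0.0) == 0).all():
        raise ValueError("zero within-cell variance")
    model = smf.ols("value ~ C(sex) * C(group)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)

    sexes = sorted(df["sex"].unique())
    groups = sorted(df["group"].unique())
    contrasts = []
    for s in sexes:
        sub = df[df["sex"] == s]
        t, dof, p = group_ttest(sub[sub["group"] == groups[0]]["value"],
                                sub[sub["group"] == groups[1]]["value"])
        contrasts.append({"contrast": f"{groups[0]} vs {groups[1]} ({s})",
                          "t": t, "df": dof, "p": p})
    for g in groups:
        sub = df[df["group"] == g]
        t, dof, p = group_ttest(sub[sub["sex"] == sexes[0]]["value"],
                                sub[sub["sex"] == sexes[1]]["value"])
        contrasts.append({"contrast": f"{sexes[0]} vs {sexes[1]} ({g})",
                          "t": t, "df": dof, "p": p})
    n_comp = len(contrasts)
    for c in contrasts:
        c["p_bonferroni"] = min(1.0, c["p"] * n_comp)
    return {"anova": aov, "pairwise": pd.DataFrame(contrasts)}
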