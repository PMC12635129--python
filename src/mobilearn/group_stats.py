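"""Mixed-design ANOVA, post-hoc tests and related group statistics.

The design is the classic split-plot: one between-subject factor (age
group or behavioural cluster) crossed with one within-subject factor (the
six 2-min phases B, P1–P5), response = mean displacement rate per phase.
Sums of squares follow the univariate mixed-model partition:

    SS_total = SS_between + SS_subjects_within_groups
               + SS_within + SS_interaction + SS_within_error

with the between effect tested against subjects-within-groups
(df = N − g) and the within effect and interaction tested against the
subject × phase residual (df = (p − 1)(N − g)).  Unequal group sizes are
handled with weighted (cell-size) means, the convention used by standard
repeated-measures software for a single between factor.  No sphericity
correction is applied by default so degrees of freedom match the classical
table; a Greenhouse–Geisser option is exposed.

Effect sizes are partial η² = SS_effect / (SS_effect + SS_error) with 95%
confidence intervals from inversion of the noncentral-F distribution.
Post-hoc pairwise comparisons use Tukey's HSD (Tukey–Kramer for unequal
n) on the design's error term.  The family-wise significance threshold is
α = 0.01 throughout; Bonferroni division is applied only to families of
simple-main-effect tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateVarianceError,
    IncompleteDesignError,
    InsufficientDataError,
)

__all__ = [
    "mixed_anova",
    "simple_main_effects",
    "tukey_hsd",
    "origin_regression",
    "learner_flag",
    "partial_eta_sq_ci",
    "format_effect",
]

ALPHA_DEFAULT = 0.01


def _check_table(data: pd.DataFrame, subject, within, between, value):
    for col in (subject, within, between, value):
        if col not in data.columns:
            raise IncompleteDesignError(f"missing column {col!r}")
    counts = data.groupby([subject, within], observed=True)[value].count()
    if (counts != 1).any():
        raise IncompleteDesignError(
            "each subject must have exactly one value per within level"
        )
    per_subj = data.groupby(subject, observed=True)[within].nunique()
    if per_subj.nunique() != 1:
        raise IncompleteDesignError("subjects must share the within levels")
    groups = data.groupby(subject, observed=True)[between].nunique()
    if (groups != 1).any():
        raise IncompleteDesignError("each subject must have exactly one group")


def partial_eta_sq_ci(
    F: float, df1: float, df2: float, conf: float = 0.95
) -> tuple[float, float]:
    """CI for partial η² by inverting the noncentral-F distribution.

    Finds noncentrality bounds λ with ``P(F_obs | λ) = (1±conf)/2`` and
    maps them through η² = λ / (λ + df1 + df2 + 1); the lower bound is
    clipped at 0.
    """
    if not np.isfinite(F):
        return (np.nan, np.nan)
    alpha2 = (1.0 - conf) / 2.0

    def bound(prob):
        # find λ such that ncf.cdf(F; λ) = prob
        f = lambda lam: stats.ncf.cdf(F, df1, df2, lam) - prob
        if f(0.0) < 0:  # even λ=0 puts F below the target quantile
            return 0.0
        hi = 1.0
        while f(hi) > 0 and hi < 1e7:
            hi *= 2
        if f(hi) > 0:  # F so extreme the bound saturates
            return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = bound(1.0 - alpha2)
    lam_hi = bound(alpha2)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1.0)
    return (to_eta(lam_lo), to_eta(lam_hi))


def mixed_anova(
    data: pd.DataFrame,
    subject: str = "subject_id",
    within: str = "phase",
    between: str = "group",
    value: str = "value",
    sphericity_correction: bool = False,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Two-way mixed (split-plot) ANOVA.

    Returns one row per effect (between, within, interaction) with SS,
    df, F, p, partial η² and its confidence interval, plus the two error
    strata.  ``sphericity_correction=True`` applies Greenhouse–Geisser
    epsilon to the within-factor degrees of freedom.
    """
    _check_table(data, subject, within, between, value)
    wide = data.pivot_table(
        index=[subject, between], columns=within, values=value, observed=True
    )
    if wide.isna().any().any():
        raise IncompleteDesignError("missing cells in the subject × phase table")

    Y = wide.to_numpy()  # (N subjects, p phases)
    N, p = Y.shape
    grp = wide.index.get_level_values(between)
    levels = list(pd.unique(grp))
    g = len(levels)
    if g < 2:
        raise IncompleteDesignError("need at least two between-subject levels")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    phase_means = Y.mean(axis=0)

    ss_total = ((Y - grand) ** 2).sum()
    ss_subj = p * ((subj_means - grand) ** 2).sum()

    ss_between = 0.0
    ss_inter = 0.0
    for lv in levels:
        sel = grp == lv
        ng = sel.sum()
        gmean = Y[sel].mean()
        ss_between += p * ng * (gmean - grand) ** 2
        cell = Y[sel].mean(axis=0)  # (p,)
        ss_inter += ng * ((cell - gmean - phase_means + grand) ** 2).sum()

    ss_err_between = ss_subj - ss_between
    ss_within = N * ((phase_means - grand) ** 2).sum()
    ss_err_within = ss_total - ss_subj - ss_within - ss_inter

    df_between, df_err_b = g - 1, N - g
    df_within = p - 1
    df_inter = (g - 1) * (p - 1)
    df_err_w = (p - 1) * (N - g)

    eps = 1.0
    if sphericity_correction:
        eps = _gg_epsilon(Y)

    tol = 1e-12 * max(ss_total, 1.0)
    if ss_err_between <= tol or ss_err_within <= tol:
        raise DegenerateVarianceError("an error stratum has zero variance")

    def row(name, ss, df1, ss_err, df2, correct=False):
        d1, d2 = (df1 * eps, df2 * eps) if correct else (df1, df2)
        F = (ss / d1) / (ss_err / d2)
        pval = stats.f.sf(F, d1, d2)
        np2 = ss / (ss + ss_err)
        lo, hi = partial_eta_sq_ci(F, d1, d2, conf)
        return {
            "source": name,
            "SS": ss,
            "df1": d1,
            "df2": d2,
            "F": F,
            "p": pval,
            "partial_eta_sq": np2,
            "eta_ci_low": lo,
            "eta_ci_high": hi,
        }

    table = pd.DataFrame(
        [
            row("between", ss_between, df_between, ss_err_between, df_err_b),
            row("within", ss_within, df_within, ss_err_within, df_err_w, True),
            row("interaction", ss_inter, df_inter, ss_err_within, df_err_w, True),
        ]
    )
    table.attrs.update(
        {
            "SS_error_between": ss_err_between,
            "SS_error_within": ss_err_within,
            "df_error_between": df_err_b,
            "df_error_within": df_err_w,
            "SS_total": ss_total,
            "n_subjects": N,
            "n_within": p,
            "n_between": g,
            "between_levels": levels,
            "gg_epsilon": eps,
        }
    )
    return table


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the within-subject covariance."""
    S = np.cov(Y, rowvar=False)
    p = S.shape[0]
    mean_diag = np.trace(S) / p
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (p * (mean_diag - mean_all)) ** 2
    den = (p - 1) * (
        (S**2).sum() - 2 * p * (row_means**2).sum() + p**2 * mean_all**2
    )
    return float(num / den)


def simple_main_effects(
    data: pd.DataFrame,
    direction: str = "within-at-between",
    subject: str = "subject_id",
    within: str = "phase",
    between: str = "group",
    value: str = "value",
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Simple-main-effect F tests after a significant interaction.

    ``within-at-between``: per group, the phase effect tested against the
    omnibus subject × phase error (df matching the omnibus table, e.g.
    F(5, 915)).  ``between-at-within``: per phase, a one-way ANOVA across
    groups on that phase's values (error df N − g).  The significance
    threshold is Bonferroni-divided by the number of slices.
    """
    omnibus = mixed_anova(data, subject, within, between, value)
    a = omnibus.attrs
    rows = []
    if direction == "within-at-between":
        ms_err = a["SS_error_within"] / a["df_error_within"]
        df2 = a["df_error_within"]
        slices = a["between_levels"]
        for lv in slices:
            sub = data[data[between] == lv]
            wide = sub.pivot_table(
                index=subject, columns=within, values=value, observed=True
            ).to_numpy()
            ng = wide.shape[0]
            pm = wide.mean(axis=0)
            ss = ng * ((pm - wide.mean()) ** 2).sum()
            df1 = a["n_within"] - 1
            F = (ss / df1) / ms_err
            rows.append((lv, ss, df1, df2, F))
    elif direction == "between-at-within":
        slices = list(data[within].unique())
        for ph in slices:
            sub = data[data[within] == ph]
            groups = [
                v[value].to_numpy() for _, v in sub.groupby(between, observed=True)
            ]
            ns = np.array([len(x) for x in groups])
            means = np.array([x.mean() for x in groups])
            grand = np.concatenate(groups).mean()
            ss = (ns * (means - grand) ** 2).sum()
            ss_err = sum(((x - x.mean()) ** 2).sum() for x in groups)
            df1, df2 = len(groups) - 1, int(ns.sum()) - len(groups)
            F = (ss / df1) / (ss_err / df2)
            rows.append((ph, ss, df1, df2, F))
    else:
        raise ValueError(f"unknown direction {direction!r}")

    threshold = alpha / len(rows)
    out = pd.DataFrame(
        rows, columns=["slice", "SS", "df1", "df2", "F"]
    )
    out["p"] = stats.f.sf(out["F"], out["df1"], out["df2"])
    # partial η² per slice, written in terms of F so it uses the same
    # error stratum as the test itself
    out["partial_eta_sq"] = (out["F"] * out["df1"]) / (
        out["F"] * out["df1"] + out["df2"]
    )
    cis = [partial_eta_sq_ci(f, d1, d2) for f, d1, d2 in zip(out.F, out.df1, out.df2)]
    out["eta_ci_low"] = [c[0] for c in cis]
    out["eta_ci_high"] = [c[1] for c in cis]
    out["threshold"] = threshold
    out["significant"] = out["p"] < threshold
    return out


def tukey_hsd(
    values: np.ndarray,
    groups: np.ndarray,
    ms_error: float | None = None,
    df_error: float | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (Tukey–Kramer for unequal n).

    With ``ms_error``/``df_error`` given, comparisons are made on that
    error term (e.g. the subject × phase stratum for the within factor);
    otherwise the pooled one-way within-group mean square is used.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise InsufficientDataError("need at least two levels")
    samples = {lv: values[groups == lv] for lv in levels}
    ns = {lv: len(s) for lv, s in samples.items()}
    if any(n < 2 for n in ns.values()):
        raise InsufficientDataError("each level needs at least two observations")
    if ms_error is None:
        df_error = sum(ns.values()) - len(levels)
        ms_error = (
            sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / df_error
        )
    if ms_error <= 0:
        raise DegenerateVarianceError("zero error variance in Tukey HSD")
    k = len(levels)
    rows = []
    for a_, b_ in combinations(levels, 2):
        diff = samples[a_].mean() - samples[b_].mean()
        se = np.sqrt(ms_error / 2.0 * (1.0 / ns[a_] + 1.0 / ns[b_]))
        q = abs(diff) / se
        p_adj = stats.studentized_range.sf(q, k, df_error)
        p_adj = float(np.clip(p_adj, 0.0, 1.0))
        rows.append(
            {
                "level_a": a_,
                "level_b": b_,
                "mean_diff": diff,
                "q": q,
                "p_adj": p_adj,
                "reject": p_adj < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs.update({"ms_error": ms_error, "df_error": df_error, "alpha": alpha})
    return out


def tukey_hsd_within(
    data: pd.DataFrame,
    subject: str = "subject_id",
    within: str = "phase",
    between: str = "group",
    value: str = "value",
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Tukey HSD across within-subject levels using the omnibus
    subject × phase error term and its degrees of freedom."""
    omnibus = mixed_anova(data, subject, within, between, value)
    a = omnibus.attrs
    ms = a["SS_error_within"] / a["df_error_within"]
    return tukey_hsd(
        data[value].to_numpy(),
        data[within].to_numpy(),
        ms_error=ms,
        df_error=a["df_error_within"],
        alpha=alpha,
    )


def origin_regression(x, y) -> float:
    """Least-squares slope of a regression line constrained through the
    origin: coef = Σxy / Σx²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float((x * x).sum())
    if sxx == 0:
        raise DegenerateVarianceError("all x are zero; slope undefined")
    return float((x * y).sum() / sxx)


def learner_flag(
    ratio_blocks: pd.Series | dict,
    threshold: float = 1.5,
    play_blocks: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5"),
) -> bool:
    """Conventional learning criterion: True iff any play-block mean ConA
    baseline ratio reaches ``threshold`` (≥, boundary inclusive)."""
    blocks = dict(ratio_blocks)
    return any(blocks[b] >= threshold for b in play_blocks if b in blocks)


def format_effect(row: pd.Series) -> str:
    """Compact report line: F(df1, df2) = …, p = …, ηp² = … [CI]."""
    p = row["p"]
    p_str = "p < 0.001" if p < 0.001 else f"p = {p:.3f}"
    return (
        f"F({row['df1']:g}, {row['df2']:g}) = {row['F']:.2f}, {p_str}, "
        f"ηp² = {row['partial_eta_sq']:.3f}, "
        f"95% CI = [{row['eta_ci_low']:.3f}, {row['eta_ci_high']:.3f}]"
    )
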