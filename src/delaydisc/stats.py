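"""Frequentist group-level statistics for the two-group, two-condition design.

Covers the 2 (group, between) x 2 (condition, within) split-plot ANOVA with
partial eta squared and Bonferroni post-hoc simple effects, two-sample
t-tests with Cohen's d, the uncorrected Pearson chi-square on 2x2 counts
with effect size r = sqrt(chi2 / N), and the proportion-of-SS dependent
variable for fixed batteries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

CONDITIONS = ("immediate", "non_immediate")


@dataclass
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    eta_sq: float


@dataclass
class AnovaResult:
    """Split-plot ANOVA effects plus Bonferroni post-hoc simple comparisons."""

    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    posthoc: pd.DataFrame  # comparison, mean_diff, p_raw, p_adj, ci_low, ci_high

    def tidy(self) -> pd.DataFrame:
        rows = []
        for name, eff in (
            ("group", self.between),
            ("condition", self.within),
            ("group:condition", self.interaction),
        ):
            rows.append(
                {
                    "effect": name,
                    "statistic": eff.F,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "partial_eta_sq": eff.partial_eta_sq,
                    "eta_sq": eff.eta_sq,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohen_d: float
    ci_low: float
    ci_high: float
    variant: str


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    effect_r: float


def _anova_cells(y1: np.ndarray, y2: np.ndarray) -> dict:
    """Split-plot sums of squares from per-group (n_g, 2) response arrays.

    Between-subjects error is subjects within groups; within-subjects error
    is the condition x subjects-within-groups interaction.
    """
    groups = [np.asarray(y1, dtype=float), np.asarray(y2, dtype=float)]
    for g in groups:
        if g.ndim != 2 or g.shape[1] != 2:
            raise ValidationError("each group needs an (n, 2) array of condition values")
        if not np.isfinite(g).all():
            raise ValidationError("missing or non-finite cell values")
        if g.shape[0] < 2:
            raise ValidationError("each group needs at least 2 subjects")
    all_y = np.vstack(groups)
    n_subj = all_y.shape[0]
    grand = all_y.mean()

    ss_total = float(((all_y - grand) ** 2).sum())
    subj_means = all_y.mean(axis=1)
    ss_between_subj = float(2.0 * ((subj_means - grand) ** 2).sum())
    ss_group = float(
        sum(2.0 * g.shape[0] * (g.mean() - grand) ** 2 for g in groups)
    )
    ss_subj_within = ss_between_subj - ss_group

    cond_means = all_y.mean(axis=0)
    ss_cond = float(n_subj * ((cond_means - grand) ** 2).sum())
    ss_cells = float(
        sum(
            g.shape[0] * (g[:, c].mean() - grand) ** 2
            for g in groups
            for c in (0, 1)
        )
    )
    ss_inter = ss_cells - ss_group - ss_cond
    ss_within = ss_total - ss_between_subj
    ss_cond_err = ss_within - ss_cond - ss_inter

    df_err_b = n_subj - 2
    df_err_w = n_subj - 2
    return {
        "ss_group": ss_group,
        "ss_subj_within": ss_subj_within,
        "ss_cond": ss_cond,
        "ss_inter": ss_inter,
        "ss_cond_err": ss_cond_err,
        "ss_total": ss_total,
        "df_err_b": df_err_b,
        "df_err_w": df_err_w,
    }


def _effect(ss_eff: float, ss_err: float, df_eff: int, df_err: int, ss_total: float) -> EffectResult:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err == 0:
        # degenerate design with zero error variance: F pinned at 0 or infinity
        f = 0.0 if ms_eff == 0 else float("inf")
    else:
        f = ms_eff / ms_err
    p = float(sps.f.sf(f, df_eff, df_err))
    pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    eta = ss_eff / ss_total if ss_total > 0 else 0.0
    return EffectResult(F=float(f), df1=df_eff, df2=df_err, p=p, partial_eta_sq=float(pes), eta_sq=float(eta))


def mixed_anova_2x2(data: pd.DataFrame, value: str = "value") -> AnovaResult:
    """2x2 mixed ANOVA on a long table (participant, group, condition, value).

    Requires exactly one value per participant x condition (a complete within
    factor); between-group sizes may differ.  Post-hoc: group comparisons
    within each condition, Bonferroni-adjusted over the two conditions.
    """
    required = {"participant_id", "group", "condition", value}
    missing = required - set(data.columns)
    if missing:
        raise ValidationError(f"data missing columns: {sorted(missing)}")
    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    if set(data["condition"].unique()) != set(CONDITIONS):
        raise ValidationError(f"need exactly the conditions {CONDITIONS}")
    wide = data.pivot_table(
        index=["group", "participant_id"],
        columns="condition",
        values=value,
        aggfunc="first",
    )
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValidationError(f"missing cells for participants: {bad}")
    counts = data.groupby(["group", "participant_id", "condition"]).size()
    if (counts > 1).any():
        raise ValidationError("more than one value per participant x condition cell")

    wide = wide[list(CONDITIONS)]
    y = {g: wide.loc[g].to_numpy() for g in groups}
    ss = _anova_cells(y[groups[0]], y[groups[1]])

    between = _effect(ss["ss_group"], ss["ss_subj_within"], 1, ss["df_err_b"], ss["ss_total"])
    within = _effect(ss["ss_cond"], ss["ss_cond_err"], 1, ss["df_err_w"], ss["ss_total"])
    interaction = _effect(ss["ss_inter"], ss["ss_cond_err"], 1, ss["df_err_w"], ss["ss_total"])

    # post-hoc simple effects: group difference within each condition
    m = 2
    rows = []
    for c, cond in enumerate(CONDITIONS):
        a, b = y[groups[0]][:, c], y[groups[1]][:, c]
        res = t_test_with_d(a, b, variant="student")
        p_adj = min(1.0, m * res.p)
        # Bonferroni-adjusted CI: 1 - alpha/m coverage
        n1, n2 = a.size, b.size
        diff = a.mean() - b.mean()
        pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        se = np.sqrt(pooled * (1 / n1 + 1 / n2))
        tcrit = sps.t.ppf(1 - 0.05 / (2 * m), n1 + n2 - 2)
        half = tcrit * se
        rows.append(
            {
                "comparison": f"{groups[0]} - {groups[1]} | {cond}",
                "mean_diff": diff,
                "p_raw": res.p,
                "p_adj": p_adj,
                "ci_low": diff - half,
                "ci_high": diff + half,
            }
        )
    return AnovaResult(
        between=between,
        within=within,
        interaction=interaction,
        posthoc=pd.DataFrame(rows),
    )


def t_test_with_d(x, y, variant: str = "student") -> TTestResult:
    """Two-sample t-test with Cohen's d (pooled-SD standardization)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if variant == "auto":
        # variance-homogeneity pre-check (Levene); Welch on failure
        _, p_lev = sps.levene(x, y)
        variant = "welch" if p_lev < 0.05 else "student"
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown variant {variant!r}")
    equal_var = variant == "student"
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    n1, n2 = x.size, y.size
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        if x.mean() == y.mean():
            d = 0.0
        else:
            raise ValidationError("zero pooled variance; Cohen's d undefined")
    else:
        d = (x.mean() - y.mean()) / np.sqrt(pooled_var)
    df = float(res.df)
    diff = x.mean() - y.mean()
    if equal_var:
        se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    else:
        se = np.sqrt(x.var(ddof=1) / n1 + y.var(ddof=1) / n2)
    tcrit = sps.t.ppf(0.975, df)
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        cohen_d=float(d),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        variant=variant,
    )


def cohen_d_from_t(t: float, n1: int, n2: int) -> float:
    """d = t * sqrt(1/n1 + 1/n2) for the pooled (student) two-sample test."""
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def effect_r_from_chi2(chi2: float, n: int) -> float:
    """r = sqrt(chi2 / N) for a 2x2 contingency table."""
    return float(np.sqrt(chi2 / n))


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) with effect size r."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValidationError("need a 2x2 count table")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError("zero marginal total")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    if np.any(expected <= 0):
        raise ValidationError("expected counts must be positive")
    n = obs.sum()
    return ChiSquareResult(
        chi2=float(chi2), df=int(df), p=float(p), effect_r=effect_r_from_chi2(chi2, n)
    )


def attention_table(attention: pd.DataFrame, column: str) -> np.ndarray:
    """2x2 counts (group x delay/reward) from the attention table."""
    if column not in attention.columns:
        raise ValidationError(f"missing column {column!r}")
    groups = sorted(attention["group"].unique())
    if len(groups) != 2:
        raise ValidationError("need exactly 2 groups")
    out = np.zeros((2, 2))
    for i, g in enumerate(groups):
        sub = attention[attention["group"] == g]
        out[i, 0] = int((sub[column] == "delay").sum())
        out[i, 1] = int((sub[column] == "reward").sum())
    return out


def proportion_ss(trials: pd.DataFrame) -> pd.DataFrame:
    """Fraction of SS choices per participant x condition (fixed batteries)."""
    required = {"participant_id", "condition", "choice"}
    missing = required - set(trials.columns)
    if missing:
        raise ValidationError(f"trials missing columns: {sorted(missing)}")
    if len(trials) == 0:
        raise ValidationError("empty trials table")
    out = (
        trials.assign(is_ss=(trials["choice"] == "SS").astype(float))
        .groupby(["participant_id", "condition"], sort=True, observed=True)["is_ss"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "proportion_ss", "size": "n_trials"})
    )
    if (out["n_trials"] == 0).any():
        raise ValidationError("zero trials in a participant x condition cell")
    if "group" in trials.columns:
        key = trials.drop_duplicates("participant_id").set_index("participant_id")["group"]
        out["group"] = out["participant_id"].map(key)
    return out
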