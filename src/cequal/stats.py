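"""Cohort-level statistics: mixed repeated-measures ANOVA, t and chi-square
tests, and the study report tables.

The study design is a two-way mixed (split-plot) layout: preparation arm is
the between-subjects factor, SB quartile (Q1..Q4) the within-subjects
factor, and each video contributes one 4-vector of per-quartile fractions.
The classical decomposition is used:

    SS_total = SS_group + SS_subjects(group) + SS_quartile
             + SS_group:quartile + SS_residual

with the group effect tested against subjects-within-groups and the two
within-subject effects against the subject-by-quartile residual. Marginal
quartile means are weighted by group size, which keeps the decomposition
exact for unequal arms. No sphericity correction is applied by default;
Greenhouse-Geisser is available via ``correction="gg"``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import round_half_up


@dataclass
class MixedAnovaResult:
    """ANOVA table of the mixed design plus the epsilon actually applied."""

    table: pd.DataFrame  # rows: group, subjects(group), quartile, interaction, residual
    epsilon: float = 1.0

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    @property
    def ss_total(self) -> float:
        return float(self.table["ss"].sum())


def _gg_epsilon(y: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    n, r = y.shape
    pooled = np.zeros((r, r))
    for g in range(n_groups):
        block = y[group_idx == g]
        pooled += (len(block) - 1) * np.cov(block, rowvar=False)
    pooled /= n - n_groups
    # double-centre
    row = pooled.mean(axis=0, keepdims=True)
    col = pooled.mean(axis=1, keepdims=True)
    a = pooled - row - col + pooled.mean()
    num = np.trace(a) ** 2
    den = (r - 1) * (a * a).sum()
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (r - 1), 1.0))


def mixed_anova(
    values: np.ndarray,
    groups: np.ndarray,
    correction: str = "none",
) -> MixedAnovaResult:
    """Two-way mixed ANOVA with repeated measures.

    Parameters
    ----------
    values
        Shape ``(n_subjects, n_repeats)`` — one row of repeated measures
        (per-quartile fractions) per subject (video). No missing cells.
    groups
        Length-``n_subjects`` arm labels (two or more groups, each with at
        least two subjects).
    correction
        ``"none"`` (default) or ``"gg"`` for Greenhouse-Geisser-adjusted
        degrees of freedom on the within-subject tests.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("values must be (n_subjects, n_repeats>=2)")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    if correction not in ("none", "gg"):
        raise ValueError("correction must be 'none' or 'gg'")
    labels, idx = np.unique(np.asarray(groups), return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least two groups")
    n, r = y.shape
    if len(idx) != n:
        raise ValueError("groups length must match number of subjects")
    sizes = np.bincount(idx)
    if (sizes < 2).any():
        raise ValueError("each group needs at least two subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    grp_means = np.array([subj_means[idx == g].mean() for g in range(a)])
    q_means = y.mean(axis=0)
    cell_means = np.array([y[idx == g].mean(axis=0) for g in range(a)])

    ss_group = r * float((sizes * (grp_means - grand) ** 2).sum())
    ss_subj = r * float(((subj_means - grp_means[idx]) ** 2).sum())
    ss_q = n * float(((q_means - grand) ** 2).sum())
    ss_inter = float(
        (sizes[:, None] * (cell_means - grp_means[:, None] - q_means[None, :] + grand) ** 2).sum()
    )
    resid = y - cell_means[idx] - subj_means[:, None] + grp_means[idx][:, None]
    ss_resid = float((resid**2).sum())

    df_group = a - 1
    df_subj = n - a
    df_q = r - 1
    df_inter = (a - 1) * (r - 1)
    df_resid = (r - 1) * (n - a)

    eps = _gg_epsilon(y, idx, a) if correction == "gg" else 1.0

    def f_and_p(ss_num, df_num, ss_den, df_den, within: bool):
        ms_num = ss_num / df_num if df_num else np.nan
        ms_den = ss_den / df_den if df_den else np.nan
        if not np.isfinite(ms_den) or ms_den <= 0:
            return ms_num, np.nan, np.nan
        f = ms_num / ms_den
        e = eps if within else 1.0
        p = float(sps.f.sf(f, df_num * e, df_den * e))
        return ms_num, f, p

    rows = []
    ms, f, p = f_and_p(ss_group, df_group, ss_subj, df_subj, within=False)
    rows.append(("group", ss_group, df_group, ms, f, p))
    rows.append(("subjects(group)", ss_subj, df_subj, ss_subj / df_subj, np.nan, np.nan))
    ms, f, p = f_and_p(ss_q, df_q, ss_resid, df_resid, within=True)
    rows.append(("quartile", ss_q, df_q, ms, f, p))
    ms, f, p = f_and_p(ss_inter, df_inter, ss_resid, df_resid, within=True)
    rows.append(("group:quartile", ss_inter, df_inter, ms, f, p))
    rows.append(("residual", ss_resid, df_resid, ss_resid / df_resid, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["source", "ss", "df", "ms", "F", "p"])
    return MixedAnovaResult(table=table, epsilon=eps)


def two_sample_t(x, y, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test (Welch's unequal-variance form by default).

    Returns ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by default).

    Table layout: rows are groups, columns outcome: ``[[a, b], [c, d]]``.
    Returns ``(statistic, p)``; a zero row or column margin is degenerate.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Group-level analogue of the study's report tables.

    ``demographics`` and ``outcomes`` are per-arm summary tables with
    p-values; ``interaction`` holds one long table per endpoint
    (columns group, quartile, mean_fraction, sd, n); ``anova`` the mixed
    ANOVA per endpoint (``abundant`` bubbles; ``adequate`` cleanliness).
    """

    arms: tuple[str, str]
    demographics: pd.DataFrame
    outcomes: pd.DataFrame
    interaction: dict[str, pd.DataFrame] = field(default_factory=dict)
    anova: dict[str, MixedAnovaResult] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "arms": list(self.arms),
            "demographics": self.demographics.to_dict(orient="records"),
            "outcomes": self.outcomes.to_dict(orient="records"),
            "interaction": {k: v.to_dict(orient="records") for k, v in self.interaction.items()},
            "anova": {
                k: v.table.to_dict(orient="records") for k, v in self.anova.items()
            },
        }


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1)


def _rate_row(name: str, flags: dict[str, np.ndarray], arms) -> dict:
    counts = {arm: int(flags[arm].sum()) for arm in arms}
    totals = {arm: flags[arm].size for arm in arms}
    try:
        _, p = chi_square_2x2(
            counts[arms[0]], totals[arms[0]] - counts[arms[0]],
            counts[arms[1]], totals[arms[1]] - counts[arms[1]],
        )
    except ValueError:
        p = np.nan  # degenerate margin (e.g. all videos complete in both arms)
    row = {"measure": name, "p": p}
    for arm in arms:
        row[arm] = _pct(counts[arm], totals[arm])
    return row


def _mean_sd_row(name: str, values: dict[str, np.ndarray], arms, ndigits: int = 1) -> dict:
    _, _, p = two_sample_t(values[arms[0]], values[arms[1]])
    row = {"measure": name, "p": p}
    for arm in arms:
        v = values[arm]
        row[arm] = f"{round_half_up(v.mean(), ndigits)} ± {round_half_up(v.std(ddof=1), ndigits)}"
    return row


def build_report(summaries: pd.DataFrame, roster: pd.DataFrame) -> StudyReport:
    """Assemble the full study report from per-video summaries and the roster.

    ``summaries`` must contain one row per video with columns ``arm``,
    ``abundant_q1..q4``, ``adequate_q1..q4``, ``gastric_transit_min``,
    ``sb_transit_min``, ``n_images``, ``complete``, ``dy_positive``,
    ``has_p1``, ``has_p2``. Percentages are reported rounded half-up to one
    decimal; rate p-values are Pearson chi-square, continuous p-values
    Welch t.
    """
    arms = tuple(sorted(summaries["arm"].unique()))
    if len(arms) != 2:
        raise ValueError(f"expected exactly two arms, got {arms}")
    by_arm = {arm: summaries[summaries["arm"] == arm] for arm in arms}
    for arm, block in by_arm.items():
        if len(block) == 0:
            raise ValueError(f"arm {arm} has no videos")

    # demographics from the roster
    demo_rows = []
    rost = {arm: roster[roster["arm_label"] == arm] for arm in arms}
    demo_rows.append({"measure": "n", arms[0]: len(rost[arms[0]]), arms[1]: len(rost[arms[1]]), "p": np.nan})
    demo_rows.append(
        _mean_sd_row("age_years", {a: rost[a]["age"].to_numpy(float) for a in arms}, arms)
    )
    if "sex" in roster.columns:
        demo_rows.append(
            _rate_row("male_pct", {a: (rost[a]["sex"] == "M").to_numpy() for a in arms}, arms)
        )
    if "overt_ogib" in roster.columns:
        demo_rows.append(
            _rate_row("overt_ogib_pct", {a: rost[a]["overt_ogib"].to_numpy(bool) for a in arms}, arms)
        )
    demographics = pd.DataFrame(demo_rows)

    # outcome table
    out_rows = [
        _rate_row("p1_rate_pct", {a: by_arm[a]["has_p1"].to_numpy(bool) for a in arms}, arms),
        _rate_row("p2_rate_pct", {a: by_arm[a]["has_p2"].to_numpy(bool) for a in arms}, arms),
        _rate_row("dy_p1_or_p2_pct", {a: by_arm[a]["dy_positive"].to_numpy(bool) for a in arms}, arms),
        _mean_sd_row("gastric_transit_min", {a: by_arm[a]["gastric_transit_min"].to_numpy(float) for a in arms}, arms, 0),
        _mean_sd_row("sb_transit_min", {a: by_arm[a]["sb_transit_min"].to_numpy(float) for a in arms}, arms, 0),
        _rate_row("completion_pct", {a: by_arm[a]["complete"].to_numpy(bool) for a in arms}, arms),
        _mean_sd_row("n_images", {a: by_arm[a]["n_images"].to_numpy(float) for a in arms}, arms, 0),
    ]
    outcomes = pd.DataFrame(out_rows)

    interaction: dict[str, pd.DataFrame] = {}
    anova: dict[str, MixedAnovaResult] = {}
    for endpoint in ("abundant", "adequate"):
        cols = [f"{endpoint}_q{q}" for q in range(1, 5)]
        rows = []
        for arm in arms:
            block = by_arm[arm][cols].to_numpy(float)
            for q in range(4):
                rows.append(
                    {
                        "group": arm,
                        "quartile": f"Q{q + 1}",
                        "mean_fraction": float(block[:, q].mean()),
                        "sd": float(block[:, q].std(ddof=1)),
                        "n": block.shape[0],
                    }
                )
        interaction[endpoint] = pd.DataFrame(rows)
        anova[endpoint] = mixed_anova(
            summaries[cols].to_numpy(float), summaries["arm"].to_numpy()
        )

    return StudyReport(
        arms=arms,
        demographics=demographics,
        outcomes=outcomes,
        interaction=interaction,
        anova=anova,
    )
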