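"""Cohort-level statistics on per-trial SampEn values.

The analysis treats SampEn as the dependent variable in a split-plot
(mixed) design: group (control / beginner / biathlete) varies between
subjects, task (QS / SP / AT) within subjects, and each direction (AP, ML)
is analyzed separately.  Repeated trials are averaged per subject and
condition first, then:

* assumption checks — Shapiro-Wilk normality per group x task cell,
  Levene's homogeneity of variance across groups per task, Mauchly's
  sphericity of the within factor;
* two-way mixed ANOVA with the classical weighted (type II) sums of
  squares, reporting F, degrees of freedom, p and generalized eta squared
  (Bakeman's statistic: SS_effect over SS_effect plus all subject-related
  error SS), with a Greenhouse-Geisser corrected p alongside when
  sphericity is rejected;
* Bonferroni-corrected pairwise t-tests — independent t between groups
  within each task, paired t between tasks within each group — gated on the
  corresponding omnibus effects.

Trial tables are plain long-format DataFrames with columns
``subject, group, task, repeat, direction, sampen``; +inf SampEn sentinels
are converted to missing, never treated as large values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, MissingCellError
from .forceplate_io import Direction, Group, Task

TRIAL_COLUMNS = ["subject", "group", "task", "repeat", "direction", "sampen"]
GROUP_ORDER = [g.value for g in Group]
TASK_ORDER = [t.value for t in Task]

#: Cohen's guideline bands for generalized eta squared.
EFFECT_SIZE_BANDS = {"small": 0.01, "medium": 0.06, "large": 0.14}


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect line: F, df, p and generalized eta squared."""

    name: str  # 'group', 'task' or 'group:task'
    ss: float
    df_num: int
    df_den: int
    F: float
    p: float
    eta_g_sq: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected (within effects)


@dataclass
class AnovaReport:
    direction: str
    effects: list[EffectResult]
    assumptions: dict
    alpha: float
    n_subjects: int
    group_sizes: dict[str, int]

    def effect(self, name: str) -> EffectResult:
        for eff in self.effects:
            if eff.name == name:
                return eff
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "alpha": self.alpha,
            "n_subjects": self.n_subjects,
            "group_sizes": self.group_sizes,
            "effects": [
                {
                    "name": e.name,
                    "SS": e.ss,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "F": e.F,
                    "p": e.p,
                    "p_gg": e.p_gg,
                    "eta_g_sq": e.eta_g_sq,
                    "effect_size_class": classify_effect_size(e.eta_g_sq),
                }
                for e in self.effects
            ],
            "assumptions": self.assumptions,
        }

    def render(self) -> str:
        """Human-readable summary in the conventional reporting style."""
        lines = [f"Mixed ANOVA, direction {self.direction} "
                 f"(groups n={self.group_sizes}, alpha={self.alpha}):"]
        for e in self.effects:
            p_txt = "p<0.001" if e.p < 0.001 else f"p={e.p:.3f}"
            lines.append(
                f"  {e.name:<11} F = {e.F:.3f}; df = {e.df_num}, {e.df_den}; {p_txt}; "
                f"eta_G^2 = {e.eta_g_sq:.3f} ({classify_effect_size(e.eta_g_sq)})"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class PairwiseComparison:
    direction: str
    scope: str  # 'between-groups-within-task' | 'between-tasks-within-group'
    stratum: str  # the task (between scope) or the group (within scope)
    pair: tuple[str, str]
    t: float
    df: float
    p_raw: float
    p_adj: float
    mean_diff: float


@dataclass
class PairwiseReport:
    comparisons: list[PairwiseComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "direction": c.direction,
                    "scope": c.scope,
                    "stratum": c.stratum,
                    "a": c.pair[0],
                    "b": c.pair[1],
                    "t": c.t,
                    "df": c.df,
                    "p_raw": c.p_raw,
                    "p_adj": c.p_adj,
                    "mean_diff": c.mean_diff,
                }
                for c in self.comparisons
            ]
        )

    def to_dict(self) -> dict:
        return {"comparisons": self.to_frame().to_dict(orient="records")}


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def average_repeats(trials: pd.DataFrame) -> pd.DataFrame:
    """Average repeated trials per (subject, group, task, direction).

    +inf and NaN SampEn values are excluded (with a warning); a cell left
    with zero usable repeats raises :class:`MissingCellError`.
    """
    df = trials.copy()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"trial table missing columns {missing}")
    usable = np.isfinite(df["sampen"].to_numpy(dtype=float))
    if not usable.all():
        bad = df.loc[~usable, ["subject", "task", "direction"]]
        warnings.warn(
            f"{len(bad)} trial(s) with missing/infinite SampEn excluded: "
            f"{bad.to_dict(orient='records')}",
            RuntimeWarning,
            stacklevel=2,
        )
        df = df[usable]
    grouped = df.groupby(["subject", "group", "task", "direction"], sort=False, observed=True)
    means = grouped["sampen"].mean().reset_index()
    # every (subject, task, direction) present in the input must survive
    expected = trials[["subject", "task", "direction"]].drop_duplicates()
    got = means[["subject", "task", "direction"]].drop_duplicates()
    lost = expected.merge(got, how="left", indicator=True)
    lost = lost[lost["_merge"] == "left_only"]
    if len(lost):
        row = lost.iloc[0]
        raise MissingCellError(
            f"subject {row['subject']}, task {row['task']}, direction {row['direction']}: "
            "no usable repeats"
        )
    return means


# ---------------------------------------------------------------------------
# Assumption checks
# ---------------------------------------------------------------------------

def _wide(means: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Subjects x tasks table for one direction, with the group label as index level."""
    sub = means[means["direction"] == direction]
    wide = sub.pivot_table(
        index=["subject", "group"], columns="task", values="sampen", observed=True
    )
    tasks = [t for t in TASK_ORDER if t in wide.columns]
    wide = wide[tasks]
    if wide.isna().any().any():
        idx = wide.index[wide.isna().any(axis=1)][0]
        raise MissingCellError(f"incomplete subject x task table: subject {idx[0]}")
    return wide


def check_assumptions(means: pd.DataFrame, direction: str, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per cell, Levene per task, Mauchly sphericity.

    Failed preconditions (n < 3, zero variance) skip the check with a
    warning and a None p-value; violations are flagged, never fatal.
    """
    wide = _wide(means, Direction(direction).value)
    tasks = list(wide.columns)
    groups = wide.index.get_level_values("group")
    out: dict = {"direction": Direction(direction).value, "alpha": alpha,
                 "shapiro": {}, "levene": {}, "mauchly": None, "flags": []}
    for g in pd.unique(groups):
        for t in tasks:
            cell = wide.loc[groups == g, t].to_numpy()
            key = f"{g}:{t}"
            if len(cell) < 3:
                warnings.warn(f"Shapiro-Wilk skipped for {key}: n={len(cell)} < 3",
                              RuntimeWarning, stacklevel=2)
                out["shapiro"][key] = None
                continue
            if np.ptp(cell) == 0:
                warnings.warn(f"Shapiro-Wilk skipped for {key}: identical values",
                              RuntimeWarning, stacklevel=2)
                out["shapiro"][key] = None
                continue
            p = float(stats.shapiro(cell).pvalue)
            out["shapiro"][key] = p
            if p < alpha:
                out["flags"].append(f"normality rejected in cell {key} (p={p:.3g})")
    for t in tasks:
        samples = [wide.loc[groups == g, t].to_numpy() for g in pd.unique(groups)]
        if any(len(s) < 2 for s in samples):
            warnings.warn(f"Levene skipped for task {t}: a group has n < 2",
                          RuntimeWarning, stacklevel=2)
            out["levene"][t] = None
            continue
        p = float(stats.levene(*samples).pvalue)
        out["levene"][t] = p
        if p < alpha:
            out["flags"].append(f"variance homogeneity rejected for task {t} (p={p:.3g})")
    if len(tasks) <= 2:
        # sphericity holds automatically with two within levels
        out["mauchly"] = {"W": 1.0, "p": 1.0, "trivial": True}
    else:
        import pingouin as pg

        long = wide.reset_index().melt(
            id_vars=["subject", "group"], var_name="task", value_name="sampen"
        )
        spher = pg.sphericity(long, dv="sampen", within="task", subject="subject")
        out["mauchly"] = {"W": float(spher.W), "p": float(spher.pval), "trivial": False}
        if spher.pval < alpha:
            out["flags"].append(f"sphericity rejected (Mauchly p={spher.pval:.3g})")
    return out


# ---------------------------------------------------------------------------
# Mixed ANOVA
# ---------------------------------------------------------------------------

def _gg_epsilon(wide: pd.DataFrame) -> float:
    """Greenhouse-Geisser epsilon from the task covariance matrix."""
    import pingouin as pg

    return float(pg.epsilon(wide.reset_index(drop=True), correction="gg"))


def mixed_anova(
    means: pd.DataFrame,
    direction: str,
    alpha: float = 0.05,
    ss_type: str = "weighted",
    with_assumptions: bool = True,
) -> AnovaReport:
    """Two-way mixed ANOVA (group between, task within) for one direction.

    Sums of squares follow the classical split-plot decomposition on the
    observed (weighted) means; ``ss_type="unweighted"`` recomputes the
    between-group SS from unweighted cell means with the harmonic mean
    group size (type-III style), relevant only when group sizes differ.
    Generalized eta squared divides each effect SS by itself plus both
    error SS (subjects-within-groups and task x subjects).
    """
    if ss_type not in ("weighted", "unweighted"):
        raise ValueError(f"ss_type must be 'weighted' or 'unweighted', got {ss_type!r}")
    direction = Direction(direction).value
    wide = _wide(means, direction)
    y = wide.to_numpy(dtype=float)
    n_subj, k = y.shape
    groups = wide.index.get_level_values("group").to_numpy()
    group_levels = [g for g in GROUP_ORDER if g in set(groups)] + sorted(
        set(groups) - set(GROUP_ORDER)
    )
    g = len(group_levels)
    if g < 2 or k < 2:
        raise DegenerateDataError("need at least two groups and two tasks")
    sizes = {lvl: int((groups == lvl).sum()) for lvl in group_levels}

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    subj_means = y.mean(axis=1)
    task_means = y.mean(axis=0)
    cell_means = np.vstack([y[groups == lvl].mean(axis=0) for lvl in group_levels])
    n_g = np.array([sizes[lvl] for lvl in group_levels], dtype=float)
    group_means = np.array([subj_means[groups == lvl].mean() for lvl in group_levels])

    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(k * (n_g * (group_means - grand) ** 2).sum())
    if ss_type == "unweighted":
        n_h = g / (1.0 / n_g).sum()
        uw_grand = group_means.mean()
        ss_group = float(k * n_h * ((group_means - uw_grand) ** 2).sum())
    ss_err_between = ss_subjects - float(
        k * (n_g * (group_means - grand) ** 2).sum()
    )
    ss_task = float(n_subj * ((task_means - grand) ** 2).sum())
    ss_cells = float((n_g[:, None] * (cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - float(k * (n_g * (group_means - grand) ** 2).sum()) - ss_task
    ss_err_within = ss_total - ss_cells - ss_err_between

    df_group, df_task, df_inter = g - 1, k - 1, (g - 1) * (k - 1)
    df_eb, df_ew = n_subj - g, (n_subj - g) * (k - 1)
    if df_eb <= 0 or df_ew <= 0:
        raise DegenerateDataError("too few subjects for the requested design")
    ms_eb = ss_err_between / df_eb
    ms_ew = ss_err_within / df_ew
    if ms_eb <= 0 or ms_ew <= 0:
        raise DegenerateDataError("zero residual variance: F is undefined")

    ss_noise = ss_err_between + ss_err_within  # all subject-related variance

    def _effect(name, ss, dfn, dfd, ms_err, gg_eps=None):
        F = (ss / dfn) / ms_err
        p = float(stats.f.sf(F, dfn, dfd))
        p_gg = None
        if gg_eps is not None:
            p_gg = float(stats.f.sf(F, dfn * gg_eps, dfd * gg_eps))
        eta = ss / (ss + ss_noise) if ss > 0 else 0.0
        return EffectResult(name, ss, dfn, dfd, F, p, eta, p_gg)

    eps = _gg_epsilon(wide) if k > 2 else 1.0
    effects = [
        _effect("group", ss_group, df_group, df_eb, ms_eb),
        _effect("task", ss_task, df_task, df_ew, ms_ew, gg_eps=eps),
        _effect("group:task", ss_inter, df_inter, df_ew, ms_ew, gg_eps=eps),
    ]
    assumptions = check_assumptions(means, direction, alpha=alpha) if with_assumptions else {}
    return AnovaReport(
        direction=direction,
        effects=effects,
        assumptions=assumptions,
        alpha=alpha,
        n_subjects=n_subj,
        group_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# Post hoc tests
# ---------------------------------------------------------------------------

def bonferroni(p_raw: float, k: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, k * p_raw)


def pairwise_posthoc(
    means: pd.DataFrame,
    anova: AnovaReport,
    alpha: float | None = None,
    always: bool = False,
) -> PairwiseReport:
    """Bonferroni-corrected pairwise t-tests, gated on the omnibus effects.

    Between-group comparisons (independent two-sample t, pooled variance)
    run within each task when the group or interaction effect is
    significant; between-task comparisons (paired t) run within each group
    when the task or interaction effect is significant.  The Bonferroni
    family is all comparisons within a scope for one direction (9 each for
    a 3 x 3 design).  ``always=True`` bypasses the gating.
    """
    alpha = anova.alpha if alpha is None else alpha
    direction = anova.direction
    wide = _wide(means, direction)
    tasks = list(wide.columns)
    groups = wide.index.get_level_values("group")
    group_levels = [lvl for lvl in GROUP_ORDER if lvl in set(groups)] + sorted(
        set(groups) - set(GROUP_ORDER)
    )
    report = PairwiseReport()

    sig = {e.name: e.p < alpha for e in anova.effects}
    run_between = always or sig.get("group", False) or sig.get("group:task", False)
    run_within = always or sig.get("task", False) or sig.get("group:task", False)

    if run_between:
        cand = []
        for t in tasks:
            for a, b in itertools.combinations(group_levels, 2):
                xa = wide.loc[groups == a, t].to_numpy()
                xb = wide.loc[groups == b, t].to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    warnings.warn(
                        f"comparison {a} vs {b} in task {t} skipped: n < 2",
                        RuntimeWarning, stacklevel=2,
                    )
                    continue
                res = stats.ttest_ind(xa, xb)
                cand.append(
                    (t, (a, b), float(res.statistic), float(res.df),
                     float(res.pvalue), float(xa.mean() - xb.mean()))
                )
        k = len(cand)
        for t, pair, tval, df, p_raw, diff in cand:
            report.comparisons.append(
                PairwiseComparison(direction, "between-groups-within-task", t, pair,
                                   tval, df, p_raw, bonferroni(p_raw, k), diff)
            )
    if run_within:
        cand = []
        for lvl in group_levels:
            block = wide.loc[groups == lvl]
            for ta, tb in itertools.combinations(tasks, 2):
                xa = block[ta].to_numpy()
                xb = block[tb].to_numpy()
                if len(xa) < 2:
                    warnings.warn(
                        f"comparison {ta} vs {tb} in group {lvl} skipped: n < 2",
                        RuntimeWarning, stacklevel=2,
                    )
                    continue
                res = stats.ttest_rel(xa, xb)
                cand.append(
                    (lvl, (ta, tb), float(res.statistic), float(len(xa) - 1),
                     float(res.pvalue), float(xa.mean() - xb.mean()))
                )
        k = len(cand)
        for lvl, pair, tval, df, p_raw, diff in cand:
            report.comparisons.append(
                PairwiseComparison(direction, "between-tasks-within-group", lvl, pair,
                                   tval, df, p_raw, bonferroni(p_raw, k), diff)
            )
    return report


def classify_effect_size(eta_g_sq: float) -> str:
    """Cohen's bands for generalized eta squared: 0.01 / 0.06 / 0.14."""
    if not 0 <= eta_g_sq <= 1 or math.isnan(eta_g_sq):
        raise ValueError(f"eta_g_sq must lie in [0, 1], got {eta_g_sq}")
    if eta_g_sq >= EFFECT_SIZE_BANDS["large"]:
        return "large"
    if eta_g_sq >= EFFECT_SIZE_BANDS["medium"]:
        return "medium"
    if eta_g_sq >= EFFECT_SIZE_BANDS["small"]:
        return "small"
    return "below_small"
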