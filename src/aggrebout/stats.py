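"""Statistical procedures for the behavioral readouts.

Attack durations are heavy-tailed and occasionally exactly zero (a
session without a single attack), so analyses run on log-transformed
values with a zero-safe constant.  Group contrasts use Welch's unequal-
variance t-test (also computable from published summary statistics).
The drug cross-over design (between-subject factor: genotype;
within-subject factor: treatment) is analyzed with a split-plot
(mixed repeated-measures) two-way ANOVA, followed by Tukey HSD over the
genotype x treatment cell means or a Sidak correction for planned
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TransformResult",
    "WelchResult",
    "AnovaTable",
    "zero_safe_log",
    "welch_t",
    "welch_t_from_summary",
    "mixed_rm_anova",
    "tukey_hsd",
    "sidak_adjust",
]


# --------------------------------------------------------------------------
# zero-safe log transform


@dataclass(frozen=True)
class TransformResult:
    """Log-transformed values and the constant that made zeros loggable.

    ``constant`` is 0 when the data contain no zeros; otherwise it is
    sqrt(Q1/Q3) of the full value set (quartiles by linear
    interpolation).  That reading of the transform constant — the square
    root of the ratio of the quartiles — is recorded here explicitly
    because the alternative parse sqrt(Q1)/Q3 carries the data's units
    into the constant.
    """

    values: np.ndarray
    constant: float
    q1: float
    q3: float
    note: str = "constant = sqrt(Q1/Q3); natural log"


def zero_safe_log(values: np.ndarray) -> TransformResult:
    """log(x + c) with c chosen so zeros stay in the analysis.

    No zeros: c = 0 and the transform is a plain natural log.  With
    zeros present, c = sqrt(Q1/Q3) computed on the full value set; if Q1
    is itself 0 (heavily zero-inflated data) the fallback is half the
    smallest positive value, with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if np.any(x < 0):
        raise ValueError("negative values cannot be log-transformed")
    if np.all(x == 0):
        raise ValueError("all values are zero; nothing to transform")
    q1, q3 = np.percentile(x, [25, 75])
    if x.min() > 0:
        c = 0.0
    elif q1 > 0 and q3 > 0:
        c = float(np.sqrt(q1 / q3))
    else:
        c = float(x[x > 0].min() / 2.0)
        warnings.warn(
            "first quartile is 0; falling back to half the smallest "
            "positive value as the log constant"
        )
    return TransformResult(values=np.log(x + c), constant=c, q1=float(q1),
                           q3=float(q3))


# --------------------------------------------------------------------------
# Welch tests


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


def welch_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch's t-test from group means, SDs and sizes.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom; two-sided p.  Published tables report exactly
    these summaries, so results are reproducible without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both group variances are zero")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(
        t=float(t), df=float(df), p=float(p),
        mean1=float(m1), sd1=float(sd1), n1=int(n1),
        mean2=float(m2), sd2=float(sd2), n2=int(n2),
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Welch's two-sample t-test on raw values (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    return welch_t_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


# --------------------------------------------------------------------------
# split-plot (mixed repeated-measures) two-way ANOVA


@dataclass
class AnovaTable:
    """Split-plot ANOVA results.

    ``effects`` has one row per effect (between, within, interaction)
    with SS, df, MS, F, p.  The two error strata are kept for post-hoc
    use: the between-subject error (subjects within genotype) and the
    within-subject residual.  ``n_dropped_subjects`` counts subjects
    removed for missing within-subject levels (complete-case analysis).
    """

    effects: pd.DataFrame
    between: str
    within: str
    dv: str
    ms_subject_error: float
    df_subject_error: int
    ms_residual: float
    df_residual: int
    cell_stats: pd.DataFrame
    n_complete_subjects: int
    n_dropped_subjects: int


def mixed_rm_anova(
    table: pd.DataFrame,
    dv: str = "attack_duration_s",
    between: str = "genotype",
    within: str = "treatment",
    subject: str = "animal_id",
) -> AnovaTable:
    """Two-way mixed ANOVA: one between-subject and one within-subject factor.

    Classic split-plot decomposition.  The between-subject stratum tests
    the between factor against subjects-within-groups; the within
    stratum tests the within factor and the interaction against the
    subject-by-treatment residual.  Subjects missing any within level
    are dropped (complete cases) and counted.
    """
    df = table[[subject, between, within, dv]].dropna()
    levels_w = sorted(df[within].unique())
    b = len(levels_w)
    if b < 2:
        raise ValueError("the within factor needs >= 2 levels")
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == b].index
    n_dropped = df[subject].nunique() - len(complete)
    df = df[df[subject].isin(complete)]
    per_group = df.groupby(between)[subject].nunique()
    if (per_group < 2).any() or len(per_group) < 2:
        raise ValueError(
            "need >= 2 complete subjects in each of >= 2 between-factor levels"
        )

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    n_subj = df[subject].nunique()

    ss_total = float(((y - grand) ** 2).sum())
    subj_mean = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()
    ss_between_subj = float(b * ((subj_mean - grand) ** 2).sum())
    group_mean = df.groupby(between)[dv].mean()
    group_n = df.groupby(between)[subject].nunique()
    ss_between = float(
        sum(b * group_n[g] * (group_mean[g] - grand) ** 2 for g in group_mean.index)
    )
    ss_subj_err = ss_between_subj - ss_between

    within_mean = df.groupby(within)[dv].mean()
    ss_within_f = float(sum(n_subj * (within_mean[w] - grand) ** 2
                            for w in within_mean.index))
    cell = df.groupby([between, within])[dv].agg(["mean", "std", "count"])
    ss_cells = float(
        sum(row["count"] * (row["mean"] - grand) ** 2 for _, row in cell.iterrows())
    )
    ss_inter = max(ss_cells - ss_between - ss_within_f, 0.0)
    ss_resid = max(ss_total - ss_between_subj - ss_within_f - ss_inter, 0.0)

    a = len(group_mean)
    df_between = a - 1
    df_subj_err = n_subj - a
    df_within = b - 1
    df_inter = (a - 1) * (b - 1)
    df_resid = (n_subj - a) * (b - 1)

    ms_between = ss_between / df_between
    ms_subj_err = ss_subj_err / df_subj_err
    ms_within = ss_within_f / df_within
    ms_inter = ss_inter / df_inter
    ms_resid = ss_resid / df_resid

    def _f(ms_effect: float, ms_error: float) -> float:
        # degenerate data (zero error MS) must not crash the table
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(np.float64(ms_effect) / np.float64(ms_error))

    rows = [
        {
            "effect": between, "SS": ss_between, "df": df_between,
            "MS": ms_between, "F": _f(ms_between, ms_subj_err),
            "error_df": df_subj_err,
        },
        {
            "effect": within, "SS": ss_within_f, "df": df_within,
            "MS": ms_within, "F": _f(ms_within, ms_resid),
            "error_df": df_resid,
        },
        {
            "effect": f"{between}:{within}", "SS": ss_inter, "df": df_inter,
            "MS": ms_inter, "F": _f(ms_inter, ms_resid),
            "error_df": df_resid,
        },
    ]
    for r in rows:
        r["p"] = float(sps.f.sf(r["F"], r["df"], r["error_df"]))
    effects = pd.DataFrame(rows)

    cell = cell.reset_index().rename(columns={"count": "n", "std": "sd"})
    return AnovaTable(
        effects=effects,
        between=between,
        within=within,
        dv=dv,
        ms_subject_error=ms_subj_err,
        df_subject_error=df_subj_err,
        ms_residual=ms_resid,
        df_residual=df_resid,
        cell_stats=cell,
        n_complete_subjects=n_subj,
        n_dropped_subjects=int(n_dropped),
    )


def tukey_hsd(anova: AnovaTable) -> pd.DataFrame:
    """Tukey HSD over the between x within cell means of a split-plot ANOVA.

    All pairwise cell comparisons use the studentized-range distribution
    with k = number of cells.  The error term follows split-plot
    practice: comparisons whose cells differ in the within factor use
    the within-subject residual MS; comparisons differing only in the
    between factor use the between-subject error MS.
    """
    cells = anova.cell_stats
    if len(cells) < 2:
        raise ValueError("need at least 2 cells for post-hoc comparisons")
    k = len(cells)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = cells.iloc[i], cells.iloc[j]
            same_within = ci[anova.within] == cj[anova.within]
            if same_within:
                ms, dferr = anova.ms_subject_error, anova.df_subject_error
            else:
                ms, dferr = anova.ms_residual, anova.df_residual
            diff = ci["mean"] - cj["mean"]
            se = np.sqrt(ms * (1.0 / ci["n"] + 1.0 / cj["n"]) / 2.0)
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, dferr))
            rows.append(
                {
                    "group1": f"{ci[anova.between]}/{ci[anova.within]}",
                    "group2": f"{cj[anova.between]}/{cj[anova.within]}",
                    "diff": float(diff),
                    "se": float(se),
                    "q": float(q),
                    "df_error": dferr,
                    "p_adj": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)


def sidak_adjust(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= the number of p-values")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)
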