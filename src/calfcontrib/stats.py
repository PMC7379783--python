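"""Repeated-measures statistics for condition comparisons.

Implements the source analysis from first principles: a skewness screen
(advisory only), one-way repeated-measures ANOVA across conditions with the
classical sum-of-squares decomposition, and Fisher's least-significant-
difference (LSD) post hoc — uncorrected pairwise t-tests on the ANOVA error
term.  No sphericity correction is applied (Greenhouse-Geisser epsilon is
reported informationally); LSD p-values carry no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import StatsError

__all__ = [
    "RmAnovaResult",
    "PosthocResult",
    "skewness",
    "rm_anova",
    "lsd_posthoc",
    "compare_conditions",
]


def skewness(values: np.ndarray) -> float:
    """Moment-based skewness g1 = m3 / m2^(3/2) (biased moments)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise StatsError("need a 1-D sample of size >= 3")
    d = x - x.mean()
    m2 = float(np.mean(d**2))
    if m2 <= 0:
        raise StatsError("degenerate sample: zero variance")
    m3 = float(np.mean(d**3))
    return m3 / m2**1.5


@dataclass(frozen=True)
class RmAnovaResult:
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    ms_error: float
    n_subjects: int
    n_conditions: int
    gg_epsilon: float  # Greenhouse-Geisser epsilon, informational only
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _check_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise StatsError("data must be an n_subjects x k_conditions matrix")
    if np.any(~np.isfinite(data)):
        raise StatsError("unbalanced design: missing cell")
    n, k = data.shape
    if n < 2 or k < 2:
        raise StatsError("need >= 2 subjects and >= 2 conditions")
    return data


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance."""
    k = data.shape[1]
    cov = np.cov(data, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    centred = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    num = np.trace(centred) ** 2
    den = (k - 1) * np.sum(centred**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def rm_anova(data: np.ndarray, alpha: float = 0.05) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions
    matrix, with SS_total = SS_condition + SS_subject + SS_error."""
    data = _check_matrix(data)
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)

    ss_condition = n * float(np.sum((cond_means - grand) ** 2))
    ss_subject = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_error = ss_total - ss_condition - ss_subject

    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_condition = ss_condition / df1
    ms_error = ss_error / df2
    if ms_error <= 0:
        if ss_condition > 1e-12:
            raise StatsError("degenerate error term: MS_error = 0")
        f_stat, p = 0.0, 1.0
    else:
        f_stat = ms_condition / ms_error
        p = float(_st.f.sf(f_stat, df1, df2))
    return RmAnovaResult(
        f_statistic=float(f_stat),
        df=(df1, df2),
        p_value=p,
        ss_condition=ss_condition,
        ss_subject=ss_subject,
        ss_error=ss_error,
        ms_error=ms_error,
        n_subjects=n,
        n_conditions=k,
        gg_epsilon=_gg_epsilon(data),
        alpha=alpha,
    )


@dataclass(frozen=True)
class PosthocResult:
    """Pairwise LSD comparisons; p-values are two-sided and uncorrected."""

    pairs: tuple[tuple[int, int], ...]
    mean_diffs: np.ndarray
    t_statistics: np.ndarray
    df: int
    p_values: np.ndarray

    def as_frame(self, labels: list | None = None) -> pd.DataFrame:
        rows = []
        for (i, j), d, t, p in zip(
            self.pairs, self.mean_diffs, self.t_statistics, self.p_values
        ):
            a = labels[i] if labels else i
            b = labels[j] if labels else j
            rows.append(
                {"pair": f"{a} vs {b}", "mean_diff": d, "t": t, "df": self.df, "p": p}
            )
        return pd.DataFrame(rows)


def lsd_posthoc(data: np.ndarray, anova: RmAnovaResult) -> PosthocResult:
    """Fisher's LSD: t = (mean_i - mean_j) / sqrt(2 MS_error / n), on the
    ANOVA error degrees of freedom."""
    data = _check_matrix(data)
    n, k = data.shape
    if (n, k) != (anova.n_subjects, anova.n_conditions):
        raise StatsError("ANOVA result does not match data shape")
    cond_means = data.mean(axis=0)
    df = anova.df[1]
    se = np.sqrt(2.0 * anova.ms_error / n)
    pairs, diffs, ts, ps = [], [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            d = float(cond_means[i] - cond_means[j])
            if se > 0:
                t = d / se
                p = float(2.0 * _st.t.sf(abs(t), df))
            else:
                t, p = 0.0, 1.0
            pairs.append((i, j))
            diffs.append(d)
            ts.append(t)
            ps.append(p)
    return PosthocResult(
        pairs=tuple(pairs),
        mean_diffs=np.array(diffs),
        t_statistics=np.array(ts),
        df=df,
        p_values=np.array(ps),
    )


def compare_conditions(
    table: pd.DataFrame, phase: str = "braking", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-muscle RM-ANOVA + LSD report over a cohort contribution table.

    ``table`` is long format with columns subject, condition, phase, muscle,
    contribution_pct (see :mod:`calfcontrib.contributions`).  Returns one row
    per muscle with F, df, p, skewness, the significance flag at ``alpha``
    and, for every condition pair, the LSD p-value.
    """
    sub = table[table["phase"] == phase]
    if sub.empty:
        raise StatsError(f"no rows for phase {phase!r}")
    conditions = sorted(sub["condition"].unique())
    if len(conditions) < 2:
        raise StatsError("need >= 2 conditions")
    subjects = sorted(sub["subject"].unique())

    rows = []
    for muscle in dict.fromkeys(sub["muscle"]):
        msub = sub[sub["muscle"] == muscle]
        cell = (
            msub.groupby(["subject", "condition"])["contribution_pct"]
            .mean()
            .unstack()
        )
        if cell.isna().any().any() or cell.shape != (len(subjects), len(conditions)):
            raise StatsError("unbalanced design: missing subject x condition cell")
        data = cell.loc[subjects, conditions].to_numpy()
        anova = rm_anova(data, alpha=alpha)
        posthoc = lsd_posthoc(data, anova)
        row = {
            "muscle": muscle,
            "F": anova.f_statistic,
            "df1": anova.df[0],
            "df2": anova.df[1],
            "p": anova.p_value,
            "gg_epsilon": anova.gg_epsilon,
            "skewness": skewness(data.ravel()) if np.var(data) > 0 else 0.0,
            "significant": anova.significant,
        }
        for (i, j), p in zip(posthoc.pairs, posthoc.p_values):
            row[f"p_{conditions[i]}_vs_{conditions[j]}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
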