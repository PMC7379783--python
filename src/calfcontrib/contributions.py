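"""Phase-wise individual muscle contribution percentages.

A muscle's contribution over a phase is its time-integrated force as a
percentage of the summed time-integrated force of all muscle elements:

    contribution_i = 100 * int_phase F_i dt / int_phase sum_j F_j dt

(trapezoidal integration on solved frames).  An alternative per-frame-mean
reading — the mean of instantaneous force shares — is available via
``method="mean_share"``; the integral ratio is the default because it
assigns a single well-defined number to the phase.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContributionError
from .optimization import MuscleForceSolution

__all__ = [
    "phase_contribution",
    "trial_contributions",
    "cohort_table",
    "aggregate_cohort",
]

#: Maximum tolerated fraction of unsolved frames inside a phase.
MAX_UNSOLVED_FRAC = 0.20


def phase_contribution(
    solution: MuscleForceSolution,
    phase: tuple[float, float],
    method: str = "integral",
) -> np.ndarray:
    """Contribution %% vector over ``phase = (start, end)``; sums to 100."""
    start, end = phase
    if end <= start:
        raise ContributionError(f"empty phase interval ({start}, {end})")
    t = solution.time
    mask = (t >= start - 1e-12) & (t <= end + 1e-12)
    n_phase = int(mask.sum())
    if n_phase < 2:
        raise ContributionError("insufficient coverage: < 2 frames inside phase")
    solved = mask & solution.solved_mask
    if (n_phase - int(solved.sum())) / n_phase > MAX_UNSOLVED_FRAC:
        raise ContributionError(
            "insufficient coverage: too many unsolved frames inside phase"
        )
    if int(solved.sum()) < 2:
        raise ContributionError("insufficient coverage: < 2 solved frames")

    tt = t[solved]
    ff = solution.forces[solved]
    if method == "integral":
        per_muscle = np.trapezoid(ff, tt, axis=0)
        total = float(per_muscle.sum())
        if total <= 0:
            raise ContributionError("no force in phase")
        return 100.0 * per_muscle / total
    if method == "mean_share":
        totals = ff.sum(axis=1)
        if np.any(totals <= 0):
            raise ContributionError("no force in phase")
        return 100.0 * np.mean(ff / totals[:, None], axis=0)
    raise ContributionError(f"unknown contribution method {method!r}")


def trial_contributions(
    solution: MuscleForceSolution,
    intervals: Mapping[str, tuple[float, float]],
    phases: Sequence[str] = ("braking", "push_off", "stance"),
    method: str = "integral",
) -> pd.DataFrame:
    """Long-format table (phase, muscle, contribution_pct) for one trial.

    Phases without optimizer output (e.g. preactivation) are skipped.
    """
    rows = []
    for phase in phases:
        vec = phase_contribution(solution, intervals[phase], method=method)
        for muscle, pct in zip(solution.muscle_order, vec):
            rows.append({"phase": phase, "muscle": muscle, "contribution_pct": pct})
    return pd.DataFrame(rows)


def cohort_table(per_trial: Iterable[tuple[int, float, pd.DataFrame]]) -> pd.DataFrame:
    """Stack per-trial tables into (subject, condition, phase, muscle, %) rows."""
    frames = []
    for subject, condition, df in per_trial:
        df = df.copy()
        df.insert(0, "subject", subject)
        df.insert(1, "condition", condition)
        frames.append(df)
    if not frames:
        raise ContributionError("empty cohort")
    return pd.concat(frames, ignore_index=True)


def aggregate_cohort(
    table: pd.DataFrame, phase: str = "braking"
) -> pd.DataFrame:
    """Group summary: mean and SD of contribution %% per muscle x condition.

    Requires a balanced repeated-measures design (every subject in every
    condition).  Multiple trials of one subject in one cell are averaged
    first, then cell statistics are taken across subjects.
    """
    sub = table[table["phase"] == phase]
    if sub.empty:
        raise ContributionError(f"no rows for phase {phase!r}")
    subjects = sorted(sub["subject"].unique())
    conditions = sorted(sub["condition"].unique())
    cell_counts = sub.groupby(["subject", "condition"]).size().unstack(fill_value=0)
    if (cell_counts.values == 0).any() or cell_counts.shape != (
        len(subjects),
        len(conditions),
    ):
        raise ContributionError("unbalanced design: missing subject x condition cell")

    per_subject = (
        sub.groupby(["muscle", "condition", "subject"], sort=False)["contribution_pct"]
        .mean()
        .reset_index()
    )
    summary = (
        per_subject.groupby(["muscle", "condition"], sort=False)["contribution_pct"]
        .agg(["mean", "std"])
        .reset_index()
        .pivot(index="muscle", columns="condition")
    )
    # preserve model muscle order where possible
    order = list(dict.fromkeys(sub["muscle"]))
    return summary.loc[order]
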