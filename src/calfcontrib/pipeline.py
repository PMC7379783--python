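"""End-to-end analysis: recording -> phases -> moments -> forces -> contributions."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contributions import cohort_table, trial_contributions
from .dynamics import JointMomentSeries, inverse_dynamics
from .events import GaitPhases, segment_phases
from .io_signal import TrialRecording, filter_recording
from .model import ModelDefinition
from .optimization import MuscleForceSolution, solve_trial

__all__ = ["TrialResult", "analyze_trial", "analyze_cohort"]


@dataclass(frozen=True)
class TrialResult:
    phases: GaitPhases
    moments: JointMomentSeries
    solution: MuscleForceSolution
    contributions: pd.DataFrame  # long format: phase, muscle, contribution_pct


def analyze_trial(
    recording: TrialRecording,
    model: ModelDefinition,
    prefiltered: bool = False,
    relax: bool = False,
) -> TrialResult:
    """Run the full per-trial pipeline (filtering included unless disabled).

    Gait events are detected on the unfiltered force signal: the zero-phase
    low-pass smears the sharp contact onset by a few milliseconds, while the
    plate's raw threshold crossings are already robust (detect_stance bridges
    sub-50 ms noise episodes).  Dynamics consumes the filtered streams.
    """
    rec = recording if prefiltered else filter_recording(recording)
    phases = segment_phases(recording)
    moments = inverse_dynamics(rec, model, phases)
    solution = solve_trial(model, moments, relax=relax)
    contrib = trial_contributions(solution, phases.intervals)
    return TrialResult(phases, moments, solution, contrib)


def analyze_cohort(
    trials,  # iterable of (subject, condition, TrialRecording)
    model: ModelDefinition,
) -> pd.DataFrame:
    """Per-trial pipeline over a cohort; returns the long contribution table."""
    per_trial = []
    for subject, condition, recording in trials:
        result = analyze_trial(recording, model)
        per_trial.append((subject, condition, result.contributions))
    return cohort_table(per_trial)
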