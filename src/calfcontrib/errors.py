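"""Exception hierarchy for calfcontrib.

Error messages follow a stable vocabulary so callers (and the CLI) can match
on them: "model schema error", "irregular sampling", "ambiguous stance", ...
"""


class CalfContribError(Exception):
    """Base class for all package errors."""


class ModelSchemaError(CalfContribError):
    """Model-definition file is structurally invalid (missing fields, duplicates)."""


class ModelValidationError(CalfContribError):
    """Model parses but violates a physical invariant (e.g. f_max <= 0)."""


class SignalError(CalfContribError):
    """Problem with a time series: units, sampling, gaps, length."""


class EventError(CalfContribError):
    """Gait-event detection failure (ambiguous stance, missing transition...)."""


class DynamicsError(CalfContribError):
    """Inverse-dynamics preconditions violated (missing CoP, unsynchronized streams)."""


class SolverError(CalfContribError):
    """Static-optimization failure beyond per-frame infeasibility."""


class ContributionError(CalfContribError):
    """Phase-contribution computation failure (no force in phase, coverage...)."""


class StatsError(CalfContribError):
    """Statistical-analysis precondition failure (unbalanced design, degenerate sample)."""


class ScenarioError(CalfContribError):
    """Synthetic-trial parameters are invalid or physically infeasible."""
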