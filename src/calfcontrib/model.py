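"""Reduced musculoskeletal model of the calf.

Seventeen muscle elements act about three degrees of freedom
(``ankle_flexion``, ``subtalar``, ``mtp_flexion``) through constant signed
moment arms.  The model is loaded from a plain-text definition file; a
documented default is bundled with the package (see ``data/default_model.tsv``
for the sign conventions and the caveat that its parameter values are
configurable surrogates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ModelSchemaError, ModelValidationError

__all__ = [
    "MuscleElement",
    "SegmentAnthropometry",
    "ModelDefinition",
    "MomentArmMatrix",
    "load_model",
    "default_model_path",
    "default_model",
    "moment_arm_matrix",
]

#: Anatomical plausibility bound on any single moment arm, metres.
MAX_MOMENT_ARM_M = 0.12

MUSCLE_GROUPS = frozenset(
    {
        "dorsiflexor",
        "plantarflexor",
        "invertor",
        "evertor",
        "toe flexor",
        "toe extensor",
    }
)


@dataclass(frozen=True)
class MuscleElement:
    """One muscle element: max isometric force and signed moment arms per DOF."""

    name: str
    f_max: float
    moment_arms: Mapping[str, float]
    group: str

    def validate(self, dofs: Sequence[str]) -> None:
        if not np.isfinite(self.f_max) or self.f_max <= 0:
            raise ModelValidationError(
                f"model validation error: muscle {self.name!r} has f_max "
                f"{self.f_max} (must be > 0)"
            )
        if self.group not in MUSCLE_GROUPS:
            raise ModelValidationError(
                f"model validation error: muscle {self.name!r} has unknown "
                f"group {self.group!r}"
            )
        for dof, r in self.moment_arms.items():
            if dof not in dofs:
                raise ModelSchemaError(
                    f"model schema error: muscle {self.name!r} references "
                    f"unknown DOF {dof!r}"
                )
            if not np.isfinite(r) or abs(r) > MAX_MOMENT_ARM_M:
                raise ModelValidationError(
                    f"model validation error: muscle {self.name!r} moment arm "
                    f"{r} m about {dof!r} exceeds ±{MAX_MOMENT_ARM_M} m"
                )
        if not any(self.moment_arms.get(d, 0.0) != 0.0 for d in dofs):
            raise ModelValidationError(
                f"model validation error: muscle {self.name!r} spans no DOF "
                "with a nonzero moment arm"
            )

    def arm(self, dof: str) -> float:
        return float(self.moment_arms.get(dof, 0.0))


@dataclass(frozen=True)
class SegmentAnthropometry:
    """Scaling record for one body segment.

    mass_fraction is the fraction of total body mass; com_offset_m is the
    centre-of-mass offset along the segment's longitudinal axis from its
    proximal joint; gyration_radius_m yields the segment moment of inertia
    as mass * gyration_radius**2.
    """

    name: str
    mass_fraction: float
    com_offset_m: float
    gyration_radius_m: float

    def validate(self) -> None:
        if not (0 < self.mass_fraction < 1):
            raise ModelValidationError(
                f"model validation error: segment {self.name!r} mass_fraction "
                f"{self.mass_fraction} outside (0, 1)"
            )
        if self.gyration_radius_m < 0:
            raise ModelValidationError(
                f"model validation error: segment {self.name!r} negative "
                "gyration radius"
            )


@dataclass(frozen=True)
class ModelDefinition:
    muscles: tuple[MuscleElement, ...]
    dofs: tuple[str, ...]
    segments: Mapping[str, SegmentAnthropometry]

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    @property
    def f_max(self) -> np.ndarray:
        return np.array([m.f_max for m in self.muscles], dtype=float)

    def muscle_index(self, name: str) -> int:
        try:
            return self.muscle_names.index(name)
        except ValueError:
            raise KeyError(f"unknown muscle: {name!r}") from None

    def validate(self) -> None:
        names = [m.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise ModelSchemaError("model schema error: duplicate muscle names")
        if len(set(self.dofs)) != len(self.dofs):
            raise ModelSchemaError("model schema error: duplicate DOF names")
        if not self.muscles:
            raise ModelSchemaError("model schema error: no muscles defined")
        if not self.dofs:
            raise ModelSchemaError("model schema error: no DOFs defined")
        for muscle in self.muscles:
            muscle.validate(self.dofs)
        for segment in self.segments.values():
            segment.validate()
        # Antagonist representability: with >= 2 muscles overall, every DOF
        # must be loadable in both directions.
        if len(self.muscles) >= 2:
            for dof in self.dofs:
                arms = [m.arm(dof) for m in self.muscles]
                if not (any(a > 0 for a in arms) and any(a < 0 for a in arms)):
                    raise ModelValidationError(
                        f"model validation error: DOF {dof!r} lacks "
                        "opposite-signed moment arms"
                    )


@dataclass(frozen=True)
class MomentArmMatrix:
    """n_dof x n_muscle signed moment-arm matrix, row/column order fixed."""

    values: np.ndarray
    dof_order: tuple[str, ...]
    muscle_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.dof_order), len(self.muscle_order)):
            raise ModelSchemaError(
                "model schema error: moment-arm matrix shape mismatch"
            )


def moment_arm_matrix(model: ModelDefinition) -> MomentArmMatrix:
    """Assemble the DOF-by-muscle moment-arm matrix from a validated model."""
    values = np.array(
        [[m.arm(dof) for m in model.muscles] for dof in model.dofs], dtype=float
    )
    return MomentArmMatrix(values, tuple(model.dofs), model.muscle_names)


def default_model_path() -> Path:
    """Path to the bundled default model definition."""
    return Path(resources.files("calfcontrib.data") / "default_model.tsv")


def default_model() -> ModelDefinition:
    return load_model(default_model_path())


def _parse_float(token: str, context: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ModelSchemaError(
            f"model schema error: non-numeric value {token!r} in {context}"
        ) from None


def load_model(path: str | Path) -> ModelDefinition:
    """Load and validate a model-definition file.

    The format is a sectioned, tab-separated UTF-8 text file with sections
    ``[dofs]``, ``[muscles]`` and ``[segments]``; ``#`` starts a comment.
    """
    path = Path(path)
    if not path.exists():
        raise ModelSchemaError(f"model schema error: file not found: {path}")

    sections: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            name = stripped[1:-1].strip().lower()
            current = sections.setdefault(name, [])
            continue
        if current is None:
            raise ModelSchemaError(
                f"model schema error: content before any section header: {line!r}"
            )
        current.append([tok.strip() for tok in line.split("\t")])

    for required in ("dofs", "muscles"):
        if required not in sections or not sections[required]:
            raise ModelSchemaError(
                f"model schema error: missing [{required}] section"
            )

    dofs = tuple(row[0] for row in sections["dofs"])

    muscle_rows = sections["muscles"]
    header = [h.lower() for h in muscle_rows[0]]
    expected_lead = ["muscle", "group", "f_max_n"]
    if header[:3] != expected_lead:
        raise ModelSchemaError(
            "model schema error: [muscles] header must start with "
            "'muscle<TAB>group<TAB>f_max_N'"
        )
    arm_cols = header[3:]
    arm_dofs = []
    for col in arm_cols:
        if not (col.startswith("r_") and col.endswith("_m")):
            raise ModelSchemaError(
                f"model schema error: unrecognized moment-arm column {col!r}"
            )
        arm_dofs.append(col[2:-2])
    # Column stems map onto DOF names by prefix (r_ankle_m -> ankle_flexion).
    resolved = []
    for stem in arm_dofs:
        matches = [d for d in dofs if d == stem or d.startswith(stem)]
        if len(matches) != 1:
            raise ModelSchemaError(
                f"model schema error: moment-arm column r_{stem}_m does not "
                "match exactly one DOF"
            )
        resolved.append(matches[0])

    muscles = []
    for row in muscle_rows[1:]:
        if len(row) != 3 + len(arm_cols):
            raise ModelSchemaError(
                f"model schema error: muscle row has {len(row)} fields, "
                f"expected {3 + len(arm_cols)}: {row!r}"
            )
        name, group = row[0], row[1]
        f_max = _parse_float(row[2], f"f_max of {name!r}")
        arms = {
            dof: _parse_float(tok, f"moment arm of {name!r}")
            for dof, tok in zip(resolved, row[3:])
        }
        muscles.append(MuscleElement(name, f_max, arms, group))

    segments: dict[str, SegmentAnthropometry] = {}
    for row in sections.get("segments", [])[1:]:
        if len(row) != 4:
            raise ModelSchemaError(
                f"model schema error: segment row has {len(row)} fields: {row!r}"
            )
        seg = SegmentAnthropometry(
            row[0],
            _parse_float(row[1], f"mass_fraction of {row[0]!r}"),
            _parse_float(row[2], f"com_offset of {row[0]!r}"),
            _parse_float(row[3], f"gyration_radius of {row[0]!r}"),
        )
        segments[seg.name] = seg

    model = ModelDefinition(tuple(muscles), dofs, segments)
    model.validate()
    return model
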