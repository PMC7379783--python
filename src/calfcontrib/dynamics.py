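"""Inverse dynamics of the foot about ankle, subtalar and MTP axes.

The foot is a rigid segment (its mass includes the shoe's); toes are
massless for the MTP balance.  Net internal joint moments are obtained from
a Newton-Euler balance about the joint centre:

    M_int = I*alpha + (com - p) x (m*a_com) - (cop - p) x F - (com - p) x (m*g)

with g = (0, 0, -9.81) m/s^2 and +Z up, +X the direction of travel.

DOF extraction (see the model file for the sign conventions):

* ``ankle_flexion``  (dorsiflexion +) = -M_int_y about the ankle,
* ``subtalar``       (inversion +)    = -M_int_x about the ankle, estimated
  from the mediolateral CoP offset,
* ``mtp_flexion``    (toe extension +) = -M_int_y about the MTP joint, from
  GRF applied whenever the CoP lies distal to the MTP marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DynamicsError, SignalError
from .events import GaitPhases, VGRF_THRESHOLD_N
from .io_signal import TrialRecording
from .model import ModelDefinition

__all__ = [
    "GRAVITY",
    "FootState",
    "JointMomentSeries",
    "differentiate",
    "foot_inertial_params",
    "internal_foot_moment",
    "dof_moments",
    "inverse_dynamics",
]

GRAVITY = 9.81  # m/s^2, +Z up
_G_VEC = np.array([0.0, 0.0, -GRAVITY])

CANONICAL_DOFS = ("ankle_flexion", "subtalar", "mtp_flexion")


def differentiate(time: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration by finite differences.

    Central differences in the interior (exact for polynomials of degree <= 2),
    second-order one-sided stencils at the ends.
    """
    time = np.asarray(time, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if time.size < 3:
        raise SignalError("insufficient samples: need >= 3 for differentiation")
    dt = float(np.median(np.diff(time)))
    vel = np.gradient(positions, dt, axis=0, edge_order=2)
    acc = np.empty_like(positions)
    acc[1:-1] = (positions[2:] - 2 * positions[1:-1] + positions[:-2]) / dt**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return vel, acc


@dataclass(frozen=True)
class FootState:
    """Per-frame rigid-body state of the foot on the marker clock."""

    time: np.ndarray
    ankle: np.ndarray  # (n, 3) joint centre, m
    mtp: np.ndarray  # (n, 3) metatarsophalangeal joint, m
    com: np.ndarray  # (n, 3) segment CoM (incl. shoe), m
    com_acc: np.ndarray  # (n, 3), m/s^2
    alpha_y: np.ndarray  # sagittal angular acceleration, rad/s^2
    mass: float  # kg, includes shoe mass
    inertia: float  # kg m^2 about CoM, sagittal


@dataclass(frozen=True)
class JointMomentSeries:
    """Net internal DOF moments on the force clock, inside stance only."""

    time: np.ndarray
    values: np.ndarray  # (n, n_dof) N*m
    dof_order: tuple[str, ...]

    def column(self, dof: str) -> np.ndarray:
        return self.values[:, self.dof_order.index(dof)]


def foot_inertial_params(
    model: ModelDefinition, body_mass: float, shoe_mass: float
) -> tuple[float, float, float]:
    """(mass, com_offset, inertia) of the foot+shoe segment."""
    try:
        seg = model.segments["foot"]
    except KeyError:
        raise DynamicsError("model has no 'foot' segment anthropometry") from None
    mass = seg.mass_fraction * body_mass + shoe_mass
    inertia = mass * seg.gyration_radius_m**2
    return mass, seg.com_offset_m, inertia


def foot_state(
    recording: TrialRecording, model: ModelDefinition
) -> FootState:
    """Build the foot rigid-body state from the heel/toe/ankle/mtp markers."""
    required = ("heel", "toe", "ankle", "mtp")
    for name in required:
        if name not in recording.markers:
            raise DynamicsError(f"missing marker {name!r} for foot dynamics")
    heel = recording.markers["heel"]
    toe = recording.markers["toe"]
    ankle = recording.markers["ankle"]
    mtp = recording.markers["mtp"]

    mass, com_offset, inertia = foot_inertial_params(
        model, recording.body_mass, recording.shoe_mass
    )
    axis = toe - heel
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    if np.any(norm < 1e-9):
        raise DynamicsError("degenerate foot axis: heel and toe coincide")
    u = axis / norm
    com = ankle + com_offset * u

    _, com_acc = differentiate(recording.marker_time, com)
    # sagittal foot angle about +Y (x-z plane)
    theta = np.arctan2(-axis[:, 2], axis[:, 0])
    theta = np.unwrap(theta)
    _, alpha = differentiate(recording.marker_time, theta[:, None])
    return FootState(
        time=recording.marker_time,
        ankle=ankle,
        mtp=mtp,
        com=com,
        com_acc=com_acc,
        alpha_y=alpha[:, 0],
        mass=mass,
        inertia=inertia,
    )


def internal_foot_moment(
    point: np.ndarray,
    cop: np.ndarray,
    grf: np.ndarray,
    com: np.ndarray,
    mass: float,
    com_acc: np.ndarray | None = None,
    inertia: float = 0.0,
    alpha_y: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized internal joint moment (n, 3) about ``point``.

    ``cop`` is (n, 3) with z = plate surface height (usually 0); omitted
    inertial terms default to the static case.
    """
    point = np.atleast_2d(point)
    cop = np.atleast_2d(cop)
    grf = np.atleast_2d(grf)
    com = np.atleast_2d(com)
    n = max(point.shape[0], grf.shape[0])
    m_int = np.zeros((n, 3))
    if inertia and alpha_y is not None:
        m_int[:, 1] += inertia * np.asarray(alpha_y)
    if com_acc is not None:
        m_int += np.cross(com - point, mass * np.asarray(com_acc))
    m_int -= np.cross(cop - point, grf)
    m_int -= np.cross(com - point, mass * _G_VEC)
    return m_int


def dof_moments(
    ankle: np.ndarray,
    mtp: np.ndarray,
    cop: np.ndarray,
    grf: np.ndarray,
    com: np.ndarray,
    mass: float,
    com_acc: np.ndarray | None = None,
    inertia: float = 0.0,
    alpha_y: np.ndarray | None = None,
) -> np.ndarray:
    """(n, 3) array of [ankle_flexion, subtalar, mtp_flexion] moments."""
    m_ankle = internal_foot_moment(
        ankle, cop, grf, com, mass, com_acc, inertia, alpha_y
    )
    out = np.empty((m_ankle.shape[0], 3))
    out[:, 0] = -m_ankle[:, 1]  # dorsiflexion +
    out[:, 1] = -m_ankle[:, 0]  # inversion +
    # toes: massless, loaded only when the CoP is distal to the MTP joint
    mtp2 = np.atleast_2d(mtp)
    cop2 = np.atleast_2d(cop)
    loaded = cop2[:, 0] > mtp2[:, 0]
    m_mtp = internal_foot_moment(mtp, cop, grf, np.zeros_like(mtp), 0.0)
    out[:, 2] = np.where(loaded, -m_mtp[:, 1], 0.0)  # toe extension +
    return out


def inverse_dynamics(
    recording: TrialRecording,
    model: ModelDefinition,
    phases: GaitPhases,
    threshold: float = VGRF_THRESHOLD_N,
) -> JointMomentSeries:
    """Net internal DOF moments across stance, on the force clock.

    Marker-derived quantities (200 Hz) are interpolated onto the force
    samples (1000 Hz) inside stance; GRF and CoP are consumed at native rate.
    """
    for dof in CANONICAL_DOFS:
        if dof not in model.dofs:
            raise DynamicsError(f"model lacks required DOF {dof!r}")

    state = foot_state(recording, model)
    ft = recording.force_time
    mask = (ft >= phases.heel_strike) & (ft <= phases.toe_off)
    t = ft[mask]
    if t.size < 2:
        raise DynamicsError("unsynchronized streams: no force samples in stance")
    if t[0] < state.time[0] - 1e-9 or t[-1] > state.time[-1] + 1e-9:
        raise DynamicsError("unsynchronized streams: stance outside marker record")

    grf = recording.forces[mask]
    cop_xy = recording.cop[mask]
    loaded = grf[:, 2] > threshold
    if np.any(~np.isfinite(cop_xy[loaded])):
        raise DynamicsError("missing CoP while vGRF above threshold")
    cop = np.column_stack([cop_xy, np.zeros(t.size)])
    cop = np.where(np.isfinite(cop), cop, 0.0)

    def interp(series: np.ndarray) -> np.ndarray:
        series = np.atleast_2d(series.T).T
        return np.column_stack(
            [np.interp(t, state.time, series[:, j]) for j in range(series.shape[1])]
        )

    ankle = interp(state.ankle)
    mtp = interp(state.mtp)
    com = interp(state.com)
    com_acc = interp(state.com_acc)
    alpha = np.interp(t, state.time, state.alpha_y)

    values = dof_moments(
        ankle, mtp, cop, grf, com, state.mass, com_acc, state.inertia, alpha
    )
    if not np.all(np.isfinite(values)):
        raise DynamicsError("non-finite joint moments inside stance")
    order = tuple(d for d in model.dofs if d in CANONICAL_DOFS)
    col = {"ankle_flexion": 0, "subtalar": 1, "mtp_flexion": 2}
    values = values[:, [col[d] for d in order]]
    return JointMomentSeries(time=t, values=values, dof_order=order)
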