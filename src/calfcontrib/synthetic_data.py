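"""Synthetic running trials with known ground-truth muscle forces.

Construction guarantees an exactly feasible inverse problem:

1. GRF templates — a double-hump vertical profile and a braking-then-
   propulsive anterior-posterior profile — are evaluated on the force clock;
2. smooth ankle/subtalar moment targets are chosen, and the centre of
   pressure is *solved* from the static foot moment balance so that inverse
   dynamics on the rendered data reproduces those targets exactly (the MTP
   moment follows from the CoP geometry);
3. ground-truth muscle forces are the squared-activation-minimal
   distribution of the truth moments, so the downstream optimizer can
   recover them (an optional effect specification perturbs the truth away
   from the optimum while preserving the moment balance).

The foot is rendered stationary during the trial (a quasi-static stance),
which keeps the rigid-body inertial terms exactly zero pre-noise.
All randomness flows through one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from . import dynamics as _dyn
from .contributions import phase_contribution
from .errors import ScenarioError, SolverError
from .events import VGRF_THRESHOLD_N, GaitPhases
from .io_signal import FORCE_RATE_HZ, MARKER_RATE_HZ, TrialRecording, write_trial
from .model import ModelDefinition, moment_arm_matrix
from .optimization import MuscleForceSolution, solve_trial

__all__ = [
    "TrialParams",
    "SyntheticTrial",
    "grf_profile",
    "generate_trial",
    "generate_cohort",
    "DEFAULT_SHOE_MASSES",
]

DEFAULT_SHOE_MASSES = (0.175, 0.255, 0.335, 0.415)

#: Static marker positions (m) used to pose the foot-shank chain.
_MARKER_POSITIONS = {
    "toe": (0.18, 0.0, 0.010),
    "mtp": (0.12, 0.0, 0.015),
    "heel": (-0.06, 0.0, 0.020),
    "ankle": (0.0, 0.0, 0.080),
    "knee": (0.02, 0.0, 0.480),
    "hip": (0.03, 0.0, 0.950),
}

_VGRF_DIP = 0.6  # relative mid-stance dip of the double-hump template
#: Edge exponent of the vertical template: > 1 keeps the profile C1 at the
#: endpoints (bounding low-pass edge transients) while rising steeply enough
#: that the 10 N contact threshold is crossed within ~1 ms of the support.
_VGRF_EDGE_EXP = 1.3
_AP_PEAK_BW = 0.32  # braking lobe scale as a fraction of body weight


@dataclass(frozen=True)
class TrialParams:
    """Parameters of one synthetic running trial."""

    body_mass: float = 68.0
    shoe_mass: float = 0.255
    stance_duration: float = 0.22
    stride_duration: float = 0.70
    peak_vgrf_bw: float = 2.5
    braking_fraction: float = 0.5
    noise_sd_marker: float = 0.0  # m
    noise_sd_force: float = 0.0  # N
    seed: int = 0
    heel_strike_time: float = 0.15  # s after recording start
    ankle_lever_m: float = 0.195  # CoP excursion scale driving the ankle moment
    subtalar_lever_m: float = 0.004  # mediolateral lever scale

    def validate(self) -> None:
        if not 0 < self.braking_fraction < 1:
            raise ScenarioError(
                f"braking_fraction must be in (0, 1), got {self.braking_fraction}"
            )
        if not self.stance_duration < self.stride_duration - self.heel_strike_time:
            raise ScenarioError("stance must end before the recording does")
        if self.body_mass <= 0 or self.shoe_mass <= 0:
            raise ScenarioError("all masses must be > 0")
        if self.heel_strike_time < 0.05:
            raise ScenarioError("need >= 50 ms of pre-contact recording")
        if self.peak_vgrf_bw <= 0:
            raise ScenarioError("peak_vgrf_bw must be > 0")
        if self.noise_sd_marker < 0 or self.noise_sd_force < 0:
            raise ScenarioError("noise SDs must be >= 0")


@dataclass(frozen=True)
class SyntheticTrial:
    """A rendered recording plus its generating ground truth."""

    recording: TrialRecording
    truth_forces: np.ndarray  # (n_stance_frames, n_muscle), N
    truth_moments: _dyn.JointMomentSeries
    truth_phases: GaitPhases
    params: TrialParams
    muscle_order: tuple[str, ...]
    subject: int | None = None
    condition: float | None = None

    def truth_solution(self) -> MuscleForceSolution:
        """Ground truth packaged like an optimizer output."""
        f_max_like = np.maximum(self.truth_forces.max(axis=0), 1.0)
        n = self.truth_forces.shape[0]
        return MuscleForceSolution(
            time=self.truth_moments.time,
            forces=self.truth_forces,
            activations=self.truth_forces / f_max_like,
            objective=np.zeros(n),
            status=np.asarray(["solved"] * n, dtype=object),
            residual=np.zeros(n),
            muscle_order=self.muscle_order,
        )

    def truth_contribution(self, phase: str = "braking") -> np.ndarray:
        """Contribution %% per muscle computed directly from truth forces."""
        interval = self.truth_phases.intervals[phase]
        return phase_contribution(self.truth_solution(), interval)


# ---------------------------------------------------------------------------
# GRF templates


def _vgrf_shape(s: np.ndarray) -> np.ndarray:
    """Unit-normalized double-hump vertical profile on s in [0, 1].

    C1 at both endpoints (zero slope), so low-pass filtering introduces no
    edge transients.
    """
    s = np.asarray(s, dtype=float)
    raw = np.sin(np.pi * np.clip(s, 0, 1)) ** _VGRF_EDGE_EXP * (
        1.0 + _VGRF_DIP * np.cos(2.0 * np.pi * s)
    )
    return np.where((s >= 0) & (s <= 1), raw, 0.0) / _VGRF_SHAPE_MAX


_s_dense = np.linspace(0.0, 1.0, 20001)
_VGRF_SHAPE_MAX = float(
    np.max(
        np.sin(np.pi * _s_dense) ** _VGRF_EDGE_EXP
        * (1.0 + _VGRF_DIP * np.cos(2.0 * np.pi * _s_dense))
    )
)


def _ap_shape(s: np.ndarray, braking_fraction: float) -> np.ndarray:
    """Braking-then-propulsive AP profile; C1 at the stance endpoints.

    Two sine lobes changing sign exactly at ``braking_fraction``, tapered by
    a sin(pi s) envelope; for braking_fraction = 0.5 the profile is
    antisymmetric about mid-stance (zero net impulse).
    """
    s = np.asarray(s, dtype=float)
    b = braking_fraction
    brake = -np.sin(np.pi * np.clip(s, 0, b) / b)
    push = np.sin(np.pi * (np.clip(s, b, 1) - b) / (1 - b)) * (b / (1 - b))
    out = np.where(s <= b, brake, push) * np.sin(np.pi * np.clip(s, 0, 1))
    return np.where((s >= 0) & (s <= 1), out, 0.0)


def grf_profile(t: float | np.ndarray, params: TrialParams) -> np.ndarray:
    """Ground reaction force 3-vector(s) (Fx ap, Fy ml, Fz vertical) at
    stance-relative time ``t`` in seconds, 0 <= t <= stance_duration."""
    params.validate()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < -1e-12) or np.any(t_arr > params.stance_duration + 1e-12):
        raise ScenarioError("out of range: t outside stance")
    s = t_arr / params.stance_duration
    bw = params.body_mass * _dyn.GRAVITY
    fz = params.peak_vgrf_bw * bw * _vgrf_shape(s)
    fx = _AP_PEAK_BW * bw * _ap_shape(s, params.braking_fraction)
    out = np.column_stack([fx, np.zeros_like(fz), fz])
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# trial generation


def _moment_targets(
    s: np.ndarray, vgrf: np.ndarray, params: TrialParams
) -> tuple[np.ndarray, np.ndarray]:
    """Designed ankle/subtalar moment target curves (N*m).

    The ankle target tracks a CoP that migrates heel-to-toe (dorsiflexor
    demand at contact, large plantarflexor demand through push-off); the
    subtalar target is a gentle inversion-then-eversion wave.  Both scale
    with the instantaneous vGRF so the implied CoP stays bounded.
    """
    lever_a = 0.03 - params.ankle_lever_m * np.clip(s, 0, 1) ** 1.3
    m_ankle = vgrf * lever_a
    m_sub = vgrf * params.subtalar_lever_m * np.sin(2.0 * np.pi * np.clip(s, 0, 1))
    return m_ankle, m_sub


def _capacity_check(model: ModelDefinition, m_ankle: np.ndarray, m_sub: np.ndarray) -> None:
    mam = moment_arm_matrix(model).values
    f_max = model.f_max
    for j, series in ((0, m_ankle), (1, m_sub)):
        pos_cap = float(np.sum(np.where(mam[j] > 0, mam[j], 0) * f_max))
        neg_cap = float(np.sum(np.where(mam[j] < 0, -mam[j], 0) * f_max))
        if np.max(series, initial=0.0) > pos_cap or -np.min(series, initial=0.0) > neg_cap:
            raise ScenarioError(
                f"infeasible scenario: designed moment exceeds capacity on DOF {j}"
            )


def generate_trial(
    model: ModelDefinition, params: TrialParams, subject: int | None = None
) -> SyntheticTrial:
    """Render one synthetic trial with per-frame ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    force_time = np.arange(round(params.stride_duration * FORCE_RATE_HZ)) / FORCE_RATE_HZ
    marker_time = np.arange(round(params.stride_duration * MARKER_RATE_HZ)) / MARKER_RATE_HZ

    t_hs = params.heel_strike_time
    s = (force_time - t_hs) / params.stance_duration
    in_stance = (s >= 0) & (s <= 1)
    bw = params.body_mass * _dyn.GRAVITY
    vgrf = params.peak_vgrf_bw * bw * _vgrf_shape(np.clip(s, 0, 1)) * in_stance
    ap = _AP_PEAK_BW * bw * _ap_shape(np.clip(s, 0, 1), params.braking_fraction) * in_stance
    forces = np.column_stack([ap, np.zeros_like(vgrf), vgrf])

    # static marker pose
    markers = {
        name: np.tile(np.asarray(pos, dtype=float), (marker_time.size, 1))
        for name, pos in _MARKER_POSITIONS.items()
    }
    # cosmetic vertical bobbing of the hip (does not enter calf dynamics)
    markers["hip"] = markers["hip"].copy()
    markers["hip"][:, 2] += 0.01 * np.sin(
        2.0 * np.pi * marker_time / params.stride_duration
    )

    mass, com_offset, _ = _dyn.foot_inertial_params(
        model, params.body_mass, params.shoe_mass
    )
    ankle = np.asarray(_MARKER_POSITIONS["ankle"])
    heel = np.asarray(_MARKER_POSITIONS["heel"])
    toe = np.asarray(_MARKER_POSITIONS["toe"])
    u = (toe - heel) / np.linalg.norm(toe - heel)
    com = ankle + com_offset * u
    c_rel = com - ankle
    rz = -ankle[2]  # CoP sits on the plate surface z = 0

    m_ankle_t, m_sub_t = _moment_targets(np.clip(s, 0, 1), vgrf, params)
    m_ankle_t *= in_stance
    m_sub_t *= in_stance
    _capacity_check(model, m_ankle_t[in_stance], m_sub_t[in_stance])

    # solve CoP from the static moment balance (see dynamics.dof_moments):
    #   M_ankle = rz*Fx - rx*Fz + m*g*c_x   =>  rx
    #   M_sub   = ry*Fz - m*g*c_y           =>  ry
    cop = np.zeros((force_time.size, 2))
    loaded = vgrf > VGRF_THRESHOLD_N
    fz = vgrf[loaded]
    cop[loaded, 0] = ankle[0] + (
        rz * ap[loaded] + mass * _dyn.GRAVITY * c_rel[0] - m_ankle_t[loaded]
    ) / fz
    cop[loaded, 1] = ankle[1] + (
        m_sub_t[loaded] + mass * _dyn.GRAVITY * c_rel[1]
    ) / fz

    # ground-truth moments on the loaded frames, via the shared formula
    t_stance = force_time[loaded]
    cop3 = np.column_stack([cop[loaded], np.zeros(loaded.sum())])
    truth_m = _dyn.dof_moments(
        np.tile(ankle, (t_stance.size, 1)),
        np.tile(np.asarray(_MARKER_POSITIONS["mtp"]), (t_stance.size, 1)),
        cop3,
        forces[loaded],
        np.tile(com, (t_stance.size, 1)),
        mass,
    )
    truth_moments = _dyn.JointMomentSeries(
        time=t_stance, values=truth_m, dof_order=_dyn.CANONICAL_DOFS
    )

    try:
        truth_sol = solve_trial(model, truth_moments, max_infeasible_frac=0.0)
    except SolverError as exc:
        raise ScenarioError(f"infeasible scenario: {exc}") from exc
    truth_forces = truth_sol.forces

    # exact event times from the noiseless template
    shape10 = VGRF_THRESHOLD_N / (params.peak_vgrf_bw * bw)

    def _f(x: float) -> float:
        return float(_vgrf_shape(np.asarray(x)) - shape10)

    s_peak = float(_s_dense[np.argmax(_vgrf_shape(_s_dense))])
    s_on = brentq(_f, 1e-9, s_peak)
    s_off = brentq(_f, 1.0 - (1.0 - s_peak), 1.0 - 1e-9) if _f(0.5) > 0 else brentq(_f, 0.5, 1 - 1e-9)
    truth_phases = GaitPhases(
        heel_strike=t_hs + s_on * params.stance_duration,
        toe_off=t_hs + s_off * params.stance_duration,
        brake_end=t_hs + params.braking_fraction * params.stance_duration,
    )

    # measurement noise (drawn in a fixed order for determinism)
    if params.noise_sd_marker > 0:
        for name in sorted(markers):
            markers[name] = markers[name] + rng.normal(
                0.0, params.noise_sd_marker, size=markers[name].shape
            )
    if params.noise_sd_force > 0:
        forces = forces + rng.normal(0.0, params.noise_sd_force, size=forces.shape)
    if params.noise_sd_marker > 0:
        cop = cop.copy()
        cop[loaded] += rng.normal(0.0, params.noise_sd_marker, size=(int(loaded.sum()), 2))

    recording = TrialRecording(
        marker_time=marker_time,
        markers=markers,
        force_time=force_time,
        forces=forces,
        cop=cop,
        body_mass=params.body_mass,
        shoe_mass=params.shoe_mass,
    )
    recording.validate()
    return SyntheticTrial(
        recording=recording,
        truth_forces=truth_forces,
        truth_moments=truth_moments,
        truth_phases=truth_phases,
        params=params,
        muscle_order=model.muscle_names,
        subject=subject,
        condition=params.shoe_mass,
    )


# ---------------------------------------------------------------------------
# cohorts and condition effects


def _apply_effect(
    trial: SyntheticTrial, model: ModelDefinition, effect: Mapping[str, float]
) -> SyntheticTrial:
    """Scale named muscles' truth forces, preserving the moment balance.

    ``effect`` maps muscle name -> fractional force change delta; the moment
    deficit is redistributed over the remaining muscles by a minimum-norm
    activation correction.  The perturbed truth is no longer the
    squared-activation optimum (recovery is only exact for delta = 0).
    """
    from .optimization import _dual_newton

    forces = trial.truth_forces.copy()
    mam = moment_arm_matrix(model)
    R = mam.values
    f_max = model.f_max
    A = R * f_max

    idx = [model.muscle_index(name) for name in effect]
    deltas = np.array([effect[name] for name in effect], dtype=float)
    others = np.setdiff1d(np.arange(len(f_max)), idx)

    d_forces = forces[:, idx] * deltas  # (n_frames, len(idx))
    forces[:, idx] += d_forces
    if np.any(forces[:, idx] < -1e-9) or np.any(
        forces[:, idx] > f_max[idx][None, :] + 1e-9
    ):
        raise ScenarioError(
            "infeasible scenario: effect specification pushes truth forces "
            "outside bounds"
        )
    # cancel the moment error with the other muscles: per frame, the
    # smallest activation change keeping the balance exact and all forces
    # within bounds (box-constrained projection QP)
    m_err = d_forces @ R[:, idx].T  # (n_frames, n_dof)
    A_o = A[:, others]
    a_others = forces[:, others] / f_max[others]
    targets = a_others @ A_o.T - m_err
    lam = None
    for k in range(forces.shape[0]):
        out = _dual_newton(A_o, targets[k], lam0=lam, center=a_others[k])
        if out is None:
            raise ScenarioError(
                "infeasible scenario: effect specification pushes truth "
                "forces outside bounds"
            )
        x, lam = out
        forces[k, others] = x * f_max[others]
    return replace(trial, truth_forces=forces)


def generate_cohort(
    model: ModelDefinition,
    n_subjects: int,
    conditions: Sequence[float] = DEFAULT_SHOE_MASSES,
    effect: Mapping[str, Mapping[float, float]] | None = None,
    seed: int = 0,
    base_params: TrialParams | None = None,
    noise_sd_marker: float = 0.0,
    noise_sd_force: float = 0.0,
) -> list[SyntheticTrial]:
    """One trial per subject x shoe-mass condition, with between-subject
    random parameter offsets and within-subject per-trial jitter.

    ``effect`` maps muscle name -> {shoe_mass: fractional force delta},
    perturbing that muscle's ground-truth force curve per condition.
    """
    if n_subjects < 2:
        raise ScenarioError("need >= 2 subjects")
    if len(conditions) < 2:
        raise ScenarioError("need >= 2 conditions")
    if effect:
        for name in effect:
            model.muscle_index(name)  # raises KeyError("unknown muscle: ...")

    base = base_params or TrialParams(
        noise_sd_marker=noise_sd_marker, noise_sd_force=noise_sd_force
    )
    rng = np.random.default_rng(seed)
    trials: list[SyntheticTrial] = []
    for subj in range(n_subjects):
        body_mass = float(rng.normal(68.0, 4.3))
        stance = float(rng.normal(base.stance_duration, 0.010))
        peak = float(rng.normal(base.peak_vgrf_bw, 0.10))
        brf = float(np.clip(rng.normal(base.braking_fraction, 0.02), 0.3, 0.7))
        lever = float(rng.normal(base.ankle_lever_m, 0.004))
        sub_lever = float(rng.normal(base.subtalar_lever_m, 0.0004))
        for cond in conditions:
            params = replace(
                base,
                body_mass=body_mass,
                shoe_mass=float(cond),
                stance_duration=stance + float(rng.normal(0.0, 0.004)),
                peak_vgrf_bw=peak + float(rng.normal(0.0, 0.04)),
                braking_fraction=float(np.clip(brf + rng.normal(0.0, 0.008), 0.3, 0.7)),
                ankle_lever_m=lever + float(rng.normal(0.0, 0.002)),
                subtalar_lever_m=sub_lever + float(rng.normal(0.0, 0.0002)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trial = generate_trial(model, params, subject=subj)
            if effect:
                per_cond = {
                    name: spec[float(cond)]
                    for name, spec in effect.items()
                    if float(cond) in spec
                }
                if per_cond:
                    trial = _apply_effect(trial, model, per_cond)
            trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# on-disk bundle (CLI `simulate`)


def write_trial_bundle(trial: SyntheticTrial, out_dir: str | Path, prefix: str) -> None:
    """Write marker/force/meta files plus ground-truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trial(
        trial.recording,
        out / f"{prefix}_markers.tsv",
        out / f"{prefix}_forces.tsv",
        out / f"{prefix}_meta.tsv",
    )
    header = ["time_s"] + [f"F_{m.replace(' ', '_')}_N" for m in trial.muscle_order]
    lines = ["\t".join(header)]
    for i, t in enumerate(trial.truth_moments.time):
        lines.append(
            "\t".join([repr(float(t))] + [repr(float(v)) for v in trial.truth_forces[i]])
        )
    (out / f"{prefix}_truth_forces.tsv").write_text("\n".join(lines) + "\n")
    lines = ["time_s\t" + "\t".join(trial.truth_moments.dof_order)]
    for i, t in enumerate(trial.truth_moments.time):
        lines.append(
            "\t".join(
                [repr(float(t))]
                + [repr(float(v)) for v in trial.truth_moments.values[i]]
            )
        )
    (out / f"{prefix}_truth_moments.tsv").write_text("\n".join(lines) + "\n")
    p = trial.params
    (out / f"{prefix}_params.tsv").write_text(
        "\n".join(f"{k}\t{v!r}" for k, v in vars(p).items()) + "\n"
    )
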