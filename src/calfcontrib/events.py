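"""Gait-event detection and phase segmentation.

Stance is the single contiguous interval where the vertical ground reaction
force exceeds a 10 N threshold; the braking phase runs from heel strike to
the anterior-posterior GRF's braking-to-propulsion transition, push-off from
there to toe-off, and preactivation is the 50 ms window before heel strike.

Sign convention: the AP GRF acting on the runner is negative (decelerating)
during braking and positive during propulsion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EventError
from .io_signal import TrialRecording

__all__ = ["GaitPhases", "detect_stance", "detect_brake_end", "segment_phases"]

VGRF_THRESHOLD_N = 10.0
PREACTIVATION_S = 0.050
MIN_EPISODE_S = 0.050


@dataclass(frozen=True)
class GaitPhases:
    """Event times (s) and the four named half-open phase intervals."""

    heel_strike: float
    toe_off: float
    brake_end: float

    def __post_init__(self) -> None:
        if not (self.heel_strike < self.brake_end < self.toe_off):
            raise EventError(
                "invalid phases: require heel_strike < brake_end < toe_off "
                f"(got {self.heel_strike}, {self.brake_end}, {self.toe_off})"
            )

    @property
    def preactivation_start(self) -> float:
        return self.heel_strike - PREACTIVATION_S

    @property
    def intervals(self) -> dict[str, tuple[float, float]]:
        return {
            "preactivation": (self.preactivation_start, self.heel_strike),
            "stance": (self.heel_strike, self.toe_off),
            "braking": (self.heel_strike, self.brake_end),
            "push_off": (self.brake_end, self.toe_off),
        }

    @property
    def stance_duration(self) -> float:
        return self.toe_off - self.heel_strike

    def to_tsv(self) -> str:
        lines = ["phase\tstart_s\tend_s\tduration_s"]
        for name, (a, b) in self.intervals.items():
            lines.append(f"{name}\t{a!r}\t{b!r}\t{b - a!r}")
        return "\n".join(lines) + "\n"


def _cross_time(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    """Linear-interpolated time where the segment (t0,v0)-(t1,v1) crosses level."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def detect_stance(
    time: np.ndarray, vgrf: np.ndarray, threshold: float = VGRF_THRESHOLD_N
) -> tuple[float, float]:
    """Locate heel strike and toe-off as interpolated threshold crossings.

    Supra-threshold episodes shorter than 50 ms are treated as spikes and
    ignored; sub-threshold dips shorter than 50 ms between episodes are
    bridged (hysteresis against noise at the threshold).  Exactly one
    episode must remain.
    """
    time = np.asarray(time, dtype=float)
    vgrf = np.asarray(vgrf, dtype=float)
    if time.shape != vgrf.shape or time.ndim != 1:
        raise EventError("vgrf and time must be equal-length 1-D arrays")

    above = vgrf > threshold
    if not above.any():
        raise EventError("ambiguous stance: no supra-threshold episode found")
    # episode boundaries as index ranges [start, end)
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]

    # bridge short sub-threshold gaps
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and time[s] - time[merged[-1][1] - 1] < MIN_EPISODE_S:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # drop short spikes
    episodes = [
        (s, e) for s, e in merged if time[e - 1] - time[s] >= MIN_EPISODE_S
    ]
    if not episodes:
        raise EventError("spike rejected, no stance")
    if len(episodes) > 1:
        raise EventError(
            f"ambiguous stance: {len(episodes)} supra-threshold episodes"
        )
    s, e = episodes[0]

    if s == 0:
        heel_strike = float(time[0])
    else:
        heel_strike = _cross_time(
            time[s - 1], time[s], vgrf[s - 1], vgrf[s], threshold
        )
    if e == time.size:
        toe_off = float(time[-1])
    else:
        toe_off = _cross_time(time[e - 1], time[e], vgrf[e - 1], vgrf[e], threshold)
    if not heel_strike < toe_off:
        raise EventError("ambiguous stance: degenerate episode")
    return heel_strike, toe_off


def detect_brake_end(
    time: np.ndarray,
    ap_grf: np.ndarray,
    stance: tuple[float, float],
) -> float:
    """Interpolated braking-to-propulsion transition of the AP GRF.

    Within stance, the AP trace must start braking-signed (negative); the
    transition is the last upward zero crossing between the braking minimum
    and the propulsive maximum, after which the trace stays propulsive.
    """
    time = np.asarray(time, dtype=float)
    ap_grf = np.asarray(ap_grf, dtype=float)
    heel_strike, toe_off = stance
    mask = (time >= heel_strike) & (time <= toe_off)
    if mask.sum() < 3:
        raise EventError("no braking/propulsion transition: stance too short")
    t = time[mask]
    ap = ap_grf[mask]

    imin = int(np.argmin(ap))
    imax = int(np.argmax(ap))
    if ap[imin] >= 0 or imin > imax or np.nanmax(ap) <= 0:
        if ap.max() <= 0:
            raise EventError("no braking/propulsion transition: AP GRF never propulsive")
        raise EventError("unexpected AP polarity: no braking onset at heel strike")
    # early samples must be braking-signed (allow a sliver of threshold noise)
    if ap[0] > 0 and ap[: max(imin, 1)].min() > 0:
        raise EventError("unexpected AP polarity: propulsive at heel strike")

    seg = slice(imin, imax + 1)
    ups = np.flatnonzero((ap[seg][:-1] < 0) & (ap[seg][1:] >= 0))
    if ups.size == 0:
        raise EventError("no braking/propulsion transition found")
    k = imin + int(ups[-1])
    brake_end = _cross_time(t[k], t[k + 1], ap[k], ap[k + 1], 0.0)
    if not heel_strike < brake_end < toe_off:
        raise EventError("no braking/propulsion transition inside stance")
    return float(brake_end)


def segment_phases(
    recording: TrialRecording, threshold: float = VGRF_THRESHOLD_N
) -> GaitPhases:
    """Detect stance and the braking transition; build the phase partition."""
    heel_strike, toe_off = detect_stance(
        recording.force_time, recording.vgrf, threshold
    )
    brake_end = detect_brake_end(
        recording.force_time, recording.ap_grf, (heel_strike, toe_off)
    )
    phases = GaitPhases(heel_strike, toe_off, brake_end)
    if phases.preactivation_start < recording.force_time[0] - 1e-12:
        raise EventError(
            "insufficient pre-contact data: recording starts "
            f"{recording.force_time[0] - phases.preactivation_start:.3f} s too late"
        )
    return phases
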