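"""Trial I/O, stream synchronization, filtering and normalization.

A trial is three UTF-8, tab-separated text files:

* marker file  — header line ``# units: mm`` (or ``m``), then a header row
  ``time_s`` followed by ``<marker>_x``, ``<marker>_y``, ``<marker>_z``
  triplets, then one row per 200 Hz frame;
* force file   — header line ``# units: N m``, then
  ``time_s  fx_N  fy_N  fz_N  cop_x_m  cop_y_m`` rows at 1000 Hz
  (CoP columns are zero whenever the plate is unloaded);
* metadata file — ``key<TAB>value`` lines: ``body_mass_kg``, ``shoe_mass_kg``,
  ``side``.

All quantities are stored in SI units in memory (markers in metres).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import signal as _signal

from .errors import SignalError

__all__ = [
    "TrialRecording",
    "FilterSpec",
    "load_trial",
    "write_trial",
    "lowpass",
    "normalize_grf",
    "normalize_cycle",
    "filter_recording",
]

MARKER_RATE_HZ = 200.0
FORCE_RATE_HZ = 1000.0

#: Maximum marker gap (consecutive NaN samples) repaired by interpolation.
MAX_GAP_SAMPLES = 10

#: Relative tolerance on sampling-interval uniformity.
_DT_RTOL = 1e-4


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase low-pass Butterworth specification (single-pass order)."""

    order: int = 4
    cutoff_hz: float = 12.0
    passes: int = 2  # forward-backward

    def validate(self, rate_hz: float) -> None:
        if self.order < 2 or self.order % 2:
            raise SignalError(f"filter order must be even and >= 2, got {self.order}")
        if not 0 < self.cutoff_hz < rate_hz / 2:
            raise SignalError(
                f"cutoff {self.cutoff_hz} Hz not below Nyquist of {rate_hz} Hz stream"
            )
        if self.passes != 2:
            raise SignalError("only forward-backward (passes=2) filtering is supported")


KINEMATIC_FILTER = FilterSpec(order=4, cutoff_hz=12.0)
FORCE_FILTER = FilterSpec(order=4, cutoff_hz=50.0)


@dataclass(frozen=True)
class TrialRecording:
    """Synchronized marker and force-plate streams plus trial metadata.

    ``markers`` maps a marker name to an (n_marker_frames, 3) array in metres;
    ``forces`` is (n_force_frames, 3) in newtons, ``cop`` is (n_force_frames, 2)
    in metres (x anterior, y mediolateral; NaN rows where undefined).
    """

    marker_time: np.ndarray
    markers: Mapping[str, np.ndarray]
    force_time: np.ndarray
    forces: np.ndarray
    cop: np.ndarray
    body_mass: float
    shoe_mass: float
    side: str = "right"
    t0_offset: float = 0.0

    @property
    def marker_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.marker_time)))

    @property
    def force_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.force_time)))

    @property
    def vgrf(self) -> np.ndarray:
        return self.forces[:, 2]

    @property
    def ap_grf(self) -> np.ndarray:
        return self.forces[:, 0]

    def validate(self) -> None:
        for name, t in (("marker", self.marker_time), ("force", self.force_time)):
            _check_uniform(t, f"{name} stream")
        ratio = self.force_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-3 or round(ratio) < 1:
            raise SignalError(
                "force rate must be an integer multiple of the marker rate "
                f"(got {self.force_rate:.1f} / {self.marker_rate:.1f})"
            )
        if self.body_mass <= 0:
            raise SignalError("invalid mass: body_mass must be > 0")
        if self.shoe_mass < 0:
            raise SignalError("invalid mass: shoe_mass must be >= 0")


def _check_uniform(t: np.ndarray, what: str) -> float:
    if t.ndim != 1 or t.size < 2:
        raise SignalError(f"insufficient samples in {what}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SignalError(f"irregular sampling: non-monotone time base in {what}")
    dt0 = float(np.median(dt))
    if np.max(np.abs(dt - dt0)) > _DT_RTOL * dt0:
        raise SignalError(f"irregular sampling: jittered time stamps in {what}")
    return dt0


def _fill_gaps(values: np.ndarray, what: str) -> np.ndarray:
    """Linearly interpolate NaN runs of <= MAX_GAP_SAMPLES; longer runs error."""
    out = values.astype(float).copy()
    for col in range(out.shape[1]):
        x = out[:, col]
        isnan = np.isnan(x)
        if not isnan.any():
            continue
        if isnan.all() or isnan[0] or isnan[-1]:
            raise SignalError(f"gap too long: unbounded NaN run in {what}")
        # locate NaN runs
        edges = np.flatnonzero(np.diff(isnan.astype(int)))
        starts = edges[::2] + 1
        ends = edges[1::2] + 1
        for s, e in zip(starts, ends):
            if e - s > MAX_GAP_SAMPLES:
                raise SignalError(
                    f"gap too long: {e - s} consecutive missing samples in {what}"
                )
        idx = np.arange(x.size)
        x[isnan] = np.interp(idx[isnan], idx[~isnan], x[~isnan])
        out[:, col] = x
    return out


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    """Return (comment header lines, column names, data array)."""
    header_comments: list[str] = []
    columns: list[str] | None = None
    rows: list[list[float]] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            continue
        if raw.lstrip().startswith("#"):
            if columns is None:
                header_comments.append(raw.strip())
            continue
        toks = raw.split("\t")
        if columns is None:
            columns = [t.strip() for t in toks]
            continue
        rows.append([float(t) if t.strip().lower() != "nan" else np.nan for t in toks])
    if columns is None or not rows:
        raise SignalError(f"empty or headerless table: {path}")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != len(columns):
        raise SignalError(f"ragged table: {path}")
    return header_comments, columns, data


def _units_from_header(comments: list[str], path: Path) -> str:
    for line in comments:
        body = line.lstrip("# ").strip().lower()
        if body.startswith("units:"):
            return body.split(":", 1)[1].strip()
    raise SignalError(f"unknown units: no '# units:' header in {path}")


def load_trial(
    marker_path: str | Path, force_path: str | Path, meta_path: str | Path
) -> TrialRecording:
    """Load, unit-normalize and synchronize one trial."""
    marker_path, force_path, meta_path = map(Path, (marker_path, force_path, meta_path))
    for p in (marker_path, force_path, meta_path):
        if not p.exists():
            raise SignalError(f"file not found: {p}")

    comments, cols, data = _read_table(marker_path)
    units = _units_from_header(comments, marker_path)
    if units not in ("mm", "m"):
        raise SignalError(f"unknown units: marker units {units!r} (expected mm or m)")
    scale = 1e-3 if units == "mm" else 1.0
    if cols[0] != "time_s":
        raise SignalError(f"marker file must start with a time_s column: {marker_path}")
    marker_time = data[:, 0]
    _check_uniform(marker_time, "marker stream")
    markers: dict[str, np.ndarray] = {}
    if (len(cols) - 1) % 3:
        raise SignalError(f"marker columns not in x/y/z triplets: {marker_path}")
    for i in range(1, len(cols), 3):
        base = cols[i]
        if not base.endswith("_x"):
            raise SignalError(f"expected marker column '<name>_x', got {base!r}")
        name = base[:-2]
        block = data[:, i : i + 3] * scale
        markers[name] = _fill_gaps(block, f"marker {name!r}")

    comments_f, cols_f, data_f = _read_table(force_path)
    _units_from_header(comments_f, force_path)  # presence check
    expected = ["time_s", "fx_N", "fy_N", "fz_N", "cop_x_m", "cop_y_m"]
    if cols_f != expected:
        raise SignalError(f"force file columns must be {expected}: {force_path}")
    force_time = data_f[:, 0]
    _check_uniform(force_time, "force stream")
    forces = _fill_gaps(data_f[:, 1:4], "force channels")
    cop = data_f[:, 4:6]

    meta: dict[str, str] = {}
    for raw in meta_path.read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        key, _, value = raw.partition("\t")
        meta[key.strip()] = value.strip()
    for key in ("body_mass_kg", "shoe_mass_kg"):
        if key not in meta:
            raise SignalError(f"metadata missing {key!r}: {meta_path}")

    rec = TrialRecording(
        marker_time=marker_time,
        markers=markers,
        force_time=force_time,
        forces=forces,
        cop=cop,
        body_mass=float(meta["body_mass_kg"]),
        shoe_mass=float(meta["shoe_mass_kg"]),
        side=meta.get("side", "right"),
    )
    rec.validate()
    return rec


def _fmt(x: float) -> str:
    return "nan" if np.isnan(x) else repr(float(x))


def write_trial(
    recording: TrialRecording,
    marker_path: str | Path,
    force_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write a recording in the same dialect :func:`load_trial` reads.

    Marker coordinates are emitted in millimetres (the capture-system
    convention); floats are written with shortest round-trip precision so
    ``load_trial(write_trial(r)) == r``.
    """
    lines = ["# units: mm"]
    names = list(recording.markers)
    header = ["time_s"]
    for n in names:
        header += [f"{n}_x", f"{n}_y", f"{n}_z"]
    lines.append("\t".join(header))
    for i, t in enumerate(recording.marker_time):
        row = [_fmt(t)]
        for n in names:
            row += [_fmt(v * 1e3) for v in recording.markers[n][i]]
        lines.append("\t".join(row))
    Path(marker_path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["# units: N m", "time_s\tfx_N\tfy_N\tfz_N\tcop_x_m\tcop_y_m"]
    for i, t in enumerate(recording.force_time):
        row = [_fmt(t)] + [_fmt(v) for v in recording.forces[i]]
        row += [_fmt(v) for v in recording.cop[i]]
        lines.append("\t".join(row))
    Path(force_path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    meta_lines = [
        f"body_mass_kg\t{_fmt(recording.body_mass)}",
        f"shoe_mass_kg\t{_fmt(recording.shoe_mass)}",
        f"side\t{recording.side}",
    ]
    Path(meta_path).write_text("\n".join(meta_lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# filtering and normalization


def lowpass(
    series: np.ndarray,
    spec: FilterSpec,
    rate_hz: float,
    padtype: str = "even",
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Note the cascaded pass squares the single-pass magnitude response, so the
    gain at the nominal cutoff is 0.5, not 1/sqrt(2).  Reflective (even)
    padding of 3x the filter order suppresses endpoint transients; ramp-like
    series (e.g. CoP trajectories) may use slope-preserving ``"odd"`` padding.
    """
    spec.validate(rate_hz)
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    padlen = 3 * spec.order
    if n <= padlen:
        raise SignalError(
            f"insufficient samples: need > {padlen}, got {n}"
        )
    sos = _signal.butter(spec.order, spec.cutoff_hz, fs=rate_hz, output="sos")
    return _signal.sosfiltfilt(sos, series, axis=0, padtype=padtype, padlen=padlen)


def filter_recording(
    recording: TrialRecording,
    kinematic: FilterSpec = KINEMATIC_FILTER,
    force: FilterSpec = FORCE_FILTER,
) -> TrialRecording:
    """Return a copy with markers, force channels and the loaded CoP segment
    low-pass filtered.

    The CoP is only defined while the plate is loaded, and its loaded segment
    is ramp-like, so it is detrended (linear fit) before the zero-phase pass
    and retrended after — plain reflective padding of a ramp would inject
    endpoint transients larger than the noise being removed.
    """
    markers = {
        name: lowpass(xyz, kinematic, recording.marker_rate)
        for name, xyz in recording.markers.items()
    }
    forces = lowpass(recording.forces, force, recording.force_rate)
    cop = recording.cop.copy()
    idx = np.flatnonzero(recording.forces[:, 2] > 10.0)
    if idx.size > 6 * force.order + 1 and np.all(np.diff(idx) == 1):
        seg = cop[idx]
        if np.all(np.isfinite(seg)):
            x = np.arange(idx.size, dtype=float)
            coeffs = np.polynomial.polynomial.polyfit(x, seg, 1)
            trend = np.polynomial.polynomial.polyval(x, coeffs).T
            cop[idx] = trend + lowpass(
                seg - trend, force, recording.force_rate
            )
    return replace(recording, markers=markers, forces=forces, cop=cop)


def normalize_grf(forces: np.ndarray, body_mass: float) -> np.ndarray:
    """Divide force components by body mass (N/kg); reporting convenience."""
    if body_mass <= 0:
        raise SignalError(f"invalid mass: {body_mass}")
    return np.asarray(forces, dtype=float) / body_mass


def normalize_cycle(
    time: np.ndarray,
    series: np.ndarray,
    cycle_start: float,
    cycle_end: float,
) -> np.ndarray:
    """Resample onto 101 points spanning 0..100% of the cycle.

    Linear interpolation on each column; endpoints equal the interpolated
    boundary values.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    if cycle_end <= cycle_start:
        raise SignalError("out of range: cycle_end must exceed cycle_start")
    if cycle_start < time[0] - 1e-12 or cycle_end > time[-1] + 1e-12:
        raise SignalError("out of range: cycle interval not covered by series")
    grid = np.linspace(cycle_start, cycle_end, 101)
    if series.ndim == 1:
        return np.interp(grid, time, series)
    return np.column_stack(
        [np.interp(grid, time, series[:, j]) for j in range(series.shape[1])]
    )
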