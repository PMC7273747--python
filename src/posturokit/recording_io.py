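"""Plain-text recording format for pressure-sensor plate sessions.

A recording is a time-ordered stack of sensor-grid frames sampled from a
rectangular force-sensor plate (by default a 45 x 45 grid of sensors covering
a 25 x 25 cm arena floor, sampled at 30 Hz for 300 s).  Commercial
acquisition systems store such data in proprietary containers; this module
defines an open, two-file dialect instead:

* ``<name>.csv`` (optionally ``.csv.gz``): long-format table with header
  ``frame_index,t,row,col,weight_g`` holding only the non-zero cells.
  Omitted cells are zero.
* ``<name>.json`` sidecar: plate geometry, sampling rate, frame timestamps
  and session metadata.

Weights are grams, lengths centimetres, times seconds throughout.  The
centre of sensor ``(row, col)`` is at
``(origin_x + col * pitch_x, origin_y + row * pitch_y)`` in plate
coordinates (origin at a plate corner); every downstream module uses this
convention.
"""

from __future__ import annotations

import gzip
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlateGeometry",
    "SensorFrame",
    "Recording",
    "RecordingFormatError",
    "RecordingValidationError",
    "default_geometry",
    "load_recording",
    "save_recording",
    "validate_recording",
]

#: tolerance on inter-frame spacing, seconds
_DT_TOL = 1e-6


class RecordingFormatError(Exception):
    """Raised when a file does not conform to the recording dialect."""


class RecordingValidationError(Exception):
    """Raised when a recording violates its invariants on load."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class PlateGeometry:
    """Sensor-grid geometry of the plate.

    ``origin`` is the position (cm) of the centre of sensor (0, 0), i.e. by
    default half a pitch in from the plate corner so that the grid of cell
    centres tiles the plate.
    """

    n_rows: int = 45
    n_cols: int = 45
    pitch_x: float = 25.0 / 45.0
    pitch_y: float = 25.0 / 45.0
    origin: tuple[float, float] = (25.0 / 90.0, 25.0 / 90.0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float]:
        """Plate extent (width, height) in cm."""
        return (self.n_cols * self.pitch_x, self.n_rows * self.pitch_y)

    @property
    def center(self) -> tuple[float, float]:
        return (self.extent[0] / 2.0, self.extent[1] / 2.0)

    def sensor_center(self, row: int, col: int) -> tuple[float, float]:
        """Centre of sensor ``(row, col)`` in cm."""
        return (
            self.origin[0] + col * self.pitch_x,
            self.origin[1] + row * self.pitch_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(xs[n_cols], ys[n_rows])`` of cell-centre coordinates."""
        xs = self.origin[0] + np.arange(self.n_cols) * self.pitch_x
        ys = self.origin[1] + np.arange(self.n_rows) * self.pitch_y
        return xs, ys

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_x": self.pitch_x,
            "pitch_y": self.pitch_y,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateGeometry":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            pitch_x=float(d["pitch_x"]),
            pitch_y=float(d["pitch_y"]),
            origin=(float(d["origin"][0]), float(d["origin"][1])),
        )


def default_geometry() -> PlateGeometry:
    """45 x 45 sensors (2025, matching the ~2,000-sensor plate) on 25 x 25 cm."""
    return PlateGeometry()


@dataclass(frozen=True)
class SensorFrame:
    """One sampled frame: time (s) and the per-sensor weight grid (g)."""

    t: float
    weights: np.ndarray  # shape (n_rows, n_cols), grams

    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass
class Recording:
    """A full plate session: geometry, frame stack and metadata.

    ``weights`` is stored as one dense array of shape
    ``(n_frames, n_rows, n_cols)``; ``frames`` iterates ``SensorFrame`` views.
    """

    geometry: PlateGeometry
    times: np.ndarray  # (n_frames,), seconds
    weights: np.ndarray  # (n_frames, n_rows, n_cols), grams
    rate_hz: float = 30.0
    animal_id: str = ""
    session_label: str = ""
    group: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz

    @property
    def frames(self) -> Iterator[SensorFrame]:
        for i in range(self.n_frames):
            yield SensorFrame(t=float(self.times[i]), weights=self.weights[i])

    def frame(self, i: int) -> SensorFrame:
        return SensorFrame(t=float(self.times[i]), weights=self.weights[i])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.geometry == other.geometry
            and self.rate_hz == other.rate_hz
            and self.animal_id == other.animal_id
            and self.session_label == other.session_label
            and self.group == other.group
            and self.times.shape == other.times.shape
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.weights, other.weights)
        )


def new_recording(
    geometry: PlateGeometry,
    n_frames: int,
    rate_hz: float = 30.0,
    t0: float = 0.0,
    **meta: str,
) -> Recording:
    """Allocate an all-zero recording with evenly spaced timestamps."""
    times = t0 + np.arange(n_frames, dtype=float) / rate_hz
    weights = np.zeros((n_frames, geometry.n_rows, geometry.n_cols))
    return Recording(geometry=geometry, times=times, weights=weights, rate_hz=rate_hz, **meta)


def validate_recording(rec: Recording) -> list[str]:
    """Check every recording invariant; return the list of violations.

    An empty list means the recording is valid.  This function reports and
    never raises.
    """
    report: list[str] = []
    g = rec.geometry
    if g.n_rows <= 0 or g.n_cols <= 0:
        report.append("geometry: n_rows and n_cols must be positive")
    if g.pitch_x <= 0 or g.pitch_y <= 0:
        report.append("geometry: sensor pitch must be positive")
    if rec.rate_hz <= 0:
        report.append("rate_hz must be positive")
    if rec.weights.ndim != 3 or rec.weights.shape[0] != rec.n_frames:
        report.append("weights array must have shape (n_frames, n_rows, n_cols)")
        return report
    if rec.weights.shape[1:] != (g.n_rows, g.n_cols):
        report.append(
            f"frame shape {rec.weights.shape[1:]} does not match geometry {(g.n_rows, g.n_cols)}"
        )
    if rec.n_frames:
        if not np.all(np.isfinite(rec.times)):
            report.append("timestamps must be finite")
        else:
            dt = np.diff(rec.times)
            if np.any(dt <= 0):
                report.append("timestamps strictly increasing")
            elif rec.rate_hz > 0 and np.any(np.abs(dt - 1.0 / rec.rate_hz) > _DT_TOL):
                report.append(f"frame spacing must be 1/rate_hz within {_DT_TOL} s")
    if not np.all(np.isfinite(rec.weights)):
        report.append("weights must be finite")
    elif rec.weights.size and float(rec.weights.min()) < 0:
        report.append("weights must be non-negative")
    return report


def _sidecar_path(path: Path) -> Path:
    name = path.name
    if name.endswith(".csv.gz"):
        return path.with_name(name[: -len(".csv.gz")] + ".json")
    if name.endswith(".csv"):
        return path.with_name(name[: -len(".csv")] + ".json")
    return path.with_name(name + ".json")


def save_recording(rec: Recording, path: str | os.PathLike) -> Path:
    """Write ``rec`` to ``path`` (long-format CSV, '.gz' suffix gzips) plus a
    JSON sidecar.  Zero cells are omitted; weights and timestamps are written
    in shortest-round-trip decimal so that a reload is bit-exact.  Both files
    are replaced atomically."""
    violations = validate_recording(rec)
    if violations:
        raise RecordingValidationError(violations)
    path = Path(path)
    sidecar = _sidecar_path(path)

    fi, ri, ci = np.nonzero(rec.weights)
    df = pd.DataFrame(
        {
            "frame_index": fi,
            # repr() is the shortest decimal that round-trips exactly
            "t": [repr(float(v)) for v in rec.times[fi]],
            "row": ri,
            "col": ci,
            "weight_g": [repr(float(v)) for v in rec.weights[fi, ri, ci]],
        }
    )
    meta = {
        "format": "posturokit-recording",
        "version": 1,
        "geometry": rec.geometry.to_dict(),
        "rate_hz": rec.rate_hz,
        "n_frames": rec.n_frames,
        "times": [float(t).hex() for t in rec.times],
        "animal_id": rec.animal_id,
        "session_label": rec.session_label,
        "group": rec.group,
    }

    csv_text = df.to_csv(index=False)  # str() of floats round-trips exactly
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            payload = csv_text.encode()
            fh.write(gzip.compress(payload) if path.name.endswith(".gz") else payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=sidecar.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(meta, fh)
        os.replace(tmp, sidecar)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def load_recording(path: str | os.PathLike) -> Recording:
    """Read a recording written by :func:`save_recording`.

    Raises :class:`RecordingFormatError` for a missing/invalid sidecar or a
    malformed table, :class:`RecordingValidationError` when the data violate
    recording invariants (negative weights, non-monotone timestamps, ...).
    """
    path = Path(path)
    if not path.exists():
        raise RecordingFormatError(f"no such file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RecordingFormatError(f"missing JSON sidecar: {sidecar}")
    with open(sidecar) as fh:
        try:
            meta = json.load(fh)
        except json.JSONDecodeError as e:
            raise RecordingFormatError(f"invalid sidecar JSON: {e}") from e
    if meta.get("format") != "posturokit-recording":
        raise RecordingFormatError("sidecar is not a posturokit recording descriptor")
    geometry = PlateGeometry.from_dict(meta["geometry"])
    n_frames = int(meta["n_frames"])
    raw_times = meta["times"]
    times = np.array(
        [float.fromhex(t) if isinstance(t, str) else float(t) for t in raw_times]
    )
    if len(times) != n_frames:
        raise RecordingFormatError("sidecar n_frames does not match times array")

    df = pd.read_csv(path, compression="infer", float_precision="round_trip")
    expected = ["frame_index", "t", "row", "col", "weight_g"]
    if list(df.columns) != expected:
        raise RecordingFormatError(f"CSV header must be {','.join(expected)}")
    weights = np.zeros((n_frames, geometry.n_rows, geometry.n_cols))
    if len(df):
        fi = df["frame_index"].to_numpy(dtype=int)
        ri = df["row"].to_numpy(dtype=int)
        ci = df["col"].to_numpy(dtype=int)
        if fi.min() < 0 or fi.max() >= n_frames:
            raise RecordingFormatError("frame_index out of range")
        if (
            ri.min() < 0
            or ri.max() >= geometry.n_rows
            or ci.min() < 0
            or ci.max() >= geometry.n_cols
        ):
            raise RecordingFormatError("sensor index out of range")
        weights[fi, ri, ci] = df["weight_g"].to_numpy(dtype=float)

    rec = Recording(
        geometry=geometry,
        times=times,
        weights=weights,
        rate_hz=float(meta["rate_hz"]),
        animal_id=str(meta.get("animal_id", "")),
        session_label=str(meta.get("session_label", "")),
        group=str(meta.get("group", "")),
    )
    violations = validate_recording(rec)
    if violations:
        raise RecordingValidationError(violations)
    return rec
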