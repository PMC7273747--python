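import numpy as np
import pytest

from posturokit.contact_detection import ZoneTrack
from posturokit.recording_io import PlateGeometry, Recording, default_geometry


@pytest.fixture
def geometry() -> PlateGeometry:
    return default_geometry()


def make_recording(frames: np.ndarray, geometry: PlateGeometry | None = None, rate_hz: float = 30.0, **meta) -> Recording:
    """Recording from a dense (n, rows, cols) weight stack."""
    geometry = geometry or default_geometry()
    frames = np.asarray(frames, dtype=float)
    times = np.arange(len(frames)) / rate_hz
    return Recording(geometry=geometry, times=times, weights=frames, rate_hz=rate_hz, **meta)


def make_track(zone_id: int, frame_idx, xy, w=None, label=None, rate_hz: float = 30.0) -> ZoneTrack:
    """Toy zone track from explicit frames and positions."""
    frame_idx = np.asarray(frame_idx, dtype=int)
    xy = np.asarray(xy, dtype=float)
    if w is None:
        w = np.full(len(frame_idx), 100.0)
    return ZoneTrack(
        zone_id=zone_id,
        label=label,
        frame_idx=frame_idx,
        t=frame_idx / rate_hz,
        x=xy[:, 0],
        y=xy[:, 1],
        w=np.asarray(w, dtype=float),
    )


def quadruped_tracks(n_frames: int, center=(12.5, 12.5), half_len=3.0, half_wid=1.8, w=100.0):
    """Four paw tracks frozen at rectangle corners for every frame."""
    cx, cy = center
    corners = {
        "FL": (cx - half_wid, cy + half_len),
        "FR": (cx + half_wid, cy + half_len),
        "RL": (cx - half_wid, cy - half_len),
        "RR": (cx + half_wid, cy - half_len),
    }
    fi = np.arange(n_frames)
    tracks = []
    for z, (lab, (x, y)) in enumerate(corners.items()):
        tracks.append(make_track(z, fi, np.column_stack([np.full(n_frames, x), np.full(n_frames, y)]), w=np.full(n_frames, w), label=lab))
    return tracks
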