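"""Static/dynamic segmentation by the 700 ms mobility rule.

The device convention: the animal is *static* at an instant when every body
area in contact with the sensors has been stationary for at least 700 ms,
otherwise it is *dynamic*.  Operationally, per zone track we flag each pair
of consecutive grounded samples whose centroid displacement is at most
``stationary_tol_cm`` (one sensor pitch by default — the natural noise
floor of the grid).  A maximal run of k flagged pairs spans k+1 frames
(the anchor frame the first displacement is measured from is part of the
stationary span); the zone is *settled* at those frames iff the span lasts
at least ``static_min_s``.  A frame is provisionally static iff at least
one zone is grounded and every grounded zone is settled; maximal
provisional runs of at least ``static_min_s`` become STATIC segments, and
everything else is DYNAMIC.  At 30 Hz, 700 ms = 21 frames: a bout of 21
identical positions (20 zero displacements + the anchor) is exactly long
enough.

Frames with no contact at all are DYNAMIC (there is no stationary contact
to speak of).  Episodes where the animal is static *and* on all four paws
are the substrate of the postural (barycenter) analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contact_detection import PAW_LABELS, ZoneTrack
from .recording_io import PlateGeometry

__all__ = [
    "MobilityConfig",
    "MobilitySegment",
    "StaticQuadrupedEpisode",
    "zone_stationarity",
    "zone_settled",
    "segment_mobility",
    "extract_static_quadruped",
    "segments_to_states",
]

STATIC = "STATIC"
DYNAMIC = "DYNAMIC"


@dataclass(frozen=True)
class MobilityConfig:
    """Parameters of the mobility rule.

    ``static_min_s``: minimum stationary span (the 700 ms threshold).
    ``stationary_tol_cm``: maximum per-sample centroid displacement counted
    as stationary; defaults to one sensor pitch of the default grid.
    """

    static_min_s: float = 0.7
    stationary_tol_cm: float = 25.0 / 45.0

    def __post_init__(self):
        if self.static_min_s <= 0:
            raise ValueError("static_min_s must be positive")
        if self.stationary_tol_cm <= 0:
            raise ValueError("stationary_tol_cm must be positive")

    @classmethod
    def for_geometry(cls, geometry: PlateGeometry, static_min_s: float = 0.7) -> "MobilityConfig":
        return cls(static_min_s=static_min_s, stationary_tol_cm=max(geometry.pitch_x, geometry.pitch_y))


@dataclass(frozen=True)
class MobilitySegment:
    t_start: float
    t_end: float
    state: str  # STATIC | DYNAMIC

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class StaticQuadrupedEpisode:
    """Maximal interval inside a STATIC segment with all four paws grounded.

    ``start_frame``/``stop_frame`` index recording frames (stop exclusive).
    """

    start_frame: int
    stop_frame: int
    t_start: float
    t_end: float

    @property
    def n_frames(self) -> int:
        return self.stop_frame - self.start_frame


def zone_stationarity(track: ZoneTrack, cfg: MobilityConfig) -> np.ndarray:
    """Per-sample flags: sample k is stationary iff its centroid moved at
    most ``stationary_tol_cm`` since the track's previous grounded sample.
    The track's first sample carries no displacement and is flagged True."""
    if track.n_samples == 0:
        return np.zeros(0, dtype=bool)
    flags = np.ones(track.n_samples, dtype=bool)
    if track.n_samples > 1:
        disp = np.hypot(np.diff(track.x), np.diff(track.y))
        flags[1:] = disp <= cfg.stationary_tol_cm
    return flags


def zone_settled(track: ZoneTrack, cfg: MobilityConfig, rate_hz: float) -> np.ndarray:
    """Per-sample flags: True where the sample lies in a stationary span of
    at least ``static_min_s``.

    A span is a maximal run of consecutive stationary displacements plus the
    anchor sample preceding the run; its duration is counted in frames
    between the first and last sample inclusive.
    """
    n = track.n_samples
    settled = np.zeros(n, dtype=bool)
    if n < 2:
        return settled
    min_frames = int(np.ceil(cfg.static_min_s * rate_hz - 1e-9))
    disp_ok = np.hypot(np.diff(track.x), np.diff(track.y)) <= cfg.stationary_tol_cm
    k = 0
    while k < n - 1:
        if not disp_ok[k]:
            k += 1
            continue
        j = k
        while j < n - 1 and disp_ok[j]:
            j += 1
        # run of pairs k..j-1 -> samples k..j; span in frames:
        span = track.frame_idx[j] - track.frame_idx[k] + 1
        if span >= min_frames:
            settled[k : j + 1] = True
        k = j
    return settled


def segment_mobility(
    tracks: Sequence[ZoneTrack],
    n_frames: int,
    rate_hz: float,
    cfg: MobilityConfig | None = None,
    t0: float = 0.0,
) -> tuple[list[MobilitySegment], np.ndarray]:
    """Partition the session into alternating STATIC/DYNAMIC segments.

    Returns ``(segments, static_mask)`` where ``static_mask`` is the
    per-frame boolean state.  Segments tile ``[t0, t0 + n_frames/rate]``
    without overlap, alternate state, and STATIC segments last at least
    ``static_min_s``.
    """
    cfg = cfg or MobilityConfig()
    if n_frames == 0:
        return [], np.zeros(0, dtype=bool)
    grounded = np.zeros(n_frames, dtype=int)
    unsettled = np.zeros(n_frames, dtype=int)
    for tr in tracks:
        grounded[tr.frame_idx] += 1
        s = zone_settled(tr, cfg, rate_hz)
        unsettled[tr.frame_idx[~s]] += 1
    provisional = (grounded > 0) & (unsettled == 0)

    min_frames = int(np.ceil(cfg.static_min_s * rate_hz - 1e-9))
    static_mask = np.zeros(n_frames, dtype=bool)
    for a, b in _runs(provisional):
        if b - a >= min_frames:
            static_mask[a:b] = True

    segments: list[MobilitySegment] = []
    i = 0
    while i < n_frames:
        j = i
        while j < n_frames and static_mask[j] == static_mask[i]:
            j += 1
        segments.append(
            MobilitySegment(
                t_start=t0 + i / rate_hz,
                t_end=t0 + j / rate_hz,
                state=STATIC if static_mask[i] else DYNAMIC,
            )
        )
        i = j
    return segments, static_mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as (start, stop) pairs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    stops = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [mask.size]))
    return list(zip(starts.tolist(), stops.tolist()))


def segments_to_states(segments: Sequence[MobilitySegment], n_frames: int, rate_hz: float, t0: float = 0.0) -> np.ndarray:
    """Per-frame boolean static mask reconstructed from segments."""
    mask = np.zeros(n_frames, dtype=bool)
    for seg in segments:
        a = int(round((seg.t_start - t0) * rate_hz))
        b = int(round((seg.t_end - t0) * rate_hz))
        if seg.state == STATIC:
            mask[a:b] = True
    return mask


def extract_static_quadruped(
    static_mask: np.ndarray,
    tracks: Sequence[ZoneTrack],
    rate_hz: float,
    t0: float = 0.0,
    min_frames: int = 2,
) -> list[StaticQuadrupedEpisode]:
    """Maximal STATIC sub-intervals during which FL, FR, RL and RR are all
    grounded.  Episodes shorter than ``min_frames`` (default 2 — barycenter
    speed needs two samples) are discarded."""
    n_frames = len(static_mask)
    paws = np.zeros((4, n_frames), dtype=bool)
    for tr in tracks:
        if tr.label in PAW_LABELS:
            paws[PAW_LABELS.index(tr.label), tr.frame_idx] = True
    ok = static_mask & paws.all(axis=0)
    episodes = []
    for a, b in _runs(ok):
        if b - a >= min_frames:
            episodes.append(
                StaticQuadrupedEpisode(
                    start_frame=a,
                    stop_frame=b,
                    t_start=t0 + a / rate_hz,
                    t_end=t0 + b / rate_hz,
                )
            )
    return episodes
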