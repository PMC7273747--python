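"""Behavioural biomarkers: lateral weight distribution, abdomen-support
time, and circling lap counts.

*Lateral weight distribution* is the share of the instantaneous paw-borne
weight carried by the left (FL+RL) versus right (FR+RR) paws, averaged over
frames of the requested mobility state and expressed in percent.

*Abdomen-support time* counts the time the animal leans on a body part
other than its paws, with coordinates between its four legs (inside the
convex hull of the four paw centroids), split by mobility state.

*Circling* quantifies the vestibular rotation phenotype: each front paw's
successive step positions are converted to polar angles about a reference
origin (the plate centre by default); the wrapped angle increment per step
is accumulated, and each +/-360 deg crossing counts one full lap to the
left/right.  To separate genuine fast circling from slow wall-following
(thigmotaxis), steps whose stance lasts longer than 500 ms are excluded and
break the accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contact_detection import PAW_LABELS, ZoneTrack, is_between_paws

__all__ = [
    "UndefinedResult",
    "LateralityResult",
    "AbdomenTimeResult",
    "CirclingConfig",
    "CirclingResult",
    "paw_frame_table",
    "lateral_weight_distribution",
    "abdomen_time",
    "stance_steps",
    "step_angle_series",
    "count_laps",
    "circling",
]


class UndefinedResult(ValueError):
    """Raised when a biomarker is undefined for the given data
    (e.g. no qualifying frames, zero total weight)."""


@dataclass(frozen=True)
class LateralityResult:
    left_pct: float
    right_pct: float
    n_frames: int


@dataclass(frozen=True)
class AbdomenTimeResult:
    static_s: float
    dynamic_s: float


@dataclass(frozen=True)
class CirclingConfig:
    """``max_support_s``: stance-duration filter (the 500 ms rule) — steps
    with longer supports are excluded and break the angle accumulation.
    ``origin``: reference point of the polar angles; ``None`` means the
    plate centre."""

    max_support_s: float = 0.5
    origin: tuple[float, float] | None = None

    def __post_init__(self):
        if self.max_support_s <= 0:
            raise ValueError("max_support_s must be positive")


@dataclass
class CirclingResult:
    left_laps: float
    right_laps: float
    theta: dict = field(default_factory=dict)  # paw label -> list of angle runs (deg)


def paw_frame_table(
    tracks: Sequence[ZoneTrack], n_frames: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame paw state from labelled tracks.

    Returns ``(pos, w)`` with ``pos`` of shape (n_frames, 4, 2) (NaN while
    airborne) and ``w`` of shape (n_frames, 4) (0 while airborne); paw order
    FL, FR, RL, RR.
    """
    pos = np.full((n_frames, 4, 2), np.nan)
    w = np.zeros((n_frames, 4))
    for tr in tracks:
        if tr.label not in PAW_LABELS:
            continue
        p = PAW_LABELS.index(tr.label)
        pos[tr.frame_idx, p, 0] = tr.x
        pos[tr.frame_idx, p, 1] = tr.y
        w[tr.frame_idx, p] = tr.w
    return pos, w


def lateral_weight_distribution(
    tracks: Sequence[ZoneTrack],
    static_mask: np.ndarray,
    state: str,
) -> LateralityResult:
    """Percent of paw-borne weight on the left vs right limbs, averaged over
    the frames of the requested mobility state ("STATIC" or "DYNAMIC").
    Ungrounded paws contribute 0 g.  Raises :class:`UndefinedResult` when no
    frame of that state bears paw weight."""
    n_frames = len(static_mask)
    _, w = paw_frame_table(tracks, n_frames)
    sel = static_mask if state == "STATIC" else ~static_mask
    total = w.sum(axis=1)
    use = sel & (total > 0)
    if not use.any():
        raise UndefinedResult(f"no {state} frame with grounded paws")
    left_share = (w[use, 0] + w[use, 2]) / total[use]  # FL + RL
    left = float(left_share.mean() * 100.0)
    return LateralityResult(left_pct=left, right_pct=100.0 - left, n_frames=int(use.sum()))


def abdomen_time(
    tracks: Sequence[ZoneTrack],
    static_mask: np.ndarray,
    rate_hz: float,
) -> AbdomenTimeResult:
    """Seconds with an OTHER zone grounded between the four paws, split by
    mobility state.  Frames where fewer than four paws are grounded are
    skipped (the hull is undefined there)."""
    n_frames = len(static_mask)
    pos, _ = paw_frame_table(tracks, n_frames)
    four = ~np.isnan(pos[:, :, 0]).any(axis=1)
    counted = np.zeros(n_frames, dtype=bool)
    for tr in tracks:
        if tr.label != "OTHER":
            continue
        for k in range(tr.n_samples):
            f = tr.frame_idx[k]
            if counted[f] or not four[f]:
                continue
            if is_between_paws((tr.x[k], tr.y[k]), [tuple(p) for p in pos[f]]):
                counted[f] = True
    static_s = float(np.sum(counted & static_mask)) / rate_hz
    dynamic_s = float(np.sum(counted & ~static_mask)) / rate_hz
    return AbdomenTimeResult(static_s=static_s, dynamic_s=dynamic_s)


def stance_steps(
    tracks: Sequence[ZoneTrack], label: str, rate_hz: float
) -> list[tuple[float, float, float, float]]:
    """Time-ordered stance bouts of one paw, pooled over all tracks with
    that label: tuples ``(t_start, duration_s, x, y)`` with the bout's mean
    centroid.  A stepping paw typically yields one short track per stance,
    so steps must be pooled across tracks."""
    steps = []
    for tr in tracks:
        if tr.label != label:
            continue
        for a, b in tr.bouts:
            dur = (tr.frame_idx[b - 1] - tr.frame_idx[a] + 1) / rate_hz
            steps.append(
                (float(tr.t[a]), float(dur), float(tr.x[a:b].mean()), float(tr.y[a:b].mean()))
            )
    steps.sort(key=lambda s: s[0])
    return steps


def step_angle_series(
    steps: Sequence[tuple[float, float, float, float]],
    cfg: CirclingConfig,
    origin: tuple[float, float],
) -> list[np.ndarray]:
    """Wrapped polar-angle increments (degrees) between successive steps.

    ``steps`` are stance bouts as produced by :func:`stance_steps`.  Steps
    with stance duration above ``cfg.max_support_s`` are excluded and break
    the series; each returned array is one unbroken run of increments.
    Increments are wrapped to (-180, 180]."""
    ox, oy = cfg.origin if cfg.origin is not None else origin
    runs: list[np.ndarray] = []
    cur: list[float] = []
    prev_angle: float | None = None
    for t, dur, x, y in steps:
        if dur > cfg.max_support_s:
            if cur:
                runs.append(np.array(cur))
                cur = []
            prev_angle = None
            continue
        ang = np.degrees(np.arctan2(y - oy, x - ox))
        if prev_angle is not None:
            d = ang - prev_angle
            d = (d + 180.0) % 360.0 - 180.0
            if d == -180.0:  # wrap convention: (-180, 180]
                d = 180.0
            cur.append(float(d))
        prev_angle = ang
    if cur:
        runs.append(np.array(cur))
    return runs


def count_laps(theta_runs: Sequence[np.ndarray]) -> tuple[int, int]:
    """Count full laps from angle-increment runs.

    Within each unbroken run the increments are accumulated; every +360 deg
    crossing counts one lap to the left (and 360 is carried over), every
    -360 deg crossing one lap to the right.  The accumulator resets at run
    breaks.  Returns ``(left_laps, right_laps)``.
    """
    tol = 1e-9  # exact crossings survive float rounding of the angle sums
    left = right = 0
    for run in theta_runs:
        acc = 0.0
        for d in run:
            acc += d
            while acc >= 360.0 - tol:
                left += 1
                acc -= 360.0
            while acc <= -360.0 + tol:
                right += 1
                acc += 360.0
    return left, right


def circling(
    tracks: Sequence[ZoneTrack],
    rate_hz: float,
    plate_center: tuple[float, float],
    cfg: CirclingConfig | None = None,
) -> CirclingResult:
    """Mean lap counts over the two front paws.

    A front paw with no qualifying steps contributes 0 laps.  Lap counts
    per direction are averaged across FL and FR, so results may be
    half-integral.
    """
    cfg = cfg or CirclingConfig()
    theta = {}
    lefts, rights = [], []
    for label in ("FL", "FR"):
        steps = stance_steps(tracks, label, rate_hz)
        runs = step_angle_series(steps, cfg, plate_center)
        theta[label] = runs
        l, r = count_laps(runs)
        lefts.append(l)
        rights.append(r)
    return CirclingResult(
        left_laps=float(np.mean(lefts)),
        right_laps=float(np.mean(rights)),
        theta=theta,
    )
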