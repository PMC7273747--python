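"""Detection, tracking and labelling of body-contact zones.

A part of the animal's body is detected in a frame when it activates a
connected group of sensors satisfying three rules (the acquisition
thresholds of the plate device): at least ``min_pixels`` active sensors, a
central (maximum-weight) sensor of at least 0.7 g, and at least one sensor
adjacent to it recording 0.3 g or more.  Detected blobs are linked over time
into zone tracks by nearest-centroid matching, and tracks are labelled as
one of the four paws (FL, FR, RL, RR) or as OTHER (tail, abdomen, head...),
either from an operator-supplied hint file or by a geometric heuristic based
on the animal's body axis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from shapely.geometry import MultiPoint, Point

from .recording_io import PlateGeometry, Recording, SensorFrame

__all__ = [
    "DetectionConfig",
    "ContactBlob",
    "ZoneTrack",
    "PAW_LABELS",
    "detect_blobs",
    "track_blobs",
    "assign_labels",
    "is_between_paws",
    "read_label_hints",
]

PAW_LABELS = ("FL", "FR", "RL", "RR")
OTHER = "OTHER"

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for blob detection and parameters for track linking.

    Defaults follow the plate device's acquisition settings: a contact
    activates >= 2 sensors, its central sensor carries >= 0.7 g and at least
    one adjacent sensor >= 0.3 g.
    """

    central_min_g: float = 0.7
    adjacent_min_g: float = 0.3
    min_pixels: int = 2
    connectivity: int = 8  # 4 or 8; also used for "adjacent"
    merge_radius_cm: float = 1.5  # frame-to-frame linking gate
    max_gap_frames: int = 3  # frames a track may vanish before closing

    def __post_init__(self):
        if not (self.central_min_g >= self.adjacent_min_g > 0):
            raise ValueError("need central_min_g >= adjacent_min_g > 0")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ContactBlob:
    """One detected contact area in one frame."""

    t: float
    pixels: frozenset  # of (row, col)
    weight_g: float
    centroid_cm: tuple[float, float]


@dataclass
class ZoneTrack:
    """Time series of one contact zone (a paw or another body part).

    ``frame_idx``/``t``/``x``/``y``/``w`` are parallel arrays with one entry
    per frame in which the zone is grounded.  ``bouts`` are the maximal runs
    of consecutive grounded frames, as (start, stop) indices into the sample
    arrays (stop exclusive).
    """

    zone_id: int
    label: str | None = None
    frame_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    w: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_samples(self) -> int:
        return len(self.frame_idx)

    @property
    def bouts(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive grounded frames, as sample-index
        (start, stop) pairs."""
        if self.n_samples == 0:
            return []
        breaks = np.nonzero(np.diff(self.frame_idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [self.n_samples]))
        return list(zip(starts.tolist(), stops.tolist()))

    def grounded_mask(self, n_frames: int) -> np.ndarray:
        m = np.zeros(n_frames, dtype=bool)
        m[self.frame_idx] = True
        return m


def detect_blobs(frame: SensorFrame, geometry: PlateGeometry, cfg: DetectionConfig | None = None) -> list[ContactBlob]:
    """Detect contact blobs in one frame.

    Blobs are the connected components of strictly positive sensors, kept
    when they satisfy the size/central/adjacent weight rules.  Pixel sets of
    returned blobs are disjoint and each blob's weight is the sum of its
    member sensors.
    """
    cfg = cfg or DetectionConfig()
    w = frame.weights
    struct = _STRUCT_8 if cfg.connectivity == 8 else _STRUCT_4
    labels, n = ndimage.label(w > 0, structure=struct)
    if n == 0:
        return []
    xs, ys = geometry.cell_centers()
    blobs: list[ContactBlob] = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        sub = w[sl]
        npix = int(mask.sum())
        if npix < cfg.min_pixels:
            continue
        vals = np.where(mask, sub, 0.0)
        r0, c0 = np.unravel_index(np.argmax(vals), vals.shape)
        if vals[r0, c0] < cfg.central_min_g:
            continue
        # neighbours of the central (max-weight) pixel, in full-frame coords
        rr = r0 + sl[0].start
        cc = c0 + sl[1].start
        if not _has_adjacent(w, rr, cc, cfg):
            continue
        rows, cols = np.nonzero(mask)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        weights = w[rows, cols]
        total = float(weights.sum())
        cx = float(np.dot(weights, xs[cols]) / total)
        cy = float(np.dot(weights, ys[rows]) / total)
        blobs.append(
            ContactBlob(
                t=frame.t,
                pixels=frozenset(zip(rows.tolist(), cols.tolist())),
                weight_g=total,
                centroid_cm=(cx, cy),
            )
        )
    return blobs


def _has_adjacent(w: np.ndarray, r: int, c: int, cfg: DetectionConfig) -> bool:
    if cfg.connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    n_rows, n_cols = w.shape
    for dr, dc in offs:
        rr, cc = r + dr, c + dc
        if 0 <= rr < n_rows and 0 <= cc < n_cols and w[rr, cc] >= cfg.adjacent_min_g:
            return True
    return False


def track_blobs(rec: Recording, cfg: DetectionConfig | None = None) -> list[ZoneTrack]:
    """Detect blobs in every frame and link them into zone tracks.

    Linking is a per-frame optimal assignment (Hungarian) between open
    tracks and new blobs, gated at ``merge_radius_cm``; a track that goes
    undetected for more than ``max_gap_frames`` consecutive frames is
    closed.  Each returned track is time-ordered with one sample per
    grounded frame.
    """
    cfg = cfg or DetectionConfig()

    class _Live:
        __slots__ = ("zone_id", "last_xy", "last_frame", "fi", "t", "x", "y", "w")

        def __init__(self, zone_id):
            self.zone_id = zone_id
            self.fi, self.t, self.x, self.y, self.w = [], [], [], [], []
            self.last_xy = (np.nan, np.nan)
            self.last_frame = -1

    done: list[_Live] = []
    live: list[_Live] = []
    next_id = 0
    for i in range(rec.n_frames):
        blobs = detect_blobs(rec.frame(i), rec.geometry, cfg)
        assigned_b: set[int] = set()
        if live and blobs:
            d = np.full((len(live), len(blobs)), np.inf)
            for a, tr in enumerate(live):
                for b, bl in enumerate(blobs):
                    d[a, b] = np.hypot(
                        tr.last_xy[0] - bl.centroid_cm[0], tr.last_xy[1] - bl.centroid_cm[1]
                    )
            cost = np.where(d <= cfg.merge_radius_cm, d, 1e9)
            ai, bi = linear_sum_assignment(cost)
            for a, b in zip(ai, bi):
                if d[a, b] <= cfg.merge_radius_cm:
                    _append(live[a], i, blobs[b])
                    assigned_b.add(b)
        for b, bl in enumerate(blobs):
            if b not in assigned_b:
                tr = _Live(next_id)
                next_id += 1
                _append(tr, i, bl)
                live.append(tr)
        still = []
        for tr in live:
            if i - tr.last_frame > cfg.max_gap_frames:
                done.append(tr)
            else:
                still.append(tr)
        live = still
    done.extend(live)
    done.sort(key=lambda tr: tr.fi[0])
    return [
        ZoneTrack(
            zone_id=k,
            frame_idx=np.array(tr.fi, dtype=int),
            t=np.array(tr.t),
            x=np.array(tr.x),
            y=np.array(tr.y),
            w=np.array(tr.w),
        )
        for k, tr in enumerate(done)
    ]


def _append(tr, i: int, bl: ContactBlob) -> None:
    tr.fi.append(i)
    tr.t.append(bl.t)
    tr.x.append(bl.centroid_cm[0])
    tr.y.append(bl.centroid_cm[1])
    tr.w.append(bl.weight_g)
    tr.last_xy = bl.centroid_cm
    tr.last_frame = i


def is_between_paws(
    other_centroid: tuple[float, float], paw_centroids: Sequence[tuple[float, float]]
) -> bool:
    """True iff the point lies inside (or on the boundary of) the convex
    hull of the four paw centroids."""
    if len(paw_centroids) != 4:
        raise ValueError("need exactly four paw centroids")
    hull = MultiPoint([tuple(p) for p in paw_centroids]).convex_hull
    return bool(hull.covers(Point(other_centroid)))


def read_label_hints(path: str | Path) -> dict[int, str]:
    """Read an operator hint file: CSV with header ``zone_id,label``."""
    hints: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["zone_id", "label"]:
            raise ValueError("hint file header must be 'zone_id,label'")
        for row in reader:
            hints[int(row["zone_id"])] = row["label"].strip()
    return hints


def assign_labels(
    tracks: Sequence[ZoneTrack],
    n_frames: int,
    rate_hz: float,
    hints: Mapping[int, str] | str | Path | None = None,
    window_s: float = 1.0,
) -> list[ZoneTrack]:
    """Label tracks as FL/FR/RL/RR/OTHER (in place; returns the list).

    With ``hints`` (mapping zone_id -> label, or a CSV path) the labels are
    applied verbatim; remaining tracks are labelled automatically.  The
    automatic heuristic votes frame by frame: the animal's body centre and
    principal (body) axis are estimated from all grounded centroids in a
    +/- ``window_s``/2 window, the axis is oriented along the direction of
    travel, and each grounded candidate track votes for the paw quadrant
    (front/rear x left/right) it occupies, weighted by its contact weight.
    Grounded zones lying inside the convex hull of the other grounded zones
    (e.g. the abdomen between the paws) are excluded from paw candidacy.
    Tracks never matching a paw slot become OTHER; when two time-overlapping
    tracks claim the same paw the stronger vote wins.
    """
    if hints is not None and not isinstance(hints, Mapping):
        hints = read_label_hints(hints)
    hinted: dict[int, str] = {}
    if hints:
        known = {tr.zone_id for tr in tracks}
        for zid, lab in hints.items():
            if zid not in known:
                raise ValueError(f"hint names unknown zone_id {zid}")
            if lab not in PAW_LABELS and lab != OTHER:
                raise ValueError(f"unknown label {lab!r} for zone {zid}")
            hinted[zid] = lab
        _check_hint_conflicts(tracks, hinted)

    # per-frame grounded samples
    per_frame: list[list[tuple[int, float, float, float]]] = [[] for _ in range(n_frames)]
    by_id = {tr.zone_id: tr for tr in tracks}
    for tr in tracks:
        for k in range(tr.n_samples):
            per_frame[tr.frame_idx[k]].append((tr.zone_id, tr.x[k], tr.y[k], tr.w[k]))

    # instantaneous body centre: unweighted mean of the grounded centroids
    # (for a diagonal stance couplet this is the body centre exactly, and
    # unlike a load-weighted mean it does not move with weight shifts);
    # forward-filled through contact-free frames
    cx = np.full(n_frames, np.nan)
    cy = np.full(n_frames, np.nan)
    for i, samples in enumerate(per_frame):
        if samples:
            cx[i] = sum(s[1] for s in samples) / len(samples)
            cy[i] = sum(s[2] for s in samples) / len(samples)
        elif i > 0:
            cx[i] = cx[i - 1]
            cy[i] = cy[i - 1]

    # heading: centred chord of the body-centre path, accepted only when
    # both half-chords are substantial (the body is translating) and
    # mutually aligned; otherwise the previous heading is kept.  This
    # keeps the heading pinned through stops, where a spurious small
    # chord at the stop transition could point anywhere.
    half = max(1, int(round(window_s * rate_hz / 5)))
    votes: dict[int, dict[str, float]] = {tr.zone_id: {} for tr in tracks}
    forward = np.array([np.nan, np.nan])
    for i in range(n_frames):
        samples = per_frame[i]
        if not samples or not np.isfinite(cx[i]):
            continue
        j0, j1 = max(0, i - half), min(n_frames - 1, i + half)
        vb = np.array([cx[i] - cx[j0], cy[i] - cy[j0]])
        vf = np.array([cx[j1] - cx[i], cy[j1] - cy[i]])
        if np.hypot(*vb) > 0.5 and np.hypot(*vf) > 0.5 and float(vb @ vf) > 0:
            v = vb + vf
            forward = v / np.hypot(*v)
        if not np.isfinite(forward[0]):
            continue
        cands = samples
        if len(samples) >= 5:
            cands = _drop_interior(samples)
        for zid, x, y, w in cands:
            d = np.array([x - cx[i], y - cy[i]])
            front = float(d @ forward) > 0
            left = (forward[0] * d[1] - forward[1] * d[0]) > 0
            lab = ("F" if front else "R") + ("L" if left else "R")
            votes[zid][lab] = votes[zid].get(lab, 0.0) + float(w)

    # provisional label = strongest vote; no votes -> OTHER
    order = sorted(
        (tr for tr in tracks if tr.zone_id not in hinted),
        key=lambda tr: -max(votes[tr.zone_id].values(), default=0.0),
    )
    claimed: dict[str, np.ndarray] = {lab: np.zeros(n_frames, dtype=bool) for lab in PAW_LABELS}
    for zid, lab in hinted.items():
        by_id[zid].label = lab
        if lab in PAW_LABELS:
            claimed[lab][by_id[zid].frame_idx] = True
    for tr in order:
        ranked = sorted(votes[tr.zone_id].items(), key=lambda kv: -kv[1])
        tr.label = OTHER
        for lab, _ in ranked:
            if not claimed[lab][tr.frame_idx].any():
                tr.label = lab
                claimed[lab][tr.frame_idx] = True
                break
    return list(tracks)


def _drop_interior(samples):
    """Remove grounded zones lying inside the hull of the other zones."""
    kept = []
    pts = [(x, y) for _, x, y, _ in samples]
    for k, s in enumerate(samples):
        others = [p for j, p in enumerate(pts) if j != k]
        if len(others) >= 3:
            hull = MultiPoint(others).convex_hull
            if hull.area > 0 and hull.contains(Point(pts[k])):
                continue
        kept.append(s)
    return kept if kept else samples


def _check_hint_conflicts(tracks: Sequence[ZoneTrack], hinted: Mapping[int, str]) -> None:
    by_id = {tr.zone_id: tr for tr in tracks}
    by_label: dict[str, list[int]] = {}
    for zid, lab in hinted.items():
        if lab in PAW_LABELS:
            by_label.setdefault(lab, []).append(zid)
    for lab, ids in by_label.items():
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                fa = set(by_id[ids[a]].frame_idx.tolist())
                fb = set(by_id[ids[b]].frame_idx.tolist())
                if fa & fb:
                    raise ValueError(
                        f"hints map overlapping tracks {ids[a]} and {ids[b]} to the same paw {lab}"
                    )
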