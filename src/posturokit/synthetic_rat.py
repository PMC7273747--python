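"""Seedable synthetic plate sessions with known ground truth.

The simulator emulates a freely moving rat on the sensor plate so that
every pipeline stage can be validated without real recordings:

* quadruped stepping in diagonal couplets (FL+RR alternating with FR+RL)
  along a slow, wall-distant loop — ordinary locomotion, whose ~600 ms
  stances fall above the 500 ms support filter and therefore accrue no
  laps (a built-in thigmotaxis-like control);
* stationary (frozen) bouts with all four paws planted, configurable
  left/right weight asymmetry and a gentle sinusoidal redistribution of
  the paw loads that makes the barycenter sway realistically without
  moving the contacts;
* circling episodes: fast steps (250 ms stances by default) around the
  plate centre accumulating exactly +/-360 deg of arena-origin polar angle
  per lap, bracketed by 1 s holds so the step series is cleanly isolated;
* abdomen contact intervals rendered as a broad low-pressure blob centred
  between the paw girdles (inside the paw hull by construction);
* truncated-Gaussian pressure footprints integrating exactly to each
  contact's load, plus clipped additive sensor noise.

Ground truth carries both the *scheduled* quantities (bout spans, lap
counts, target weight fractions — exact by construction) and the *derived*
quantities obtained by applying the rule definitions to the noise-free
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .behavior_biomarkers import (
    CirclingConfig,
    abdomen_time,
    circling,
    lateral_weight_distribution,
)
from .contact_detection import PAW_LABELS, ZoneTrack
from .mobility_segmentation import MobilityConfig, segment_mobility
from .recording_io import PlateGeometry, Recording, default_geometry

__all__ = [
    "CirclingEpisodeSpec",
    "SyntheticConfig",
    "GroundTruth",
    "simulate_session",
    "render_frames",
    "preset_config",
    "PRESETS",
]

#: body-frame paw offsets (cm): x forward, y left; order FL, FR, RL, RR
_PAW_OFFSETS = np.array([[3.0, 1.8], [3.0, -1.8], [-3.0, 1.8], [-3.0, -1.8]])
_STEPS_PER_LAP = 8
_HOLD_S = 1.0  # stillness bracketing each circling episode
_WALK_LOOP_RADIUS = 6.0  # cm
_ORBIT_RADIUS = 3.0  # cm, circling
_FRONT_SHARE = 0.55  # nominal fraction of paw weight on the front girdle


@dataclass(frozen=True)
class CirclingEpisodeSpec:
    start_s: float
    n_laps: int
    direction: str  # "left" (counter-clockwise) or "right"
    stance_s: float = 0.25

    def __post_init__(self):
        if self.direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        if self.n_laps < 1:
            raise ValueError("n_laps must be >= 1")
        if self.stance_s <= 0:
            raise ValueError("stance_s must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of one synthetic session.

    Weight fractions are the target shares of paw-borne weight on the left
    limbs, per mobility state.  All randomness (stance jitter, load noise,
    sensor noise) is fixed by ``seed``.
    """

    duration_s: float = 300.0
    rate_hz: float = 30.0
    body_weight_g: float = 400.0
    left_fraction_static: float = 0.5
    left_fraction_dynamic: float = 0.5
    stationary_bouts: tuple = ()  # of (start_s, duration_s)
    circling: tuple = ()  # of CirclingEpisodeSpec
    abdomen_intervals: tuple = ()  # of (start_s, duration_s)
    stance_s: float = 0.6
    swing_s: float = 0.1
    step_length_cm: float = 5.0
    stance_noise_cm: float = 0.05
    sensor_noise_g: float = 0.05
    footprint_sigma_cm: float = 0.4
    abdomen_sigma_cm: float = 0.8
    abdomen_weight_g: float = 40.0
    load_sway_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.left_fraction_static <= 1.0 and 0.0 <= self.left_fraction_dynamic <= 1.0):
            raise ValueError("weight fractions must lie in [0, 1]")
        if self.stance_s <= 0 or self.swing_s <= 0:
            raise ValueError("gait timings must be positive")


@dataclass
class GroundTruth:
    """Per-frame truth and session-level truth biomarkers."""

    paw_pos: np.ndarray  # (n, 4, 2), NaN while airborne; order FL, FR, RL, RR
    paw_load: np.ndarray  # (n, 4), grams
    abdomen_pos: np.ndarray  # (n, 2), NaN when absent
    abdomen_load: np.ndarray  # (n,)
    static_mask: np.ndarray  # (n,) bool, rule applied to true trajectories
    scheduled_static: list  # of (start_frame, stop_frame)
    scheduled_left_laps: int
    scheduled_right_laps: int
    left_laps: float
    right_laps: float
    abdomen_static_s: float
    abdomen_dynamic_s: float
    laterality_static: tuple | None  # (left_pct, right_pct)
    laterality_dynamic: tuple | None
    barycenter: np.ndarray  # (n, 2), NaN outside 4-paw frames
    support_surface: np.ndarray  # (n,), NaN outside 4-paw frames
    max_support_surface: float

    def truth_tracks(self) -> list[ZoneTrack]:
        """Exact zone tracks (one per paw plus the abdomen) rebuilt from the
        per-frame truth."""
        return _truth_tracks(self.paw_pos, self.paw_load, self.abdomen_pos, self.abdomen_load)


def _rot(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def _jitter(seed: int, *key: int, scale: float) -> np.ndarray:
    rng = np.random.default_rng([abs(int(seed)), *[int(k) for k in key]])
    return rng.normal(0.0, scale, size=2)


class _CircleEpisode:
    """Precomputed landing schedule of one circling episode."""

    def __init__(self, spec: CirclingEpisodeSpec, cfg: SyntheticConfig, center, idx: int):
        self.spec = spec
        self.idx = idx
        self.t0 = spec.start_s
        self.period = spec.stance_s + cfg.swing_s
        self.lap_time = _STEPS_PER_LAP * self.period
        self.sign = 1.0 if spec.direction == "left" else -1.0
        # couplet phases (fractions of a period): FL+RR then FR+RL
        self.phase = np.array([0.0, 0.5, 0.5, 0.0])
        # two extra steps of margin beyond the exact lap count
        self.j_max = _STEPS_PER_LAP * spec.n_laps + 2
        self.end = self.t0 + (self.j_max + 0.5) * self.period + spec.stance_s
        self.center = np.asarray(center)
        self.alpha0 = 0.0  # set at simulation time for heading continuity

    def alpha_at(self, t: float) -> float:
        return self.alpha0 + self.sign * 2 * np.pi * (t - self.t0) / self.lap_time

    def body_pose(self, t: float) -> tuple[np.ndarray, float]:
        alpha = self.alpha_at(t)
        c = self.center + _ORBIT_RADIUS * np.array([np.cos(alpha), np.sin(alpha)])
        return c, alpha + self.sign * np.pi / 2

    def paw_position(self, paw: int, j: int, cfg: SyntheticConfig) -> np.ndarray:
        t_mid = self.t0 + (j + self.phase[paw]) * self.period + self.spec.stance_s / 2
        c, heading = self.body_pose(t_mid)
        pos = c + _rot(heading) @ _PAW_OFFSETS[paw]
        return pos + _jitter(cfg.seed, 2, self.idx, paw, j, scale=cfg.stance_noise_cm)

    def stance_of(self, paw: int, t: float) -> int | None:
        s = t - self.t0 - self.phase[paw] * self.period
        j = int(np.floor(s / self.period))
        if j < 0 or j > self.j_max:
            return None
        if s - j * self.period < self.spec.stance_s:
            return j
        return None


def _validate_schedule(cfg: SyntheticConfig, episodes: Sequence[_CircleEpisode]) -> list[tuple[float, float, str]]:
    """Merge the static and circling schedules, checking feasibility.
    Returns the static intervals (start, end, kind) including circling
    holds."""
    intervals: list[tuple[float, float, str]] = []
    for s, d in cfg.stationary_bouts:
        intervals.append((float(s), float(s + d), "frozen"))
    occupied = list(intervals)
    for ep in episodes:
        intervals.append((ep.t0 - _HOLD_S, ep.t0, f"hold_pre:{ep.idx}"))
        intervals.append((ep.end, ep.end + _HOLD_S, f"hold_post:{ep.idx}"))
        occupied.append((ep.t0 - _HOLD_S, ep.end + _HOLD_S, "circle"))
    for a0, a1, _ in occupied:
        if a0 < 0 or a1 > cfg.duration_s:
            raise ValueError("scheduled episode outside the session")
    occ = sorted(occupied)
    for (a0, a1, _), (b0, b1, _) in zip(occ, occ[1:]):
        if b0 < a1:
            raise ValueError("overlapping stationary/circling schedule")
    for s, d in cfg.abdomen_intervals:
        if s < 0 or s + d > cfg.duration_s:
            raise ValueError("abdomen interval outside the session")
    return sorted(intervals)


def simulate_session(
    cfg: SyntheticConfig, geometry: PlateGeometry | None = None, **meta: str
) -> tuple[Recording, GroundTruth]:
    """Simulate one session and render it to a Recording.

    Deterministic given ``cfg.seed``.  Raises ``ValueError`` for infeasible
    schedules.
    """
    geometry = geometry or default_geometry()
    center = np.array(geometry.center)
    rate = cfg.rate_hz
    n = int(round(cfg.duration_s * rate))
    t = np.arange(n) / rate

    episodes = [
        _CircleEpisode(spec, cfg, center, i) for i, spec in enumerate(cfg.circling)
    ]
    static_iv = _validate_schedule(cfg, episodes)

    # --- per-frame mode -------------------------------------------------
    WALK, FROZEN, CIRCLE = 0, 1, 2
    mode = np.full(n, WALK, dtype=int)
    frozen_id = np.full(n, -1, dtype=int)
    circle_id = np.full(n, -1, dtype=int)
    for b, (a0, a1, _) in enumerate(static_iv):
        sel = (t >= a0) & (t < a1)
        mode[sel] = FROZEN
        frozen_id[sel] = b
    for e, ep in enumerate(episodes):
        sel = (t >= ep.t0) & (t < ep.end)
        mode[sel] = CIRCLE
        circle_id[sel] = e

    # walk clock: walking time elapsed at each frame
    wc = np.concatenate(([0.0], np.cumsum(mode == WALK)[:-1])) / rate

    # --- nominal body pose on the walking loop --------------------------
    speed = cfg.step_length_cm / (cfg.stance_s + cfg.swing_s)
    omega = speed / _WALK_LOOP_RADIUS

    def walk_pose(tau: float) -> tuple[np.ndarray, float]:
        beta = -np.pi / 2 + omega * tau
        c = center + _WALK_LOOP_RADIUS * np.array([np.cos(beta), np.sin(beta)])
        return c, beta + np.pi / 2

    # orbit entry angle chosen so the heading is continuous with walking
    for e, ep in enumerate(episodes):
        idx = np.nonzero(circle_id == e)[0]
        if len(idx):
            _, h_walk = walk_pose(wc[idx[0]])
            ep.alpha0 = h_walk - ep.sign * np.pi / 2

    cycle = cfg.stance_s + cfg.swing_s
    walk_phase = np.array([0.0, 0.5, 0.5, 0.0])  # couplets FL+RR / FR+RL

    walk_anchor: dict[tuple[int, int], np.ndarray] = {}
    frozen_anchor: dict[tuple[int, int], np.ndarray] = {}
    circle_anchor: dict[tuple[int, int, int], np.ndarray] = {}

    def walk_anchor_pos(paw: int, k: int) -> np.ndarray:
        key = (paw, k)
        if key not in walk_anchor:
            tau_mid = (k + walk_phase[paw]) * cycle + cfg.stance_s / 2
            c, phi = walk_pose(tau_mid)
            walk_anchor[key] = (
                c + _rot(phi) @ _PAW_OFFSETS[paw]
                + _jitter(cfg.seed, 1, paw, k, scale=cfg.stance_noise_cm)
            )
        return walk_anchor[key]

    # --- per-frame trajectories ----------------------------------------
    paw_pos = np.full((n, 4, 2), np.nan)
    abd_pos = np.full((n, 2), np.nan)
    abd_on = np.zeros(n, dtype=bool)
    for s, d in cfg.abdomen_intervals:
        abd_on[(t >= s) & (t < s + d)] = True

    for i in range(n):
        if mode[i] == WALK:
            tau = wc[i]
            for p in range(4):
                s = tau - walk_phase[p] * cycle
                k = int(np.floor(s / cycle))
                if k >= 0 and s - k * cycle < cfg.stance_s:
                    paw_pos[i, p] = walk_anchor_pos(p, k)
            body_c, _ = walk_pose(tau)
        elif mode[i] == FROZEN:
            b = frozen_id[i]
            if (b, 0) not in frozen_anchor:
                kind = static_iv[b][2]
                if kind.startswith("hold_post:"):
                    ep = episodes[int(kind.split(":")[1])]
                    c, phi = ep.body_pose(ep.end)
                elif kind.startswith("hold_pre:"):
                    ep = episodes[int(kind.split(":")[1])]
                    c, phi = ep.body_pose(ep.t0)
                else:
                    c, phi = walk_pose(wc[i])
                for p in range(4):
                    frozen_anchor[(b, p)] = (
                        c + _rot(phi) @ _PAW_OFFSETS[p]
                        + _jitter(cfg.seed, 3, b, p, scale=cfg.stance_noise_cm)
                    )
                frozen_anchor[(b, -1)] = c
            for p in range(4):
                paw_pos[i, p] = frozen_anchor[(b, p)]
            body_c = frozen_anchor[(b, -1)]
        else:  # CIRCLE
            ep = episodes[circle_id[i]]
            for p in range(4):
                j = ep.stance_of(p, t[i])
                if j is not None:
                    key = (ep.idx, p, j)
                    if key not in circle_anchor:
                        circle_anchor[key] = ep.paw_position(p, j, cfg)
                    paw_pos[i, p] = circle_anchor[key]
            body_c, _ = ep.body_pose(t[i])
        if abd_on[i]:
            abd_pos[i] = body_c

    # --- loads ----------------------------------------------------------
    rng = np.random.default_rng([abs(int(cfg.seed)), 7])
    n_bouts = max(1, len(static_iv))
    sway_phase = rng.uniform(0, 2 * np.pi, size=(n_bouts, 2))
    load_noise = rng.normal(0.0, 0.5, size=(n, 4))

    paw_load = np.zeros((n, 4))
    abd_load = np.zeros(n)
    for i in range(n):
        total = cfg.body_weight_g
        if abd_on[i] and np.isfinite(abd_pos[i, 0]):
            abd_load[i] = cfg.abdomen_weight_g
            total -= cfg.abdomen_weight_g
        if mode[i] == FROZEN:
            b = frozen_id[i]
            f = cfg.left_fraction_static + cfg.load_sway_fraction * np.sin(
                2 * np.pi * 0.8 * t[i] + sway_phase[b % n_bouts, 0]
            )
            g = _FRONT_SHARE + 1.25 * cfg.load_sway_fraction * np.sin(
                2 * np.pi * 0.6 * t[i] + sway_phase[b % n_bouts, 1]
            )
        else:
            f = cfg.left_fraction_dynamic
            g = _FRONT_SHARE
        f = float(np.clip(f, 0.02, 0.98))
        grounded = np.isfinite(paw_pos[i, :, 0])
        if not grounded.any():
            continue
        left = [p for p in (0, 2) if grounded[p]]  # FL, RL
        right = [p for p in (1, 3) if grounded[p]]
        if not left or not right:
            share = total / grounded.sum()
            paw_load[i, grounded] = share
        else:
            for side, frac in ((left, f), (right, 1.0 - f)):
                if len(side) == 2:
                    paw_load[i, side[0]] = frac * total * g
                    paw_load[i, side[1]] = frac * total * (1.0 - g)
                else:
                    paw_load[i, side[0]] = frac * total
        if mode[i] == FROZEN:
            w = paw_load[i, grounded] + load_noise[i, grounded]
            paw_load[i, grounded] = np.clip(w, 1.0, None)

    # --- render ---------------------------------------------------------
    contacts: list[list[tuple[float, float, float, float]]] = []
    for i in range(n):
        row = []
        for p in range(4):
            if np.isfinite(paw_pos[i, p, 0]) and paw_load[i, p] > 0:
                row.append((paw_pos[i, p, 0], paw_pos[i, p, 1], paw_load[i, p], cfg.footprint_sigma_cm))
        if abd_load[i] > 0:
            row.append((abd_pos[i, 0], abd_pos[i, 1], abd_load[i], cfg.abdomen_sigma_cm))
        contacts.append(row)
    weights = render_frames(contacts, geometry, cfg.sensor_noise_g, np.random.default_rng([abs(int(cfg.seed)), 11]))
    rec = Recording(
        geometry=geometry,
        times=t.copy(),
        weights=weights,
        rate_hz=rate,
        **meta,
    )

    # --- ground truth ---------------------------------------------------
    tracks = _truth_tracks(paw_pos, paw_load, abd_pos, abd_load)
    mob_cfg = MobilityConfig.for_geometry(geometry)
    _, static_mask = segment_mobility(tracks, n, rate, mob_cfg)
    circ = circling(tracks, rate, geometry.center)
    abd = abdomen_time(tracks, static_mask, rate)

    def _lat(state):
        try:
            r = lateral_weight_distribution(tracks, static_mask, state)
            return (r.left_pct, r.right_pct)
        except Exception:
            return None

    four = np.isfinite(paw_pos[:, :, 0]).all(axis=1)
    bary = np.full((n, 2), np.nan)
    supp = np.full(n, np.nan)
    tot = paw_load.sum(axis=1)
    sel = four & (tot > 0)
    bary[sel] = (paw_pos[sel] * paw_load[sel][:, :, None]).sum(axis=1) / tot[sel, None]
    for i in np.nonzero(four)[0]:
        supp[i] = _hull_area(paw_pos[i])
    static_four = four & static_mask
    max_supp = float(np.nanmax(supp[static_four])) if static_four.any() else float("nan")

    sched = [
        (int(np.ceil(a0 * rate - 1e-9)), int(np.ceil(a1 * rate - 1e-9)))
        for a0, a1, _ in static_iv
    ]
    left_sched = sum(ep.spec.n_laps for ep in episodes if ep.sign > 0)
    right_sched = sum(ep.spec.n_laps for ep in episodes if ep.sign < 0)
    gt = GroundTruth(
        paw_pos=paw_pos,
        paw_load=paw_load,
        abdomen_pos=abd_pos,
        abdomen_load=abd_load,
        static_mask=static_mask,
        scheduled_static=sched,
        scheduled_left_laps=left_sched,
        scheduled_right_laps=right_sched,
        left_laps=circ.left_laps,
        right_laps=circ.right_laps,
        abdomen_static_s=abd.static_s,
        abdomen_dynamic_s=abd.dynamic_s,
        laterality_static=_lat("STATIC"),
        laterality_dynamic=_lat("DYNAMIC"),
        barycenter=bary,
        support_surface=supp,
        max_support_surface=max_supp,
    )
    return rec, gt


def _hull_area(pts: np.ndarray) -> float:
    from shapely.geometry import MultiPoint

    return float(MultiPoint([tuple(p) for p in pts]).convex_hull.area)


def _truth_tracks(paw_pos, paw_load, abd_pos, abd_load) -> list[ZoneTrack]:
    n = len(paw_pos)
    t = np.arange(n, dtype=float)
    tracks = []
    for p, lab in enumerate(PAW_LABELS):
        fi = np.nonzero(np.isfinite(paw_pos[:, p, 0]))[0]
        tracks.append(
            ZoneTrack(
                zone_id=p,
                label=lab,
                frame_idx=fi,
                t=t[fi],
                x=paw_pos[fi, p, 0],
                y=paw_pos[fi, p, 1],
                w=paw_load[fi, p],
            )
        )
    fi = np.nonzero(abd_load > 0)[0]
    if len(fi):
        tracks.append(
            ZoneTrack(
                zone_id=4,
                label="OTHER",
                frame_idx=fi,
                t=t[fi],
                x=abd_pos[fi, 0],
                y=abd_pos[fi, 1],
                w=abd_load[fi],
            )
        )
    return tracks


def render_frames(
    contacts: Sequence[Sequence[tuple[float, float, float, float]]],
    geometry: PlateGeometry,
    sensor_noise_g: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render per-frame contact lists to a sensor-weight stack.

    Each contact is ``(x_cm, y_cm, load_g, sigma_cm)`` and is rendered as a
    truncated (2 sigma) Gaussian footprint over the sensor grid, normalised
    to integrate exactly to the load.  The stamp window is at least 3 x 3
    sensors, so even sub-pixel footprints activate >= 2 sensors.  Additive
    Gaussian noise (std ``sensor_noise_g``) is applied to active sensors
    and clipped at 0.  Raises ``ValueError`` for contacts outside the
    plate.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    xs, ys = geometry.cell_centers()
    ex, ey = geometry.extent
    out = np.zeros((len(contacts), geometry.n_rows, geometry.n_cols))
    for i, row in enumerate(contacts):
        w = out[i]
        for x, y, load, sigma in row:
            if not (0.0 <= x <= ex and 0.0 <= y <= ey):
                raise ValueError(f"contact ({x:.2f}, {y:.2f}) outside the plate")
            rpx = max(
                1,
                int(np.ceil(2.0 * sigma / geometry.pitch_x)),
                int(np.ceil(2.0 * sigma / geometry.pitch_y)),
            )
            c0 = int(round((x - geometry.origin[0]) / geometry.pitch_x))
            r0 = int(round((y - geometry.origin[1]) / geometry.pitch_y))
            ca, cb = max(0, c0 - rpx), min(geometry.n_cols, c0 + rpx + 1)
            ra, rb = max(0, r0 - rpx), min(geometry.n_rows, r0 + rpx + 1)
            dx = xs[ca:cb] - x
            dy = ys[ra:rb] - y
            d2 = dy[:, None] ** 2 + dx[None, :] ** 2
            ker = np.exp(-d2 / (2.0 * sigma**2))
            mask = d2 <= (2.0 * sigma) ** 2
            if mask.sum() < 2:
                mask = np.ones_like(mask)
            ker = np.where(mask, ker, 0.0)
            ker *= load / ker.sum()
            w[ra:rb, ca:cb] += ker
        active = w > 0
        if sensor_noise_g > 0 and active.any():
            w[active] = np.clip(
                w[active] + rng.normal(0.0, sensor_noise_g, size=int(active.sum())), 0.0, None
            )
    return out


def preset_config(name: str, seed: int = 0, duration_s: float = 300.0) -> SyntheticConfig:
    """Named phenotype presets.

    ``sham``: symmetric weight bearing, frozen bouts, no circling, no
    abdomen support.  ``uvn_d1``: acute unilateral (left) vestibular-lesion
    phenotype — static weight shifted to the right (35/65), symmetric
    dynamic distribution, 3 fast left laps, 10 s of abdomen support.
    ``uvn_d30``: compensated phenotype — mild ipsilesional overshoot and
    larger postural sway.  ``thigmotaxis``: the uvn_d1 circular path walked
    with 800 ms stances (must count zero laps).
    """
    scale = duration_s / 300.0
    if scale <= 0:
        raise ValueError("duration must be positive")

    def _t(x):
        return x * scale

    bouts = ((_t(40.0), _t(40.0)), (_t(140.0), _t(40.0)), (_t(240.0), _t(40.0)))
    if name == "sham":
        return SyntheticConfig(
            duration_s=duration_s, stationary_bouts=bouts, seed=seed
        )
    if name == "uvn_d1":
        circ_start = bouts[0][0] + bouts[0][1] + _HOLD_S + 0.2  # just after bout 1
        return SyntheticConfig(
            duration_s=duration_s,
            left_fraction_static=0.35,
            left_fraction_dynamic=0.50,
            stationary_bouts=bouts,
            circling=(CirclingEpisodeSpec(start_s=circ_start, n_laps=3, direction="left"),),
            abdomen_intervals=((bouts[0][0] + 2.0, 5.0), (bouts[2][0] + 2.0, 5.0)),
            seed=seed,
        )
    if name == "uvn_d30":
        return SyntheticConfig(
            duration_s=duration_s,
            left_fraction_static=0.55,
            left_fraction_dynamic=0.52,
            stationary_bouts=bouts,
            load_sway_fraction=0.08,
            seed=seed,
        )
    if name == "thigmotaxis":
        tbouts = ((_t(40.0), _t(40.0)), (_t(240.0), _t(40.0)))
        circ_start = tbouts[0][0] + tbouts[0][1] + _HOLD_S + 0.2
        return SyntheticConfig(
            duration_s=duration_s,
            stationary_bouts=tbouts,
            circling=(
                CirclingEpisodeSpec(start_s=circ_start, n_laps=3, direction="left", stance_s=0.8),
            ),
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("sham", "uvn_d1", "uvn_d30", "thigmotaxis")
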