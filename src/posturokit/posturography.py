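"""Static postural biomarkers: support surface, barycenter
statokinesiograms, 90% confidence-ellipse body sway, barycenter speed and
SFA.

The *barycenter* of the bearing forces is the weight-weighted mean of the
four paw positions,

    bar_x = (FLx*FLw + FRx*FRw + RLx*RLw + RRx*RRw) / (FLw+FRw+RLw+RRw)

(and likewise for y); it is the rodent analogue of the centre of pressure
and is evaluated at every frame of a static-quadruped episode.  The 2-D
trace of successive barycenter positions is the statokinesiogram.

*Body sway* is the area of the confidence ellipse that includes 90% of the
barycenter positions.  Following the classical trimmed reading, the 10%
most extreme points (by Mahalanobis distance from the cloud) are first
eliminated — suppressing sway values due to quasi-voluntary movements —
then the ellipse is the 0.90 chi-square (2 df) level set of the refitted
mean/covariance.  The refitted covariance is rescaled by the standard
90%-truncation consistency factor for a bivariate normal, so that on
Gaussian data the trimmed estimate converges to the untrimmed 90% ellipse
(area pi * 4.6052 * sigma^2 for an isotropic cloud) and the ellipse covers
90% of the underlying distribution.  Setting ``trim=0`` gives the pure,
untrimmed 90% ellipse.

*Barycenter speed* is the path length of the trace divided by its
duration, and *SFA* (speed as a function of the sway area) is the ratio of
the session-level speed to the session-level sway area — a proxy for the
energy spent stabilising posture.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import chi2
from shapely.geometry import MultiPoint

from .behavior_biomarkers import UndefinedResult, paw_frame_table
from .contact_detection import PAW_LABELS, ZoneTrack
from .mobility_segmentation import StaticQuadrupedEpisode

__all__ = [
    "BarycenterTrace",
    "SwayResult",
    "PosturoSessionResult",
    "barycenter",
    "support_surface",
    "max_support_surface",
    "compute_traces",
    "sway_ellipse",
    "barycenter_speed",
    "session_posturography",
    "export_statokinesiogram",
]

#: 0.90 quantile of the chi-square distribution with 2 df
CHI2_90_2DF = float(chi2.ppf(0.90, df=2))


def barycenter(
    positions: np.ndarray | Sequence[Sequence[float]],
    weights: np.ndarray | Sequence[float],
) -> tuple[float, float]:
    """Weight-weighted mean of the four paw positions (exact arithmetic,
    no smoothing).  Raises :class:`UndefinedResult` on zero total weight."""
    p = np.asarray(positions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != (4, 2) or w.shape != (4,):
        raise ValueError("need four (x, y) positions and four weights")
    total = w.sum()
    if total <= 0:
        raise UndefinedResult("zero total paw weight")
    bx, by = (p * w[:, None]).sum(axis=0) / total
    return float(bx), float(by)


def support_surface(positions: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Area (cm^2) of the convex hull of the four paw positions.
    Collinear points give 0."""
    p = np.asarray(positions, dtype=float)
    if p.shape != (4, 2):
        raise ValueError("need four (x, y) positions")
    return float(MultiPoint([tuple(q) for q in p]).convex_hull.area)


def max_support_surface(
    tracks: Sequence[ZoneTrack],
    episodes: Sequence[StaticQuadrupedEpisode],
    n_frames: int,
) -> float:
    """Maximum per-frame support surface over all static-quadruped frames —
    the session's instability peak."""
    pos, _ = paw_frame_table(tracks, n_frames)
    best = None
    for ep in episodes:
        for f in range(ep.start_frame, ep.stop_frame):
            a = support_surface(pos[f])
            if best is None or a > best:
                best = a
    if best is None:
        raise UndefinedResult("no static-quadruped frame")
    return best


@dataclass
class BarycenterTrace:
    """(t, x, y) series of the barycenter within one static-quadruped
    episode — the statokinesiogram substrate."""

    episode: StaticQuadrupedEpisode
    t: np.ndarray
    xy: np.ndarray  # (n, 2)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples > 1 else 0.0


def compute_traces(
    tracks: Sequence[ZoneTrack],
    episodes: Sequence[StaticQuadrupedEpisode],
    n_frames: int,
    rate_hz: float,
    t0: float = 0.0,
) -> list[BarycenterTrace]:
    """Barycenter trace of every episode (one sample per episode frame)."""
    pos, w = paw_frame_table(tracks, n_frames)
    traces = []
    for ep in episodes:
        sl = slice(ep.start_frame, ep.stop_frame)
        total = w[sl].sum(axis=1)
        xy = (pos[sl] * w[sl][:, :, None]).sum(axis=1) / total[:, None]
        t = t0 + np.arange(ep.start_frame, ep.stop_frame) / rate_hz
        traces.append(BarycenterTrace(episode=ep, t=t, xy=xy))
    return traces


@dataclass(frozen=True)
class SwayResult:
    ellipse_area_cm2: float
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation_deg: float
    retained_fraction: float


def _trim_consistency(keep: float) -> float:
    """E[per-axis variance] of a bivariate normal truncated to its central
    ``keep`` Mahalanobis mass, relative to the full variance:
    F_chi2(4)(q) / keep with q = chi2(2)^-1(keep)."""
    q = chi2.ppf(keep, df=2)
    return float(chi2.cdf(q, df=4) / keep)


def sway_ellipse(trace: BarycenterTrace | np.ndarray, trim: float = 0.10) -> SwayResult:
    """90% confidence ellipse of a barycenter cloud.

    With ``trim`` > 0 the most extreme ``trim`` fraction of points (by
    Mahalanobis distance) is eliminated before refitting, and the refitted
    covariance is divided by the truncation consistency factor (see module
    docstring).  Requires at least 10 samples.  Degenerate (collinear)
    clouds return area 0 with a warning.
    """
    pts = trace.xy if isinstance(trace, BarycenterTrace) else np.asarray(trace, dtype=float)
    n = len(pts)
    if n < 10:
        raise UndefinedResult("need at least 10 barycenter samples")
    if not 0 <= trim < 1:
        raise ValueError("trim must be in [0, 1)")
    keep = 1.0 - trim
    retained = pts
    if trim > 0:
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T)
        d = pts - mu
        try:
            inv = np.linalg.inv(cov)
            m2 = np.einsum("ij,jk,ik->i", d, inv, d)
        except np.linalg.LinAlgError:
            m2 = (d**2).sum(axis=1)
        m_keep = max(3, int(np.floor(keep * n)))
        retained = pts[np.argsort(m2)[:m_keep]]
    mu = retained.mean(axis=0)
    cov = np.cov(retained.T)
    if trim > 0:
        cov = cov / _trim_consistency(keep)
    det = float(np.linalg.det(cov))
    if not np.isfinite(det) or det <= 0:
        warnings.warn("degenerate barycenter cloud; sway area set to 0", stacklevel=2)
        return SwayResult(0.0, (float(mu[0]), float(mu[1])), (0.0, 0.0), 0.0, len(retained) / n)
    evals, evecs = np.linalg.eigh(cov)
    semi = np.sqrt(CHI2_90_2DF * evals[::-1])  # major first
    angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
    area = float(np.pi * CHI2_90_2DF * np.sqrt(det))
    return SwayResult(
        ellipse_area_cm2=area,
        center=(float(mu[0]), float(mu[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        orientation_deg=angle,
        retained_fraction=len(retained) / n,
    )


def barycenter_speed(trace: BarycenterTrace) -> float:
    """Mean barycenter speed (cm/s): path length over trace duration."""
    if trace.n_samples < 2:
        raise UndefinedResult("need at least 2 barycenter samples")
    dur = trace.duration_s
    if dur <= 0:
        raise UndefinedResult("zero trace duration")
    path = float(np.hypot(*np.diff(trace.xy, axis=0).T).sum())
    return path / dur


@dataclass
class PosturoSessionResult:
    """Session-level postural summary.

    ``sway_area_cm2`` and ``mean_speed_cm_s`` are duration-weighted means
    over episodes; ``sfa`` is their ratio (1/(cm*s)) computed from the
    session aggregates.  ``per_episode`` rows: dicts with t_start, t_end,
    duration_s, n_samples, sway_area_cm2, speed_cm_s.
    """

    max_support_surface_cm2: float
    sway_area_cm2: float | None
    mean_speed_cm_s: float | None
    sfa: float | None
    per_episode: list[dict] = field(default_factory=list)


def session_posturography(
    tracks: Sequence[ZoneTrack],
    episodes: Sequence[StaticQuadrupedEpisode],
    n_frames: int,
    rate_hz: float,
    trim: float = 0.10,
    t0: float = 0.0,
) -> PosturoSessionResult:
    """Aggregate postural biomarkers over all static-quadruped episodes.

    Episodes too short for a given quantity (fewer than 10 samples for the
    sway ellipse, fewer than 2 for speed) are excluded from that quantity's
    duration-weighted mean.
    """
    if not episodes:
        raise UndefinedResult("no static-quadruped episode")
    traces = compute_traces(tracks, episodes, n_frames, rate_hz, t0=t0)
    rows = []
    for tr in traces:
        row: dict = {
            "t_start": tr.episode.t_start,
            "t_end": tr.episode.t_end,
            "duration_s": tr.episode.n_frames / rate_hz,
            "n_samples": tr.n_samples,
            "sway_area_cm2": None,
            "speed_cm_s": None,
        }
        if tr.n_samples >= 10:
            row["sway_area_cm2"] = sway_ellipse(tr, trim=trim).ellipse_area_cm2
        if tr.n_samples >= 2:
            row["speed_cm_s"] = barycenter_speed(tr)
        rows.append(row)

    def wmean(key):
        vals = [(r[key], r["duration_s"]) for r in rows if r[key] is not None]
        if not vals:
            return None
        v, d = zip(*vals)
        return float(np.average(v, weights=d))

    sway = wmean("sway_area_cm2")
    speed = wmean("speed_cm_s")
    sfa = None
    if speed is not None and sway is not None:
        if sway > 0:
            sfa = speed / sway
    return PosturoSessionResult(
        max_support_surface_cm2=max_support_surface(tracks, episodes, n_frames),
        sway_area_cm2=sway,
        mean_speed_cm_s=speed,
        sfa=sfa,
        per_episode=rows,
    )


def export_statokinesiogram(
    tracks: Sequence[ZoneTrack],
    episodes: Sequence[StaticQuadrupedEpisode],
    n_frames: int,
    rate_hz: float,
    csv_path: str | Path,
    fig_path: str | Path | None = None,
    t0: float = 0.0,
) -> Path:
    """Write the statokinesiogram: a CSV of ``t,zone,x,y`` rows (the four
    paw positions and the barycenter at every episode frame) and,
    optionally, a figure with the per-paw point clouds, mean paw positions
    (black crosses), the barycenter cloud and its mean (red dot).
    """
    if not episodes:
        raise UndefinedResult("no static-quadruped episode to plot")
    traces = compute_traces(tracks, episodes, n_frames, rate_hz, t0=t0)
    pos, _ = paw_frame_table(tracks, n_frames)
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    clouds: dict[str, list] = {lab: [] for lab in PAW_LABELS}
    bary = []
    with open(csv_path, "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["t", "zone", "x", "y"])
        for trc in traces:
            for k, f in enumerate(range(trc.episode.start_frame, trc.episode.stop_frame)):
                t = trc.t[k]
                for p, lab in enumerate(PAW_LABELS):
                    wtr.writerow([t, lab, pos[f, p, 0], pos[f, p, 1]])
                    clouds[lab].append(pos[f, p])
                wtr.writerow([t, "barycenter", trc.xy[k, 0], trc.xy[k, 1]])
                bary.append(trc.xy[k])
    if fig_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        colors = {"FL": "violet", "FR": "lightblue", "RL": "red", "RR": "darkblue"}
        for lab in PAW_LABELS:
            cl = np.array(clouds[lab])
            ax.scatter(cl[:, 0], cl[:, 1], s=4, color=colors[lab], label=lab, alpha=0.5)
            ax.plot(*cl.mean(axis=0), "k+", markersize=14, markeredgewidth=2)
        b = np.array(bary)
        ax.scatter(b[:, 0], b[:, 1], s=4, color="green", alpha=0.5, label="barycenter")
        ax.plot(*b.mean(axis=0), "o", color="red", markersize=8)
        ax.set_xlabel("x (cm)")
        ax.set_ylabel("y (cm)")
        ax.set_aspect("equal")
        ax.legend(loc="upper right", fontsize=8)
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
    return csv_path
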