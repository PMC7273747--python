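"""End-to-end session analysis: recording -> SessionReport.

Chains blob detection, zone tracking, paw labelling, mobility
segmentation and all biomarkers into a single per-session summary that
can be serialised to JSON and compared against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .behavior_biomarkers import (
    CirclingConfig,
    UndefinedResult,
    abdomen_time,
    circling,
    lateral_weight_distribution,
)
from .contact_detection import DetectionConfig, assign_labels, track_blobs
from .mobility_segmentation import (
    MobilityConfig,
    extract_static_quadruped,
    segment_mobility,
)
from .posturography import session_posturography
from .recording_io import Recording

__all__ = ["SessionReport", "analyze_recording"]


@dataclass
class SessionReport:
    """All per-session biomarkers.

    Laterality percentages refer to the paw-borne weight; ``None`` marks
    biomarkers undefined for the session (e.g. no static episode).
    """

    animal_id: str
    session_label: str
    group: str
    duration_s: float
    static_s: float
    dynamic_s: float
    static_left_pct: float | None
    static_right_pct: float | None
    dynamic_left_pct: float | None
    dynamic_right_pct: float | None
    abdomen_static_s: float
    abdomen_dynamic_s: float
    left_laps: float
    right_laps: float
    max_support_surface_cm2: float | None
    sway_area_cm2: float | None
    mean_speed_cm_s: float | None
    sfa: float | None
    n_static_quadruped_episodes: int
    per_episode: list = field(default_factory=list)
    ground_truth: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path


def analyze_recording(
    rec: Recording,
    detection: DetectionConfig | None = None,
    mobility: MobilityConfig | None = None,
    circling_cfg: CirclingConfig | None = None,
    hints: Mapping[int, str] | str | None = None,
    sway_trim: float = 0.10,
) -> SessionReport:
    """Run the full analysis pipeline on one recording."""
    detection = detection or DetectionConfig()
    mobility = mobility or MobilityConfig.for_geometry(rec.geometry)
    tracks = track_blobs(rec, detection)
    assign_labels(tracks, rec.n_frames, rec.rate_hz, hints=hints)
    segments, static_mask = segment_mobility(tracks, rec.n_frames, rec.rate_hz, mobility)
    episodes = extract_static_quadruped(static_mask, tracks, rec.rate_hz)

    def _lat(state):
        try:
            r = lateral_weight_distribution(tracks, static_mask, state)
            return r.left_pct, r.right_pct
        except UndefinedResult:
            return None, None

    sl, sr = _lat("STATIC")
    dl, dr = _lat("DYNAMIC")
    abd = abdomen_time(tracks, static_mask, rec.rate_hz)
    circ = circling(tracks, rec.rate_hz, rec.geometry.center, circling_cfg)

    max_supp = sway = speed = sfa = None
    per_episode: list = []
    if episodes:
        post = session_posturography(
            tracks, episodes, rec.n_frames, rec.rate_hz, trim=sway_trim
        )
        max_supp = post.max_support_surface_cm2
        sway = post.sway_area_cm2
        speed = post.mean_speed_cm_s
        sfa = post.sfa
        per_episode = post.per_episode

    return SessionReport(
        animal_id=rec.animal_id,
        session_label=rec.session_label,
        group=rec.group,
        duration_s=rec.duration_s,
        static_s=float(static_mask.sum()) / rec.rate_hz,
        dynamic_s=float((~static_mask).sum()) / rec.rate_hz,
        static_left_pct=sl,
        static_right_pct=sr,
        dynamic_left_pct=dl,
        dynamic_right_pct=dr,
        abdomen_static_s=abd.static_s,
        abdomen_dynamic_s=abd.dynamic_s,
        left_laps=circ.left_laps,
        right_laps=circ.right_laps,
        max_support_surface_cm2=max_supp,
        sway_area_cm2=sway,
        mean_speed_cm_s=speed,
        sfa=sfa,
        n_static_quadruped_episodes=len(episodes),
        per_episode=per_episode,
    )
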