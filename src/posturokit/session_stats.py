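"""Qualitative symptom scoring, baseline normalisation and
quantitative-vs-qualitative correlation.

The qualitative vestibular scale is cumulative: each observed symptom adds
its severity weight (tumbling 5, retropulsion 4, circling 3, bobbing 2,
head-tilt 1), for a total of 0-15.  Quantitative biomarkers are normalised
per animal by the value obtained in the pre-operative session, removing
inter-individual differences in weight or foot placement.  Pearson
correlations between the two families of measures use the two-sided
t-test with n-2 degrees of freedom.

Group-level inferential statistics (repeated-measures ANOVA, post-hoc
tests) are deliberately not reimplemented here; the tidy per-animal tables
this module produces feed any standard statistics package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_biomarkers import UndefinedResult

__all__ = [
    "SYMPTOM_WEIGHTS",
    "QualitativeScore",
    "NormalizedSeries",
    "qualitative_score",
    "read_qualitative_scores",
    "normalize_to_baseline",
    "correlate",
    "correlation_table",
]

SYMPTOM_WEIGHTS = {
    "tumbling": 5,
    "retropulsion": 4,
    "circling": 3,
    "bobbing": 2,
    "head_tilt": 1,
}


@dataclass(frozen=True)
class QualitativeScore:
    tumbling: bool = False
    retropulsion: bool = False
    circling: bool = False
    bobbing: bool = False
    head_tilt: bool = False

    @property
    def score(self) -> int:
        return qualitative_score(self)


def qualitative_score(flags: QualitativeScore | Mapping[str, bool]) -> int:
    """Cumulative symptom score (0-15)."""
    if isinstance(flags, QualitativeScore):
        flags = {k: getattr(flags, k) for k in SYMPTOM_WEIGHTS}
    return sum(w for k, w in SYMPTOM_WEIGHTS.items() if flags.get(k, False))


def read_qualitative_scores(path: str | Path) -> pd.DataFrame:
    """Read observer scores: CSV ``animal_id,session,tumbling,...,head_tilt``
    with 0/1 flags.  Adds a ``score`` column."""
    df = pd.read_csv(path)
    required = ["animal_id", "session", *SYMPTOM_WEIGHTS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"qualitative score file missing columns: {missing}")
    df["score"] = sum(df[k].astype(int) * w for k, w in SYMPTOM_WEIGHTS.items())
    return df


@dataclass
class NormalizedSeries:
    """Per-session biomarker values of one animal divided by its
    pre-operative value.  When the pre-operative value is 0 the ratio is
    undefined; the absolute values are kept instead and flagged."""

    animal_id: str
    biomarker: str
    values: dict = field(default_factory=dict)  # session -> ratio (or absolute)
    absolute_fallback: bool = False


def normalize_to_baseline(
    values: Mapping[str, float],
    preop_key: str = "preop",
    animal_id: str = "",
    biomarker: str = "",
) -> NormalizedSeries:
    """Normalise per-session values by the pre-operative session's value."""
    if preop_key not in values:
        raise KeyError(f"missing pre-operative session {preop_key!r}")
    baseline = values[preop_key]
    if baseline == 0:
        return NormalizedSeries(
            animal_id=animal_id,
            biomarker=biomarker,
            values=dict(values),
            absolute_fallback=True,
        )
    return NormalizedSeries(
        animal_id=animal_id,
        biomarker=biomarker,
        values={k: v / baseline for k, v in values.items()},
        absolute_fallback=False,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p (t-distribution, n-2 df) between two
    paired series.  Requires >= 3 finite pairs and non-zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise UndefinedResult("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UndefinedResult("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResult("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(
    quantitative: pd.DataFrame,
    qualitative: pd.DataFrame,
    biomarkers: Sequence[str] | None = None,
    group: str | None = "UVN",
) -> pd.DataFrame:
    """Correlate each quantitative biomarker with the qualitative score.

    Both inputs are tidy tables with ``animal_id`` and ``session`` columns;
    ``quantitative`` holds one column per biomarker, ``qualitative`` a
    ``score`` column.  Rows are paired by animal x session.  By default the
    lesioned (UVN) group only is used when a ``group`` column is present;
    pass ``group=None`` to pool.  Returns a table ``biomarker, r, p``;
    undefined correlations yield NaN.
    """
    q = quantitative
    if group is not None and "group" in q.columns:
        q = q[q["group"] == group]
    merged = q.merge(qualitative[["animal_id", "session", "score"]], on=["animal_id", "session"])
    if biomarkers is None:
        skip = {"animal_id", "session", "group", "score"}
        biomarkers = [c for c in q.columns if c not in skip and pd.api.types.is_numeric_dtype(q[c])]
    rows = []
    for b in biomarkers:
        sub = merged[[b, "score"]].dropna()
        try:
            r, p = correlate(sub[b].to_numpy(), sub["score"].to_numpy())
        except UndefinedResult:
            r, p = float("nan"), float("nan")
        rows.append({"biomarker": b, "r": r, "p": p})
    return pd.DataFrame(rows)
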