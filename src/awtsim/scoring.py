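"""Threshold and Attention-Window scoring.

A trial counts as correct only when the reported light-gray-triangle count
is right for *both* stimulus groups. Per meridian class (the two diagonals
are pooled by trial union) accuracy is tabulated on the full separation
grid; the meridian's threshold is found by an ascending scan: the first
separation whose accuracy drops below the 75 % criterion stops the scan
and the threshold is the separation immediately below it. Accuracy exactly
at the criterion passes (with 9 trials the effective pass mark is 7/9).
If no separation fails, the threshold is the largest tested separation
(ceiling-censored); if the smallest separation already fails, it is 0°
(floor-censored, kept numeric so the ANOVA input stays complete).

The Attention Window itself is the octagon spanned by the per-meridian
endpoints: vertices at radius threshold/2 along the eight half-meridians,
with area by the shoelace formula (for vertices every 45° this equals
½·sin 45°·Σ rᵢrᵢ₊₁). An ellipse-based area and the horizontal/vertical
aspect ratio are attached as secondary descriptors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import MERIDIAN_CLASSES, MERIDIANS

__all__ = [
    "MeridianThreshold",
    "AttentionWindow",
    "score_records",
    "estimate_threshold",
    "thresholds_from_records",
    "build_attention_window",
]

logger = logging.getLogger(__name__)

DEFAULT_CRITERION = 0.75

#: Half-meridian vertex angles of the window polygon, degrees CCW.
VERTEX_ANGLES_DEG = tuple(45.0 * i for i in range(8))

_ANGLE_TO_MERIDIAN = {
    0.0: "horizontal", 180.0: "horizontal",
    90.0: "vertical", 270.0: "vertical",
    45.0: "diagonal1", 225.0: "diagonal1",
    135.0: "diagonal2", 315.0: "diagonal2",
}


@dataclass(frozen=True)
class MeridianThreshold:
    """75 %-criterion separation for one meridian (class)."""

    meridian: str
    threshold_deg: float
    censoring: str = "none"  # none | floor | ceiling

    def __post_init__(self) -> None:
        if self.threshold_deg < 0:
            raise ValueError("threshold must be non-negative")
        if self.censoring not in ("none", "floor", "ceiling"):
            raise ValueError("censoring must be none|floor|ceiling")


@dataclass(frozen=True)
class AttentionWindow:
    """Endpoint polygon of the attention window with shape descriptors."""

    thresholds: dict[str, float]  # per raw meridian
    vertices: tuple[tuple[float, float], ...]  # cartesian, deg visual angle
    polygon_area_deg2: float
    ellipse_area_deg2: float
    aspect_ratio: float  # horizontal / vertical threshold


def score_records(
    records: pd.DataFrame,
    by: Sequence[str] = ("subject",),
    pool_diagonals: bool = True,
) -> pd.DataFrame:
    """Aggregate pair-correct accuracy per group × meridian (class) × separation.

    Parameters
    ----------
    records
        Trial-record table with ``meridian``, ``separation_deg`` and boolean
        ``correct`` columns (plus any grouping columns).
    by
        Extra grouping keys (subject, task version, cue validity, ...);
        keys absent from the table are ignored.
    pool_diagonals
        Pool ``diagonal1``/``diagonal2`` into one ``diagonal`` class by trial
        union (18 trials per separation under the default design, vs 9 for
        horizontal/vertical).
    """
    df = records.copy()
    if "meridian_class" not in df.columns:
        df["meridian_class"] = df["meridian"].map(MERIDIAN_CLASSES)
    mer_key = "meridian_class" if pool_diagonals else "meridian"
    keys = [k for k in by if k in df.columns] + [mer_key, "separation_deg"]
    grouped = df.groupby(keys, as_index=False, observed=True).agg(
        n_trials=("correct", "size"), n_correct=("correct", "sum")
    )
    grouped["accuracy"] = grouped["n_correct"] / grouped["n_trials"]
    if grouped.empty:
        logger.warning("score_records: no trials to score")
    return grouped


def estimate_threshold(
    separations_deg: Sequence[float],
    accuracies: Sequence[float],
    criterion: float = DEFAULT_CRITERION,
    grid: Sequence[float] | None = None,
    meridian: str = "",
) -> MeridianThreshold:
    """Ascending first-failure threshold rule.

    Scans the separations in increasing order; the threshold is the
    separation immediately below the first one whose accuracy falls below
    ``criterion`` (accuracy == criterion passes). Later recoveries above
    criterion are ignored. ``grid`` (when given) is the full design grid;
    a missing grid point raises, since the sequential procedure is
    gap-intolerant.
    """
    seps = [float(s) for s in separations_deg]
    accs = [float(a) for a in accuracies]
    if len(seps) != len(accs) or not seps:
        raise ValueError("separations and accuracies must be equal-length and non-empty")
    order = np.argsort(seps)
    seps = [seps[i] for i in order]
    accs = [accs[i] for i in order]
    if grid is not None:
        expected = sorted(float(g) for g in grid)
        if seps != expected:
            missing = sorted(set(expected) - set(seps))
            raise ValueError(f"accuracy profile does not cover the design grid; missing {missing}")
    for i, (s, a) in enumerate(zip(seps, accs)):
        if a < criterion:
            if i == 0:
                return MeridianThreshold(meridian, 0.0, "floor")
            return MeridianThreshold(meridian, seps[i - 1], "none")
    return MeridianThreshold(meridian, seps[-1], "ceiling")


def thresholds_from_records(
    records: pd.DataFrame,
    by: Sequence[str] = ("subject",),
    criterion: float = DEFAULT_CRITERION,
    grid: Sequence[float] | None = None,
    pool_diagonals: bool = True,
) -> pd.DataFrame:
    """Per-group, per-meridian-class thresholds from a trial-record table."""
    cells = score_records(records, by=by, pool_diagonals=pool_diagonals)
    mer_key = "meridian_class" if pool_diagonals else "meridian"
    keys = [k for k in by if k in cells.columns] + [mer_key]
    rows = []
    for key_vals, sub in cells.groupby(keys, observed=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        thr = estimate_threshold(
            sub["separation_deg"], sub["accuracy"],
            criterion=criterion, grid=grid,
            meridian=str(key_vals[-1]),
        )
        row = dict(zip(keys, key_vals))
        row["threshold_deg"] = thr.threshold_deg
        row["censoring"] = thr.censoring
        rows.append(row)
    return pd.DataFrame(rows)


def _raw_thresholds(thresholds: Mapping[str, float]) -> dict[str, float]:
    """Expand a pooled (3-class) or raw (4-meridian) mapping to raw meridians."""
    t = dict(thresholds)
    if set(t) == {"horizontal", "vertical", "diagonal"}:
        d = t.pop("diagonal")
        t["diagonal1"] = d
        t["diagonal2"] = d
    missing = set(MERIDIANS) - set(t)
    if missing:
        raise ValueError(f"thresholds missing for meridians: {sorted(missing)}")
    return {m: float(t[m]) for m in MERIDIANS}


def shoelace_area(vertices: Sequence[tuple[float, float]]) -> float:
    x = np.array([v[0] for v in vertices])
    y = np.array([v[1] for v in vertices])
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def build_attention_window(thresholds: Mapping[str, float]) -> AttentionWindow:
    """Reconstruct the window polygon from per-meridian thresholds.

    Accepts thresholds keyed by the four raw meridians or by the three
    analysis classes (the pooled diagonal value is applied to both
    diagonals). Vertices sit at radius threshold/2 along the eight
    half-meridians; equal thresholds give a regular octagon of area 2√2·R².
    The ellipse area uses semi-axes H/2 and V/2 (the endpoint radii):
    π·(H/2)·(V/2).
    """
    raw = _raw_thresholds(thresholds)
    if any(v < 0 for v in raw.values()):
        raise ValueError("thresholds must be non-negative")
    verts = []
    for ang in VERTEX_ANGLES_DEG:
        r = raw[_ANGLE_TO_MERIDIAN[ang]] / 2.0
        a = math.radians(ang)
        verts.append((r * math.cos(a), r * math.sin(a)))
    h, v = raw["horizontal"], raw["vertical"]
    return AttentionWindow(
        thresholds=raw,
        vertices=tuple(verts),
        polygon_area_deg2=shoelace_area(verts),
        ellipse_area_deg2=math.pi * (h / 2.0) * (v / 2.0),
        aspect_ratio=(h / v) if v > 0 else float("nan"),
    )
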