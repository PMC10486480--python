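"""Seven-item radiological point scale (0–12) for NPH on non-contrast CT.

Items and maximum points:

1. Evans' index (frontal-horn width / inner-table width)      0–2
2. Mean temporal horn width (mm, mean of right and left)      0–2
3. Callosal angle (degrees, narrow is abnormal)               0–2
4. Narrow sulci at the high parietal convexity (visual grade) 0–2
5. Periventricular hypodensities (none/caps/confluent)        0–2
6. Dilated Sylvian fissures (present/absent)                  0–1
7. Focally enlarged sulci (present/absent)                    0–1

The total ranges 0–12 and maps to a predicted category: 0–2 Negative,
3–4 Borderline, ≥5 Positive.

The per-item cut-offs shipped here are reference-derived defaults in line
with the iNPH Radscale literature and are fully configurable (pass a
``thresholds`` mapping or load one from YAML): the scale's hard constraints
are the item list, each item's grade range and the total of 12, not the
numeric cut points. Cut values themselves belong to the middle band (an
Evans' index of exactly 0.30 or 0.35 scores 1; a callosal angle of exactly
90° or 60° scores 1; a mean temporal horn of exactly 4 or 6 mm scores 1).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import MeasurementError, ParameterError

PERIVENTRICULAR_GRADES = {"none": 0, "caps": 1, "confluent": 2}

#: Reference-derived default cut-offs; override any subset via `thresholds`.
DEFAULT_THRESHOLDS: dict[str, dict[str, float]] = {
    # grade 0 if value <= low edge is False... encoded as two upper bounds:
    # value <= b1 -> 0, value <= b2 -> 1, else 2 (direction-aware below).
    "evans_index": {"grade1_above": 0.30, "grade2_above": 0.35},
    "temporal_horn_mm": {"grade1_above": 4.0, "grade2_above": 6.0},
    "callosal_angle_deg": {"grade1_below": 90.0, "grade2_below": 60.0},
}

_CATEGORY_BANDS = ((0, 2, "Negative"), (3, 4, "Borderline"), (5, 12, "Positive"))

ITEM_NAMES = (
    "evans_index",
    "temporal_horns",
    "callosal_angle",
    "narrow_parietal_sulci",
    "periventricular",
    "sylvian_dilated",
    "focal_sulci",
)


@dataclass(frozen=True)
class RadscaleMeasurements:
    """Raw per-subject measurements feeding the point scale."""

    frontal_horn_width: float  # mm, maximal frontal-horn width (B–C)
    inner_table_width: float  # mm, maximal inner-table width, same axial image
    temporal_horn_right: float  # mm
    temporal_horn_left: float  # mm
    callosal_angle: float  # degrees
    narrow_parietal_sulci: int  # visual grade 0/1/2
    sylvian_dilated: bool
    focal_sulci: bool
    periventricular: str  # none | caps | confluent

    def __post_init__(self) -> None:
        for name in (
            "frontal_horn_width",
            "inner_table_width",
            "temporal_horn_right",
            "temporal_horn_left",
        ):
            if getattr(self, name) <= 0:
                raise MeasurementError(f"{name} must be > 0 mm")
        if not 0 < self.callosal_angle < 180:
            raise MeasurementError("callosal_angle must be in (0, 180) degrees")
        if self.narrow_parietal_sulci not in (0, 1, 2):
            raise MeasurementError("narrow_parietal_sulci grade must be 0, 1 or 2")
        if self.periventricular not in PERIVENTRICULAR_GRADES:
            raise MeasurementError(
                f"periventricular must be one of {sorted(PERIVENTRICULAR_GRADES)}"
            )


@dataclass(frozen=True)
class RadscaleScore:
    """Per-item points, their total (0–12) and the predicted category."""

    item_points: dict[str, int]
    total: int
    category: str


def evans_index(frontal_horn_width: float, inner_table_width: float) -> float:
    """Frontal-horn width divided by inner-table width on the same axial image."""
    if frontal_horn_width <= 0 or inner_table_width <= 0:
        raise MeasurementError("widths must be > 0 mm")
    if frontal_horn_width > inner_table_width:
        raise MeasurementError(
            "frontal-horn width cannot exceed the inner-table width"
        )
    return frontal_horn_width / inner_table_width


def _grade_high(value: float, b1: float, b2: float) -> int:
    """0/1/2 grade for a measure where larger is more abnormal.

    Bands: value < b1 -> 0; b1 <= value <= b2 -> 1; value > b2 -> 2.
    Both cut values belong to the middle band.
    """
    if value < b1:
        return 0
    if value <= b2:
        return 1
    return 2


def _grade_low(value: float, b1: float, b2: float) -> int:
    """0/1/2 grade for a measure where smaller is more abnormal.

    Bands: value > b1 -> 0; b2 <= value <= b1 -> 1; value < b2 -> 2.
    """
    if value > b1:
        return 0
    if value >= b2:
        return 1
    return 2


def _merge_thresholds(overrides: dict | None) -> dict[str, dict[str, float]]:
    merged = copy.deepcopy(DEFAULT_THRESHOLDS)
    for item, vals in (overrides or {}).items():
        if item not in merged:
            raise ParameterError(f"unknown threshold item {item!r}")
        merged[item].update(vals)
    return merged


def grade_items(
    m: RadscaleMeasurements, thresholds: dict | None = None
) -> dict[str, int]:
    """Per-item points under the configured cut-offs (max attainable sum 12)."""
    t = _merge_thresholds(thresholds)
    ei = evans_index(m.frontal_horn_width, m.inner_table_width)
    temporal_mean = 0.5 * (m.temporal_horn_right + m.temporal_horn_left)
    return {
        "evans_index": _grade_high(ei, *_pair(t["evans_index"], "above")),
        "temporal_horns": _grade_high(temporal_mean, *_pair(t["temporal_horn_mm"], "above")),
        "callosal_angle": _grade_low(m.callosal_angle, *_pair(t["callosal_angle_deg"], "below")),
        "narrow_parietal_sulci": int(m.narrow_parietal_sulci),
        "periventricular": PERIVENTRICULAR_GRADES[m.periventricular],
        "sylvian_dilated": int(bool(m.sylvian_dilated)),
        "focal_sulci": int(bool(m.focal_sulci)),
    }


def _pair(d: dict[str, float], direction: str) -> tuple[float, float]:
    return d[f"grade1_{direction}"], d[f"grade2_{direction}"]


def predict_category(total: int) -> str:
    """Map a total score to Negative (0–2), Borderline (3–4) or Positive (≥5)."""
    if not 0 <= total <= 12:
        raise ParameterError(f"total must be in [0, 12], got {total}")
    for lo, hi, cat in _CATEGORY_BANDS:
        if lo <= total <= hi:
            return cat
    raise AssertionError("unreachable")


def score_subject(
    m: RadscaleMeasurements, thresholds: dict | None = None
) -> RadscaleScore:
    """Grade all seven items and return the total score and category."""
    points = grade_items(m, thresholds)
    total = sum(points.values())
    return RadscaleScore(item_points=points, total=total, category=predict_category(total))


def load_thresholds(path: str | Path) -> dict:
    """Load threshold overrides from a YAML file."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


_CSV_COLUMNS = [
    "frontal_horn_width",
    "inner_table_width",
    "temporal_horn_right",
    "temporal_horn_left",
    "callosal_angle",
    "narrow_parietal_sulci",
    "sylvian_dilated",
    "focal_sulci",
    "periventricular",
]


def score_table(df: pd.DataFrame, thresholds: dict | None = None) -> pd.DataFrame:
    """Score a table of subjects (one row each, the nine measurement columns).

    Returns a copy with per-item point columns (``points_<item>``), ``total``
    and ``category`` appended.
    """
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"missing measurement columns: {missing}")
    out = df.copy()
    scored = []
    for _, row in df.iterrows():
        m = RadscaleMeasurements(
            frontal_horn_width=float(row["frontal_horn_width"]),
            inner_table_width=float(row["inner_table_width"]),
            temporal_horn_right=float(row["temporal_horn_right"]),
            temporal_horn_left=float(row["temporal_horn_left"]),
            callosal_angle=float(row["callosal_angle"]),
            narrow_parietal_sulci=int(row["narrow_parietal_sulci"]),
            sylvian_dilated=bool(row["sylvian_dilated"]),
            focal_sulci=bool(row["focal_sulci"]),
            periventricular=str(row["periventricular"]),
        )
        scored.append(score_subject(m, thresholds))
    for item in ITEM_NAMES:
        out[f"points_{item}"] = [s.item_points[item] for s in scored]
    out["total"] = [s.total for s in scored]
    out["category"] = [s.category for s in scored]
    return out
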