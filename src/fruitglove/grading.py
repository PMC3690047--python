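"""Grasp detection, turgor-pressure ripeness classes and quality scoring.

Fruit firmness tracks the turgor pressure of its cells: firm unripe fruit
sits around 150-400 kPa, ripe fruit around 20-100 kPa, and pressures near
zero indicate fruit inadequate for consumption (spoiled or overripe).  The
glove measures turgor through fingertip pressure sensors while the user
grasps the fruit; each grasp shows up as a pressure plateau on the fingers
that made good contact.

This module detects those grasp episodes in a multi-finger pressure trace,
discards fingers whose contact pressure is far below the best finger,
classifies the resulting turgor estimate, and folds pressure and geometry
into a single weighted quality score with an alert flag for the glove's
vibration feedback.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Ripeness",
    "GraspTrace",
    "GraspEvent",
    "FruitReport",
    "GradingError",
    "detect_grasps",
    "valid_fingers",
    "classify_ripeness",
    "summarize_measurements",
    "quality_score",
    "alert",
    "RIPE_RANGE_KPA",
    "UNRIPE_RANGE_KPA",
]

#: Literature ranges for climacteric fruit turgor pressure (kPa).
RIPE_RANGE_KPA = (20.0, 100.0)
UNRIPE_RANGE_KPA = (150.0, 400.0)

#: Demo per-variety ripe/unripe decision threshold for tomatoes (kPa).
TOMATO_THRESHOLD_KPA = 200.0

DEFAULT_FINGERS = ("index", "middle", "ring", "little")


class GradingError(ValueError):
    pass


class Ripeness(str, enum.Enum):
    INADEQUATE = "inadequate"
    RIPE = "ripe"
    RIPENING = "ripening"
    UNRIPE = "unripe"


@dataclass
class GraspTrace:
    """Multi-finger fingertip pressure time series in kPa."""

    sample_rate: float
    pressures: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise GradingError("sample_rate must be positive")
        if not self.pressures:
            raise GradingError("trace needs at least one finger channel")
        lengths = {len(v) for v in self.pressures.values()}
        if len(lengths) != 1:
            raise GradingError("finger channels have unequal lengths")
        self.pressures = {k: np.asarray(v, dtype=float) for k, v in self.pressures.items()}
        for name, v in self.pressures.items():
            if not np.all(np.isfinite(v)):
                raise GradingError(f"non-finite pressure in channel {name!r}")
            if np.any(v < 0):
                raise GradingError(f"negative pressure in channel {name!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.pressures.values())))

    @property
    def fingers(self) -> list[str]:
        return list(self.pressures)

    def envelope(self) -> np.ndarray:
        """Per-sample maximum across fingers."""
        return np.max(np.stack(list(self.pressures.values())), axis=0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_rate: float | None = None) -> "GraspTrace":
        """Build from a table with a ``t_s`` time column plus finger columns.

        Small negative readings (sensor noise after unit conversion) are
        clipped to zero.
        """
        df = df.copy()
        if sample_rate is None:
            if "t_s" not in df.columns:
                raise GradingError("need a t_s column or an explicit sample_rate")
            t = df["t_s"].to_numpy(dtype=float)
            if len(t) < 2:
                raise GradingError("trace too short to infer sample rate")
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        cols = [c for c in df.columns if c != "t_s"]
        if not cols:
            raise GradingError("no finger columns found")
        pressures = {c: np.clip(df[c].to_numpy(dtype=float), 0.0, None) for c in cols}
        return cls(sample_rate=float(sample_rate), pressures=pressures)

    @classmethod
    def from_csv(cls, path, sample_rate: float | None = None) -> "GraspTrace":
        return cls.from_dataframe(pd.read_csv(path), sample_rate=sample_rate)


@dataclass
class GraspEvent:
    """One detected grasp episode (half-open sample interval)."""

    start: int
    end: int
    plateaus: dict[str, float]
    valid: list[str] = field(default_factory=list)
    pressure_kPa: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GradingError("event must span at least one sample")


def _middle_slice(start: int, end: int, trim: float = 0.1) -> slice:
    n = end - start
    k = int(math.floor(n * trim))
    if n - 2 * k < 1:
        k = 0
    return slice(start + k, end - k)


def detect_grasps(
    trace: GraspTrace,
    on_kPa: float = 20.0,
    min_duration_s: float = 1.0,
    valid_ratio: float = 0.5,
) -> list[GraspEvent]:
    """Detect grasp episodes in a multi-finger pressure trace.

    An episode is a maximal run where the across-finger maximum exceeds
    ``on_kPa`` for at least ``min_duration_s``.  Each finger's plateau
    statistic is the median over the middle 80% of the episode (trimming the
    rise and release ramps); fingers below ``valid_ratio`` of the best
    finger's plateau are treated as poor contacts and excluded from the
    event pressure, which is the mean of the valid plateaus.
    """
    if on_kPa <= 0:
        raise GradingError("on_kPa must be positive")
    if trace.n_samples == 0:
        raise GradingError("empty trace")
    env = trace.envelope()
    above = env > on_kPa
    min_len = max(1, int(round(min_duration_s * trace.sample_rate)))
    events: list[GraspEvent] = []
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        mid = _middle_slice(int(s), int(e))
        plateaus = {f: float(np.median(v[mid])) for f, v in trace.pressures.items()}
        ev = GraspEvent(start=int(s), end=int(e), plateaus=plateaus)
        ev.valid = valid_fingers(ev, valid_ratio)
        ev.pressure_kPa = float(np.mean([plateaus[f] for f in ev.valid]))
        events.append(ev)
    return events


def valid_fingers(event: GraspEvent | Mapping[str, float], ratio: float = 0.5) -> list[str]:
    """Fingers whose plateau reaches ``ratio`` of the best finger's plateau.

    Fingers far below the maximum did not properly contact the fruit and
    would drag the turgor estimate down.
    """
    if not 0.0 < ratio <= 1.0:
        raise GradingError("ratio must lie in (0, 1]")
    plateaus = event.plateaus if isinstance(event, GraspEvent) else dict(event)
    best = max(plateaus.values())
    return [f for f, p in plateaus.items() if p >= ratio * best]


def classify_ripeness(p_kPa: float) -> Ripeness:
    """Map a turgor pressure to a ripeness class.

    Near-zero pressure (< 20 kPa) means inadequate fruit; 20-100 kPa is the
    ripe band, 150 kPa upward the unripe band, and the literature's
    unassigned 100-150 kPa gap is labelled ``ripening``.  Values above
    400 kPa stay ``unripe`` (the classification is a total monotone
    partition of [0, inf)).
    """
    if not math.isfinite(p_kPa) or p_kPa < 0:
        raise GradingError("pressure must be finite and non-negative")
    if p_kPa < RIPE_RANGE_KPA[0]:
        return Ripeness.INADEQUATE
    if p_kPa <= RIPE_RANGE_KPA[1]:
        return Ripeness.RIPE
    if p_kPa < UNRIPE_RANGE_KPA[0]:
        return Ripeness.RIPENING
    return Ripeness.UNRIPE


def summarize_measurements(values: Sequence[float]) -> dict[str, float]:
    """Mean, extrema and sample standard deviation of repeated measurements."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise GradingError("need at least two measurements")
    return {
        "average": float(np.mean(v)),
        "max": float(np.max(v)),
        "min": float(np.min(v)),
        "sd": float(np.std(v, ddof=1)),
    }


def _triangular(x: float, lo: float, hi: float) -> float:
    if not lo < hi:
        raise GradingError("feature range must satisfy lo < hi")
    c = 0.5 * (lo + hi)
    return max(0.0, 1.0 - abs(x - c) / (c - lo))


def quality_score(
    features: Mapping[str, float],
    weights: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float]],
) -> float:
    """Weighted overall quality in [0, 1].

    Each feature is normalised by a triangular membership over its
    user-configured ideal range (1 at the range centre, 0 at the limits);
    the score is the weight-normalised sum, invariant to uniform weight
    rescaling.
    """
    names = [n for n in features if weights.get(n, 0.0) > 0]
    if not names:
        raise GradingError("no weighted features to score")
    if any(weights[n] < 0 for n in names):
        raise GradingError("weights must be non-negative")
    total_w = sum(weights[n] for n in names)
    score = sum(weights[n] * _triangular(features[n], *ranges[n]) for n in names) / total_w
    return float(min(max(score, 0.0), 1.0))


def alert(score: float, threshold: float) -> bool:
    """True when the quality score falls below the user's alert threshold
    (the glove then vibrates)."""
    return score < threshold


@dataclass
class FruitReport:
    """Fused per-fruit measurement record."""

    pressure_kPa: float | None = None
    ripeness: Ripeness | None = None
    area_cm2: float | None = None
    radius_cm: float | None = None
    volume_cm3: float | None = None
    diameter_mm: float | None = None
    depth_cm: float | None = None
    depth_source: str | None = None
    quality: float | None = None
    alert: bool | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _round(v):
            return None if v is None else round(float(v), 6)

        return {
            "schema": "fruitglove-report/1",
            "pressure_kPa": _round(self.pressure_kPa),
            "ripeness": self.ripeness.value if self.ripeness else None,
            "area_cm2": _round(self.area_cm2),
            "radius_cm": _round(self.radius_cm),
            "volume_cm3": _round(self.volume_cm3),
            "diameter_mm": _round(self.diameter_mm),
            "depth_cm": _round(self.depth_cm),
            "depth_source": self.depth_source,
            "quality": _round(self.quality),
            "alert": self.alert,
            "flags": list(self.flags),
            "units": {
                "pressure": "kPa",
                "area": "cm2",
                "radius": "cm",
                "volume": "cm3",
                "diameter": "mm",
                "depth": "cm",
            },
        }
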