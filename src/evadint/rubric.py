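"""Scoring rubric: the weighted behavioral table, its defaults, loading and validation.

The rubric assigns points along two axes:

* **event rows** — seizures and hyperactivity (or other atypical motor
  behavior) scored by severity (none/mild/moderate/severe);
* **latency rows** — four recovery milestones (maintenance of sternal
  posture, unstimulated movement, movement without ataxia, normal
  grooming/eating/nesting) scored by the scheduled checkpoint at which
  the behavior is first sustainably regained.  The final checkpoint
  column doubles as the "no recovery" column.

A mouse that dies within the observation window receives a fixed override
score (default 75) in place of the component sum.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import yaml

__all__ = [
    "Severity",
    "EVENT_CATEGORIES",
    "LATENCY_CATEGORIES",
    "NO_RECOVERY",
    "DEFAULT_CHECKPOINTS_H",
    "EventCategoryWeights",
    "LatencyCategoryWeights",
    "Rubric",
    "RubricFormatError",
    "RubricValidationError",
    "default_rubric",
    "load_rubric",
    "serialize_rubric",
    "validate_rubric",
]


class Severity(enum.IntEnum):
    """Ordered event severity: NONE < MILD < MODERATE < SEVERE."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown severity label {label!r}") from None


EVENT_CATEGORIES: tuple[str, ...] = ("seizure", "hyperactivity")
LATENCY_CATEGORIES: tuple[str, ...] = (
    "sternal_posture",
    "unstimulated_movement",
    "movement_without_ataxia",
    "grooming_eating_nesting",
)

#: Sentinel checkpoint value meaning the behavior was never regained within
#: the observation window; scores the final checkpoint column.
NO_RECOVERY = "no_recovery"

DEFAULT_CHECKPOINTS_H: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 24.0)

Checkpoint = Union[float, str]  # a scheduled hour, or NO_RECOVERY


class RubricFormatError(ValueError):
    """The rubric document could not be parsed into the expected structure."""


class RubricValidationError(ValueError):
    """The rubric parsed but violates an invariant; message names the cell."""


@dataclass(frozen=True)
class EventCategoryWeights:
    """Points by severity for one event category (seizure or hyperactivity)."""

    category: str
    points_by_severity: tuple[float, float, float, float]  # NONE..SEVERE

    def points(self, severity: Severity) -> float:
        return self.points_by_severity[int(severity)]


@dataclass(frozen=True)
class LatencyCategoryWeights:
    """Points by recovery checkpoint for one latency (recovery-milestone) row."""

    category: str
    checkpoints_h: tuple[float, ...]
    points: tuple[float, ...]  # parallel to checkpoints_h; last column = no recovery

    def points_at(self, checkpoint: Checkpoint) -> float:
        """Points for recovery at a scheduled checkpoint, or NO_RECOVERY."""
        if checkpoint == NO_RECOVERY:
            return self.points[-1]
        try:
            idx = self.checkpoints_h.index(float(checkpoint))
        except ValueError:
            raise ValueError(
                f"checkpoint {checkpoint!r} not in schedule {self.checkpoints_h}"
            ) from None
        return self.points[idx]


@dataclass(frozen=True)
class Rubric:
    """Complete scoring table: event rows, latency rows, death override."""

    event_weights: Mapping[str, EventCategoryWeights]
    latency_weights: Mapping[str, LatencyCategoryWeights]
    death_score: float = 75.0
    observation_window_h: float = 24.0

    @property
    def checkpoints_h(self) -> tuple[float, ...]:
        return next(iter(self.latency_weights.values())).checkpoints_h

    def max_surviving_total(self) -> float:
        """Largest total a surviving animal can accrue (sum of row maxima)."""
        return sum(max(w.points_by_severity) for w in self.event_weights.values()) + sum(
            max(w.points) for w in self.latency_weights.values()
        )


# --- defaults -------------------------------------------------------------

_DEFAULT_EVENT_POINTS: dict[str, tuple[float, float, float, float]] = {
    "seizure": (0.0, 10.0, 15.0, 20.0),
    "hyperactivity": (0.0, 5.0, 10.0, 15.0),
}

_DEFAULT_LATENCY_POINTS: dict[str, tuple[float, ...]] = {
    "sternal_posture": (0.0, 4.0, 8.0, 12.0, 20.0),
    "unstimulated_movement": (0.0, 3.0, 6.0, 9.0, 15.0),
    "movement_without_ataxia": (0.0, 2.0, 4.0, 6.0, 10.0),
    "grooming_eating_nesting": (0.0, 1.0, 2.0, 3.0, 5.0),
}


def default_rubric() -> Rubric:
    """The published default table.

    Seizure 0/10/15/20 (death 75), hyperactivity 0/5/10/15, and the four
    recovery rows 0/4/8/12/20, 0/3/6/9/15, 0/2/4/6/10 and 0/1/2/3/5 over
    the checkpoint schedule 0.5/1/2/4/24 h.
    """
    events = {
        c: EventCategoryWeights(category=c, points_by_severity=_DEFAULT_EVENT_POINTS[c])
        for c in EVENT_CATEGORIES
    }
    latencies = {
        c: LatencyCategoryWeights(
            category=c,
            checkpoints_h=DEFAULT_CHECKPOINTS_H,
            points=_DEFAULT_LATENCY_POINTS[c],
        )
        for c in LATENCY_CATEGORIES
    }
    return Rubric(event_weights=events, latency_weights=latencies,
                  death_score=75.0, observation_window_h=24.0)


# --- validation -----------------------------------------------------------


def validate_rubric(r: Rubric) -> list[str]:
    """Return every invariant violation (empty list when the rubric is valid)."""
    violations: list[str] = []
    for cat in EVENT_CATEGORIES:
        if cat not in r.event_weights:
            violations.append(f"missing event category {cat!r}")
    for cat in LATENCY_CATEGORIES:
        if cat not in r.latency_weights:
            violations.append(f"missing latency category {cat!r}")

    for cat, w in r.event_weights.items():
        pts = w.points_by_severity
        if len(pts) != 4:
            violations.append(f"event row {cat!r} must have 4 severity cells, got {len(pts)}")
            continue
        if pts[0] != 0:
            violations.append(f"event row {cat!r}: points at severity 'none' must be 0, got {pts[0]}")
        negative = {i for i, p in enumerate(pts) if p < 0}
        for i in sorted(negative):
            violations.append(f"event row {cat!r}, cell {Severity(i).label}: negative points {pts[i]}")
        for i in range(1, len(pts)):
            # a negative cell is reported once, not again as a monotonicity break
            if pts[i] < pts[i - 1] and not {i - 1, i} & negative:
                violations.append(
                    f"event row {cat!r}, cell {Severity(i).label}: points decrease "
                    f"({pts[i - 1]} -> {pts[i]})"
                )

    schedules = set()
    for cat, w in r.latency_weights.items():
        cps, pts = w.checkpoints_h, w.points
        schedules.add(cps)
        if len(cps) != len(pts):
            violations.append(f"latency row {cat!r}: {len(cps)} checkpoints vs {len(pts)} cells")
            continue
        if any(cps[i] >= cps[i + 1] for i in range(len(cps) - 1)):
            violations.append(f"latency row {cat!r}: checkpoints not strictly ascending {cps}")
        if pts and pts[0] != 0:
            violations.append(f"latency row {cat!r}: points at first checkpoint must be 0, got {pts[0]}")
        negative = {i for i, p in enumerate(pts) if p < 0}
        for i in sorted(negative):
            violations.append(f"latency row {cat!r}, checkpoint {cps[i]} h: negative points {pts[i]}")
        for i in range(1, len(pts)):
            if pts[i] < pts[i - 1] and not {i - 1, i} & negative:
                violations.append(
                    f"latency row {cat!r}, checkpoint {cps[i]} h: points decrease "
                    f"({pts[i - 1]} -> {pts[i]})"
                )
    if len(schedules) > 1:
        violations.append(f"latency rows disagree on checkpoint schedule: {sorted(schedules)}")

    if r.death_score < 0:
        violations.append(f"death_score negative: {r.death_score}")
    row_maxima = [max(w.points_by_severity) for w in r.event_weights.values()] + [
        max(w.points) for w in r.latency_weights.values() if w.points
    ]
    if row_maxima and r.death_score < max(row_maxima):
        violations.append(
            f"death_score {r.death_score} below largest single-category maximum {max(row_maxima)}"
        )
    if r.observation_window_h <= 0:
        violations.append(f"observation window must be positive, got {r.observation_window_h}")
    elif schedules and max(max(s) for s in schedules) > r.observation_window_h:
        violations.append("checkpoint schedule extends past the observation window")
    return violations


# --- (de)serialization ----------------------------------------------------


def serialize_rubric(r: Rubric) -> str:
    """Canonical YAML form of a rubric; inverse of :func:`load_rubric`."""
    doc = {
        "checkpoints_h": list(r.checkpoints_h),
        "death_score": r.death_score,
        "observation_window_h": r.observation_window_h,
        "events": {
            cat: {Severity(i).label: w.points_by_severity[i] for i in range(4)}
            for cat, w in r.event_weights.items()
        },
        "latencies": {cat: list(w.points) for cat, w in r.latency_weights.items()},
    }
    return yaml.safe_dump(doc, sort_keys=True)


def load_rubric(config_text: str) -> Rubric:
    """Parse a YAML rubric document, merging overrides onto the defaults.

    An empty document yields :func:`default_rubric`.  Raises
    :class:`RubricFormatError` on malformed documents and
    :class:`RubricValidationError` (naming the offending cell) when the
    merged rubric violates an invariant.
    """
    try:
        doc = yaml.safe_load(io.StringIO(config_text))
    except yaml.YAMLError as exc:
        raise RubricFormatError(f"could not parse rubric document: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise RubricFormatError(f"rubric document must be a mapping, got {type(doc).__name__}")

    known = {"checkpoints_h", "death_score", "observation_window_h", "events", "latencies"}
    unknown = set(doc) - known
    if unknown:
        raise RubricFormatError(f"unknown rubric keys: {sorted(unknown)}")

    base = default_rubric()
    try:
        checkpoints = tuple(float(t) for t in doc.get("checkpoints_h", base.checkpoints_h))
    except (TypeError, ValueError) as exc:
        raise RubricFormatError(f"bad checkpoints_h: {exc}") from exc

    for section in ("events", "latencies"):
        if section in doc and not isinstance(doc[section], dict):
            raise RubricFormatError(f"{section!r} must be a mapping of category rows")

    events = dict(base.event_weights)
    for cat, row in (doc.get("events") or {}).items():
        if cat not in EVENT_CATEGORIES:
            raise RubricFormatError(f"unknown event category {cat!r}")
        if not isinstance(row, dict):
            raise RubricFormatError(f"event row {cat!r} must map severity -> points")
        pts = list(events[cat].points_by_severity)
        for label, value in row.items():
            sev = Severity.from_label(str(label))
            try:
                pts[int(sev)] = float(value)
            except (TypeError, ValueError) as exc:
                raise RubricFormatError(f"event row {cat!r}, cell {label!r}: {exc}") from exc
        events[cat] = EventCategoryWeights(category=cat, points_by_severity=tuple(pts))

    latencies = {
        cat: replace(w, checkpoints_h=checkpoints)
        for cat, w in base.latency_weights.items()
    }
    for cat, row in (doc.get("latencies") or {}).items():
        if cat not in LATENCY_CATEGORIES:
            raise RubricFormatError(f"unknown latency category {cat!r}")
        try:
            pts = tuple(float(v) for v in row)
        except (TypeError, ValueError) as exc:
            raise RubricFormatError(f"latency row {cat!r}: {exc}") from exc
        if len(pts) != len(checkpoints):
            raise RubricFormatError(
                f"latency row {cat!r}: {len(pts)} cells for {len(checkpoints)} checkpoints"
            )
        latencies[cat] = LatencyCategoryWeights(category=cat, checkpoints_h=checkpoints, points=pts)

    try:
        death = float(doc.get("death_score", base.death_score))
        window = float(doc.get("observation_window_h", base.observation_window_h))
    except (TypeError, ValueError) as exc:
        raise RubricFormatError(f"bad scalar field: {exc}") from exc

    rubric = Rubric(event_weights=events, latency_weights=latencies,
                    death_score=death, observation_window_h=window)
    violations = validate_rubric(rubric)
    if violations:
        raise RubricValidationError("; ".join(violations))
    return rubric
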