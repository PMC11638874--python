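"""Observation sheets: data model, CSV ingestion, validation and blinding.

The canonical on-disk layout is two comma-delimited files:

``observations.csv``
    one row per animal per scheduled checkpoint, columns
    ``animal_id, group, time_h, alive, sternal_posture,
    unstimulated_movement, movement_without_ataxia,
    grooming_eating_nesting``.  Behavior cells are left empty on rows
    where the animal is dead.

``events.csv``
    one row per seizure/hyperactivity episode, columns
    ``animal_id, category, duration_min, intensity, descriptor``.

Time origin is anesthesia reversal; all checkpoint times are hours
post-reversal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .rubric import LATENCY_CATEGORIES, Rubric

__all__ = [
    "INTENSITY_LEVELS",
    "OBSERVATION_COLUMNS",
    "EVENT_COLUMNS",
    "MotorEvent",
    "CheckpointStatus",
    "MouseObservation",
    "BlindingMap",
    "IngestionError",
    "ValidationReport",
    "read_observations",
    "write_observations",
    "validate_observations",
    "assign_blinding",
]

INTENSITY_LEVELS: tuple[str, ...] = ("low", "moderate", "high_or_constant")

OBSERVATION_COLUMNS: tuple[str, ...] = (
    "animal_id", "group", "time_h", "alive",
    "sternal_posture", "unstimulated_movement",
    "movement_without_ataxia", "grooming_eating_nesting",
)
EVENT_COLUMNS: tuple[str, ...] = (
    "animal_id", "category", "duration_min", "intensity", "descriptor",
)

_BEHAVIOR_FLAGS: tuple[str, ...] = LATENCY_CATEGORIES  # same four names

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class IngestionError(ValueError):
    """A file could not be ingested; message includes the offending row."""


@dataclass(frozen=True)
class MotorEvent:
    """One seizure or hyperactivity episode."""

    category: str  # "seizure" | "hyperactivity"
    duration_min: float
    intensity: str  # "low" | "moderate" | "high_or_constant"
    descriptor: str = ""


@dataclass(frozen=True)
class CheckpointStatus:
    """Status flags recorded at one scheduled checkpoint.

    Behavior flags are ``None`` (absent) on checkpoints where the animal
    is dead.
    """

    time_h: float
    alive: bool
    sternal_posture: Optional[bool] = None
    unstimulated_movement: Optional[bool] = None
    movement_without_ataxia: Optional[bool] = None
    grooming_eating_nesting: Optional[bool] = None

    def flag(self, behavior: str) -> Optional[bool]:
        return getattr(self, behavior)


@dataclass(frozen=True)
class MouseObservation:
    """One animal's full 24-h observation record."""

    animal_id: str
    group_label: str
    checkpoints: tuple[CheckpointStatus, ...]
    events: tuple[MotorEvent, ...] = ()
    died: bool = False
    death_time_h: Optional[float] = None


@dataclass(frozen=True)
class BlindingMap:
    """Invertible animal-id -> opaque-code map used for blinded scoring."""

    code_by_animal: dict[str, str]
    seed: int

    @property
    def animal_by_code(self) -> dict[str, str]:
        return {code: animal for animal, code in self.code_by_animal.items()}


@dataclass
class ValidationReport:
    """Errors block scoring; warnings (e.g. behavior relapses) do not."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __iter__(self):
        return iter(self.errors + self.warnings)


# --- parsing helpers ------------------------------------------------------


def _parse_bool(cell: str, where: str) -> bool:
    token = cell.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise IngestionError(f"{where}: unparseable boolean {cell!r} "
                         f"(expected one of 0/1/true/false/yes/no)")


def _parse_optional_bool(cell: str, where: str) -> Optional[bool]:
    if cell.strip() == "":
        return None
    return _parse_bool(cell, where)


def _parse_float(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise IngestionError(f"{where}: unparseable number {cell!r}") from None


# --- reading --------------------------------------------------------------


def read_observations(
    path: Union[str, Path],
    events_path: Union[str, Path, None] = None,
) -> list[MouseObservation]:
    """Read observation sheets into per-animal records.

    Rows are grouped by ``animal_id`` and sorted by ``time_h``.  The event
    file is optional; animals absent from it carry empty event lists.
    Duplicate ``(animal_id, time_h)`` rows, unknown columns and unparseable
    cells raise :class:`IngestionError` naming the row (1-based, counting
    the header as row 1).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise IngestionError(f"{path}: {exc}") from exc
    if tuple(frame.columns) != OBSERVATION_COLUMNS:
        unknown = [c for c in frame.columns if c not in OBSERVATION_COLUMNS]
        missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns]
        raise IngestionError(
            f"{path}: header mismatch (unknown columns {unknown}, missing {missing})"
        )

    rows_by_animal: dict[str, list[tuple[int, CheckpointStatus]]] = {}
    group_by_animal: dict[str, str] = {}
    seen: set[tuple[str, float]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        where = f"{path.name} row {i}"
        animal = row.animal_id.strip()
        if not animal:
            raise IngestionError(f"{where}: empty animal_id")
        time_h = _parse_float(row.time_h, where)
        if (animal, time_h) in seen:
            raise IngestionError(f"{where}: duplicate checkpoint ({animal!r}, {time_h} h)")
        seen.add((animal, time_h))
        alive = _parse_bool(row.alive, where)
        flags = {
            name: _parse_optional_bool(getattr(row, name), where)
            for name in _BEHAVIOR_FLAGS
        }
        if not alive:
            flags = {name: None for name in _BEHAVIOR_FLAGS}  # dead rows carry no flags
        status = CheckpointStatus(time_h=time_h, alive=alive, **flags)
        prior_group = group_by_animal.setdefault(animal, row.group.strip())
        if prior_group != row.group.strip():
            raise IngestionError(
                f"{where}: animal {animal!r} assigned to both groups "
                f"{prior_group!r} and {row.group.strip()!r}"
            )
        rows_by_animal.setdefault(animal, []).append((i, status))

    events_by_animal: dict[str, list[MotorEvent]] = {}
    if events_path is not None:
        events_path = Path(events_path)
        eframe = pd.read_csv(events_path, dtype=str, keep_default_na=False)
        if tuple(eframe.columns) != EVENT_COLUMNS:
            raise IngestionError(f"{events_path}: header must be {','.join(EVENT_COLUMNS)}")
        for i, row in enumerate(eframe.itertuples(index=False), start=2):
            where = f"{events_path.name} row {i}"
            category = row.category.strip()
            if category not in ("seizure", "hyperactivity"):
                raise IngestionError(f"{where}: unknown event category {category!r}")
            intensity = row.intensity.strip()
            if intensity not in INTENSITY_LEVELS:
                raise IngestionError(f"{where}: unknown intensity {intensity!r}")
            duration = _parse_float(row.duration_min, where)
            if not np.isfinite(duration) or duration < 0:
                raise IngestionError(f"{where}: event duration must be finite and >= 0, "
                                     f"got {row.duration_min!r}")
            events_by_animal.setdefault(row.animal_id.strip(), []).append(
                MotorEvent(category=category, duration_min=duration,
                           intensity=intensity, descriptor=row.descriptor)
            )
        orphan = set(events_by_animal) - set(rows_by_animal)
        if orphan:
            raise IngestionError(
                f"{events_path.name}: events reference unknown animals {sorted(orphan)}"
            )

    observations: list[MouseObservation] = []
    for animal, numbered in rows_by_animal.items():
        statuses = tuple(s for _, s in sorted(numbered, key=lambda pair: pair[1].time_h))
        dead = [s for s in statuses if not s.alive]
        observations.append(
            MouseObservation(
                animal_id=animal,
                group_label=group_by_animal[animal],
                checkpoints=statuses,
                events=tuple(events_by_animal.get(animal, ())),
                died=bool(dead),
                death_time_h=dead[0].time_h if dead else None,
            )
        )
    return observations


# --- writing --------------------------------------------------------------


def _fmt_time(t: float) -> str:
    return f"{t:g}"


def _fmt_flag(value: Optional[bool]) -> str:
    return "" if value is None else ("1" if value else "0")


def write_observations(
    observations: Sequence[MouseObservation],
    path: Union[str, Path],
    events_path: Union[str, Path, None] = None,
) -> None:
    """Write records in the canonical dialect read by :func:`read_observations`."""
    obs_rows = []
    for obs in observations:
        for cp in obs.checkpoints:
            obs_rows.append({
                "animal_id": obs.animal_id,
                "group": obs.group_label,
                "time_h": _fmt_time(cp.time_h),
                "alive": "1" if cp.alive else "0",
                **{name: _fmt_flag(cp.flag(name)) for name in _BEHAVIOR_FLAGS},
            })
    pd.DataFrame(obs_rows, columns=list(OBSERVATION_COLUMNS)).to_csv(path, index=False)

    if events_path is not None:
        event_rows = [
            {
                "animal_id": obs.animal_id,
                "category": ev.category,
                "duration_min": f"{ev.duration_min:g}",
                "intensity": ev.intensity,
                "descriptor": ev.descriptor,
            }
            for obs in observations
            for ev in obs.events
        ]
        pd.DataFrame(event_rows, columns=list(EVENT_COLUMNS)).to_csv(events_path, index=False)


# --- validation -----------------------------------------------------------


def validate_observations(
    observations: Sequence[MouseObservation], rubric: Rubric
) -> ValidationReport:
    """Check records against a rubric's schedule and structural rules.

    Errors (block scoring): off-schedule or missing checkpoints, behavior
    flags or revival after death, negative event durations, death time
    beyond the observation window.  Warnings: behavior relapses (a flag
    true at one checkpoint and false at a later one), which the sustained-
    recovery scoring rule tolerates.
    """
    report = ValidationReport()
    schedule = rubric.checkpoints_h
    for obs in observations:
        tag = f"animal {obs.animal_id!r}"
        times = [cp.time_h for cp in obs.checkpoints]
        for t in times:
            if t not in schedule:
                report.errors.append(f"{tag}: checkpoint at {t:g} h not in schedule {schedule}")
        missing = [t for t in schedule if t not in times]
        if missing:
            report.errors.append(f"{tag}: missing checkpoints at {missing} h")
        if any(times[i] >= times[i + 1] for i in range(len(times) - 1)):
            report.errors.append(f"{tag}: checkpoint times not strictly ascending")

        dead_seen = False
        for cp in obs.checkpoints:
            if dead_seen and cp.alive:
                report.errors.append(f"{tag}: alive at {cp.time_h:g} h after recorded death")
            if not cp.alive:
                dead_seen = True
            if not cp.alive and any(cp.flag(n) for n in _BEHAVIOR_FLAGS):
                report.errors.append(f"{tag}: behavior flags set at {cp.time_h:g} h while dead")

        if obs.died and obs.death_time_h is not None and obs.death_time_h > rubric.observation_window_h:
            report.errors.append(
                f"{tag}: death at {obs.death_time_h:g} h is outside the "
                f"{rubric.observation_window_h:g} h window"
            )

        for name in _BEHAVIOR_FLAGS:
            seen_true = False
            for cp in obs.checkpoints:
                value = cp.flag(name)
                if value:
                    seen_true = True
                elif value is False and seen_true:
                    report.warnings.append(
                        f"{tag}: {name} relapse at {cp.time_h:g} h (recovered earlier)"
                    )
                    break

        for ev in obs.events:
            if not np.isfinite(ev.duration_min) or ev.duration_min < 0:
                report.errors.append(f"{tag}: event duration {ev.duration_min} invalid")

    # deterministic, order-invariant report contents
    report.errors.sort()
    report.warnings.sort()
    return report


# --- blinding -------------------------------------------------------------


def assign_blinding(
    observations: Sequence[MouseObservation], seed: int
) -> tuple[BlindingMap, list[MouseObservation]]:
    """Replace animal ids with opaque codes and strip group labels.

    The code assignment is a seeded permutation, so the same seed always
    yields the same map, and the map restores the originals exactly.
    """
    ids = [obs.animal_id for obs in observations]
    if len(set(ids)) != len(ids):
        dupes = sorted({a for a in ids if ids.count(a) > 1})
        raise ValueError(f"duplicate animal ids: {dupes}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    code_by_animal = {ids[j]: f"blind-{rank + 1:03d}" for rank, j in enumerate(order)}
    blinded = [
        replace(obs, animal_id=code_by_animal[obs.animal_id], group_label="")
        for obs in observations
    ]
    return BlindingMap(code_by_animal=code_by_animal, seed=seed), blinded
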