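"""Per-animal composite scoring under a rubric.

A surviving animal's total is the sum of six components: one severity-based
score per event category (seizure, hyperactivity) and one latency score per
recovery milestone, read off the rubric row at the checkpoint where the
behavior was sustainably regained.  An animal that dies within the window
receives the rubric's fixed death score instead, and its component fields
are not applicable.

Event severity combines duration bands (< 10 min mild, 10-30 min moderate,
> 30 min severe) with the recorded intensity via an and/or rule: whichever
classification is more severe wins.  Multiple events in a category
aggregate by maximum severity.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .observations import MotorEvent, MouseObservation
from .rubric import (
    EVENT_CATEGORIES,
    LATENCY_CATEGORIES,
    NO_RECOVERY,
    Checkpoint,
    LatencyCategoryWeights,
    Rubric,
    Severity,
)

__all__ = [
    "MouseScore",
    "CohortScores",
    "classify_event_severity",
    "overall_event_severity",
    "recovery_checkpoint",
    "latency_points",
    "score_mouse",
    "score_cohort",
    "scores_to_frame",
    "write_scores",
]

_INTENSITY_SEVERITY: dict[str, Severity] = {
    "low": Severity.MILD,
    "moderate": Severity.MODERATE,
    "high_or_constant": Severity.SEVERE,
}


@dataclass(frozen=True)
class MouseScore:
    """Component points and total for one animal.

    Component fields are ``None`` when the animal died (the death override
    replaces them).  ``exceeds_death_flag`` marks a surviving total above
    the death score, which the default table permits (maximum surviving
    total 85 vs death 75); totals are deliberately not capped.
    """

    animal_id: str
    group_label: str
    seizure_points: Optional[float]
    hyperactivity_points: Optional[float]
    sternal_posture_points: Optional[float]
    unstimulated_movement_points: Optional[float]
    movement_without_ataxia_points: Optional[float]
    grooming_eating_nesting_points: Optional[float]
    total: float
    died: bool
    exceeds_death_flag: bool

    def component(self, name: str) -> Optional[float]:
        return getattr(self, f"{name}_points")


@dataclass(frozen=True)
class CohortScores:
    """All animals' scores plus the rubric and provenance used to produce them."""

    scores: tuple[MouseScore, ...]
    rubric: Rubric
    provenance: Mapping[str, object] = field(default_factory=dict)

    @property
    def by_group(self) -> dict[str, tuple[MouseScore, ...]]:
        groups: dict[str, list[MouseScore]] = {}
        for s in self.scores:
            groups.setdefault(s.group_label, []).append(s)
        return {g: tuple(v) for g, v in groups.items()}

    def group_means(self) -> dict[str, float]:
        return {g: sum(s.total for s in v) / len(v) for g, v in self.by_group.items()}

    def totals(self, group: str) -> list[float]:
        return [s.total for s in self.by_group[group]]


def classify_event_severity(event: MotorEvent) -> Severity:
    """Severity of one episode from its duration and intensity (and/or rule)."""
    d = event.duration_min
    if d > 30:
        by_duration = Severity.SEVERE
    elif d >= 10:
        by_duration = Severity.MODERATE  # boundary durations 10 and 30 min are moderate
    else:
        by_duration = Severity.MILD
    return max(by_duration, _INTENSITY_SEVERITY[event.intensity])


def overall_event_severity(events: Sequence[MotorEvent], category: str) -> Severity:
    """Maximum severity over an animal's events of one category; NONE if no events."""
    severities = [classify_event_severity(e) for e in events if e.category == category]
    return max(severities, default=Severity.NONE)


def recovery_checkpoint(obs: MouseObservation, behavior: str) -> Checkpoint:
    """Earliest checkpoint from which a behavior stays regained (sustained rule).

    Returns the checkpoint hour, or :data:`NO_RECOVERY` if the flag is never
    true through the end of observation.  Transient relapses therefore push
    recovery to the start of the final uninterrupted run of true flags.
    """
    recovered: Checkpoint = NO_RECOVERY
    for cp in reversed(obs.checkpoints):
        if cp.flag(behavior):
            recovered = cp.time_h
        else:
            break
    return recovered


def latency_points(checkpoint: Checkpoint, weights: LatencyCategoryWeights) -> float:
    """Rubric points for recovery at a checkpoint (NO_RECOVERY -> final column)."""
    return weights.points_at(checkpoint)


def score_mouse(obs: MouseObservation, rubric: Rubric) -> MouseScore:
    """Score one animal: death override, else the six-component sum.

    The caller is expected to have run
    :func:`~evadint.observations.validate_observations` first; scoring does
    not re-validate.
    """
    if obs.died:
        return MouseScore(
            animal_id=obs.animal_id,
            group_label=obs.group_label,
            seizure_points=None,
            hyperactivity_points=None,
            sternal_posture_points=None,
            unstimulated_movement_points=None,
            movement_without_ataxia_points=None,
            grooming_eating_nesting_points=None,
            total=rubric.death_score,
            died=True,
            exceeds_death_flag=False,
        )

    event_points = {
        cat: rubric.event_weights[cat].points(overall_event_severity(obs.events, cat))
        for cat in EVENT_CATEGORIES
    }
    lat_points = {
        cat: latency_points(recovery_checkpoint(obs, cat), rubric.latency_weights[cat])
        for cat in LATENCY_CATEGORIES
    }
    total = sum(event_points.values()) + sum(lat_points.values())
    return MouseScore(
        animal_id=obs.animal_id,
        group_label=obs.group_label,
        seizure_points=event_points["seizure"],
        hyperactivity_points=event_points["hyperactivity"],
        sternal_posture_points=lat_points["sternal_posture"],
        unstimulated_movement_points=lat_points["unstimulated_movement"],
        movement_without_ataxia_points=lat_points["movement_without_ataxia"],
        grooming_eating_nesting_points=lat_points["grooming_eating_nesting"],
        total=total,
        died=False,
        exceeds_death_flag=total > rubric.death_score,
    )


def score_cohort(
    observations: Sequence[MouseObservation],
    rubric: Rubric,
    provenance: Optional[Mapping[str, object]] = None,
) -> CohortScores:
    """Score every animal; deterministic given the input, one score per animal."""
    ids = [o.animal_id for o in observations]
    if len(set(ids)) != len(ids):
        dupes = sorted({a for a in ids if ids.count(a) > 1})
        raise ValueError(f"duplicate animal ids: {dupes}")
    if provenance is None:
        provenance = {"scored_at": datetime.datetime.now().isoformat(timespec="seconds")}
    return CohortScores(
        scores=tuple(score_mouse(o, rubric) for o in observations),
        rubric=rubric,
        provenance=dict(provenance),
    )


_SCORE_COLUMNS = [
    "animal_id", "group",
    "seizure", "hyperactivity", "sternal_posture", "unstimulated_movement",
    "movement_without_ataxia", "grooming_eating_nesting",
    "total", "died", "flags",
]


def scores_to_frame(cohort: CohortScores) -> pd.DataFrame:
    """Tabular view of a cohort's scores (component columns, total, flags)."""
    rows = []
    for s in cohort.scores:
        rows.append({
            "animal_id": s.animal_id,
            "group": s.group_label,
            "seizure": s.seizure_points,
            "hyperactivity": s.hyperactivity_points,
            "sternal_posture": s.sternal_posture_points,
            "unstimulated_movement": s.unstimulated_movement_points,
            "movement_without_ataxia": s.movement_without_ataxia_points,
            "grooming_eating_nesting": s.grooming_eating_nesting_points,
            "total": s.total,
            "died": int(s.died),
            "flags": "exceeds_death_score" if s.exceeds_death_flag else "",
        })
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)


def write_scores(cohort: CohortScores, path) -> None:
    scores_to_frame(cohort).to_csv(path, sep="\t", index=False)
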