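import pytest

from evadint import (
    CheckpointStatus,
    MotorEvent,
    MouseObservation,
    default_rubric,
)

SCHEDULE = (0.5, 1.0, 2.0, 4.0, 24.0)


def make_observation(
    animal_id="m1",
    group="g",
    recovery={},  # behavior -> checkpoint hour (None = never recovers)
    events=(),
    died=False,
    death_time_h=None,
):
    """Build a survivor (or dead) record with flags true from each recovery time."""
    behaviors = (
        "sternal_posture",
        "unstimulated_movement",
        "movement_without_ataxia",
        "grooming_eating_nesting",
    )
    if died:
        checkpoints = tuple(CheckpointStatus(time_h=t, alive=False) for t in SCHEDULE)
        return MouseObservation(
            animal_id=animal_id, group_label=group, checkpoints=checkpoints,
            events=tuple(events), died=True,
            death_time_h=death_time_h if death_time_h is not None else SCHEDULE[0],
        )
    checkpoints = []
    for t in SCHEDULE:
        flags = {}
        for b in behaviors:
            r = recovery.get(b, SCHEDULE[0])
            flags[b] = (r is not None) and (t >= r)
        checkpoints.append(CheckpointStatus(time_h=t, alive=True, **flags))
    return MouseObservation(
        animal_id=animal_id, group_label=group, checkpoints=tuple(checkpoints),
        events=tuple(events), died=False, death_time_h=None,
    )


@pytest.fixture
def rubric():
    return default_rubric()


@pytest.fixture
def worked_example():
    """Survivor regaining sternal posture between 1 h and 2 h, nothing else wrong."""
    return make_observation(recovery={"sternal_posture": 2.0})


@pytest.fixture
def severe_event():
    return MotorEvent(category="seizure", duration_min=45.0,
                      intensity="high_or_constant", descriptor="constant contractions")
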