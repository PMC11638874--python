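"""Per-animal scoring: severity classification, recovery latency, totals."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evadint import (
    NO_RECOVERY,
    MotorEvent,
    Severity,
    assign_blinding,
    classify_event_severity,
    latency_points,
    overall_event_severity,
    recovery_checkpoint,
    score_cohort,
    score_mouse,
)
from conftest import SCHEDULE, make_observation

BEHAVIORS = (
    "sternal_posture",
    "unstimulated_movement",
    "movement_without_ataxia",
    "grooming_eating_nesting",
)


class TestEventSeverity:
    @pytest.mark.parametrize("duration,intensity,expected", [
        (5, "low", Severity.MILD),
        (35, "moderate", Severity.SEVERE),      # duration alone makes it severe
        (15, "high_or_constant", Severity.SEVERE),  # intensity alone makes it severe
        (15, "moderate", Severity.MODERATE),
        (5, "moderate", Severity.MODERATE),     # intensity can raise a short event
        (10, "low", Severity.MODERATE),         # boundary: exactly 10 min
        (30, "low", Severity.MODERATE),         # boundary: exactly 30 min
        (30.001, "low", Severity.SEVERE),
        (9.999, "low", Severity.MILD),
    ])
    def test_duration_intensity_and_or_rule(self, duration, intensity, expected):
        event = MotorEvent("seizure", duration, intensity, "")
        assert classify_event_severity(event) == expected

    def test_overall_is_maximum_over_events(self):
        mild = MotorEvent("seizure", 5, "low", "")
        moderate = MotorEvent("seizure", 20, "moderate", "")
        severe = MotorEvent("seizure", 40, "high_or_constant", "")
        other = MotorEvent("hyperactivity", 40, "high_or_constant", "")
        assert overall_event_severity([], "seizure") == Severity.NONE
        assert overall_event_severity([mild, moderate], "seizure") == Severity.MODERATE
        assert overall_event_severity([severe, mild], "seizure") == Severity.SEVERE
        assert overall_event_severity([other], "seizure") == Severity.NONE  # wrong category


class TestRecoveryCheckpoint:
    def test_worked_example_recovers_at_two_hours(self, worked_example):
        assert recovery_checkpoint(worked_example, "sternal_posture") == 2.0

    def test_recovered_from_start(self):
        obs = make_observation()
        for b in BEHAVIORS:
            assert recovery_checkpoint(obs, b) == 0.5

    def test_never_recovered(self):
        obs = make_observation(recovery={"grooming_eating_nesting": None})
        assert recovery_checkpoint(obs, "grooming_eating_nesting") == NO_RECOVERY

    def test_relapse_pushes_recovery_to_last_sustained_run(self):
        from dataclasses import replace
        obs = make_observation(recovery={"sternal_posture": 1.0})
        cps = list(obs.checkpoints)
        cps[2] = replace(cps[2], sternal_posture=False)  # relapse at 2 h
        obs = replace(obs, checkpoints=tuple(cps))
        assert recovery_checkpoint(obs, "sternal_posture") == 4.0


class TestLatencyPoints:
    def test_worked_example_scores_eight(self, rubric):
        assert latency_points(2.0, rubric.latency_weights["sternal_posture"]) == 8

    def test_first_column_is_free(self, rubric):
        for b in BEHAVIORS:
            assert latency_points(0.5, rubric.latency_weights[b]) == 0

    def test_no_recovery_scores_final_column(self, rubric):
        assert latency_points(NO_RECOVERY, rubric.latency_weights["sternal_posture"]) == 20

    def test_off_schedule_checkpoint_rejected(self, rubric):
        with pytest.raises(ValueError, match="schedule"):
            latency_points(3.0, rubric.latency_weights["sternal_posture"])


class TestScoreMouse:
    def test_death_override(self, rubric, severe_event):
        plain = make_observation(died=True, death_time_h=0.2)
        with_phenotypes = make_observation(died=True, death_time_h=0.2,
                                           events=[severe_event])
        for obs in (plain, with_phenotypes):
            score = score_mouse(obs, rubric)
            assert score.total == 75 and score.died
            assert score.seizure_points is None  # components not applicable

    def test_unaffected_survivor_scores_zero(self, rubric):
        score = score_mouse(make_observation(), rubric)
        assert score.total == 0 and not score.exceeds_death_flag

    def test_worst_survivor_scores_85_and_is_flagged(self, rubric):
        obs = make_observation(
            recovery={b: None for b in BEHAVIORS},
            events=[MotorEvent("seizure", 45, "high_or_constant", ""),
                    MotorEvent("hyperactivity", 45, "high_or_constant", "")],
        )
        score = score_mouse(obs, rubric)
        assert score.total == 85
        assert score.exceeds_death_flag  # surviving total above the 75 death score

    def test_hand_summed_fixture(self, rubric):
        """Four animals whose totals are added by hand from the table."""
        cohort = [
            # posture at 2 h (8) + grooming never (5), mild seizure (10)
            (make_observation("m1", "a",
                              recovery={"sternal_posture": 2.0,
                                        "grooming_eating_nesting": None},
                              events=[MotorEvent("seizure", 5, "low", "")]),
             8 + 5 + 10),
            # everything at 1 h: 4 + 3 + 2 + 1
            (make_observation("m2", "a", recovery={b: 1.0 for b in BEHAVIORS}), 10),
            # moderate hyperactivity only
            (make_observation("m3", "b",
                              events=[MotorEvent("hyperactivity", 20, "moderate", "")]),
             10),
            # death overrides a recorded severe seizure
            (make_observation("m4", "b", died=True,
                              events=[MotorEvent("seizure", 60, "high_or_constant", "")]),
             75),
        ]
        for obs, expected in cohort:
            assert score_mouse(obs, rubric).total == expected


# independently-written table for the exhaustive oracle
_ORACLE_EVENTS = {"seizure": [0, 10, 15, 20], "hyperactivity": [0, 5, 10, 15]}
_ORACLE_LATENCY = {
    "sternal_posture": {0.5: 0, 1.0: 4, 2.0: 8, 4.0: 12, 24.0: 20, None: 20},
    "unstimulated_movement": {0.5: 0, 1.0: 3, 2.0: 6, 4.0: 9, 24.0: 15, None: 15},
    "movement_without_ataxia": {0.5: 0, 1.0: 2, 2.0: 4, 4.0: 6, 24.0: 10, None: 10},
    "grooming_eating_nesting": {0.5: 0, 1.0: 1, 2.0: 2, 4.0: 3, 24.0: 5, None: 5},
}
_EVENT_FOR_SEVERITY = {
    0: [],
    1: [(5.0, "low")],
    2: [(20.0, "moderate")],
    3: [(45.0, "high_or_constant")],
}


def test_exhaustive_oracle_over_all_10000_combinations(rubric):
    """score_mouse equals direct table lookup over every severity/checkpoint combo."""
    checkpoint_options = [0.5, 1.0, 2.0, 4.0, None]  # None = beyond 4 h / no recovery
    max_seen = 0
    count = 0
    for s_seiz, s_hyper in itertools.product(range(4), repeat=2):
        events = [
            MotorEvent("seizure", d, i, "") for d, i in _EVENT_FOR_SEVERITY[s_seiz]
        ] + [
            MotorEvent("hyperactivity", d, i, "") for d, i in _EVENT_FOR_SEVERITY[s_hyper]
        ]
        for cps in itertools.product(checkpoint_options, repeat=4):
            obs = make_observation(recovery=dict(zip(BEHAVIORS, cps)), events=events)
            expected = (
                _ORACLE_EVENTS["seizure"][s_seiz]
                + _ORACLE_EVENTS["hyperactivity"][s_hyper]
                + sum(_ORACLE_LATENCY[b][cp] for b, cp in zip(BEHAVIORS, cps))
            )
            total = score_mouse(obs, rubric).total
            assert total == expected
            max_seen = max(max_seen, total)
            count += 1
    assert count == 10000
    assert max_seen == 85


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.integers(0, 3), st.integers(0, 3),
    st.lists(st.integers(0, 4), min_size=4, max_size=4),
    st.integers(0, 5),  # which dial to turn up
)
def test_monotonicity_under_worsening(s_seiz, s_hyper, cp_idx, dial):
    """Raising any severity or delaying any recovery never decreases the total."""
    from evadint import default_rubric
    rubric = default_rubric()
    checkpoint_options = [0.5, 1.0, 2.0, 4.0, None]

    def build(s1, s2, cps):
        events = [MotorEvent("seizure", d, i, "") for d, i in _EVENT_FOR_SEVERITY[s1]]
        events += [MotorEvent("hyperactivity", d, i, "") for d, i in _EVENT_FOR_SEVERITY[s2]]
        recovery = dict(zip(BEHAVIORS, (checkpoint_options[i] for i in cps)))
        return make_observation(recovery=recovery, events=events)

    base = score_mouse(build(s_seiz, s_hyper, cp_idx), rubric).total
    worse = [s_seiz, s_hyper] + list(cp_idx)
    worse[dial] = min(worse[dial] + 1, 3 if dial < 2 else 4)
    worse_total = score_mouse(
        build(worse[0], worse[1], worse[2:]), rubric
    ).total
    assert worse_total >= base


class TestCohort:
    def test_group_means(self, rubric):
        zeros = [make_observation(f"z{i}", "vehicle") for i in range(3)]
        dead = [make_observation(f"d{i}", "toxic", died=True) for i in range(2)]
        cohort = score_cohort(zeros + dead, rubric)
        assert cohort.group_means() == {"vehicle": 0.0, "toxic": 75.0}
        assert len(cohort.scores) == 5

    def test_permutation_invariance(self, rubric):
        animals = [
            make_observation(f"m{i}", f"g{i % 2}",
                             recovery={"sternal_posture": t})
            for i, t in enumerate([0.5, 1.0, 2.0, 4.0, 24.0, 0.5])
        ]
        shuffled = animals[:]
        random.Random(5).shuffle(shuffled)
        by_id = lambda cohort: {s.animal_id: s for s in cohort.scores}
        assert by_id(score_cohort(animals, rubric)) == by_id(score_cohort(shuffled, rubric))

    def test_duplicate_ids_rejected(self, rubric):
        with pytest.raises(ValueError, match="duplicate"):
            score_cohort([make_observation("m1"), make_observation("m1")], rubric)

    def test_blinding_does_not_change_totals(self, rubric, severe_event):
        animals = [
            make_observation("m1", "a", events=[severe_event]),
            make_observation("m2", "a", recovery={"sternal_posture": 4.0}),
            make_observation("m3", "b", died=True),
        ]
        mapping, blinded = assign_blinding(animals, seed=11)
        open_totals = {s.animal_id: s.total for s in score_cohort(animals, rubric).scores}
        blind_totals = {
            mapping.animal_by_code[s.animal_id]: s.total
            for s in score_cohort(blinded, rubric).scores
        }
        assert open_totals == blind_totals
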