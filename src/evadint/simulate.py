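"""Seeded synthetic cohorts with the structure the scoring assay assumes.

Each treatment arm is a phenomenological severity preset, not a
pharmacokinetic model: a latent severity ``theta`` orders the arms, and the
observable draws follow the qualitative picture of acute CNS oligonucleotide
toxicity — phenotypes worst in the first hours after anesthesia reversal,
full recovery by 24 h in survivors, deaths (when they occur) within minutes
of reversal, and vehicle animals essentially unaffected.

Recovery latencies are generated hierarchically: a log-normal base time for
regaining sternal posture, then gamma-distributed non-negative increments to
unstimulated movement, movement without ataxia, and normal grooming — so the
milestone ordering

    posture <= unstimulated movement <= no-ataxia <= grooming

holds sample-wise by construction (righting oneself is simpler than the
coordinated movement the later milestones require).  Continuous latencies
are then interval-censored at the checkpoint schedule: a flag is true at
every scheduled time at or after the draw, and draws beyond the window
yield "no recovery".

Event durations are drawn inside the severity band that was sampled
(mild: 1-10 min, moderate: 10-30 min, severe: 30 min plus an exponential
tail with mean 15 min) with the matching intensity label, so re-classifying
a simulated event recovers its sampled severity.

Preset numeric parameters are package choices calibrated to qualitative
descriptions and two printed anchors (vehicle cohorts total at most 4; a
death scores 75); no per-animal source trajectories exist to fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .observations import (
    CheckpointStatus,
    MotorEvent,
    MouseObservation,
    write_observations,
)
from .rubric import DEFAULT_CHECKPOINTS_H, LATENCY_CATEGORIES, Severity

__all__ = [
    "LatencyModel",
    "ArmParameters",
    "StudyDesign",
    "PRESET_NAMES",
    "preset",
    "default_design",
    "simulate_mouse",
    "simulate_cohort",
]

#: Shape of the gamma increments between successive recovery milestones.
GAMMA_INCREMENT_SHAPE = 2.0

#: Exponential tail mean (minutes) added past 30 min for severe events.
SEVERE_TAIL_MEAN_MIN = 15.0

_SEVERITY_ORDER = (Severity.NONE, Severity.MILD, Severity.MODERATE, Severity.SEVERE)

_INTENSITY_FOR_SEVERITY = {
    Severity.MILD: "low",
    Severity.MODERATE: "moderate",
    Severity.SEVERE: "high_or_constant",
}

_DESCRIPTOR_FOR_SEVERITY = {
    ("seizure", Severity.MILD): "short infrequent bursts",
    ("seizure", Severity.MODERATE): "repetitive twitching",
    ("seizure", Severity.SEVERE): "constant high-intensity contractions",
    ("hyperactivity", Severity.MILD): "twitching",
    ("hyperactivity", Severity.MODERATE): "slight hopping",
    ("hyperactivity", Severity.SEVERE): "popcorning",
}


@dataclass(frozen=True)
class LatencyModel:
    """Hierarchical recovery-time model for one arm.

    ``base_log_mean_h``/``base_log_sd_h`` parameterize the log-normal sternal
    posture recovery time (hours); ``increment_scales_h`` are the gamma scale
    parameters (shape fixed at :data:`GAMMA_INCREMENT_SHAPE`) of the three
    non-negative increments to the later milestones.
    """

    base_log_mean_h: float
    base_log_sd_h: float
    increment_scales_h: tuple[float, float, float]

    def draw_recovery_times(self, rng: np.random.Generator) -> dict[str, float]:
        t = float(rng.lognormal(self.base_log_mean_h, self.base_log_sd_h))
        times = {"sternal_posture": t}
        for behavior, scale in zip(LATENCY_CATEGORIES[1:], self.increment_scales_h):
            t += float(rng.gamma(GAMMA_INCREMENT_SHAPE, scale)) if scale > 0 else 0.0
            times[behavior] = t
        return times


@dataclass(frozen=True)
class ArmParameters:
    """Severity preset for one treatment arm."""

    label: str
    theta: float  # latent severity in [0, 1]; orders the arms
    p_death: float
    seizure_probs: tuple[float, float, float, float]  # P(none/mild/moderate/severe)
    hyper_probs: tuple[float, float, float, float]
    latency: LatencyModel
    death_time_range_h: tuple[float, float] = (0.05, 0.4)  # before the first checkpoint

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 <= self.p_death <= 1.0:
            raise ValueError(f"p_death must be a probability, got {self.p_death}")
        for name, probs in (("seizure", self.seizure_probs), ("hyperactivity", self.hyper_probs)):
            if len(probs) != 4 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} severity probabilities must be a 4-simplex, got {probs}")
        if any(s < 0 for s in self.latency.increment_scales_h):
            raise ValueError("increment scales must be non-negative")


@dataclass(frozen=True)
class StudyDesign:
    """A full simulated study: arms, per-arm sample size, schedule, seed."""

    arms: tuple[ArmParameters, ...]
    n_per_arm: int = 8
    checkpoints_h: tuple[float, ...] = DEFAULT_CHECKPOINTS_H
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate arm labels: {labels}")


PRESET_NAMES: tuple[str, ...] = ("vehicle", "mixed_psop", "full_ps", "ps_dna")

_PRESETS: dict[str, ArmParameters] = {
    # Vehicle-injected animals: righting and movement back within ~10 min,
    # all milestones well inside the first hour, no events, no deaths.
    "vehicle": ArmParameters(
        label="vehicle",
        theta=0.0,
        p_death=0.0,
        seizure_probs=(1.0, 0.0, 0.0, 0.0),
        hyper_probs=(1.0, 0.0, 0.0, 0.0),
        latency=LatencyModel(
            base_log_mean_h=np.log(0.08),
            base_log_sd_h=0.15,
            increment_scales_h=(0.02, 0.04, 0.06),
        ),
    ),
    # Mixed PS/PO backbone: mild, fast-resolving hypoactivity, occasional
    # mild events.
    "mixed_psop": ArmParameters(
        label="mixed_psop",
        theta=0.35,
        p_death=0.0,
        seizure_probs=(0.80, 0.20, 0.0, 0.0),
        hyper_probs=(0.60, 0.40, 0.0, 0.0),
        latency=LatencyModel(
            base_log_mean_h=np.log(0.45),
            base_log_sd_h=0.30,
            increment_scales_h=(0.08, 0.12, 0.15),
        ),
    ),
    # Full PS backbone: hours-long hypoactivity with occasional
    # mild/moderate seizures and hyperactivity, but survival.
    "full_ps": ArmParameters(
        label="full_ps",
        theta=0.75,
        p_death=0.0,
        seizure_probs=(0.45, 0.35, 0.20, 0.0),
        hyper_probs=(0.30, 0.40, 0.30, 0.0),
        latency=LatencyModel(
            base_log_mean_h=np.log(1.5),
            base_log_sd_h=0.35,
            increment_scales_h=(0.30, 0.50, 0.70),
        ),
    ),
    # Fully PS-modified DNA: severe seizures within minutes of reversal and
    # uniformly lethal before the first checkpoint.
    "ps_dna": ArmParameters(
        label="ps_dna",
        theta=1.0,
        p_death=1.0,
        seizure_probs=(0.0, 0.0, 0.0, 1.0),
        hyper_probs=(1.0, 0.0, 0.0, 0.0),
        latency=LatencyModel(
            base_log_mean_h=np.log(4.0),
            base_log_sd_h=0.5,
            increment_scales_h=(0.5, 0.8, 1.0),
        ),
    ),
}


def preset(name: str) -> ArmParameters:
    """A named arm preset: vehicle, mixed_psop, full_ps or ps_dna."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}") from None


def default_design(seed: int = 0, n_per_arm: int = 8) -> StudyDesign:
    """Four-arm study over the presets at the default checkpoint schedule."""
    return StudyDesign(
        arms=tuple(preset(name) for name in PRESET_NAMES),
        n_per_arm=n_per_arm,
        seed=seed,
    )


def _draw_severity(probs: Sequence[float], rng: np.random.Generator) -> Severity:
    return _SEVERITY_ORDER[int(rng.choice(4, p=np.asarray(probs, dtype=float)))]


def _draw_event(category: str, severity: Severity, rng: np.random.Generator) -> MotorEvent:
    if severity is Severity.MILD:
        duration = float(rng.uniform(1.0, 10.0))
    elif severity is Severity.MODERATE:
        duration = float(rng.uniform(10.0, 30.0))
    else:
        duration = 30.0 + float(rng.exponential(SEVERE_TAIL_MEAN_MIN))
    return MotorEvent(
        category=category,
        duration_min=duration,
        intensity=_INTENSITY_FOR_SEVERITY[severity],
        descriptor=_DESCRIPTOR_FOR_SEVERITY[(category, severity)],
    )


def simulate_mouse(
    arm: ArmParameters,
    rng: np.random.Generator,
    checkpoints_h: tuple[float, ...] = DEFAULT_CHECKPOINTS_H,
    animal_id: str = "m001",
) -> MouseObservation:
    """One animal's observation record drawn from an arm's preset."""
    died = bool(rng.random() < arm.p_death)
    events: list[MotorEvent] = []
    for category, probs in (("seizure", arm.seizure_probs), ("hyperactivity", arm.hyper_probs)):
        severity = _draw_severity(probs, rng)
        if severity is not Severity.NONE:
            events.append(_draw_event(category, severity, rng))

    if died:
        death_time = float(rng.uniform(*arm.death_time_range_h))
        checkpoints = tuple(
            CheckpointStatus(time_h=t, alive=False) for t in checkpoints_h
        )
        return MouseObservation(
            animal_id=animal_id, group_label=arm.label, checkpoints=checkpoints,
            events=tuple(events), died=True, death_time_h=death_time,
        )

    recovery = arm.latency.draw_recovery_times(rng)
    checkpoints = tuple(
        CheckpointStatus(
            time_h=t,
            alive=True,
            **{behavior: bool(t >= recovery[behavior]) for behavior in LATENCY_CATEGORIES},
        )
        for t in checkpoints_h
    )
    return MouseObservation(
        animal_id=animal_id, group_label=arm.label, checkpoints=checkpoints,
        events=tuple(events), died=False, death_time_h=None,
    )


def simulate_cohort(
    design: StudyDesign,
    out_dir: Union[str, Path, None] = None,
) -> list[MouseObservation]:
    """Simulate every arm of a design; optionally write the canonical CSVs.

    Each animal gets its own RNG substream keyed by (arm index, animal
    index) spawned from the design seed, so appending an arm or growing a
    cohort leaves existing animals' draws untouched.
    """
    observations: list[MouseObservation] = []
    for arm_idx, arm in enumerate(design.arms):
        for animal_idx in range(design.n_per_arm):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=design.seed, spawn_key=(arm_idx, animal_idx))
            )
            obs = simulate_mouse(
                arm, rng, design.checkpoints_h,
                animal_id=f"{arm.label}-{animal_idx + 1:02d}",
            )
            observations.append(obs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_observations(observations, out_dir / "observations.csv",
                           out_dir / "events.csv")
    return observations
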