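"""Rank-stability analysis under rubric weight perturbation.

The scoring table's weights were chosen on an intuitive severity ordering,
so the analysis here asks the natural sensitivity question: if the relative
weightings of death, seizures and the behavioral milestones are changed,
do the treatment arms keep their toxicity ranking?  Each perturbation
rescales rubric rows by independent log-uniform factors, the same animals
are re-scored, and the ranking of arm means is compared to the baseline
ranking with Kendall's tau-b.

Perturbation never changes an animal's event severities or recovery
checkpoints — only the points attached to them — so re-scoring is exact,
not resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .observations import MouseObservation
from .rubric import (
    EVENT_CATEGORIES,
    LATENCY_CATEGORIES,
    Rubric,
    validate_rubric,
)
from .scoring import score_cohort

__all__ = [
    "PerturbationSpec",
    "RobustnessReport",
    "draw_category_factors",
    "apply_category_factors",
    "perturb_rubric",
    "rank_concordance",
    "robustness_analysis",
    "report_to_frame",
]

#: Order in which per-category factors are drawn and applied:
#: seizure (shared with the death score), hyperactivity, then the four
#: recovery milestones.
FACTOR_ORDER: tuple[str, ...] = EVENT_CATEGORIES + LATENCY_CATEGORIES


@dataclass(frozen=True)
class PerturbationSpec:
    """How to jitter the rubric.

    ``factor`` bounds the multiplicative range [1/factor, factor]; draws are
    log-uniform so up- and down-weighting are symmetric.  ``per_category``
    scales whole rows (death tied to the seizure row); ``per_cell`` jitters
    individual cells and re-sorts each row to preserve monotonicity.
    """

    factor: float = 2.0
    n_perturbations: int = 1000
    seed: int = 0
    scope: str = "per_category"  # "per_category" | "per_cell"

    def __post_init__(self) -> None:
        if not self.factor >= 1.0:
            raise ValueError(f"factor must be >= 1, got {self.factor}")
        if self.n_perturbations < 1:
            raise ValueError(f"n_perturbations must be >= 1, got {self.n_perturbations}")
        if self.scope not in ("per_category", "per_cell"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class RobustnessReport:
    """Outcome of a perturbation sweep."""

    baseline_ranking: tuple[str, ...]  # groups ordered by increasing mean total
    baseline_means: Mapping[str, float]
    concordances: tuple[float, ...]  # Kendall tau-b per perturbation
    spec: PerturbationSpec

    @property
    def fraction_perfect(self) -> float:
        return float(np.mean([c == 1.0 for c in self.concordances]))

    @property
    def mean_concordance(self) -> float:
        return float(np.mean(self.concordances))

    @property
    def min_concordance(self) -> float:
        return float(np.min(self.concordances))


def _rng_for_draw(spec: PerturbationSpec, draw_index: int) -> np.random.Generator:
    # independent substream per draw; same (seed, draw_index) -> same rubric
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(draw_index,))
    )


def _log_uniform(rng: np.random.Generator, factor: float, size=None):
    span = np.log(factor)
    return np.exp(rng.uniform(-span, span, size=size))


def draw_category_factors(spec: PerturbationSpec, draw_index: int) -> dict[str, float]:
    """Log-uniform factor per rubric row for one draw (per_category scope)."""
    rng = _rng_for_draw(spec, draw_index)
    return {cat: float(_log_uniform(rng, spec.factor)) for cat in FACTOR_ORDER}


def apply_category_factors(rubric: Rubric, factors: Mapping[str, float]) -> Rubric:
    """Rescale each rubric row by its factor; the death score follows seizure.

    The death score is floored at the largest single-category maximum so the
    perturbed table still dominates every row, as the table's own structure
    requires.
    """
    events = {
        cat: replace(w, points_by_severity=tuple(p * factors[cat] for p in w.points_by_severity))
        for cat, w in rubric.event_weights.items()
    }
    latencies = {
        cat: replace(w, points=tuple(p * factors[cat] for p in w.points))
        for cat, w in rubric.latency_weights.items()
    }
    death = rubric.death_score * factors["seizure"]
    row_max = max(
        [max(w.points_by_severity) for w in events.values()]
        + [max(w.points) for w in latencies.values()]
    )
    return replace(rubric, event_weights=events, latency_weights=latencies,
                   death_score=max(death, row_max))


def _perturb_per_cell(rubric: Rubric, spec: PerturbationSpec,
                      rng: np.random.Generator) -> Rubric:
    def jitter_row(points: Sequence[float]) -> tuple[float, ...]:
        jittered = [p * float(_log_uniform(rng, spec.factor)) for p in points]
        return tuple(sorted(jittered))  # re-sort to keep monotone rows; zeros stay first

    events = {
        cat: replace(w, points_by_severity=jitter_row(w.points_by_severity))
        for cat, w in rubric.event_weights.items()
    }
    latencies = {
        cat: replace(w, points=jitter_row(w.points))
        for cat, w in rubric.latency_weights.items()
    }
    death = rubric.death_score * float(_log_uniform(rng, spec.factor))
    row_max = max(
        [max(w.points_by_severity) for w in events.values()]
        + [max(w.points) for w in latencies.values()]
    )
    return replace(rubric, event_weights=events, latency_weights=latencies,
                   death_score=max(death, row_max))


def perturb_rubric(rubric: Rubric, spec: PerturbationSpec, draw_index: int) -> Rubric:
    """One seeded perturbed rubric; output always passes ``validate_rubric``."""
    if spec.scope == "per_category":
        perturbed = apply_category_factors(rubric, draw_category_factors(spec, draw_index))
    else:
        perturbed = _perturb_per_cell(rubric, spec, _rng_for_draw(spec, draw_index))
    violations = validate_rubric(perturbed)
    if violations:  # defensive: construction above should preclude this
        raise AssertionError(f"perturbed rubric invalid: {violations}")
    return perturbed


def rank_concordance(
    means_a: Mapping[str, float], means_b: Mapping[str, float]
) -> float:
    """Kendall tau-b between two group-mean maps over the same groups."""
    if set(means_a) != set(means_b):
        raise ValueError(
            f"group keys differ: {sorted(means_a)} vs {sorted(means_b)}"
        )
    keys = sorted(means_a)
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    a = np.array([means_a[k] for k in keys], dtype=float)
    b = np.array([means_b[k] for k in keys], dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("rank concordance undefined for an all-tied mean vector")
    tau = stats.kendalltau(a, b, variant="b").statistic
    return float(tau)


def robustness_analysis(
    observations: Sequence[MouseObservation],
    rubric: Rubric,
    spec: PerturbationSpec,
) -> RobustnessReport:
    """Score the baseline, re-score under each perturbed rubric, compare rankings."""
    baseline = score_cohort(observations, rubric, provenance={"analysis": "robustness"})
    baseline_means = baseline.group_means()
    if len(baseline_means) < 2:
        raise ValueError("robustness analysis needs at least 2 groups")
    ranking = tuple(sorted(baseline_means, key=baseline_means.__getitem__))

    concordances = []
    for i in range(spec.n_perturbations):
        perturbed_rubric = perturb_rubric(rubric, spec, i)
        perturbed = score_cohort(observations, perturbed_rubric,
                                 provenance={"analysis": "robustness", "draw": i})
        concordances.append(rank_concordance(baseline_means, perturbed.group_means()))
    return RobustnessReport(
        baseline_ranking=ranking,
        baseline_means=dict(baseline_means),
        concordances=tuple(concordances),
        spec=spec,
    )


def report_to_frame(report: RobustnessReport) -> pd.DataFrame:
    """Per-perturbation table plus summary rows, for TSV output."""
    rows = [
        {"perturbation": i, "kendall_tau_b": tau}
        for i, tau in enumerate(report.concordances)
    ]
    frame = pd.DataFrame(rows, columns=["perturbation", "kendall_tau_b"])
    summary = pd.DataFrame(
        [
            {"perturbation": "fraction_perfect", "kendall_tau_b": report.fraction_perfect},
            {"perturbation": "mean", "kendall_tau_b": report.mean_concordance},
            {"perturbation": "min", "kendall_tau_b": report.min_concordance},
        ]
    )
    return pd.concat([frame, summary], ignore_index=True)
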