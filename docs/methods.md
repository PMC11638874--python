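# Methods

## The scoring model

Each animal is observed at a shared checkpoint schedule (default 0.5, 1, 2, 4
and 24 h after anesthesia reversal; t = 0 is the reversal injection) and its
seizure / hyperactivity episodes are logged with duration and intensity. The
composite score has six additive components for survivors and a fixed
override for deaths.

**Event components.** An episode's severity is the maximum of a duration
class and an intensity class ("and/or" rule):

| class    | duration        | intensity          |
|----------|-----------------|--------------------|
| mild     | < 10 min        | low                |
| moderate | 10–30 min       | moderate           |
| severe   | > 30 min        | high / constant    |

Boundary durations of exactly 10 and exactly 30 min are classed moderate
(mild is strictly "< 10", severe strictly "> 30"). Multiple episodes of one
category aggregate by **maximum** severity, not sum — the table allots one
severity cell per category, and short infrequent bursts are already folded
into "mild". Seizure and hyperactivity are scored independently and
additively; the rubric presents them as separate rows and nothing makes them
exclusive, so an episode that is both could in principle count twice. That is
an operationalization choice, documented here rather than hidden. The
three-level intensity vocabulary is likewise our operationalization of
qualitative field descriptions ("constant high-intensity contractions",
"slight hopping").

**Latency components.** For each of four milestones (sternal posture,
unstimulated movement, movement without ataxia, normal
grooming/eating/nesting) the scored checkpoint is the earliest scheduled time
from which the behavior flag is true **through the end of observation**
(sustained-recovery rule). Behavior that relapses after apparent recovery
therefore scores from the start of the final uninterrupted run of true flags;
validation flags relapses as warnings because the milestone being scored is
*maintenance* of the behavior. Recovery latencies are interval-censored at
the checkpoints: recovery anywhere in (1 h, 2 h] scores the 2 h column
(e.g. 8 points for sternal posture). The final column conflates
recovery-at-the-last-checkpoint with never recovering; recovery between 4 h
and 24 h scores that final column.

**Death.** Death at any time inside the window assigns the fixed death score
(default 75) and discards partial pre-death components. Death is a
rubric-level override, not a fifth severity of the seizure row: it applies
whatever killed the animal. Surviving totals are **not** capped at the death
score — the component maxima sum to 85 under the default table — and a
surviving total above the death score raises `exceeds_death_flag` instead of
being truncated, since the definition of a survivor's score is the plain sum.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| checkpoint schedule | 0.5, 1, 2, 4, 24 h | shared across all latency rows |
| event rows | seizure 0/10/15/20; hyperactivity 0/5/10/15 | points by severity |
| latency rows | 0/4/8/12/20; 0/3/6/9/15; 0/2/4/6/10; 0/1/2/3/5 | points by checkpoint column |
| `death_score` | 75 | override for deaths; must dominate every single row maximum |
| `observation_window_h` | 24 | deaths past the window are not scored as deaths |

All of these can be overridden through a YAML document merged onto the
defaults (`load_rubric`); invariants (non-negativity, monotonicity in
severity and in checkpoint, zero first column, dominating death score,
shared schedule) are enforced and violations are reported cell by cell.

## Group statistics

Arm comparisons use the definitional one-way fixed-effects ANOVA
(`F = MSB/MSW`) and Tukey–Kramer HSD,
`q_ij = |m_i − m_j| / sqrt(MSW/2 · (1/n_i + 1/n_j))`, with adjusted p-values
from the studentized-range distribution on (k, N − k); scipy supplies that
distribution function (tail probabilities good to well under 1e−6, the
tolerance we test at). Totals are treated as continuous despite the integer
rubric cells, matching how such scores are analyzed in practice. A group
that is all ties (e.g. a uniformly lethal arm at 75) strains the normality
assumption; the statistics still run with a warning, and only a zero pooled
within-group variance is a hard error. Because figure conventions alternate
between SD and SEM error bars, summaries report both.

## Weight robustness

The rubric weights encode an intuitive severity ordering, so we test whether
conclusions depend on them. `per_category` scope (default) draws one
log-uniform factor in [1/f, f] (default f = 2) per rubric row — the death
score shares the seizure row's factor — because the weighting question is
factor-level ("death, seizures, and the other behavioral observations"), and
log-uniform makes up- and down-weighting symmetric. `per_cell` scope jitters
individual cells and re-sorts each row to restore monotonicity. One subtlety:
independent factors can push a latency row's maximum above the scaled death
score, which would break the dominance invariant, so the perturbed death
score is floored at the largest single-category maximum. The floor is
inactive when all factors are equal, so global rescaling leaves every ranking
and every ratio exactly invariant.

Each perturbation re-scores the **same** animals (severities and recovery
checkpoints never change, only the points attached to them) and the ranking
of arm means is compared with the baseline ranking via Kendall's tau-b;
reports carry the per-draw coefficients, their mean and minimum, and the
fraction of draws with perfect concordance. Group means (rather than
medians) are compared because arm effects are assessed by ANOVA on means.

Rank stability has a real boundary: arms are provably order-stable under
*every* admissible weighting only when one arm's weighted mean cannot cross
another's — e.g. an all-zero arm vs. anything, any surviving arm whose
doubled mean stays below the floored minimum death score vs. a uniformly
lethal arm, or arms whose per-component means dominate each other. A
severely affected *surviving* arm and a lethal arm can swap when seizures
and death are down-weighted by 2 while latencies are up-weighted by 2; at
factor 2 this costs a few percent of draws on the four-preset simulation.
That is a property of the weighting scheme worth knowing, not a failure of
the analysis.

## The synthetic cohort generator

The generator emulates the study conditions the scorer was designed for:
phenotypes worst in the first 1–3 h, survivors fully recovered by 24 h,
deaths (when they occur) within minutes of reversal, vehicle animals
essentially unaffected. Each arm is a phenomenological severity preset with
a latent ordering parameter θ:

| preset | θ | p(death) | events | posture base latency |
|---|---|---|---|---|
| `vehicle` | 0.0 | 0 | none | lognormal(ln 0.08 h, 0.15) |
| `mixed_psop` | 0.35 | 0 | mild seizure 20%, mild hyperactivity 40% | lognormal(ln 0.45 h, 0.30) |
| `full_ps` | 0.75 | 0 | mild/moderate seizures 55%, hyperactivity 70% | lognormal(ln 1.5 h, 0.35) |
| `ps_dna` | 1.0 | 1 | severe seizure, always | (not reached) |

Recovery times are hierarchical: a log-normal base latency for sternal
posture plus three gamma-distributed non-negative increments (shape 2,
per-arm scales) to the later milestones, so the ordering posture ≤
unstimulated movement ≤ no-ataxia ≤ grooming holds in every sampled animal
by construction — righting oneself is simpler than the coordinated movement
the later milestones need. Continuous draws are censored to checkpoint
flags; draws past the window become "no recovery". Event durations are drawn
inside the sampled severity band (mild U(1,10) min, moderate U(10,30),
severe 30 + Exp(15)) with matching intensity, so re-classifying a simulated
event returns its sampled severity. Deaths occur uniformly in (0.05, 0.4) h,
before the first checkpoint. Randomness is hierarchical
(`SeedSequence(seed, spawn_key=(arm, animal))`), so appending an arm or
enlarging a cohort never changes existing animals' draws and all outputs are
byte-reproducible from the design seed.

The preset numbers are package choices calibrated to qualitative
descriptions and exactly two printed anchors — vehicle cohorts total at most
4 (the vehicle latency parameters put all four milestones inside the first
hour with overwhelming probability, so totals of 0–3 dominate and the worst
case stays ≤ 4), and deaths score 75. No per-animal source trajectories
exist to fit. What the generator deliberately does **not** model: dose
response, pharmacokinetics, any mechanism (protein binding, ion chelation),
inter-observer noise, relapsing phenotypes, or deaths late in the window for
the presets. Passing tests on simulated cohorts therefore demonstrate that
the pipeline's logic and statistics behave correctly under the assumed data
structure — not that real cohorts will show these effect sizes.

## Numerical and interface choices

- Scores are exact integer-valued arithmetic on the default table (no
  rounding anywhere); component additivity is exact.
- CSV ingestion is strict: fixed headers, booleans only from
  {0,1,true,false,yes,no}, duplicate (animal, checkpoint) rows rejected with
  the row number. Dead rows carry empty behavior cells. Observations record
  only checkpoint-resolved data; continuous observation is out of scope.
- A death time read from a sheet is the first checkpoint with alive = 0
  (the schema cannot carry a finer time), while the simulator keeps its
  continuous draw in memory; files round-trip byte-exactly
  (write → read → write is the identity on the canonical dialect).
- Blinding replaces ids by a seeded permutation of opaque codes and strips
  group labels; scoring is blind-safe (identical totals either way).
- Problem sizes in the validation suite — 10,000-combination exhaustive
  scoring oracle, 100–200 seeds for the vehicle ceiling and stochastic
  ordering checks, 1000 weight perturbations — were chosen so each suite
  section completes in seconds while the Monte Carlo assertions sit far from
  their thresholds.

## Known limitations

- The scorer assumes one scoring pass per animal; inter-rater reliability is
  out of scope.
- Double counting of one episode as both seizure and hyperactivity is
  permitted (see above).
- The latency rows cannot distinguish recovery at the final checkpoint from
  no recovery; a finer schedule is the only remedy.
- The weight-robustness analysis is empirical over sampled weightings; it
  does not derive the region of weight space that preserves a ranking.
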