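"""Multi-criteria competition scoring for toxicity-modelling submissions.

A team submits one or more models, each predicting a toxicity endpoint.
Each model n carries:

* ``A1`` — dataset-quality coefficient (0 or 1; 0 eliminates the model),
* ``A2`` — model-quality multiplier, 1 unless the model improves on its
  cited benchmark by at least 5% (regression RMSE) or 3% (classification
  ROC AUC) under five-fold CV, in which case A2 = 1 + M/100 (regression) or
  1 + M/50 (classification), M being the percentage improvement,
* ``A3``/``a3`` — dataset-extent and sample-uniqueness rank points
  (1 / 0.75 / 0.5 for the top three positions, ties share evenly,
  positions beyond third score 0),
* ``a4`` — data-acquisition difficulty, ``a5`` — number-of-sources points,
* ``a8`` — chemical-space diversity point, ``a10`` — interpretability point.

Team-level points: ``a7`` (notebook checklist, 0–3), ``a7'`` (presentation
checklist, 0–3), ``a9`` (unique-endpoint point).  The team score is

    Score = Σₙ A1ₙ·A2ₙ·A3ₙ·(a3ₙ + a4ₙ + a5ₙ + a8ₙ + a10ₙ) + a7 + a7' + a9

and is forced to 0 when the submission is incomplete or no model has
A1 ≠ 0.  The published formula's grouping is ambiguous; the grouping above
is the only one consistent with endpoints being scored individually with
their multipliers while the notebook/presentation/uniqueness points are
per-team.  Setting ``extent_as_bonus`` replaces the annihilating A3 factor
with (1 + A3) for sensitivity analysis; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .modelkit import EvalConfig
from .molio import Task

__all__ = [
    "ModelEntry",
    "ScoreSheet",
    "model_multiplier",
    "rank_points",
    "difficulty_points",
    "source_points",
    "checklist_points",
    "team_score",
]

RANK_SCHEDULE = (1.0, 0.75, 0.5)


def model_multiplier(
    task: Task,
    baseline_metric: float,
    achieved_metric: float,
    config: EvalConfig = EvalConfig(),
) -> float:
    """Model-quality multiplier A2 from a benchmark comparison.

    M is the relative percentage improvement over the benchmark mean:
    100·(baseline − achieved)/baseline for regression (lower RMSE is
    better), 100·(achieved − baseline)/baseline for classification.  Below
    the task's improvement threshold the multiplier is 1; at or above it,
    1 + M/100 (regression) or 1 + M/50 (classification).
    """
    import math

    if not (math.isfinite(baseline_metric) and math.isfinite(achieved_metric)):
        raise ValueError("metrics must be finite")
    if task == Task.REGRESSION:
        if baseline_metric <= 0:
            raise ValueError("baseline RMSE must be > 0")
        M = 100.0 * (baseline_metric - achieved_metric) / baseline_metric
        threshold = config.regression_improve_threshold
        return 1.0 + M / 100.0 if M >= threshold else 1.0
    else:
        if not 0 < baseline_metric < 1:
            raise ValueError("baseline ROC AUC must be in (0, 1)")
        M = 100.0 * (achieved_metric - baseline_metric) / baseline_metric
        threshold = config.classification_improve_threshold
        return 1.0 + M / 50.0 if M >= threshold else 1.0


def rank_points(
    values: Sequence[float],
    schedule: Sequence[float] = RANK_SCHEDULE,
    larger_is_better: bool = True,
) -> list[float]:
    """Top-three rank points with even sharing among ties.

    The best value gets ``schedule[0]``, the next ``schedule[1]``, etc.;
    positions beyond the schedule get 0.  A tie spanning positions p..q
    shares the mean of those slots (slots past the schedule contribute 0),
    so the total awarded over occupied top slots is conserved.
    """
    if not values:
        raise ValueError("need at least one value")
    order = sorted(values, reverse=larger_is_better)
    slot = [
        schedule[i] if i < len(schedule) else 0.0 for i in range(len(values))
    ]
    points: dict[float, float] = {}
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and order[j] == order[i]:
            j += 1
        points[order[i]] = sum(slot[i:j]) / (j - i)
        i = j
    return [points[v] for v in values]


def difficulty_points(
    scraped_no_api_sources: int = 0,
    api_sources: int = 0,
    manual_sources: int = 0,
) -> float:
    """Points for the difficulty of acquiring the data.

    1 for scraping without an API from ≥1 source, API download from ≥3
    sources, or manual search of ≥5 sources; 0.5 for API from ≥1 or manual
    from ≥3; 0.25 for a manual search of one source; else 0.
    """
    if scraped_no_api_sources >= 1 or api_sources >= 3 or manual_sources >= 5:
        return 1.0
    if api_sources >= 1 or manual_sources >= 3:
        return 0.5
    if manual_sources >= 1:
        return 0.25
    return 0.0


def source_points(n_sources: int) -> float:
    """Points for the number of experimental-data sources: >5 → 1,
    4–5 → 0.75, 2–3 → 0.5, 1 → 0."""
    if n_sources > 5:
        return 1.0
    if n_sources >= 4:
        return 0.75
    if n_sources >= 2:
        return 0.5
    return 0.0


def checklist_points(items: Sequence[bool], fatal: bool = False) -> int:
    """Notebook/presentation checklist: one point per satisfied item, but a
    fatal defect (notebook not runnable end-to-end, factual errors) zeroes
    the whole checklist."""
    if len(items) != 3:
        raise ValueError("checklists have exactly 3 items")
    return 0 if fatal else int(sum(bool(x) for x in items))


_A3_ALLOWED_EXACT = {1.0, 0.75, 0.5, 0.0}
_A4_ALLOWED = {1.0, 0.5, 0.25, 0.0}
_A5_ALLOWED = {1.0, 0.75, 0.5, 0.0}


@dataclass(frozen=True)
class ModelEntry:
    """Per-model coefficients feeding one term of the team score."""

    endpoint_id: str
    task: Task
    A1: float
    baseline_metric: float
    achieved_metric: float
    A3: float
    a3: float
    a4: float
    a5: float
    a8: float
    a10: float

    def __post_init__(self) -> None:
        if self.A1 not in (0.0, 1.0):
            raise ValueError("A1 must be 0 or 1")
        # A3/a3 may take intermediate values through tie sharing
        for name, allowed in (("a4", _A4_ALLOWED), ("a5", _A5_ALLOWED)):
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {sorted(allowed)}")
        for name in ("a8", "a10"):
            if getattr(self, name) not in (0.0, 1.0):
                raise ValueError(f"{name} must be 0 or 1")
        for name in ("A3", "a3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ScoreSheet:
    """A team's models plus team-level points; model count is a6."""

    team_id: str
    models: list[ModelEntry] = field(default_factory=list)
    a7: int = 0
    a7_prime: int = 0
    a9: float = 0.0
    files_complete: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.a7 <= 3 or not 0 <= self.a7_prime <= 3:
            raise ValueError("a7 and a7' must be integers in [0, 3]")
        if self.a9 not in (0.0, 1.0):
            raise ValueError("a9 must be 0 or 1")

    @property
    def a6(self) -> int:
        return len(self.models)


def team_score(
    sheet: ScoreSheet,
    config: EvalConfig = EvalConfig(),
    extent_as_bonus: bool = False,
) -> float:
    """Total team score under the eligibility conditions.

    Returns 0 if the required files are incomplete or every model has
    A1 = 0.  Otherwise each model contributes
    A1·A2·A3·(a3 + a4 + a5 + a8 + a10), with A2 recomputed from the
    baseline/achieved metrics, and a7 + a7' + a9 are added once.
    """
    if not sheet.files_complete:
        return 0.0
    if not any(m.A1 != 0 for m in sheet.models):
        return 0.0
    total = 0.0
    for m in sheet.models:
        A2 = model_multiplier(m.task, m.baseline_metric, m.achieved_metric, config)
        extent = (1.0 + m.A3) if extent_as_bonus else m.A3
        total += m.A1 * A2 * extent * (m.a3 + m.a4 + m.a5 + m.a8 + m.a10)
    return total + sheet.a7 + sheet.a7_prime + sheet.a9
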