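"""Score two competition submissions with the multi-criteria formula.

Each model term is A1·A2·A3·(a3+a4+a5+a8+a10): dataset-quality gate,
metric-improvement multiplier, dataset-extent rank points, then the summed
uniqueness/difficulty/sources/diversity/interpretability points.  Notebook,
presentation and endpoint-uniqueness points are added once per team.
"""

from toxforge import (
    ModelEntry, ScoreSheet, Task, difficulty_points, rank_points,
    source_points, team_score,
)

# dataset-extent points from the two teams' dataset sizes (tie-aware)
extents = rank_points([24000, 18000])

team_a = ScoreSheet(
    "team_a",
    [
        ModelEntry("rat_oral_ld50", Task.REGRESSION, A1=1.0,
                   baseline_metric=0.592, achieved_metric=0.466,
                   A3=extents[0], a3=1.0,
                   a4=difficulty_points(scraped_no_api_sources=1),
                   a5=source_points(6), a8=1.0, a10=1.0),
    ],
    a7=3, a7_prime=2, a9=1.0,
)
team_b = ScoreSheet(
    "team_b",
    [
        ModelEntry("ames", Task.CLASSIFICATION, A1=1.0,
                   baseline_metric=0.88, achieved_metric=0.894,
                   A3=extents[1], a3=0.75,
                   a4=difficulty_points(api_sources=1),
                   a5=source_points(3), a8=0.0, a10=1.0),
    ],
    a7=2, a7_prime=3, a9=0.0,
)

for sheet in (team_a, team_b):
    print(f"{sheet.team_id}: Score = {team_score(sheet):.3f}")
print("team_a's 21.3% RMSE improvement earns multiplier 1.213; team_b's")
print("1.6% AUC gain is below the 3% threshold, so its multiplier stays 1")
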