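"""Pattern scoring: does a simulated end state show segment polarity?

The target pattern on the 1 x 4 row (cells numbered 1..4, parasegment
boundary between cells 2 and 3) is: *wingless* and *patched* mRNA high in
cell 2 only, *engrailed* and *hedgehog* mRNA high in cell 3 only.

The score is a worst-case ON/OFF contrast ratio evaluated at a single
late time (default t = 1000): for each scored species,

    sub = (max over OFF cells + delta) / (min over ON cells + delta)

with a small floor delta = 1e-6, and the total score is the max over
species.  A parameter set is a *hit* when score < 0.2, i.e. every OFF
cell expresses at most ~20% of the weakest ON cell.  There is no
stability component; scoring is expression-contrast only, which by
construction is permissive (it accepts at least every pattern a stricter
contrast-plus-stability composite would).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MRNAS, ODESystem
from .simulate import Trajectory, detect_failure

__all__ = [
    "HIT_THRESHOLD",
    "DELTA",
    "PatternTemplate",
    "ScoreResult",
    "default_template",
    "pattern_score",
    "classify_screen_run",
]

HIT_THRESHOLD = 0.2
DELTA = 1e-6


@dataclass(frozen=True)
class PatternTemplate:
    """ON/OFF target assignment per (species, cell index) plus the scoring time."""

    #: mapping species name -> tuple of per-cell booleans (True = ON)
    assignments: dict[str, tuple[bool, ...]]
    eval_time: float = 1000.0

    def __post_init__(self) -> None:
        for name, flags in self.assignments.items():
            if name not in MRNAS:
                raise ValueError(f"scored species must be an mRNA, got {name!r}")
            if not any(flags) or all(flags):
                raise ValueError(
                    f"{name}: template needs at least one ON and one OFF cell")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    @property
    def n_assignments(self) -> int:
        return sum(len(v) for v in self.assignments.values())


def default_template(grid_shape: tuple[int, int] = (1, 4), *,
                     include_ptc: bool = True,
                     eval_time: float = 1000.0) -> PatternTemplate:
    """Segment-polarity target for the 1 x 4 row.

    wg and ptc ON in cell 2 only; en and hh ON in cell 3 only (1-based cell
    numbering along the row).  ``include_ptc=False`` scores only
    {wg, en, hh} for sensitivity analysis.
    """
    if tuple(grid_shape) != (1, 4):
        raise ValueError(
            "the default template is defined for the 1x4 row; supply an "
            "explicit template for other grids")
    on2 = (False, True, False, False)
    on3 = (False, False, True, False)
    asg = {"wg": on2, "en": on3, "hh": on3}
    if include_ptc:
        asg["ptc"] = on2
    return PatternTemplate(assignments=asg, eval_time=eval_time)


@dataclass
class ScoreResult:
    score: float
    sub_scores: dict[str, float] = field(default_factory=dict)

    @property
    def hit(self) -> bool:
        return self.score < HIT_THRESHOLD


def pattern_score(traj: Trajectory, template: PatternTemplate,
                  model: ODESystem) -> ScoreResult:
    """Score a trajectory's state at the template's evaluation time.

    Raises if the trajectory failed (a failure is not scorable and must be
    tallied separately from a miss).
    """
    if detect_failure(traj):
        raise ValueError("failed trajectory is not scorable")
    if template.eval_time > traj.times[-1]:
        raise ValueError(
            f"evaluation time {template.eval_time} beyond trajectory end "
            f"{traj.times[-1]}")
    state = traj.at_time(template.eval_time)
    subs: dict[str, float] = {}
    for name, flags in template.assignments.items():
        conc = np.array([state[model.species_index(name, c)]
                         for c in range(len(flags))])
        on = conc[np.array(flags)]
        off = conc[~np.array(flags)]
        subs[name] = float((off.max() + DELTA) / (on.min() + DELTA))
    return ScoreResult(score=max(subs.values()), sub_scores=subs)


def classify_screen_run(traj: Trajectory, template: PatternTemplate,
                        model: ODESystem,
                        threshold: float = HIT_THRESHOLD) -> tuple[str, float | None]:
    """Three-way outcome of one screen attempt: hit / miss / failure.

    Returns ``(outcome, score)``; the score is None for failures.
    """
    if detect_failure(traj):
        return "failure", None
    sr = pattern_score(traj, template, model)
    return ("hit" if sr.score < threshold else "miss"), sr.score
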