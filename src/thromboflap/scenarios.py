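"""Intervention scenarios, break-even and ICER analysis.

Four scenarios are compared on the same cohort of ``N`` patients:

* **Baseline** — no screening, no prophylaxis; expected complications
  ``X = N * r``.
* **Full panel** — every patient is screened for every condition;
  test-positive patients receive prophylaxis at efficacy ``e``.
* **Limited panel** — same, but screening only a cheaper subset of
  conditions; complications among carriers of unscreened conditions (and
  among false negatives) are retained at full risk.
* **All therapy** — no screening, every patient receives prophylaxis;
  ``X = N * r * (1 - e)``.

Scenario cost accounting: the screening cost is paid by all patients, the
therapy cost only by expected test positives (or by everyone under
all-therapy). Per-patient total cost is affine in the complication cost
``C``:

    cost(C) = S + A + X * C / N

The *break-even point* of a scenario is the ``C`` at which its per-patient
cost equals baseline's; the *ICER* is the incremental cost per avoided
complication at a given ``C``, and satisfies the identity
``ICER = C_break_even - C``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._rounding import round_to_thousand
from .core import BaselineRisk, ConditionPrediction, predict_conditions
from .exceptions import NoBreakEvenError, ValidationError
from .panel import ModelParams, Panel

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "BASELINE",
    "ALL_THERAPY",
    "full_panel_spec",
    "evaluate_scenario",
    "break_even",
    "icer",
    "cost_sweep",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Which conditions are screened, or whether everyone is treated."""

    name: str
    screened_conditions: tuple[str, ...] = ()
    treat_all: bool = False

    def __post_init__(self) -> None:
        if self.treat_all and self.screened_conditions:
            raise ValidationError("treat_all scenarios cannot also screen")


BASELINE = ScenarioSpec("Baseline")
ALL_THERAPY = ScenarioSpec("All therapy", treat_all=True)


def full_panel_spec(panel: Panel) -> ScenarioSpec:
    return ScenarioSpec("Full panel", screened_conditions=panel.names)


@dataclass(frozen=True)
class ScenarioResult:
    """Per-patient costs and expected complications of one scenario.

    ``screening_cost`` (S) and ``therapy_cost`` (A) are per patient;
    ``expected_complications`` (X) is the unrounded cohort expectation.
    """

    spec: ScenarioSpec
    screening_cost: float
    therapy_cost: float
    expected_complications: float
    cohort_size: int

    def cost_per_patient_at(self, complication_cost: float) -> float:
        """Total per-patient cost as a function of the complication cost."""
        return (
            self.screening_cost
            + self.therapy_cost
            + self.expected_complications * complication_cost / self.cohort_size
        )

    @property
    def fixed_cost(self) -> float:
        return self.screening_cost + self.therapy_cost


def evaluate_scenario(
    spec: ScenarioSpec,
    panel: Panel,
    params: ModelParams,
    baseline: BaselineRisk,
    predictions: Sequence[ConditionPrediction] | None = None,
) -> ScenarioResult:
    """Compute a scenario's per-patient costs and expected complications."""
    n = params.cohort_size
    r = params.complication_rate
    e = params.therapy_efficacy
    if spec.treat_all:
        s_cost, a_cost = 0.0, params.therapy_cost
        x = n * r * (1.0 - e)
    elif not spec.screened_conditions:
        s_cost, a_cost, x = 0.0, 0.0, n * r
    else:
        sub = panel.subset(spec.screened_conditions)  # validates names
        if predictions is None:
            predictions = predict_conditions(panel, params, baseline)
        by_name = {p.name: p for p in predictions}
        s_cost = sub.panel_cost
        a_cost = params.therapy_cost * sum(
            c.prevalence * c.sensitivity for c in sub
        )
        detected = sum(by_name[name].detected_complications for name in sub.names)
        x = n * r - e * detected
    return ScenarioResult(
        spec=spec,
        screening_cost=s_cost,
        therapy_cost=a_cost,
        expected_complications=x,
        cohort_size=n,
    )


def break_even(
    scenario: ScenarioResult, baseline: ScenarioResult, params: ModelParams
) -> tuple[float, int]:
    """Complication cost at which the scenario's cost equals baseline's.

    Returns the unrounded value and the value rounded half up to the
    nearest $1000 (the reporting granularity).
    """
    averted = baseline.expected_complications - scenario.expected_complications
    if averted <= 0:
        raise NoBreakEvenError(
            f"{scenario.spec.name!r} averts no complications relative to "
            f"{baseline.spec.name!r}: no break-even exists"
        )
    incremental_fixed = scenario.fixed_cost - baseline.fixed_cost
    c_star = incremental_fixed / (averted / scenario.cohort_size)
    return c_star, round_to_thousand(c_star)


def icer(
    scenario: ScenarioResult, baseline: ScenarioResult, params: ModelParams
) -> float:
    """Incremental cost per avoided complication at ``params.complication_cost``.

    Equal to the unrounded break-even point minus the complication cost.
    """
    averted = baseline.expected_complications - scenario.expected_complications
    if averted <= 0:
        raise NoBreakEvenError(
            f"{scenario.spec.name!r} averts no complications relative to "
            f"{baseline.spec.name!r}: ICER undefined"
        )
    n = scenario.cohort_size
    incremental_total = (
        n * (scenario.fixed_cost - baseline.fixed_cost)
        - averted * params.complication_cost
    )
    return incremental_total / averted


def cost_sweep(
    scenarios: Sequence[ScenarioResult], c_grid: Sequence[float]
) -> pd.DataFrame:
    """Per-patient cost of each scenario across a grid of complication costs.

    Each scenario's line is affine in the complication cost with slope
    ``X / N``; break-even points are the crossings with the baseline line.
    """
    c_grid = list(c_grid)
    if not c_grid:
        raise ValidationError("cost grid must be nonempty")
    if any(c < 0 for c in c_grid):
        raise ValidationError("cost grid values must be nonnegative")
    return pd.DataFrame(
        {"complication_cost": c_grid}
        | {
            s.spec.name: [s.cost_per_patient_at(c) for c in c_grid]
            for s in scenarios
        }
    )
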