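"""Screening decision model and its fitted results.

:class:`ScreeningModel` bundles a thrombophilia panel with cohort-level
assumptions; :meth:`ScreeningModel.fit` calibrates the baseline per-case
thrombosis risk to the observed complication rate and returns a
:class:`ScreeningResults` carrying the per-condition predictions, the
attributable-risk summary, scenario evaluations, break-even and ICER
analyses, a Monte-Carlo simulator and a break-even plot.

Example
-------
>>> from thromboflap import ScreeningModel, datasets
>>> model = ScreeningModel(datasets.load_panel(), datasets.load_params())
>>> res = model.fit()
>>> round(res.p0, 5)
0.01798
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from ._rounding import round_half_up, round_to_int
from .core import (
    BaselineRisk,
    ConditionPrediction,
    SOLVER_TOL,
    attributable_summary,
    predict_conditions,
    predictions_frame,
    select_limited_panel,
    solve_baseline_risk,
    total_test_positive,
)
from .exceptions import ValidationError
from .panel import ModelParams, Panel, read_panel_csv
from .scenarios import (
    ALL_THERAPY,
    BASELINE,
    ScenarioResult,
    ScenarioSpec,
    break_even,
    cost_sweep,
    evaluate_scenario,
    full_panel_spec,
    icer,
)

__all__ = ["ScreeningModel", "ScreeningResults"]


class ScreeningModel:
    """Decision model for preoperative thrombophilia screening.

    Parameters
    ----------
    panel : Panel
        The thrombophilia conditions under consideration.
    params : ModelParams
        Cohort-level assumptions (size, observed complication rate, risk
        cap, therapy cost and efficacy, complication cost).
    """

    def __init__(self, panel: Panel, params: ModelParams | None = None):
        self.panel = panel
        self.params = params if params is not None else ModelParams()

    @classmethod
    def from_dataframe(
        cls, panel_df: pd.DataFrame, params: ModelParams | None = None
    ) -> "ScreeningModel":
        """Build from a DataFrame with fraction-unit columns
        ``name, prevalence, relative_risk, sensitivity, assay_cost``."""
        from .panel import Condition

        required = {"name", "prevalence", "relative_risk", "sensitivity", "assay_cost"}
        missing = required - set(panel_df.columns)
        if missing:
            raise ValidationError(f"panel frame missing columns: {sorted(missing)}")
        panel = Panel(
            tuple(
                Condition(
                    name=str(r["name"]),
                    prevalence=float(r["prevalence"]),
                    relative_risk=float(r["relative_risk"]),
                    sensitivity=float(r["sensitivity"]),
                    assay_cost=float(r["assay_cost"]),
                )
                for _, r in panel_df.iterrows()
            )
        )
        return cls(panel, params)

    @classmethod
    def from_csv(
        cls, panel_path, params: ModelParams | None = None
    ) -> "ScreeningModel":
        """Build from a percent-unit panel CSV."""
        return cls(read_panel_csv(panel_path), params)

    def fit(self, tol: float = SOLVER_TOL) -> "ScreeningResults":
        """Calibrate the baseline risk and derive all cohort expectations."""
        baseline = solve_baseline_risk(self.panel, self.params, tol=tol)
        predictions = predict_conditions(self.panel, self.params, baseline)
        return ScreeningResults(self, baseline, predictions)


class ScreeningResults:
    """Fitted screening model: calibrated risk and everything derived from it."""

    def __init__(
        self,
        model: ScreeningModel,
        baseline_risk: BaselineRisk,
        predictions: Sequence[ConditionPrediction],
    ):
        self.model = model
        self.baseline_risk = baseline_risk
        self.predictions = list(predictions)

    # -- calibration ----------------------------------------------------
    @property
    def p0(self) -> float:
        """Baseline per-case thrombosis risk of a patient with no condition."""
        return self.baseline_risk.p0

    @property
    def cap_active(self) -> frozenset[str]:
        """Conditions whose per-carrier risk hit the cap."""
        return self.baseline_risk.cap_active

    @property
    def panel(self) -> Panel:
        return self.model.panel

    @property
    def params(self) -> ModelParams:
        return self.model.params

    # -- cohort expectations --------------------------------------------
    def predictions_frame(self) -> pd.DataFrame:
        return predictions_frame(self.predictions)

    @property
    def total_test_positive(self) -> float:
        """Expected screen-positive patients under the full panel, unrounded."""
        return total_test_positive(self.panel, self.params)

    def attributable(self, detected: bool = True) -> tuple[float, float]:
        """(attributable fraction, absolute rate) of complications due to
        thrombophilia; on detected complications by default."""
        return attributable_summary(self.predictions, self.params, detected=detected)

    def limited_panel(
        self, k: int | None = None, capture_target: float | None = None
    ) -> Panel:
        """Cheaper sub-panel ranked by predicted detected complications."""
        return select_limited_panel(
            self.predictions, self.panel, k=k, capture_target=capture_target
        )

    def capture_fraction(self, sub: Panel) -> float:
        """Share of detected complications a sub-panel would capture."""
        by_name = {p.name: p.detected_complications for p in self.predictions}
        total = sum(by_name.values())
        return sum(by_name[n] for n in sub.names) / total if total else 0.0

    # -- scenarios ------------------------------------------------------
    def scenario(self, spec: ScenarioSpec) -> ScenarioResult:
        return evaluate_scenario(
            spec, self.panel, self.params, self.baseline_risk, self.predictions
        )

    def standard_scenarios(
        self, limited_k: int = 5
    ) -> Mapping[str, ScenarioResult]:
        """The four canonical scenarios: baseline, full panel, limited
        panel (top ``limited_k`` conditions), all therapy."""
        limited = self.limited_panel(k=limited_k)
        specs = [
            BASELINE,
            full_panel_spec(self.panel),
            ScenarioSpec("Limited panel", screened_conditions=limited.names),
            ALL_THERAPY,
        ]
        return {s.name: self.scenario(s) for s in specs}

    def break_even(self, scenario: ScenarioResult) -> tuple[float, int]:
        """(unrounded, nearest-$1000) break-even complication cost vs baseline."""
        return break_even(scenario, self.scenario(BASELINE), self.params)

    def icer(self, scenario: ScenarioResult) -> float:
        """Incremental cost per avoided complication vs baseline."""
        return icer(scenario, self.scenario(BASELINE), self.params)

    def cost_sweep(
        self, c_grid: Sequence[float], limited_k: int = 5
    ) -> pd.DataFrame:
        return cost_sweep(
            list(self.standard_scenarios(limited_k=limited_k).values()), c_grid
        )

    def scenario_table(self, limited_k: int = 5) -> pd.DataFrame:
        """Scenario summary: costs, complications, break-even and ICER."""
        rows = []
        base = self.scenario(BASELINE)
        for name, res in self.standard_scenarios(limited_k=limited_k).items():
            row = {
                "scenario": name,
                "screening_cost_per_patient": res.screening_cost,
                "therapy_cost_per_patient": res.therapy_cost,
                "cost_per_patient": res.cost_per_patient_at(
                    self.params.complication_cost
                ),
                "expected_complications": res.expected_complications,
                "expected_complications_display": round_to_int(
                    res.expected_complications
                ),
            }
            if name == base.spec.name:
                row["break_even"] = None
                row["icer"] = None
            else:
                _, reported = self.break_even(res)
                row["break_even"] = reported
                row["icer"] = round_half_up(self.icer(res))
            rows.append(row)
        return pd.DataFrame(rows)

    # -- simulation and plotting ----------------------------------------
    def simulate(
        self,
        n_patients: int,
        seed: int,
        scenario: ScenarioSpec = BASELINE,
        n_replicates: int = 1,
    ):
        """Monte-Carlo simulation of the fitted model under one scenario."""
        from .microsim import SimConfig, simulate_cohort

        return simulate_cohort(
            SimConfig(
                seed=seed,
                n_patients=n_patients,
                panel=self.panel,
                params=self.params,
                scenario=scenario,
                baseline=self.baseline_risk,
                n_replicates=n_replicates,
            )
        )

    def plot_break_even(self, c_max: float = 70_000.0, n_points: int = 141, ax=None):
        """Per-patient cost vs complication cost for the four scenarios."""
        import numpy as np

        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        grid = np.linspace(0.0, c_max, n_points)
        sweep = self.cost_sweep(grid)
        for col in sweep.columns[1:]:
            ax.plot(sweep["complication_cost"], sweep[col], label=col)
        ax.set_xlabel("Cost of thrombotic complication ($ per patient)")
        ax.set_ylabel("Total cost per patient ($)")
        ax.legend()
        return ax

    # -- reporting ------------------------------------------------------
    def summary(self, limited_k: int = 5) -> str:
        """Human-readable summary of calibration, panel predictions and
        scenario economics."""
        p = self.params
        af, ar = self.attributable()
        lines = [
            "Thrombophilia screening decision model",
            "=" * 54,
            f"Cohort size                      {p.cohort_size:>10,d}",
            f"Observed complication rate       {p.complication_rate:>10.3%}",
            f"Baseline per-case risk p0        {self.p0:>10.5f}",
            f"Risk cap active for              {', '.join(sorted(self.cap_active)) or 'none'}",
            f"Balance residual                 {self.baseline_risk.residual:>10.2e}",
            "",
            f"Expected screen positives        {self.total_test_positive:>10.1f}"
            f"  (displayed {round_to_int(self.total_test_positive)})",
            f"Attributable fraction            {af:>10.1%}",
            f"Absolute attributable rate       {ar:>10.1%}",
            "",
            "Per-condition predictions (unrounded):",
            self.predictions_frame().to_string(
                index=False, float_format=lambda x: f"{x:,.2f}"
            ),
            "",
            "Scenario economics (break-even to nearest $1000):",
            self.scenario_table(limited_k=limited_k).to_string(
                index=False, float_format=lambda x: f"{x:,.2f}"
            ),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ScreeningResults p0={self.p0:.5f} "
            f"conditions={len(self.panel)} cap_active={sorted(self.cap_active)}>"
        )
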